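"""QSAR regressors for log efflux ratios and log Kp,uu,brain.

Two algorithms, both on log10-transformed responses:

* random forest regression, 400 trees by default, no further tuning;
* a Gaussian process with an automatic-relevance-determination (ARD) kernel

      k(x, x') = theta1 * exp(-sum_i (x_i - x'_i)^2 / (2 * gamma_i^2)) + theta2

  plus observation-noise variance theta3 on the diagonal.  theta1 is the
  overall property scale, theta2 a constant shift of the function away from
  zero, and the per-descriptor length scales gamma_i express feature
  relevance: a small gamma_i means differences in descriptor i move the
  predicted property strongly.  Hyperparameters maximize the log marginal
  likelihood by gradient ascent with restarts.

Measured efflux ratios can enter the Kp,uu models as extra features in four
configurations (none / MDR1 only / BCRP only / both); they are used as
log10(ER), standardized on the training rows like any other column, and a
two-stage variant substitutes in-silico ER predictions for the measured
values at prediction time.
"""

from __future__ import annotations

import enum
import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as _sopt
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .features import DescriptorMatrix


class Algorithm(str, enum.Enum):
    RF = "rf"
    GP = "gp"


class Response(str, enum.Enum):
    LOG_ER_MDR1 = "log_er_mdr1"
    LOG_ER_BCRP = "log_er_bcrp"
    LOG_KPUU = "log_kpuu"


class ERFeatures(str, enum.Enum):
    NONE = "none"
    MDR1_ONLY = "mdr1_only"
    BCRP_ONLY = "bcrp_only"
    BOTH = "both"

    @property
    def columns(self) -> tuple[str, ...]:
        return {
            ERFeatures.NONE: (),
            ERFeatures.MDR1_ONLY: ("log_er_mdr1",),
            ERFeatures.BCRP_ONLY: ("log_er_bcrp",),
            ERFeatures.BOTH: ("log_er_mdr1", "log_er_bcrp"),
        }[self]


class ERSource(str, enum.Enum):
    MEASURED = "measured"
    PREDICTED_IN_SILICO = "predicted_in_silico"


@dataclass(frozen=True)
class ModelSpec:
    algorithm: Algorithm = Algorithm.GP
    response: Response = Response.LOG_KPUU
    er_features: ERFeatures = ERFeatures.NONE
    er_source: ERSource = ERSource.MEASURED
    n_trees: int = 400
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response is not Response.LOG_KPUU and self.er_features is not ERFeatures.NONE:
            # ER features are meaningless for ER-response models
            object.__setattr__(self, "er_features", ERFeatures.NONE)
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")


@dataclass(frozen=True)
class GPHyperparams:
    theta1: float
    theta2: float
    theta3: float
    gamma: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.gamma) <= 0):
            raise ValueError("length scales must be positive")


class SchemaMismatchError(ValueError):
    pass


@dataclass
class TrainedModel:
    """A fitted regressor plus the feature schema it expects.

    ``feature_names`` is the exact column order (descriptors first, then any
    ER feature columns); prediction inputs must match it.  ``er_scaling``
    holds the training mean/sd applied to each ER feature column.
    """

    spec: ModelSpec
    feature_names: tuple[str, ...]
    estimator: object
    er_scaling: dict[str, tuple[float, float]]
    y_train_range: tuple[float, float]
    nlml_trace: tuple[float, ...] = ()

    def artifact_hash(self) -> str:
        """Stable hash of everything the fit learned."""
        h = hashlib.sha256()
        for n in self.feature_names:
            h.update(n.encode())
        for k, (mu, sd) in sorted(self.er_scaling.items()):
            h.update(f"{k}:{mu:.12e}:{sd:.12e}".encode())
        est = self.estimator
        if isinstance(est, GaussianProcessRegressor):
            h.update(np.ascontiguousarray(est.kernel_.theta).tobytes())
            h.update(np.ascontiguousarray(est.alpha_).tobytes())
        else:
            h.update(np.ascontiguousarray(est.feature_importances_).tobytes())
            preds = est.predict(np.zeros((1, len(self.feature_names))))
            h.update(np.ascontiguousarray(preds).tobytes())
        return h.hexdigest()


def _assemble(X: DescriptorMatrix | pd.DataFrame, extra: pd.DataFrame | None,
              spec: ModelSpec,
              er_scaling: dict[str, tuple[float, float]] | None = None,
              ) -> tuple[np.ndarray, tuple[str, ...], dict[str, tuple[float, float]]]:
    """Stack descriptor columns with (standardized) log10 ER feature columns."""
    if isinstance(X, DescriptorMatrix):
        frame = X.to_frame()
    else:
        frame = X
    blocks = [frame.to_numpy(dtype=float)]
    names = list(map(str, frame.columns))
    scaling = dict(er_scaling or {})
    for col in spec.er_features.columns:
        if extra is None or col not in extra.columns:
            raise ValueError(f"spec requires ER feature column '{col}'")
        v = extra[col].to_numpy(dtype=float)
        if col not in scaling:
            sd = v.std(ddof=1) if v.size > 1 else 1.0
            scaling[col] = (float(v.mean()), float(sd if sd > 0 else 1.0))
        mu, sd = scaling[col]
        blocks.append(((v - mu) / sd)[:, None])
        names.append(col)
    return np.hstack(blocks), tuple(names), scaling


def _traced_optimizer(trace: list):
    def optimizer(obj_func, initial_theta, bounds):
        def fun(theta):
            val, grad = obj_func(theta, eval_gradient=True)
            trace.append(float(val))
            return val, grad

        res = _sopt.minimize(fun, initial_theta, jac=True, bounds=bounds,
                             method="L-BFGS-B", options={"maxiter": 120})
        return res.x, res.fun

    return optimizer


def _make_gp(n_features: int, spec: ModelSpec, trace: list) -> GaussianProcessRegressor:
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e4))
        * RBF(np.ones(n_features), (1e-2, 1e4))
        + ConstantKernel(0.1, (1e-8, 1e4))
        + WhiteKernel(0.1, (1e-10, 1e2))
    )
    return GaussianProcessRegressor(
        kernel=kernel,
        optimizer=_traced_optimizer(trace),
        n_restarts_optimizer=spec.n_restarts,
        normalize_y=True,
        random_state=spec.seed,
    )


def train(spec: ModelSpec, X: DescriptorMatrix | pd.DataFrame,
          extra: pd.DataFrame | None, y: np.ndarray) -> TrainedModel:
    """Fit the regressor named by ``spec`` on training rows.

    ``y`` is the log10-scale response.  ``extra`` supplies measured log10 ER
    columns when the spec asks for them.
    """
    features, names, er_scaling = _assemble(X, extra, spec)
    y = np.asarray(y, dtype=float)
    if features.shape[0] != y.size:
        raise ValueError("feature rows and response length differ")
    if features.shape[0] < 3:
        raise ValueError("at least 3 training rows are required")
    if not np.all(np.isfinite(features)):
        raise ValueError("NaN or infinite value in feature matrix")
    if not np.all(np.isfinite(y)):
        raise ValueError("NaN or infinite value in response")

    trace: list[float] = []
    if spec.algorithm is Algorithm.RF:
        est = RandomForestRegressor(
            n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1,
            bootstrap=True,
        )
        est.fit(features, y)
    else:
        est = _make_gp(features.shape[1], spec, trace)
        if float(np.ptp(y)) == 0.0:
            # degenerate constant response: marginal-likelihood surface is
            # flat in the length scales; fall back to a noise-only fit
            est.optimizer = None
        with warnings.catch_warnings():
            # an irrelevant feature's ARD length scale legitimately sits at
            # its upper bound; sklearn flags that as non-convergence
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(features, y)
    return TrainedModel(
        spec=spec, feature_names=names, estimator=est,
        er_scaling=er_scaling,
        y_train_range=(float(np.min(y)), float(np.max(y))),
        nlml_trace=tuple(trace),
    )


def _check_schema(model: TrainedModel, names: tuple[str, ...]) -> None:
    if names != model.feature_names:
        missing = [n for n in model.feature_names if n not in names]
        extra_cols = [n for n in names if n not in model.feature_names]
        raise SchemaMismatchError(
            f"feature schema mismatch: missing={missing}, unexpected={extra_cols}, "
            f"expected order={list(model.feature_names)}"
        )


def predict(model: TrainedModel, X_new: DescriptorMatrix | pd.DataFrame,
            extra: pd.DataFrame | None = None,
            *, return_std: bool = False):
    """Predict log-scale responses; for the GP optionally with predictive sd."""
    features, names, _ = _assemble(X_new, extra, model.spec, model.er_scaling)
    _check_schema(model, names)
    est = model.estimator
    if isinstance(est, GaussianProcessRegressor):
        if return_std:
            mean, std = est.predict(features, return_std=True)
            return np.asarray(mean, float), np.asarray(std, float)
        return np.asarray(est.predict(features), float)
    if return_std:
        raise ValueError("predictive variance is only available for the GP")
    return np.asarray(est.predict(features), float)


def gp_hyperparams(model: TrainedModel) -> GPHyperparams:
    est = model.estimator
    if not isinstance(est, GaussianProcessRegressor):
        raise ValueError("hyperparameters are defined for GP models only")
    k = est.kernel_
    prod, const2, white = k.k1.k1, k.k1.k2, k.k2
    return GPHyperparams(
        theta1=float(prod.k1.constant_value),
        theta2=float(const2.constant_value),
        theta3=float(white.noise_level),
        gamma=np.asarray(prod.k2.length_scale, dtype=float).reshape(-1),
    )


def top_features(model: TrainedModel, k: int = 20) -> list[tuple[str, float]]:
    """Rank features by influence.

    GP: ascending ARD length scale (smallest gamma = most influential).
    RF: descending impurity importance.  If ``k`` exceeds the feature count
    all features are returned.
    """
    est = model.estimator
    if isinstance(est, GaussianProcessRegressor):
        hp = gp_hyperparams(model)
        gamma = hp.gamma
        if gamma.size == 1:  # isotropic degenerate case
            gamma = np.repeat(gamma, len(model.feature_names))
        order = np.argsort(gamma, kind="stable")
        scored = [(model.feature_names[i], float(gamma[i])) for i in order]
    else:
        imp = est.feature_importances_
        order = np.argsort(-imp, kind="stable")
        scored = [(model.feature_names[i], float(imp[i])) for i in order]
    return scored[: min(k, len(scored))]


def predict_er_then_kpuu(
    er_models: dict[str, TrainedModel],
    kpuu_model: TrainedModel,
    X_new: DescriptorMatrix | pd.DataFrame,
) -> np.ndarray:
    """Two-stage in-silico pipeline: predict log ER from structure, then feed
    the predictions into a Kp,uu model trained with measured-ER features.

    Requires an ER model per transporter the Kp,uu model consumes.
    """
    needed = kpuu_model.spec.er_features.columns
    if not needed:
        raise ValueError("the Kp,uu model takes no ER features; nothing to substitute")
    key_of = {"log_er_mdr1": "mdr1", "log_er_bcrp": "bcrp"}
    extra = {}
    for col in needed:
        key = key_of[col]
        if key not in er_models:
            raise ValueError(f"missing in-silico ER model for {key}")
        extra[col] = predict(er_models[key], X_new)
    frame = X_new.to_frame() if isinstance(X_new, DescriptorMatrix) else X_new
    return predict(kpuu_model, X_new, pd.DataFrame(extra, index=frame.index))
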