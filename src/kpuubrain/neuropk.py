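"""Mechanistic neuroPK model of brain penetration.

At steady state, with MDR1 and BCRP as the only active transporters and
negligible bulk flow, the unbound brain-to-plasma partition coefficient is

    Kp,uu,brain = 1 / (1 + alpha * (ER_MDR1 - 1) + beta * (ER_BCRP - 1))

where ER_* are in vitro efflux ratios in transporter-overexpressing MDCK
monolayers and alpha, beta scale the in vitro efflux activity of each
transporter to its in vivo activity at the blood-brain barrier.  A passive
compound (both ER = 1) has Kp,uu = 1 by construction.

The two scaling factors are calibrated by nonlinear least squares against
observed Kp,uu,brain values, either in linear space or on log10 Kp,uu, with
95% confidence intervals from the asymptotic (Jacobian-based) covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

FitSpace = Literal["linear", "log10"]

#: Residual assigned to rows whose model denominator is nonpositive during
#: fitting; large enough to repel the optimizer without overflowing.
_PENALTY_RESIDUAL = 1e3


class ModelDomainError(ValueError):
    """The denominator 1 + alpha*(ER_M - 1) + beta*(ER_B - 1) is nonpositive."""


class UnidentifiableParametersError(ValueError):
    """The data cannot pin down both scaling factors (e.g. all ER equal 1)."""


@dataclass(frozen=True)
class NeuroPKParams:
    """Fitted scaling factors with diagnostics.

    ``alpha_ci95``/``beta_ci95`` are asymptotic 95% confidence intervals from
    the linearized covariance at the optimum with a t quantile on n - 2
    degrees of freedom.
    """

    alpha: float
    beta: float
    alpha_ci95: tuple[float, float] = (float("nan"), float("nan"))
    beta_ci95: tuple[float, float] = (float("nan"), float("nan"))
    n_fit: int = 0
    residual_sum_squares: float = float("nan")
    fit_space: FitSpace = "linear"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")
        for lo, hi in (self.alpha_ci95, self.beta_ci95):
            if np.isfinite(lo) and np.isfinite(hi) and lo > hi:
                raise ValueError("confidence bounds must be ordered")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "alpha_ci95": list(self.alpha_ci95),
            "beta_ci95": list(self.beta_ci95),
            "n": self.n_fit,
            "rss": self.residual_sum_squares,
            "fit_space": self.fit_space,
        }


def _denominator(er_mdr1, er_bcrp, alpha: float, beta: float):
    return 1.0 + alpha * (np.asarray(er_mdr1, dtype=float) - 1.0) + beta * (
        np.asarray(er_bcrp, dtype=float) - 1.0
    )


def predict_kpuu(er_mdr1, er_bcrp, params: NeuroPKParams | tuple[float, float],
                 *, min_denominator: float | None = None):
    """Model-predicted Kp,uu,brain for one compound or an array of compounds.

    Raises :class:`ModelDomainError` naming the offending row when the
    denominator is nonpositive (possible when an ER < 1 meets large scaling
    factors).  Passing ``min_denominator`` instead floors the denominator at
    that value, capping predictions at its reciprocal — the policy the
    evaluation pipeline uses so a single influx-like test compound cannot
    abort a whole run.
    """
    if isinstance(params, NeuroPKParams):
        alpha, beta = params.alpha, params.beta
    else:
        alpha, beta = params
    denom = _denominator(er_mdr1, er_bcrp, alpha, beta)
    bad = np.atleast_1d(denom <= 0)
    if bad.any():
        if min_denominator is None:
            idx = int(np.flatnonzero(bad)[0])
            raise ModelDomainError(
                f"nonpositive model denominator at row {idx} "
                f"(ER_MDR1={np.atleast_1d(er_mdr1)[idx]:.4g}, "
                f"ER_BCRP={np.atleast_1d(er_bcrp)[idx]:.4g}, "
                f"alpha={alpha:.4g}, beta={beta:.4g})"
            )
    if min_denominator is not None:
        if min_denominator <= 0:
            raise ValueError("min_denominator must be positive")
        denom = np.maximum(denom, min_denominator)
    result = 1.0 / denom
    if np.isscalar(er_mdr1) or np.ndim(er_mdr1) == 0:
        return float(result)
    return result


def _residuals(theta, er_m, er_b, kpuu_obs, fit_space: FitSpace):
    denom = _denominator(er_m, er_b, theta[0], theta[1])
    res = np.full(denom.shape, _PENALTY_RESIDUAL)
    ok = denom > 0
    pred = 1.0 / denom[ok]
    if fit_space == "linear":
        res[ok] = pred - kpuu_obs[ok]
    else:
        res[ok] = np.log10(pred) - np.log10(kpuu_obs[ok])
    return res


def _start_grid(start: tuple[float, float], n: int = 8) -> list[np.ndarray]:
    """Multi-start grid: the user start plus log-spaced scale perturbations."""
    scales = np.logspace(-1.5, 1.5, n - 1)
    starts = [np.asarray(start, dtype=float)]
    base = np.maximum(np.asarray(start, dtype=float), 1e-3)
    for i, s in enumerate(scales):
        # alternate which parameter gets the perturbation to cover the plane
        mult = np.array([s, scales[-(i + 1)]])
        starts.append(base * mult)
    return starts


def fit_scaling_factors(
    er_mdr1: Sequence[float],
    er_bcrp: Sequence[float],
    kpuu_observed: Sequence[float],
    *,
    fit_space: FitSpace = "linear",
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, np.inf), (0.0, np.inf)),
    start: tuple[float, float] = (1.0, 1.0),
) -> NeuroPKParams:
    """Fit (alpha, beta) by nonlinear least squares.

    Parameters
    ----------
    fit_space
        ``"linear"`` minimizes (pred - obs)^2 on Kp,uu itself (default);
        ``"log10"`` minimizes squared log10 residuals, matching the scale on
        which evaluation metrics are computed.
    bounds
        Per-parameter (low, high); both scaling factors are nonnegative by
        default, reflecting that efflux can only lower Kp,uu.
    start
        Initial (alpha, beta); seven additional log-spaced starts guard
        against local minima, best residual sum of squares wins, ties broken
        by the smaller parameter norm.
    """
    er_m = np.asarray(er_mdr1, dtype=float)
    er_b = np.asarray(er_bcrp, dtype=float)
    y = np.asarray(kpuu_observed, dtype=float)
    if not (er_m.shape == er_b.shape == y.shape):
        raise ValueError("input arrays must have equal length")
    n = y.size
    if n < 3:
        raise ValueError("at least 3 usable rows are required")
    if np.any(y <= 0):
        raise ValueError("all observed Kp,uu values must be positive")

    var_m = np.ptp(er_m)
    var_b = np.ptp(er_b)
    if var_m == 0 and var_b == 0 and np.all(er_m == 1) and np.all(er_b == 1):
        raise UnidentifiableParametersError(
            "all efflux ratios equal 1: both scaling factors drop out of the model"
        )

    lo = np.array([bounds[0][0], bounds[1][0]])
    hi = np.array([bounds[0][1], bounds[1][1]])
    # a degenerate bound pair (lo == hi) pins that scaling factor
    free = lo < hi
    fixed_vals = lo.copy()
    if not free.any():
        raise ValueError("both scaling factors are fixed by the bounds")

    def expand(theta_free):
        full = fixed_vals.copy()
        full[free] = theta_free
        return full

    def residuals_free(theta_free, *args):
        return _residuals(expand(theta_free), *args)

    best = None
    for x0 in _start_grid(start):
        x0 = np.clip(x0, lo, np.where(np.isfinite(hi), hi, x0))[free]
        sol = optimize.least_squares(
            residuals_free, x0, bounds=(lo[free], hi[free]),
            args=(er_m, er_b, y, fit_space),
            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        rss = float(2 * sol.cost)
        if best is None or rss < best[0] - 1e-15 or (
            abs(rss - best[0]) <= 1e-15 and np.linalg.norm(sol.x) < np.linalg.norm(best[1].x)
        ):
            best = (rss, sol)
    rss, sol = best
    if not sol.success:
        raise RuntimeError(f"nonlinear least squares failed to converge: {sol.message}")

    alpha, beta = expand(sol.x)
    dof = max(n - int(free.sum()), 1)
    sigma2 = rss / dof
    J = sol.jac
    JtJ = J.T @ J
    tq = stats.t.ppf(0.975, dof)
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
        se_free = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_free = np.full(int(free.sum()), np.inf)
    # Near-singular Jacobian (e.g. one transporter never varies): the
    # corresponding CI is reported unbounded rather than spuriously tight.
    cond = np.linalg.cond(JtJ)
    if cond > 1e12:
        se_free = np.where(np.diag(JtJ) < 1e-12 * np.max(np.diag(JtJ)),
                           np.inf, se_free)
    se = np.zeros(2)
    se[free] = se_free
    return NeuroPKParams(
        alpha=float(alpha),
        beta=float(beta),
        alpha_ci95=(float(alpha - tq * se[0]), float(alpha + tq * se[0])),
        beta_ci95=(float(beta - tq * se[1]), float(beta + tq * se[1])),
        n_fit=n,
        residual_sum_squares=rss,
        fit_space=fit_space,
    )
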