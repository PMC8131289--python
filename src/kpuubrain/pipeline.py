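"""End-to-end orchestration of the neuroPK vs machine-learning comparison.

Given a canonical compound table and a descriptor matrix, the pipeline

1. derives Kp,uu,brain through the assay-arithmetic chain (dilution-corrected
   unbound fractions, later-time-point Kp,uu, steady-state 2-fold flag);
2. builds a cluster split and a time split;
3. fits the mechanistic neuroPK scaling factors on the training rows of each
   split and predicts the test rows;
4. trains RF and GP regressors for log Kp,uu under the four ER-feature
   configurations (and for the two log ER responses), training-rows only for
   descriptor exclusion, scaling and hyperparameters;
5. evaluates everything on the held-out rows (R^2, RMSE, % within 2-fold on
   the linear scale) with paired squared-error tests against the neuroPK
   predictions, and emits a JSON-serializable report grid plus a run
   manifest with artifact hashes for leakage auditing.

All randomness flows from ``RunConfig.seed``; two runs with the same inputs
and seed produce byte-identical reports.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import assays, neuropk, validation
from .features import DescriptorMatrix, prepare_descriptors
from .mlmodels import (
    Algorithm,
    ERFeatures,
    ERSource,
    ModelSpec,
    Response,
    TrainedModel,
    predict,
    predict_er_then_kpuu,
    train,
)


#: Denominator floor for neuroPK predictions during evaluation: caps the
#: predicted Kp,uu at 1000 when an influx-like test compound (both ER < 1)
#: meets large fitted scaling factors.
MIN_PREDICT_DENOMINATOR = 1e-3


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    fit_space: neuropk.FitSpace = "linear"
    algorithms: tuple[str, ...] = ("rf", "gp")
    er_feature_configs: tuple[str, ...] = ("none", "mdr1_only", "bcrp_only", "both")
    splits: tuple[str, ...] = ("cluster", "time")
    include_er_response_models: bool = True
    include_in_silico_er_variant: bool = False
    drop_fu_flagged: bool = True
    drop_steady_state_failures: bool = False
    test_fraction: float = 0.2
    tanimoto_threshold: float = validation.DEFAULT_TANIMOTO_THRESHOLD
    n_trees: int = 400
    gp_restarts: int = 3


@dataclass
class RunResult:
    report: dict
    manifest: dict
    models: dict = field(repr=False, default_factory=dict)
    splits: dict = field(repr=False, default_factory=dict)
    neuropk_fits: dict = field(default_factory=dict)

    def report_json(self) -> str:
        return json.dumps(self.report, sort_keys=True, indent=2)


def _package_versions() -> dict:
    import sklearn
    import scipy
    versions = {"numpy": np.__version__, "pandas": pd.__version__,
                "scipy": scipy.__version__, "scikit-learn": sklearn.__version__}
    try:
        import rdkit
        versions["rdkit"] = rdkit.__version__
    except ImportError:  # pragma: no cover
        pass
    return versions


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _log_er_frame(table: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "log_er_mdr1": np.log10(table["er_mdr1"].to_numpy(float)),
        "log_er_bcrp": np.log10(table["er_bcrp"].to_numpy(float)),
    }, index=table.index)


def derive_and_filter(table: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Assay arithmetic plus the default row exclusions; returns the derived
    table and per-stage row-count deltas for the manifest."""
    derived = assays.derive_table(table)
    counts = {"input_rows": int(len(derived))}
    if config.drop_fu_flagged:
        derived = derived[~derived["fu_flag"]]
    counts["after_fu_flag"] = int(len(derived))
    if config.drop_steady_state_failures:
        derived = derived[derived["steady_state_ok"]]
    counts["after_steady_state"] = int(len(derived))
    return derived.reset_index(drop=True), counts


def build_splits(derived: pd.DataFrame, config: RunConfig,
                 cluster_ids=None, structures=None) -> dict[str, validation.SplitAssignment]:
    y_log = np.log10(derived["kpuu"].to_numpy(float))
    splits: dict[str, validation.SplitAssignment] = {}
    if "cluster" in config.splits:
        if cluster_ids is None and structures is None:
            smiles = derived["smiles"].fillna("")
            if (smiles == "").any():
                raise ValueError(
                    "cluster split needs SMILES or precomputed cluster ids"
                )
            structures = list(smiles)
        splits["cluster"] = validation.cluster_split(
            structures, y_log,
            test_fraction=config.test_fraction,
            tanimoto_threshold=config.tanimoto_threshold,
            seed=config.seed,
            cluster_ids=cluster_ids,
        )
    if "time" in config.splits:
        splits["time"] = validation.time_split(
            derived["assay_date"], train_fraction=1.0 - config.test_fraction
        )
    return splits


def _fit_neuropk_on(derived: pd.DataFrame, idx: np.ndarray,
                    config: RunConfig) -> neuropk.NeuroPKParams:
    sub = derived.iloc[idx]
    return neuropk.fit_scaling_factors(
        sub["er_mdr1"], sub["er_bcrp"], sub["kpuu"], fit_space=config.fit_space,
    )


def run_comparison(table: pd.DataFrame, descriptors: pd.DataFrame,
                   config: RunConfig = RunConfig(), *,
                   cluster_ids=None, structures=None,
                   splits: dict[str, validation.SplitAssignment] | None = None,
                   count_type: dict[str, bool] | None = None) -> RunResult:
    """Run the full comparison.

    Parameters
    ----------
    table
        Canonical compound table (see synth.CANONICAL_COLUMNS).
    descriptors
        Numeric descriptor frame indexed like ``table`` rows (compound_id
        index or positional alignment).
    cluster_ids
        Optional precomputed structural-cluster labels (e.g. scaffold
        families for abstract synthetic compounds).
    splits
        Optional precomputed split assignments keyed by method; when given
        they are used verbatim (the leakage audit relies on this).
    """
    derived, row_counts = derive_and_filter(table, config)
    keep_ids = set(derived["compound_id"])
    if descriptors.index.dtype == object and set(map(str, descriptors.index)) >= keep_ids:
        desc = descriptors.loc[list(derived["compound_id"])]
    else:
        mask = table["compound_id"].isin(keep_ids).to_numpy()
        desc = descriptors.iloc[mask]
    if cluster_ids is not None:
        cluster_ids = np.asarray(cluster_ids)[table["compound_id"].isin(keep_ids).to_numpy()]

    y_log = np.log10(derived["kpuu"].to_numpy(float))
    er_frame = _log_er_frame(derived)
    if splits is None:
        splits = build_splits(derived, config, cluster_ids=cluster_ids,
                              structures=structures)

    report: dict = {"splits": {}, "config": asdict(config)}
    models: dict = {}
    fits: dict = {}
    artifact_hashes: dict = {}

    for split_name, assignment in splits.items():
        tr, te = assignment.train_idx, assignment.test_idx
        split_report: dict = {
            "n_train": int(tr.size), "n_test": int(te.size),
            "params": dict(assignment.params),
        }

        # --- mechanistic arm -------------------------------------------------
        params = _fit_neuropk_on(derived, tr, config)
        fits[split_name] = params
        pred_test = neuropk.predict_kpuu(
            derived["er_mdr1"].to_numpy(float)[te],
            derived["er_bcrp"].to_numpy(float)[te], params,
            min_denominator=MIN_PREDICT_DENOMINATOR)
        npk_pred_log = np.log10(pred_test)
        npk_report = validation.evaluate(y_log[te], npk_pred_log)
        split_report["neuropk"] = {"fit": params.to_dict(),
                                   "metrics": npk_report.to_dict()}
        artifact_hashes[f"{split_name}/neuropk"] = _hash_obj(params.to_dict())

        # --- descriptor preparation (training rows only) ---------------------
        dm = prepare_descriptors(desc, y_log, tr, count_type=count_type)
        artifact_hashes[f"{split_name}/descriptor_schema"] = dm.schema_hash()
        artifact_hashes[f"{split_name}/descriptor_scaling"] = _hash_obj(
            {k: list(v) for k, v in dm.scaling_params.items()})
        frame_all = dm.to_frame()
        X_tr = frame_all.iloc[tr]
        X_te = frame_all.iloc[te]

        # --- ML arm ----------------------------------------------------------
        ml_report: dict = {}
        for alg in config.algorithms:
            ml_report[alg] = {}
            for er_cfg in config.er_feature_configs:
                spec = ModelSpec(
                    algorithm=Algorithm(alg), response=Response.LOG_KPUU,
                    er_features=ERFeatures(er_cfg), n_trees=config.n_trees,
                    n_restarts=config.gp_restarts, seed=config.seed,
                )
                model = train(spec, X_tr, er_frame.iloc[tr], y_log[tr])
                key = f"{split_name}/{alg}/{er_cfg}"
                models[key] = model
                artifact_hashes[key] = model.artifact_hash()
                pred_log = predict(model, X_te, er_frame.iloc[te])
                rep = validation.evaluate(y_log[te], pred_log,
                                          comparator_pred_log=npk_pred_log)
                ml_report[alg][er_cfg] = rep.to_dict()
        split_report["ml"] = ml_report

        # --- ER-response models ---------------------------------------------
        if config.include_er_response_models:
            er_rep: dict = {}
            for alg in config.algorithms:
                er_rep[alg] = {}
                for resp, col in (("mdr1", "log_er_mdr1"), ("bcrp", "log_er_bcrp")):
                    spec = ModelSpec(
                        algorithm=Algorithm(alg),
                        response=Response(f"log_er_{resp}"),
                        n_trees=config.n_trees, n_restarts=config.gp_restarts,
                        seed=config.seed,
                    )
                    y_er = er_frame[col].to_numpy(float)
                    model = train(spec, X_tr, None, y_er[tr])
                    key = f"{split_name}/er/{alg}/{resp}"
                    models[key] = model
                    artifact_hashes[key] = model.artifact_hash()
                    pred_log = predict(model, X_te)
                    er_rep[alg][resp] = validation.evaluate(
                        y_er[te], pred_log).to_dict()
            split_report["er_models"] = er_rep

        # --- in-silico-ER Kp,uu variant --------------------------------------
        if (config.include_in_silico_er_variant
                and config.include_er_response_models
                and "both" in config.er_feature_configs):
            variant: dict = {}
            for alg in config.algorithms:
                er_models = {
                    "mdr1": models[f"{split_name}/er/{alg}/mdr1"],
                    "bcrp": models[f"{split_name}/er/{alg}/bcrp"],
                }
                kpuu_model = models[f"{split_name}/{alg}/both"]
                pred_log = predict_er_then_kpuu(er_models, kpuu_model, X_te)
                rep = validation.evaluate(y_log[te], pred_log,
                                          comparator_pred_log=npk_pred_log)
                d = rep.to_dict()
                d["er_source"] = ERSource.PREDICTED_IN_SILICO.value
                variant[alg] = d
            split_report["ml_in_silico_er"] = variant

        report["splits"][split_name] = split_report

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": _package_versions(),
        "row_counts": row_counts,
        "split_sizes": {k: {"train": int(v.train_idx.size),
                            "test": int(v.test_idx.size)}
                        for k, v in splits.items()},
        "artifact_hashes": artifact_hashes,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    return RunResult(report=report, manifest=manifest, models=models,
                     splits=splits, neuropk_fits=fits)


def learning_curve(table: pd.DataFrame, descriptors: pd.DataFrame,
                   train_sizes: list[int],
                   config: RunConfig = RunConfig(),
                   *, n_repeats: int = 3,
                   algorithm: str = "gp",
                   er_features: str = "both",
                   cluster_ids=None,
                   count_type: dict[str, bool] | None = None) -> dict:
    """Test R^2 of the ML model vs the neuroPK model as training data grows.

    The test set is fixed (cluster split); at each size the training rows are
    subsampled ``n_repeats`` times and both arms are refit on the subsample.
    The mechanistic arm has only two parameters, so it wins at very small n;
    the flexible arm needs tens of compounds before catching up.
    """
    derived, _ = derive_and_filter(table, config)
    keep_ids = set(derived["compound_id"])
    mask = table["compound_id"].isin(keep_ids).to_numpy()
    desc = descriptors.iloc[mask]
    if cluster_ids is not None:
        cluster_ids = np.asarray(cluster_ids)[mask]
    y_log = np.log10(derived["kpuu"].to_numpy(float))
    er_frame = _log_er_frame(derived)
    assignment = build_splits(derived, config, cluster_ids=cluster_ids)["cluster"]
    tr_full, te = assignment.train_idx, assignment.test_idx

    results: dict = {"train_sizes": list(map(int, train_sizes)),
                     "algorithm": algorithm, "er_features": er_features,
                     "per_size": []}
    rng = np.random.default_rng(config.seed)
    for size in train_sizes:
        if size > tr_full.size:
            raise ValueError(f"train size {size} exceeds available rows {tr_full.size}")
        if size < 3:
            raise ValueError("train size must be at least 3")
        ml_r2s, npk_r2s = [], []
        for _rep in range(n_repeats):
            tr = np.sort(rng.choice(tr_full, size=size, replace=False))
            try:
                params = _fit_neuropk_on(derived, tr, config)
                npk_pred = neuropk.predict_kpuu(
                    derived["er_mdr1"].to_numpy(float)[te],
                    derived["er_bcrp"].to_numpy(float)[te], params,
                    min_denominator=MIN_PREDICT_DENOMINATOR)
                npk_r2s.append(validation.r_squared(y_log[te], np.log10(npk_pred)))
            except (ValueError, RuntimeError):
                npk_r2s.append(float("nan"))
            try:
                dm = prepare_descriptors(desc, y_log, tr, count_type=count_type)
                frame_all = dm.to_frame()
                spec = ModelSpec(algorithm=Algorithm(algorithm),
                                 er_features=ERFeatures(er_features),
                                 n_trees=config.n_trees,
                                 n_restarts=config.gp_restarts,
                                 seed=config.seed)
                model = train(spec, frame_all.iloc[tr], er_frame.iloc[tr], y_log[tr])
                pred = predict(model, frame_all.iloc[te], er_frame.iloc[te])
                ml_r2s.append(validation.r_squared(y_log[te], pred))
            except (ValueError, RuntimeError):
                ml_r2s.append(float("nan"))
        results["per_size"].append({
            "size": int(size),
            "ml_r2_mean": float(np.nanmean(ml_r2s)),
            "ml_r2_sd": float(np.nanstd(ml_r2s)),
            "neuropk_r2_mean": float(np.nanmean(npk_r2s)),
            "neuropk_r2_sd": float(np.nanstd(npk_r2s)),
        })
    return results


def crossing_size(curve: dict) -> int | None:
    """Smallest training size at which the ML mean test R^2 reaches the
    neuroPK mean test R^2, or None if it never does."""
    for entry in curve["per_size"]:
        if np.isfinite(entry["ml_r2_mean"]) and np.isfinite(entry["neuropk_r2_mean"]):
            if entry["ml_r2_mean"] >= entry["neuropk_r2_mean"]:
                return entry["size"]
    return None


def leakage_audit(table: pd.DataFrame, descriptors: pd.DataFrame,
                  config: RunConfig = RunConfig(), *,
                  cluster_ids=None,
                  count_type: dict[str, bool] | None = None,
                  perturbation: float = 10.0) -> dict:
    """Verify that no test-set row influences any trained artifact.

    The splits are computed once and frozen; one test row per split is then
    perturbed (descriptors, efflux ratios and observed concentrations) and
    the pipeline re-run with the frozen splits.  Every trained-artifact hash
    must be unchanged.
    """
    derived, _ = derive_and_filter(table, config)
    if cluster_ids is not None:
        keep = table["compound_id"].isin(set(derived["compound_id"])).to_numpy()
        frozen_cluster_ids = np.asarray(cluster_ids)[keep]
    else:
        frozen_cluster_ids = None
    splits = build_splits(derived, config, cluster_ids=frozen_cluster_ids)

    base = run_comparison(table, descriptors, config, cluster_ids=cluster_ids,
                          splits=splits, count_type=count_type)
    h0 = base.manifest["artifact_hashes"]

    # A row held out by one split may train the other, so each split is
    # audited with its own perturbed copy and re-run in isolation.
    id_to_table_row = {cid: i for i, cid in enumerate(table["compound_id"])}
    changed: list[str] = []
    for split_name, assignment in splits.items():
        table2 = table.copy()
        desc2 = descriptors.copy()
        victim_id = derived["compound_id"].iloc[assignment.test_idx[0]]
        row = id_to_table_row[victim_id]
        for col in ("er_mdr1", "er_bcrp", "c_brain_t1", "c_brain_t2"):
            table2.iloc[row, table2.columns.get_loc(col)] *= perturbation
        desc2.iloc[row] = desc2.iloc[row] + perturbation
        perturbed = run_comparison(
            table2, desc2, config, cluster_ids=cluster_ids,
            splits={split_name: assignment}, count_type=count_type)
        h1 = perturbed.manifest["artifact_hashes"]
        changed.extend(sorted(k for k in h1 if h0.get(k) != h1[k]))
    return {"clean": not changed, "changed_artifacts": changed,
            "n_artifacts": len(h0)}
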