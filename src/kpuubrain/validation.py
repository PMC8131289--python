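"""Train/test splitting and evaluation statistics.

Two splits probe two different questions:

* **cluster split** — leader (sphere-exclusion) clustering of binary
  fingerprints at a Tanimoto threshold keeps every structural cluster on one
  side; whole clusters are assigned to the test side greedily, stratified on
  quantile bins of the response, until the test set reaches the target
  fraction.  Estimates interpolation performance when similar scaffolds are
  seen in training.
* **time split** — the earliest 80% of compounds by assay date train, the
  rest test.  Estimates prospective performance on future chemistry.

Evaluation metrics follow the conventions of log-scale ADMET modelling:
R^2 = 1 - RSS/TSS with the evaluated set's own mean, RMSE with the
population (1/n) denominator, the percentage of predictions within 2-fold of
observation on the linear scale (boundary inclusive), and a two-sided paired
t-test on per-compound squared log-residuals for model-vs-model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TANIMOTO_THRESHOLD = 0.7
DEFAULT_TEST_FRACTION = 0.2
N_STRATA = 5


@dataclass(frozen=True)
class SplitAssignment:
    method: str  # "cluster" | "time"
    labels: tuple[str, ...]  # per-compound "train" | "test"
    params: dict = field(default_factory=dict)
    cluster_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        bad = set(self.labels) - {"train", "test"}
        if bad:
            raise ValueError(f"invalid labels: {bad}")

    @property
    def train_idx(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == "train")

    @property
    def test_idx(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == "test")

    def to_frame(self, compound_ids) -> pd.DataFrame:
        return pd.DataFrame({"compound_id": list(compound_ids),
                             "split": list(self.labels)})


@dataclass(frozen=True)
class EvaluationReport:
    r2: float
    rmse: float
    pct_within_2fold: float
    n_test: int
    response_scale: str = "log10"
    comparison_pvalue: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_within_2fold <= 100.0:
            raise ValueError("pct_within_2fold must lie in [0, 100]")
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")

    def to_dict(self) -> dict:
        d = {"r2": self.r2, "rmse": self.rmse,
             "pct_within_2fold": self.pct_within_2fold, "n_test": self.n_test,
             "response_scale": self.response_scale}
        if self.comparison_pvalue is not None:
            d["comparison_pvalue"] = self.comparison_pvalue
        return d


# ---------------------------------------------------------------- fingerprints

def morgan_fingerprints(smiles: list[str], radius: int = 2, n_bits: int = 2048):
    """2048-bit hashed circular (Morgan) fingerprints for clustering."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for fingerprinting: {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def _leader_clusters(fps, threshold: float, order: np.ndarray) -> np.ndarray:
    """Leader clustering: scanning in ``order``, each compound joins the first
    leader within the Tanimoto threshold or founds a new cluster."""
    from rdkit import DataStructs

    n = len(fps)
    cluster = np.full(n, -1, dtype=int)
    leaders: list[int] = []
    for i in order:
        sims = (DataStructs.BulkTanimotoSimilarity(fps[i], [fps[j] for j in leaders])
                if leaders else [])
        assigned = False
        for k, s in enumerate(sims):
            if s >= threshold:
                cluster[i] = k
                assigned = True
                break
        if not assigned:
            cluster[i] = len(leaders)
            leaders.append(i)
    return cluster


# ---------------------------------------------------------------------- splits

def _stratified_cluster_assignment(cluster: np.ndarray, y: np.ndarray,
                                   test_fraction: float,
                                   rng: np.random.Generator) -> np.ndarray:
    """Assign whole clusters to test, greedily matching response quantile bins.

    Returns a boolean test mask hitting round(test_fraction * n) within one
    compound, or raises when cluster granularity makes that impossible.
    """
    n = y.size
    n_test = int(round(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError("test_fraction leaves one side empty")
    # response strata (quantile bins); duplicate edges collapse gracefully
    qs = np.quantile(y, np.linspace(0, 1, N_STRATA + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    strata = np.searchsorted(np.unique(qs[1:-1]), y, side="left")
    n_strata = strata.max() + 1
    target = np.array([
        round(test_fraction * np.sum(strata == b)) for b in range(n_strata)
    ], dtype=float)

    ids = np.unique(cluster)
    members = {c: np.flatnonzero(cluster == c) for c in ids}
    order = rng.permutation(ids)
    test_mask = np.zeros(n, dtype=bool)
    deficit = target.copy()
    remaining = n_test

    def comp(c):
        return np.bincount(strata[members[c]], minlength=n_strata)

    # pass 1: bin-aware greedy establishes a preference ordering
    preferred = []
    for c in order:
        size = members[c].size
        if size > remaining:
            continue
        cb = comp(c)
        gain = np.minimum(cb, np.maximum(deficit, 0)).sum()
        overshoot = np.maximum(cb - np.maximum(deficit, 0), 0).sum()
        if gain > overshoot:
            preferred.append(c)
            deficit -= cb
            remaining -= size
        if remaining == 0:
            break
    # pass 2: subset-sum DP over all clusters for the exact test count
    # (slack one compound either side); preferred clusters are offered to the
    # DP first, so the stratified greedy choice is kept whenever it can be
    # completed to the target size.
    pref_set = set(preferred)
    dp_order = preferred + [c for c in order if c not in pref_set]
    sizes = [members[c].size for c in dp_order]
    cap = n_test + 1
    parent: dict[int, tuple[int, int]] = {0: (-1, -1)}
    for pos, s in enumerate(sizes):
        for total in sorted(parent, reverse=True):
            t = total + s
            if t <= cap and t not in parent:
                parent[t] = (total, pos)
    pick_total = next((t for t in (n_test, n_test - 1, n_test + 1)
                       if t in parent and t > 0), None)
    if pick_total is None:
        raise ValueError(
            f"cannot reach an 80:20 split with whole clusters: no cluster "
            f"subset sums to {n_test} compounds (clustering too coarse)"
        )
    t = pick_total
    while t > 0:
        prev, pos = parent[t]
        test_mask[members[dp_order[pos]]] = True
        t = prev
    return test_mask


def cluster_split(structures: list[str] | None, y,
                  test_fraction: float = DEFAULT_TEST_FRACTION,
                  tanimoto_threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
                  seed: int = 0, *,
                  fingerprints=None,
                  cluster_ids=None) -> SplitAssignment:
    """Cluster-aware stratified 80:20 split.

    One of ``structures`` (SMILES), ``fingerprints`` (RDKit bit vectors) or
    precomputed ``cluster_ids`` must be given; abstract synthetic compounds
    pass their scaffold-family labels as ``cluster_ids``.
    """
    y = np.asarray(y, dtype=float)
    if not 0 < tanimoto_threshold < 1:
        raise ValueError("tanimoto_threshold must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if cluster_ids is not None:
        cluster = np.asarray(cluster_ids, dtype=int)
        if cluster.size != y.size:
            raise ValueError("cluster_ids must align with y")
    else:
        if fingerprints is None:
            if structures is None:
                raise ValueError("provide structures, fingerprints or cluster_ids")
            fingerprints = morgan_fingerprints(structures)
        order = rng.permutation(len(fingerprints))
        cluster = _leader_clusters(fingerprints, tanimoto_threshold, order)
    test_mask = _stratified_cluster_assignment(cluster, y, test_fraction, rng)
    labels = tuple("test" if t else "train" for t in test_mask)
    return SplitAssignment(
        method="cluster", labels=labels,
        params={"test_fraction": test_fraction,
                "tanimoto_threshold": tanimoto_threshold, "seed": seed},
        cluster_ids=tuple(int(c) for c in cluster),
    )


def time_split(dates, train_fraction: float = 0.8) -> SplitAssignment:
    """Chronological split: earliest ``train_fraction`` of compounds train.

    Ties at the cutoff date all go to training (no later chemistry leaks into
    the training side), so the realized train fraction can exceed the target;
    the realized cutoff is recorded in ``params``.
    """
    ser = pd.to_datetime(pd.Series(list(dates)))
    if ser.isna().any():
        raise ValueError("every compound needs an assay date")
    n = len(ser)
    if n < 2:
        raise ValueError("need at least two compounds to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    cutoff = ser.sort_values(kind="stable").iloc[n_train - 1]
    labels = tuple("train" if d <= cutoff else "test" for d in ser)
    if all(lab == "train" for lab in labels):
        raise ValueError("no temporal ordering: all compounds share the cutoff date")
    return SplitAssignment(
        method="time", labels=labels,
        params={"train_fraction": train_fraction,
                "date_cutoff": str(cutoff.date())},
    )


# --------------------------------------------------------------------- metrics

def r_squared(obs_log, pred_log) -> float:
    """Coefficient of determination about the evaluated set's own mean;
    can be negative for a model worse than the mean."""
    obs = np.asarray(obs_log, dtype=float)
    pred = np.asarray(pred_log, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    rss = float(np.sum((obs - pred) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero variance in observed values")
    return 1.0 - rss / tss


def rmse(obs_log, pred_log) -> float:
    obs = np.asarray(obs_log, dtype=float)
    pred = np.asarray(pred_log, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("need equal-length nonempty vectors")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def pct_within_2fold(obs_linear, pred_linear) -> float:
    """Percentage of predictions within 2-fold of observation (inclusive),
    computed on the linear (anti-logged) scale."""
    obs = np.asarray(obs_linear, dtype=float)
    pred = np.asarray(pred_linear, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("need equal-length nonempty vectors")
    if np.any(obs <= 0) or np.any(pred <= 0):
        raise ValueError("2-fold accuracy needs positive linear-scale values")
    fold = np.maximum(pred / obs, obs / pred)
    return float(100.0 * np.mean(fold <= 2.0))


def paired_squared_error_test(errors_a_log, errors_b_log) -> tuple[float, bool]:
    """Two-sided paired t-test on squared log-residuals of two models.

    Returns ``(p_value, degenerate)``; a zero-variance difference (identical
    error magnitudes per compound) reports p = 1 with the degenerate flag.
    """
    a = np.asarray(errors_a_log, dtype=float) ** 2
    b = np.asarray(errors_b_log, dtype=float) ** 2
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need aligned vectors with n >= 3")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return 1.0, True
    res = stats.ttest_rel(a, b)
    return float(res.pvalue), False


def evaluate(obs_log, pred_log, *,
             comparator_pred_log=None) -> EvaluationReport:
    """Bundle the three headline metrics (and an optional paired test against
    a comparator's predictions on the same compounds)."""
    obs = np.asarray(obs_log, dtype=float)
    pred = np.asarray(pred_log, dtype=float)
    pval = None
    if comparator_pred_log is not None:
        comp = np.asarray(comparator_pred_log, dtype=float)
        pval, _ = paired_squared_error_test(pred - obs, comp - obs)
    return EvaluationReport(
        r2=r_squared(obs, pred),
        rmse=rmse(obs, pred),
        pct_within_2fold=pct_within_2fold(10.0 ** obs, 10.0 ** pred),
        n_test=int(obs.size),
        comparison_pvalue=pval,
    )
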