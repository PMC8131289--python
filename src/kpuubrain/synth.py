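"""Synthetic compound datasets with the statistical structure of a CNS
drug-discovery brain-penetration campaign.

The generator emulates a several-hundred-compound internal dataset in which

* efflux ratios (ER) in MDR1- and BCRP-overexpressing MDCK cells are
  log-distributed over roughly three decades, truncated to observed assay
  ranges, with a configurable fraction of transporter substrates (ER > 2);
* Kp,uu,brain arises mechanistically from the two ERs through the neuroPK
  relation 1 / (1 + alpha*(ER_MDR1 - 1) + beta*(ER_BCRP - 1)), observed with
  multiplicative log-normal measurement error;
* compounds belong to scaffold families whose descriptor profiles cluster,
  a sparse subset of descriptors carries linear signal for log ER, and
  descriptor distributions drift over assay dates (later chemistry sits in a
  shifted region of descriptor space, as real time-split test sets do);
* unbound fractions and two-time-point plasma/brain concentrations are
  emitted so the full assay-arithmetic chain (dilution correction, Kp,uu,
  steady-state 2-fold check) can be exercised end to end.

ER marginals are exact truncated log-normals: correlated uniforms from a
Gaussian copula (default correlation 0.3, dual substrates being common) are
pushed through per-transporter truncated-normal quantile functions on log10
ER.  The location of each marginal is calibrated so the substrate fraction
P(ER > 2) matches the configured target exactly under truncation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assays import (
    APICAL_VOLUME_ML,
    BASOLATERAL_VOLUME_ML,
    DEFAULT_DILUTION_FACTOR,
    MEMBRANE_AREA_CM2,
    BindingMeasurement,
    Direction,
    Matrix,
    TransportAssay,
    dilute_fraction_unbound,
)

#: Observed assay ranges used as default clamps for generated efflux ratios.
ER_MDR1_RANGE = (0.563, 151.0)
ER_BCRP_RANGE = (0.522, 100.0)

#: log10 fold-error between the two Kp,uu sampling times chosen so ~95% of
#: compound pairs agree within 2-fold: log10(2)/1.96.
STEADY_STATE_LOG10_SD = float(np.log10(2.0) / 1.959963984540054)

CANONICAL_COLUMNS = [
    "compound_id", "smiles", "assay_date", "er_mdr1", "er_bcrp",
    "fu_plasma", "fu_brain_prime", "dilution_factor",
    "c_plasma_t1", "c_brain_t1", "c_plasma_t2", "c_brain_t2",
]

# Small scaffold library for optional SMILES emission; substituent chains are
# grown per compound so family members are structurally similar but distinct.
_SCAFFOLD_SMILES = [
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1",
    "c1ccc2ncccc2c1", "c1cnc2[nH]ccc2c1", "c1ccoc1", "c1ccsc1",
    "c1cnoc1", "c1cscn1", "C1CCNCC1", "C1CCOCC1", "C1CCCCC1",
    "c1cnn(c1)C", "c1ncncn1", "c1ccc(cc1)O", "c1ccc(cc1)N",
    "c1ccc(cc1)F", "c1ccc(cc1)Cl", "c1ccc(cc1)C#N",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic campaign.

    ``alpha_true``/``beta_true`` default to in vivo scaling factors typical of
    rat MDR1/BCRP calibrations (0.58 and 1.2).  ``er_*_log_mean`` may be left
    ``None``, in which case the truncated-normal location is calibrated so
    the fraction of ER > 2 substrates matches ``frac_*_substrates``.

    ``mechanistic_misfit_sd`` (default 0: the two-transporter model is then
    exactly true) adds a descriptor-linked log10 component to the observed
    Kp,uu — in vivo disposition is shaped by more than the two efflux
    transporters (uptake transporters, metabolism), and this latent term
    gives a flexible learner something the mechanistic model cannot explain.
    """

    n_compounds: int = 640
    alpha_true: float = 0.58
    beta_true: float = 1.2
    log10_kpuu_noise_sd: float = 0.2
    er_mdr1_log_mean: float | None = None
    er_mdr1_log_sd: float = 0.60
    er_bcrp_log_mean: float | None = None
    er_bcrp_log_sd: float = 0.55
    er_log_correlation: float = 0.3
    frac_mdr1_substrates: float = 0.844
    frac_bcrp_substrates: float = 0.561
    er_mdr1_range: tuple[float, float] = ER_MDR1_RANGE
    er_bcrp_range: tuple[float, float] = ER_BCRP_RANGE
    n_scaffold_families: int = 40
    n_descriptors: int = 32
    n_informative: int = 8
    descriptor_signal: float = 1.0
    descriptor_noise_sd: float = 0.5
    family_spread: float = 0.75
    family_date_jitter: float = 0.25
    mechanistic_misfit_sd: float = 0.0
    temporal_drift_strength: float = 1.0
    steady_state_log10_sd: float = STEADY_STATE_LOG10_SD
    date_range: tuple[str, str] = ("2015-01-01", "2020-12-31")
    emit_smiles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be a positive integer")
        if self.n_scaffold_families <= 0:
            raise ValueError("n_scaffold_families must be positive")
        for name in ("alpha_true", "beta_true", "log10_kpuu_noise_sd",
                     "temporal_drift_strength", "steady_state_log10_sd", "family_date_jitter",
                     "mechanistic_misfit_sd",
                     "er_mdr1_log_sd", "er_bcrp_log_sd", "descriptor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("frac_mdr1_substrates", "frac_bcrp_substrates"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 < self.er_log_correlation < 1.0:
            raise ValueError("er_log_correlation must lie in (-1, 1)")
        for name in ("er_mdr1_range", "er_bcrp_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must be an ordered positive pair")
        d0, d1 = (pd.Timestamp(d) for d in self.date_range)
        if d0 >= d1:
            raise ValueError("date_range must be ordered")
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative cannot exceed n_descriptors")


@dataclass(frozen=True)
class SyntheticCompound:
    compound_id: str
    smiles: str
    descriptor_vector: np.ndarray
    er_mdr1: float
    er_bcrp: float
    fu_plasma_true: float
    fu_brain_true: float
    kpuu_true: float
    kpuu_observed: float
    assay_date: _dt.date
    scaffold_family: int


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated campaign: per-compound records plus the full assay table."""

    compounds: tuple[SyntheticCompound, ...]
    table: pd.DataFrame = field(repr=False)
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def descriptor_matrix(self) -> pd.DataFrame:
        X = np.vstack([c.descriptor_vector for c in self.compounds])
        names = [f"d_{j:03d}" for j in range(X.shape[1])]
        return pd.DataFrame(X, columns=names,
                            index=[c.compound_id for c in self.compounds])

    @property
    def scaffold_families(self) -> np.ndarray:
        return np.array([c.scaffold_family for c in self.compounds])

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "compound_id": [c.compound_id for c in self.compounds],
            "kpuu_true": [c.kpuu_true for c in self.compounds],
            "kpuu_observed": [c.kpuu_observed for c in self.compounds],
            "scaffold_family": [c.scaffold_family for c in self.compounds],
        })


def _calibrated_truncnorm(frac_gt2: float, log_sd: float,
                          clamp: tuple[float, float],
                          log_mean: float | None) -> stats.rv_continuous:
    """Truncated normal on log10 ER whose location either is given or is
    solved so P(ER > 2 | clamps) equals ``frac_gt2``."""
    la, lb = np.log10(clamp[0]), np.log10(clamp[1])
    t = np.log10(2.0)

    def make(mu: float):
        a, b = (la - mu) / log_sd, (lb - mu) / log_sd
        return stats.truncnorm(a, b, loc=mu, scale=log_sd)

    if log_mean is not None:
        return make(log_mean)
    if not la < t < lb:
        raise ValueError("ER = 2 lies outside the clamp range; cannot calibrate")

    def gap(mu: float) -> float:
        return make(mu).sf(t) - frac_gt2

    # P(ER>2) is monotone increasing in mu; bracket generously.
    mu = optimize.brentq(gap, la - 6 * log_sd, lb + 6 * log_sd, xtol=1e-12)
    return make(mu)


def _correlated_uniforms(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    return stats.norm.cdf(z)


def _grow_smiles(rng: np.random.Generator, scaffold: str) -> str:
    # substituent is written as a prefix so it always bonds to the first ring
    # atom of the scaffold (a carbon in every library entry)
    chain = "C" * int(rng.integers(1, 6))
    head = rng.choice(["", "O", "N", "F", "OC", "NC(=O)"])
    return head + chain + scaffold


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate one campaign; identical (seed, config) gives identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_compounds

    dist_m = _calibrated_truncnorm(cfg.frac_mdr1_substrates, cfg.er_mdr1_log_sd,
                                   cfg.er_mdr1_range, cfg.er_mdr1_log_mean)
    dist_b = _calibrated_truncnorm(cfg.frac_bcrp_substrates, cfg.er_bcrp_log_sd,
                                   cfg.er_bcrp_range, cfg.er_bcrp_log_mean)
    u = _correlated_uniforms(rng, n, cfg.er_log_correlation)
    log_er_m = dist_m.ppf(u[:, 0])
    log_er_b = dist_b.ppf(u[:, 1])
    er_m = 10.0 ** log_er_m
    er_b = 10.0 ** log_er_b

    denom = 1.0 + cfg.alpha_true * (er_m - 1.0) + cfg.beta_true * (er_b - 1.0)
    if np.any(denom <= 0):
        raise ValueError("generated ER range and scaling factors give a "
                         "nonpositive neuroPK denominator; tighten the clamps")
    kpuu_true = 1.0 / denom
    # latent non-transporter disposition component (misfit of the
    # two-transporter model); surfaces again in the descriptor block below
    misfit = rng.standard_normal(n) if cfg.mechanistic_misfit_sd > 0 else np.zeros(n)
    eps = rng.normal(0.0, cfg.log10_kpuu_noise_sd, size=n) if cfg.log10_kpuu_noise_sd > 0 else np.zeros(n)
    kpuu_obs = kpuu_true * 10.0 ** (cfg.mechanistic_misfit_sd * misfit + eps)

    # Scaffold families: uneven sizes; each family holds a descriptor centroid
    # and a characteristic synthesis era (date center).
    family = rng.integers(0, cfg.n_scaffold_families, size=n)
    centroids = rng.normal(0.0, cfg.family_spread,
                           size=(cfg.n_scaffold_families, cfg.n_descriptors))
    d0, d1 = (pd.Timestamp(d) for d in cfg.date_range)
    span_days = (d1 - d0).days
    family_era = rng.uniform(0.0, 1.0, size=cfg.n_scaffold_families)
    date_frac = np.clip(family_era[family]
                        + rng.normal(0.0, cfg.family_date_jitter, size=n), 0.0, 1.0)
    dates = np.array([
        (d0 + pd.Timedelta(days=float(f) * span_days)).date() for f in date_frac
    ])

    # Descriptors: family centroid + sparse linear ER signal + temporal drift
    # + isotropic noise.  The drift runs along the combined efflux-loading
    # direction: over a campaign, chemists push exactly the properties that
    # drive efflux, so later chemistry is shifted along the direction that
    # carries the ER signal.  Because the ER marginals themselves stay
    # stationary, the drift confounds the descriptor-ER relationship for any
    # model trained on early and evaluated on late compounds.
    informative = rng.choice(cfg.n_descriptors, size=cfg.n_informative, replace=False)
    w_m = np.zeros(cfg.n_descriptors)
    w_b = np.zeros(cfg.n_descriptors)
    w_m[informative] = rng.normal(0.0, cfg.descriptor_signal, size=cfg.n_informative)
    w_b[informative] = rng.normal(0.0, cfg.descriptor_signal, size=cfg.n_informative)
    drift_dir = w_m + w_b
    dnorm = np.linalg.norm(drift_dir)
    if dnorm > 0:
        drift_dir = drift_dir / dnorm
    else:  # descriptor_signal == 0: drift along the informative axes
        drift_dir[informative] = 1.0 / np.sqrt(max(cfg.n_informative, 1))
    s_m = (log_er_m - dist_m.mean()) / dist_m.std()
    s_b = (log_er_b - dist_b.mean()) / dist_b.std()
    w_u = np.zeros(cfg.n_descriptors)
    if cfg.mechanistic_misfit_sd > 0:
        misfit_dims = rng.choice(cfg.n_descriptors,
                                 size=min(4, cfg.n_descriptors), replace=False)
        w_u[misfit_dims] = rng.normal(0.0, max(cfg.descriptor_signal, 0.5),
                                      size=misfit_dims.size)
    X = (centroids[family]
         + np.outer(s_m, w_m) + np.outer(s_b, w_b)
         + np.outer(misfit, w_u)
         + cfg.temporal_drift_strength * np.outer(date_frac, drift_dir)
         + rng.normal(0.0, cfg.descriptor_noise_sd, size=(n, cfg.n_descriptors)))

    fu_plasma = 10.0 ** np.minimum(rng.normal(-1.0, 0.5, size=n), 0.0)
    fu_brain = 10.0 ** np.minimum(rng.normal(-1.3, 0.5, size=n), 0.0)

    # Concentrations at two sampling times; the later time defines the
    # modelling Kp,uu, the earlier one differs by an independent fold-error.
    c_plasma_t2 = 10.0 ** rng.normal(0.0, 0.4, size=n)
    c_brain_t2 = kpuu_obs * fu_plasma * c_plasma_t2 / fu_brain
    ss_eps = (rng.normal(0.0, cfg.steady_state_log10_sd, size=n)
              if cfg.steady_state_log10_sd > 0 else np.zeros(n))
    kpuu_t1 = kpuu_obs * 10.0 ** ss_eps
    c_plasma_t1 = c_plasma_t2 * 10.0 ** rng.normal(0.0, 0.1, size=n)
    c_brain_t1 = kpuu_t1 * fu_plasma * c_plasma_t1 / fu_brain

    fu_brain_prime = np.array([
        dilute_fraction_unbound(f, DEFAULT_DILUTION_FACTOR) for f in fu_brain
    ])

    if cfg.emit_smiles:
        scaffold_for_family = [
            _SCAFFOLD_SMILES[k % len(_SCAFFOLD_SMILES)]
            for k in range(cfg.n_scaffold_families)
        ]
        smiles = [_grow_smiles(rng, scaffold_for_family[k]) for k in family]
    else:
        smiles = [""] * n

    compounds = tuple(
        SyntheticCompound(
            compound_id=f"SYN-{i:05d}",
            smiles=smiles[i],
            descriptor_vector=X[i].copy(),
            er_mdr1=float(er_m[i]),
            er_bcrp=float(er_b[i]),
            fu_plasma_true=float(fu_plasma[i]),
            fu_brain_true=float(fu_brain[i]),
            kpuu_true=float(kpuu_true[i]),
            kpuu_observed=float(kpuu_obs[i]),
            assay_date=dates[i],
            scaffold_family=int(family[i]),
        )
        for i in range(n)
    )
    table = pd.DataFrame({
        "compound_id": [c.compound_id for c in compounds],
        "smiles": smiles,
        "assay_date": [d.isoformat() for d in dates],
        "er_mdr1": er_m,
        "er_bcrp": er_b,
        "fu_plasma": fu_plasma,
        "fu_brain_prime": fu_brain_prime,
        "dilution_factor": DEFAULT_DILUTION_FACTOR,
        "c_plasma_t1": c_plasma_t1,
        "c_brain_t1": c_brain_t1,
        "c_plasma_t2": c_plasma_t2,
        "c_brain_t2": c_brain_t2,
    })[CANONICAL_COLUMNS]
    return SyntheticDataset(compounds=compounds, table=table, config=cfg)


def write_canonical_table(dataset: SyntheticDataset, path) -> None:
    """UTF-8 comma-delimited canonical compound table, empty for missing."""
    dataset.table.to_csv(path, index=False, encoding="utf-8")


def read_canonical_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"canonical table is missing columns: {missing}")
    return table


def generate_transport_assay(
    papp_ab_true: float,
    papp_ba_true: float,
    c0: float = 2.0,
    *,
    noise_cv: float = 0.0,
    seed: int = 0,
    times_s: tuple[float, ...] = (3600.0,),
    v_r_ab: float = BASOLATERAL_VOLUME_ML,
    v_r_ba: float = APICAL_VOLUME_ML,
) -> dict[str, TransportAssay]:
    """Transwell fixture: receiver series follow the linear-accumulation model
    C_r(t) = Papp * A * C0 * t / V_r, with multiplicative noise of CV
    ``noise_cv``.  A->B permeation accumulates in the basolateral chamber
    (0.25 mL) and B->A in the apical chamber (0.075 mL) by default.
    """
    if papp_ab_true <= 0 or papp_ba_true <= 0:
        raise ValueError("true permeabilities must be positive")
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.asarray(times_s, dtype=float)
    out = {}
    for key, papp, v_r, direction in (
        ("A_to_B", papp_ab_true, v_r_ab, Direction.A_TO_B),
        ("B_to_A", papp_ba_true, v_r_ba, Direction.B_TO_A),
    ):
        conc = papp * MEMBRANE_AREA_CM2 * c0 * t / v_r
        if noise_cv > 0:
            conc = conc * (1.0 + noise_cv * rng.standard_normal(t.size))
            conc = np.clip(conc, 0.0, None)
        out[key] = TransportAssay(
            times_s=tuple(t), receiver_concentrations_um=tuple(conc),
            v_r=v_r, a=MEMBRANE_AREA_CM2, c0=c0, direction=direction,
        )
    return out


def generate_dialysis_assay(
    fu_true: float,
    dilution_factor: float = 1.0,
    *,
    seed: int = 0,
    noise_cv: float = 0.0,
    c_total: float = 1.0,
    matrix: Matrix = Matrix.PLASMA,
) -> BindingMeasurement:
    """Equilibrium-dialysis fixture.

    The buffer concentration equals fu' * c_total where fu' is the unbound
    fraction measured *in the (possibly diluted) matrix*: for plasma
    (``dilution_factor`` 1) fu' = fu_true, for brain homogenate it is the
    dilution-forward transform of ``fu_true``.  Multiplicative noise of CV
    ``noise_cv`` applies independently to both chambers.
    """
    if not 0 < fu_true <= 1:
        raise ValueError("fu_true must lie in (0, 1]")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    fu_prime = dilute_fraction_unbound(fu_true, dilution_factor)
    c_buffer = fu_prime * c_total
    c_matrix = c_total
    if noise_cv > 0:
        c_buffer *= max(1.0 + noise_cv * rng.standard_normal(), 1e-9)
        c_matrix *= max(1.0 + noise_cv * rng.standard_normal(), 1e-9)
    return BindingMeasurement(
        c_buffer=c_buffer, c_matrix=c_matrix, matrix=matrix,
        dilution_factor=dilution_factor,
    )


def with_overrides(config: GeneratorConfig, **kwargs) -> GeneratorConfig:
    """Return a copy of ``config`` with fields replaced (validation rerun)."""
    return replace(config, **kwargs)
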