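"""2D molecular descriptors: computation, train-referenced scaling, and the
three exclusion rules used before QSAR model building.

The descriptor battery mirrors the structure of commercial 2D SMARTS-based
sets: whole-molecule properties (molecular weight, TPSA, calculated logP,
ring/rotatable-bond counts, ...) plus counts of atom types and functional
groups.  The open battery shipped here (RDKit properties + RDKit fragment
counts + a SMARTS pattern file) is configurable; the downstream contract is
only "numeric columns with names", so abstract synthetic descriptor vectors
satisfy the same interface.

Exclusion rules, applied in order on training rows only:

1. drop descriptors with standard deviation < 0.0005 (sample sd, n-1);
2. drop count-type descriptors nonzero in < 4% of compounds;
3. for every descriptor pair with |Pearson r| > 0.95, drop the member with
   the smaller |correlation to the response|.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

try:  # RDKit is required for real structures, not for abstract descriptors
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Fragments, rdMolDescriptors
    HAVE_RDKIT = True
except ImportError:  # pragma: no cover
    HAVE_RDKIT = False

SD_THRESHOLD = 0.0005
REPRESENTATION_FRACTION = 0.04
CORRELATION_THRESHOLD = 0.95

#: Whole-molecule (continuous) properties; name -> callable(mol).
_PROPERTY_FUNCS = None


def _property_funcs():
    global _PROPERTY_FUNCS
    if _PROPERTY_FUNCS is None:
        _PROPERTY_FUNCS = {
            "prop_mw": Descriptors.MolWt,
            "prop_tpsa": Descriptors.TPSA,
            "prop_clogp": Crippen.MolLogP,
            "prop_mr": Crippen.MolMR,
            "prop_hbd": rdMolDescriptors.CalcNumHBD,
            "prop_hba": rdMolDescriptors.CalcNumHBA,
            "prop_rotb": rdMolDescriptors.CalcNumRotatableBonds,
            "prop_rings_arom": rdMolDescriptors.CalcNumAromaticRings,
            "prop_rings_aliph": rdMolDescriptors.CalcNumAliphaticRings,
            "prop_fsp3": rdMolDescriptors.CalcFractionCSP3,
            "prop_heavy_atoms": Descriptors.HeavyAtomCount,
            "prop_heteroatoms": rdMolDescriptors.CalcNumHeteroatoms,
            "prop_formal_charge": Chem.GetFormalCharge,
            "prop_stereo_centers": rdMolDescriptors.CalcNumAtomStereoCenters,
        }
    return _PROPERTY_FUNCS

#: Names of continuous properties; everything else in the battery is a count.
_CONTINUOUS_PREFIX = "prop_"


def load_smarts_battery() -> dict[str, "Chem.Mol"]:
    path = importlib.resources.files("kpuubrain.data") / "smarts_battery.csv"
    table = pd.read_csv(path)
    patterns = {}
    for name, smarts in zip(table["name"], table["smarts"]):
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in battery: {name} = {smarts}")
        patterns[name] = patt
    return patterns


@dataclass(frozen=True)
class DescriptorMatrix:
    """Compounds x descriptors with scaling and exclusion provenance.

    ``scaling_params`` maps retained descriptor name -> (train mean, train
    sample sd); ``excluded`` lists (descriptor_name, rule_id) in the order
    exclusions happened.  ``count_type`` flags count descriptors (rule 2
    applies to those only).
    """

    compound_ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    scaled: bool = False
    scaling_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    excluded: tuple[tuple[str, str], ...] = ()
    count_type: dict[str, bool] = field(default_factory=dict)
    failed_structures: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("duplicate descriptor names")
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError("values shape does not match ids x names")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *,
                   count_type: dict[str, bool] | None = None) -> "DescriptorMatrix":
        names = tuple(str(c) for c in frame.columns)
        ct = count_type or {n: False for n in names}
        return cls(
            compound_ids=tuple(str(i) for i in frame.index),
            descriptor_names=names,
            values=frame.to_numpy(dtype=float),
            count_type=ct,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.descriptor_names),
                            index=list(self.compound_ids))

    def schema_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for n in self.descriptor_names:
            h.update(n.encode())
        return h.hexdigest()[:16]


def compute_descriptors(structures: list[str],
                        compound_ids: list[str] | None = None,
                        *,
                        include_smarts_battery: bool = True,
                        include_fragment_counts: bool = True) -> DescriptorMatrix:
    """Compute the open 2D battery from SMILES.

    Unparseable SMILES are excluded from the matrix and recorded in
    ``failed_structures``; an empty input yields an empty matrix.
    """
    if not HAVE_RDKIT:  # pragma: no cover
        raise RuntimeError("RDKit is required to compute descriptors from SMILES")
    if compound_ids is None:
        compound_ids = [f"CMPD-{i:05d}" for i in range(len(structures))]
    if len(compound_ids) != len(structures):
        raise ValueError("compound_ids must align with structures")

    props = _property_funcs()
    frag_funcs = (
        {name: getattr(Fragments, name)
         for name in sorted(dir(Fragments)) if name.startswith("fr_")}
        if include_fragment_counts else {}
    )
    smarts = load_smarts_battery() if include_smarts_battery else {}

    names = list(props) + list(frag_funcs) + list(smarts)
    count_type = {n: not n.startswith(_CONTINUOUS_PREFIX) for n in names}

    rows, kept_ids, failed = [], [], []
    for cid, smi in zip(compound_ids, structures):
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is None:
            failed.append(cid)
            continue
        row = [float(f(mol)) for f in props.values()]
        row += [float(f(mol)) for f in frag_funcs.values()]
        row += [float(len(mol.GetSubstructMatches(p))) for p in smarts.values()]
        rows.append(row)
        kept_ids.append(cid)

    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(names)))
    return DescriptorMatrix(
        compound_ids=tuple(kept_ids),
        descriptor_names=tuple(names),
        values=values,
        count_type=count_type,
        failed_structures=tuple(failed),
    )


def _train_stats(values: np.ndarray, train_idx: np.ndarray):
    sub = values[train_idx]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1) if sub.shape[0] > 1 else np.zeros(sub.shape[1])
    return mean, sd


def scale_descriptors(m: DescriptorMatrix,
                      reference_rows: np.ndarray | list[int]) -> DescriptorMatrix:
    """Center/scale every column by its mean and sample sd over the training
    rows; test rows are transformed with the training parameters.  Columns
    with zero training sd are left untouched and flagged for rule 1."""
    if m.scaled:
        raise ValueError("matrix is already scaled")
    train_idx = np.asarray(reference_rows, dtype=int)
    mean, sd = _train_stats(m.values, train_idx)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    scaled_values = (m.values - mean) / safe_sd
    scaled_values[:, constant] = m.values[:, constant]
    params = {
        name: (float(mu), float(s))
        for name, mu, s, const in zip(m.descriptor_names, mean, sd, constant)
        if not const
    }
    return replace(m, values=scaled_values, scaled=True, scaling_params=params)


def filter_descriptors(m: DescriptorMatrix, y: np.ndarray,
                       reference_rows: np.ndarray | list[int] | None = None,
                       *,
                       sd_threshold: float = SD_THRESHOLD,
                       representation_fraction: float = REPRESENTATION_FRACTION,
                       correlation_threshold: float = CORRELATION_THRESHOLD,
                       ) -> DescriptorMatrix:
    """Apply the three exclusion rules; statistics use training rows only.

    Rule 3 processes pairs by descending |r| (ties by lexicographic name
    pair); once a descriptor is dropped it leaves all remaining pairs, making
    the retained set independent of the input column order.
    """
    y = np.asarray(y, dtype=float)
    if y.size != len(m.compound_ids):
        raise ValueError("response vector must align with compound rows")
    train_idx = (np.arange(len(m.compound_ids)) if reference_rows is None
                 else np.asarray(reference_rows, dtype=int))
    values = m.values
    names = list(m.descriptor_names)
    excluded: list[tuple[str, str]] = list(m.excluded)

    # Rule 1: near-constant descriptors. Uses the *unscaled* training sd when
    # scaling params are available (a scaled column always has sd 1).
    keep = np.ones(len(names), dtype=bool)
    if m.scaled and m.scaling_params:
        sds = np.array([m.scaling_params.get(n, (0.0, 0.0))[1] for n in names])
    else:
        _, sds = _train_stats(values, train_idx)
    for j, name in enumerate(names):
        if sds[j] < sd_threshold:
            keep[j] = False
            excluded.append((name, "rule1_low_sd"))

    # Rule 2: rarely represented count descriptors (nonzero in < 4% of
    # training compounds). Representation is judged on the original counts:
    # for a scaled column, value != scaled(0) iff count != 0.
    n_train = train_idx.size
    for j, name in enumerate(names):
        if not keep[j] or not m.count_type.get(name, False):
            continue
        if m.scaled and name in m.scaling_params:
            mu, sd = m.scaling_params[name]
            zero_scaled = (0.0 - mu) / sd
            nonzero = np.sum(~np.isclose(values[train_idx, j], zero_scaled))
        else:
            nonzero = np.count_nonzero(values[train_idx, j])
        if nonzero < representation_fraction * n_train:
            keep[j] = False
            excluded.append((name, "rule2_rare"))

    # Rule 3: redundant pairs.
    active = [j for j in range(len(names)) if keep[j]]
    sub = values[np.ix_(train_idx, active)]
    if len(active) >= 2:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        y_train = y[train_idx]
        y_corr = np.zeros(len(active))
        ysd = y_train.std()
        for pos, j in enumerate(active):
            xsd = sub[:, pos].std()
            if xsd > 0 and ysd > 0:
                y_corr[pos] = np.corrcoef(sub[:, pos], y_train)[0, 1]
        pairs = []
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                r = abs(corr[a, b])
                if r > correlation_threshold:
                    na, nb = names[active[a]], names[active[b]]
                    first, second = sorted([na, nb])
                    pairs.append((-r, first, second, a, b))
        pairs.sort()
        dropped = set()
        for _, _, _, a, b in pairs:
            if a in dropped or b in dropped:
                continue
            # drop the member with the smaller |correlation to y|;
            # tie -> drop the lexicographically later name
            ca, cb = abs(y_corr[a]), abs(y_corr[b])
            if ca < cb:
                victim = a
            elif cb < ca:
                victim = b
            else:
                victim = a if names[active[a]] > names[active[b]] else b
            dropped.add(victim)
            keep[active[victim]] = False
            excluded.append((names[active[victim]], "rule3_correlated"))

    kept_names = tuple(n for n, k in zip(names, keep) if k)
    kept_values = values[:, keep]
    return replace(
        m,
        descriptor_names=kept_names,
        values=kept_values,
        excluded=tuple(excluded),
        scaling_params={n: p for n, p in m.scaling_params.items() if n in kept_names},
        count_type={n: m.count_type.get(n, False) for n in kept_names},
    )


def prepare_descriptors(frame: pd.DataFrame, y: np.ndarray,
                        train_rows: np.ndarray,
                        *, count_type: dict[str, bool] | None = None,
                        ) -> DescriptorMatrix:
    """Convenience pipeline: frame -> filter (unscaled stats) -> scale.

    Filtering runs before scaling so rule 1's sd threshold sees the raw
    units; scaling then uses the training rows of the retained columns.
    """
    m = DescriptorMatrix.from_frame(frame, count_type=count_type)
    m = filter_descriptors(m, y, train_rows)
    return scale_descriptors(m, train_rows)
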