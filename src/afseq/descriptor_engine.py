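"""Sequence-level (0D/1D) protein descriptor generation.

A descriptor is built in four steps:

1. **Encoding** — each residue is replaced by the value an amino-acid
   property table assigns to it, yielding one real array per (sequence,
   index) pair.
2. **Vicinity modification** — the electrotopological-state (ES) operator
   perturbs each position by the distance-damped differences with every
   other position::

       ES_i = I_i + sum_{j != i} (I_i - I_j) / (d_ij + 1)^2,   d_ij = |j - i|

   0D descriptors skip this step (tag ``NO``); 1D descriptors apply it
   (tag ``ES``), which is what makes them sensitive to residue order.
   An autocorrelation vicinity operator (``AC``) exists as an interface
   stub only.
3. **Grouping** — the (modified) array is split into sub-arrays over 30
   residue groups: the 20 single-residue groups, nine physicochemical
   classes and the whole protein (``PRT``).
4. **Invariant aggregation** — each sub-array collapses to a scalar through
   one of 17 operators (p-norms, central tendency, dispersion/distribution
   and Shannon-entropy measures).

Descriptor columns are named ``<Index>_<Mod>_<Group>_<Aggr>``; e.g.
``HP_NO_ARM_Ar`` is the average Kyte-Doolittle hydropathy over the aromatic
residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aa_indices import AAIndexTable, INDEX_CODES, get_index
from .matrix import DescriptorMatrix
from .seq_io import AMINO_ACIDS, LabeledDataset, SequenceRecord

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Residue groups

_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class ResidueGroup:
    """A named, not necessarily contiguous, set of residue types."""

    code: str
    membership: frozenset[str]

    def __post_init__(self) -> None:
        bad = self.membership - frozenset(AMINO_ACIDS)
        if bad:
            raise ValueError(f"group {self.code}: unknown residue(s) {sorted(bad)}")


def _default_groups() -> dict[str, ResidueGroup]:
    groups: dict[str, ResidueGroup] = {}
    for aa, code in _THREE_LETTER.items():
        groups[code] = ResidueGroup(code, frozenset(aa))
    phys = {
        "AHR": "AVLIM",        # aliphatic hydrophobic
        "ARM": "FWYH",         # aromatic
        "PLR": "STNQCY",       # polar
        "PCG": "KRH",          # positively charged
        "NCG": "DE",           # negatively charged
        "CHG": "KRHDE",        # charged (PCG | NCG)
        "TRN": "GPNDS",        # turn promoting
        "SML": "GASCT",        # small
        "UNC": "STNQCYG",      # uncharged polar (PLR | G)
    }
    for code, letters in phys.items():
        groups[code] = ResidueGroup(code, frozenset(letters))
    groups["PRT"] = ResidueGroup("PRT", frozenset(AMINO_ACIDS))
    return groups


#: The 30 sequence-mode residue groups keyed by code.
GROUPS: dict[str, ResidueGroup] = _default_groups()
GROUP_CODES: tuple[str, ...] = tuple(GROUPS)


# ---------------------------------------------------------------------------
# Vicinity operators

@dataclass
class ResidueArray:
    """Per-residue real values for one sequence under one index."""

    values: np.ndarray
    index_name: str
    modified: str = "NO"   # "NO" or "ES"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ResidueArray values must be one-dimensional")


def encode_residues(record: SequenceRecord, index: AAIndexTable) -> ResidueArray:
    """Step 1: map each residue of ``record`` to its value under ``index``."""
    vec = index.as_vector()
    codes = _sequence_codes(record.sequence)
    return ResidueArray(values=vec[codes], index_name=index.name, modified="NO")


def es_values(values: np.ndarray) -> np.ndarray:
    """Electrotopological-state modification of a raw value array.

    ES_i = I_i + sum_{j != i} (I_i - I_j) / (|i - j| + 1)^2.  The pairwise
    terms are antisymmetric, so the array total is conserved.  Computed
    directly for short arrays and via FFT convolution of the 1/(d+1)^2
    kernel for long ones.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n <= 1:
        return v.copy()
    if n <= 1024:
        idx = np.arange(n)
        w = 1.0 / (np.abs(idx[:, None] - idx[None, :]) + 1.0) ** 2
        np.fill_diagonal(w, 0.0)
        return v * (1.0 + w.sum(axis=1)) - w @ v
    from scipy.signal import fftconvolve

    kernel = 1.0 / (np.abs(np.arange(-(n - 1), n)) + 1.0) ** 2
    kernel[n - 1] = 0.0
    row_sums = fftconvolve(np.ones(n), kernel)[n - 1 : 2 * n - 1]
    wv = fftconvolve(v, kernel)[n - 1 : 2 * n - 1]
    return v * (1.0 + row_sums) - wv


def apply_es(array: ResidueArray) -> ResidueArray:
    """Step 2: apply the ES vicinity operator (turns 0D values into 1D)."""
    if array.modified != "NO":
        raise ValueError(f"array already modified ({array.modified})")
    return ResidueArray(
        values=es_values(array.values), index_name=array.index_name, modified="ES"
    )


def apply_ac(array: ResidueArray, lag: int = 1) -> ResidueArray:
    """Autocorrelation vicinity operator — interface stub, not implemented."""
    raise NotImplementedError(
        "the AC vicinity operator is exposed for interface completeness only; "
        "use the ES operator"
    )


def extract_group(
    array: ResidueArray, record: SequenceRecord, group: ResidueGroup
) -> np.ndarray:
    """Step 3: sub-array of values at positions whose residue is in ``group``."""
    if array.values.size != len(record.sequence):
        raise ValueError("array and record lengths differ")
    mask = np.fromiter(
        (ch in group.membership for ch in record.sequence),
        dtype=bool,
        count=len(record.sequence),
    )
    return array.values[mask]


# ---------------------------------------------------------------------------
# Aggregation operators

#: Canonical order of the 17 aggregation operators.
OPERATOR_CODES = (
    "N1", "N2", "N3",                 # p-norms, p = 1..3
    "Ar", "GM", "HM", "MD",           # central tendency
    "MX", "MN", "VA", "SK", "KU",     # dispersion / distribution
    "Q1", "Q3", "RG", "IQ",
    "SE",                             # Shannon entropy
)
_OP_POS = {code: k for k, code in enumerate(OPERATOR_CODES)}


def _quantile_sorted(s: np.ndarray, q: float) -> float:
    # linear-interpolation (inclusive median) convention
    h = (s.size - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, s.size - 1)
    return float(s[lo] + (h - lo) * (s[hi] - s[lo]))


def aggregate_all(sub: np.ndarray) -> np.ndarray:
    """All 17 operator values for one sub-array, in ``OPERATOR_CODES`` order.

    Degenerate-input policy (chosen for totality of the feature map): the
    empty vector maps to 0 under every operator; GM and HM are taken over
    absolute values and are 0 when any entry is 0; SK/KU of a zero-variance
    vector are 0; SE of the all-zero vector is 0.
    """
    out = np.zeros(len(OPERATOR_CODES))
    v = np.asarray(sub, dtype=float)
    n = v.size
    if n == 0:
        return out
    a = np.abs(v)
    s1 = float(a.sum())
    out[0] = s1                                   # N1
    out[1] = float(np.sqrt((v * v).sum()))        # N2
    out[2] = float((a**3).sum() ** (1.0 / 3.0))   # N3
    mean = float(v.mean())
    out[3] = mean                                 # Ar
    with np.errstate(over="ignore", divide="ignore"):
        out[4] = 0.0 if np.any(a == 0.0) else float(np.exp(np.log(a).mean()))   # GM
        out[5] = 0.0 if np.any(a == 0.0) else float(n / (1.0 / a).sum())        # HM
    s = np.sort(v)
    q1 = _quantile_sorted(s, 0.25)
    md = _quantile_sorted(s, 0.50)
    q3 = _quantile_sorted(s, 0.75)
    out[6] = md                                   # MD
    out[7] = float(s[-1])                         # MX
    out[8] = float(s[0])                          # MN
    centered = v - mean
    var = float((centered**2).mean())             # population variance
    out[9] = var                                  # VA
    if var > 0.0:
        sd = np.sqrt(var)
        out[10] = float((centered**3).mean() / sd**3)   # SK
        out[11] = float((centered**4).mean() / var**2)  # KU
    out[12] = q1                                  # Q1
    out[13] = q3                                  # Q3
    out[14] = float(s[-1] - s[0])                 # RG
    out[15] = q3 - q1                             # IQ
    if s1 > 0.0:
        p = a / s1
        nz = p[p > 0.0]
        out[16] = float(-(nz * np.log2(nz)).sum())      # SE
    return out


def aggregate(sub: np.ndarray, op: str) -> float:
    """A single operator value (see :func:`aggregate_all` for semantics)."""
    if op not in _OP_POS:
        raise KeyError(f"unknown operator {op!r}; available: {OPERATOR_CODES}")
    return float(aggregate_all(np.asarray(sub, dtype=float))[_OP_POS[op]])


# ---------------------------------------------------------------------------
# Batch featurization

_AA_TO_CODE = {aa: k for k, aa in enumerate(AMINO_ACIDS)}


def _sequence_codes(sequence: str) -> np.ndarray:
    try:
        return np.fromiter(
            (_AA_TO_CODE[ch] for ch in sequence), dtype=np.intp, count=len(sequence)
        )
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None


@dataclass
class FeaturizeConfig:
    """Axes of the combinatorial descriptor generation.

    ``vicinity`` selects the descriptor family: ``("NO",)`` for 0D,
    ``("ES",)`` for 1D, both for the joint 0D+1D matrix.
    """

    indices: tuple[str, ...] = INDEX_CODES
    vicinity: tuple[str, ...] = ("NO", "ES")
    groups: tuple[str, ...] = GROUP_CODES
    operators: tuple[str, ...] = OPERATOR_CODES
    drop_constant: bool = True

    def validate(self) -> None:
        for axis, values in (
            ("indices", self.indices),
            ("vicinity", self.vicinity),
            ("groups", self.groups),
            ("operators", self.operators),
        ):
            if not values:
                raise ValueError(f"featurize config: empty axis {axis!r}")
        bad = set(self.vicinity) - {"NO", "ES"}
        if bad:
            raise ValueError(f"unknown vicinity operator(s): {sorted(bad)}")
        for g in self.groups:
            if g not in GROUPS:
                raise KeyError(f"unknown group {g!r}")
        for op in self.operators:
            if op not in _OP_POS:
                raise KeyError(f"unknown operator {op!r}")


def featurize(
    dataset: LabeledDataset | Sequence[SequenceRecord],
    config: FeaturizeConfig | None = None,
) -> DescriptorMatrix:
    """Generate the 0D/1D descriptor matrix for a dataset.

    One column per (index, vicinity, group, operator) combination, named
    ``<Index>_<Mod>_<Group>_<Aggr>``; row order follows the dataset.
    Columns constant across all instances carry no information and are
    dropped (logged).
    """
    cfg = config or FeaturizeConfig()
    cfg.validate()
    if isinstance(dataset, LabeledDataset):
        records = dataset.records
        labels = dataset.labels
    else:
        records = list(dataset)
        labels = None

    tables = {name: get_index(name).as_vector() for name in cfg.indices}
    group_members = {g: GROUPS[g].membership for g in cfg.groups}
    op_sel = np.array([_OP_POS[op] for op in cfg.operators], dtype=np.intp)

    names = [
        f"{iname}_{mod}_{g}_{op}"
        for iname in cfg.indices
        for mod in cfg.vicinity
        for g in cfg.groups
        for op in cfg.operators
    ]
    n_ops = len(cfg.operators)
    out = np.empty((len(records), len(names)))

    group_masks_cache: dict[str, dict[str, np.ndarray]] = {}
    for r, rec in enumerate(records):
        codes = _sequence_codes(rec.sequence)
        masks = group_masks_cache.get(rec.sequence)
        if masks is None:
            letters = np.array(list(rec.sequence))
            masks = {
                g: np.flatnonzero(np.isin(letters, list(members)))
                for g, members in group_members.items()
            }
            if len(group_masks_cache) < 4096:
                group_masks_cache[rec.sequence] = masks
        col = 0
        for iname in cfg.indices:
            raw = tables[iname][codes]
            arrays = {}
            if "NO" in cfg.vicinity:
                arrays["NO"] = raw
            if "ES" in cfg.vicinity:
                arrays["ES"] = es_values(raw)
            for mod in cfg.vicinity:
                arr = arrays[mod]
                for g in cfg.groups:
                    vals = aggregate_all(arr[masks[g]])
                    out[r, col : col + n_ops] = vals[op_sel]
                    col += n_ops

    df = pd.DataFrame(out, index=[rec.id for rec in records], columns=names)
    if cfg.drop_constant and len(records) > 1:
        constant = (df.nunique(axis=0) <= 1).to_numpy()
        if constant.any():
            logger.info(
                "featurize: dropping %d constant column(s) of %d",
                int(constant.sum()), len(names),
            )
            df = df.loc[:, ~constant]
    return DescriptorMatrix(df, labels)
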