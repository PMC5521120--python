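"""Synthetic two-class protein sequence datasets with controlled effect sizes.

The generator emulates the discriminative structure of an enzyme/non-enzyme
problem at the compositional level: the positive class draws residues from
a base frequency vector whose selected residues (by default glycine,
histidine and arginine — the residue types most associated with catalytic
sites) are boosted by a multiplicative shift.  Per-sequence heterogeneity
comes from a Dirichlet draw around the class frequencies; residues are
otherwise i.i.d., so any order structure must be planted explicitly with
:func:`plant_motif`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import DescriptorMatrix
from .seq_io import AMINO_ACIDS, LabeledDataset, SequenceRecord

#: Swiss-Prot-like background residue frequencies (approximate, renormalized).
PROTEOME_FREQUENCIES: dict[str, float] = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.054, "W": 0.011, "Y": 0.029, "V": 0.069,
}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults: 100 sequences per class of 50-300 residues, uniform base
    composition, a 3x boost of G/H/R in the positive class, and a Dirichlet
    concentration of 100 (moderate between-sequence compositional noise).
    """

    n_per_class: int = 100
    length_range: tuple[int, int] = (50, 300)
    base_frequencies: dict[str, float] | None = None   # None -> uniform 1/20
    shift: dict[str, float] = field(default_factory=lambda: {"G": 3.0, "H": 3.0, "R": 3.0})
    dirichlet_concentration: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError("length_range must satisfy 10 <= min <= max")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")

    def class_frequencies(self, positive: bool) -> np.ndarray:
        """Base frequencies, with the shift applied and renormalized for the
        positive class."""
        if self.base_frequencies is None:
            freq = np.full(20, 1.0 / 20.0)
        else:
            freq = np.array([self.base_frequencies[a] for a in AMINO_ACIDS], dtype=float)
            if (freq < 0).any() or freq.sum() <= 0:
                raise ValueError("invalid base frequency vector")
            freq = freq / freq.sum()
        if positive:
            mult = np.array([self.shift.get(a, 1.0) for a in AMINO_ACIDS], dtype=float)
            freq = freq * mult
            freq = freq / freq.sum()
        return freq


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a labeled dataset according to ``spec`` (deterministic per seed).

    Sequence lengths are uniform over ``length_range``; each sequence gets
    its own residue distribution drawn from a Dirichlet centered on its
    class frequencies.  Positive-class records come first.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    records: list[SequenceRecord] = []
    labels: list[int] = []
    for positive, prefix in ((True, "enz"), (False, "non")):
        base = spec.class_frequencies(positive)
        alpha = spec.dirichlet_concentration * base
        for i in range(spec.n_per_class):
            p = rng.dirichlet(alpha)
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            seq = "".join(rng.choice(aa, size=length, p=p))
            records.append(SequenceRecord(id=f"{prefix}_{i:04d}", sequence=seq))
            labels.append(1 if positive else 0)
    return LabeledDataset(records=records, labels=np.array(labels, dtype=int))


def plant_motif(
    dataset: LabeledDataset, motif: str = "HGHRH", seed: int = 0
) -> LabeledDataset:
    """Overwrite a random window of every positive-class sequence with a
    fixed k-mer, planting order structure that composition-only (0D)
    descriptors cannot see but order-sensitive (1D) descriptors can."""
    rng = np.random.default_rng(seed)
    records = []
    for rec, label in zip(dataset.records, dataset.labels):
        if label == 1 and len(rec.sequence) > len(motif):
            start = int(rng.integers(0, len(rec.sequence) - len(motif)))
            seq = rec.sequence[:start] + motif + rec.sequence[start + len(motif):]
            records.append(SequenceRecord(id=rec.id, sequence=seq))
        else:
            records.append(rec)
    return LabeledDataset(records=records, labels=dataset.labels.copy(),
                          class_names=dataset.class_names)


def make_separable_toy(n: int, gap: float, seed: int = 0) -> DescriptorMatrix:
    """Two 2-feature unit-variance Gaussian blobs with centers ``gap``
    standard deviations apart, for direct SVM tests bypassing featurization."""
    if n % 2 != 0 or n < 4:
        raise ValueError("n must be even and >= 4")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    half = n // 2
    X = rng.standard_normal((n, 2))
    X[:half, 0] -= gap / 2.0
    X[half:, 0] += gap / 2.0
    labels = np.r_[np.zeros(half, dtype=int), np.ones(half, dtype=int)]
    ids = [f"blob_{i:04d}" for i in range(n)]
    df = pd.DataFrame(X, index=ids, columns=["f1", "f2"])
    return DescriptorMatrix(df, labels)
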