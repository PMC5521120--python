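"""Pseudo-fold (2D) descriptors: Nandy lattice embedding and spectral moments.

A protein sequence is walked on the integer lattice: each residue advances
one unit step in a direction determined by a four-class physicochemical
partition of the alphabet.  Lattice points visited become graph nodes
(revisits merge, so the walk folds onto itself), consecutive distinct nodes
are connected by edges.  Nodes are weighted by the mean property value of
the residues merged into them, edges by the mean of the two node weights.
The spectral moment of order k is the trace of the k-th power of the
weighted node/adjacency matrix; the series mu_0..mu_15 is the 2D descriptor
vector for one weighting property.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .aa_indices import AAIndexTable, INDEX_CODES, get_index
from .matrix import DescriptorMatrix
from .seq_io import AMINO_ACIDS, LabeledDataset, SequenceRecord

#: Default four-class partition mapped to unit steps.  Aromatic residues step
#: +x, aliphatic hydrophobic -x, charged +y, the remaining polar/small
#: residues -y; configurable because the lattice directions are a
#: representation choice, not a property of the sequence.
DEFAULT_PARTITION: dict[str, str] = {
    "+x": "FWYH",
    "-x": "AVLIM",
    "+y": "KRDE",
    "-y": "GPSTNQC",
}

_STEPS = {"+x": (1, 0), "-x": (-1, 0), "+y": (0, 1), "-y": (0, -1)}


@dataclass
class Graph2D:
    """Node/edge-weighted graph from a lattice embedding of one sequence."""

    coords: list[tuple[int, int]]            # lattice point per node
    node_weights: np.ndarray                 # mean property of merged residues
    edges: list[tuple[int, int]]             # pairs of node indices, i < j
    walk: list[int]                          # residue k -> node index

    @property
    def n_nodes(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class SpectralMoments:
    """The mu_0..mu_kmax trace series under one weighting property."""

    mu: np.ndarray
    property_name: str


def _validate_partition(partition: dict[str, str]) -> dict[str, str]:
    if set(partition) != set(_STEPS):
        raise ValueError(f"partition must define exactly the directions {sorted(_STEPS)}")
    assignment: dict[str, str] = {}
    for direction, letters in partition.items():
        for ch in letters:
            if ch in assignment:
                raise ValueError(f"residue {ch!r} assigned to two directions")
            assignment[ch] = direction
    missing = sorted(set(AMINO_ACIDS) - set(assignment))
    if missing:
        raise ValueError(f"partition does not cover residue(s) {missing}")
    return assignment


def nandy_embed(
    record: SequenceRecord,
    index: AAIndexTable,
    partition: dict[str, str] | None = None,
) -> Graph2D:
    """Embed a sequence as a lattice walk and collapse it into a graph.

    The walk starts at the origin; residue values under ``index`` are
    averaged into the weight of the node each residue lands on.  The origin
    node receives no residue unless the walk revisits it; an unvisited-by-
    residues node has weight 0.
    """
    assignment = _validate_partition(partition or DEFAULT_PARTITION)
    node_of: dict[tuple[int, int], int] = {(0, 0): 0}
    coords: list[tuple[int, int]] = [(0, 0)]
    sums: list[float] = [0.0]
    counts: list[int] = [0]
    edges: set[tuple[int, int]] = set()
    walk: list[int] = []

    x = y = 0
    prev = 0
    for ch in record.sequence:
        dx, dy = _STEPS[assignment[ch]]
        x, y = x + dx, y + dy
        node = node_of.get((x, y))
        if node is None:
            node = len(coords)
            node_of[(x, y)] = node
            coords.append((x, y))
            sums.append(0.0)
            counts.append(0)
        sums[node] += index[ch]
        counts[node] += 1
        if node != prev:
            edges.add((min(prev, node), max(prev, node)))
        walk.append(node)
        prev = node

    weights = np.array(
        [s / c if c else 0.0 for s, c in zip(sums, counts)], dtype=float
    )
    return Graph2D(
        coords=coords, node_weights=weights, edges=sorted(edges), walk=walk
    )


def build_matrix(graph: Graph2D, include_diagonal: bool = True) -> np.ndarray:
    """Weighted node/adjacency matrix of the graph.

    Off-diagonal (i, j) holds the edge weight — the mean of the two node
    weights — where an edge exists, else 0.  With ``include_diagonal`` the
    node weights sit on the diagonal (node matrix); without it the matrix is
    a pure weighted adjacency matrix.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    w = graph.node_weights
    m = np.zeros((graph.n_nodes, graph.n_nodes))
    for i, j in graph.edges:
        m[i, j] = m[j, i] = 0.5 * (w[i] + w[j])
    if include_diagonal:
        np.fill_diagonal(m, w)
    return m


def spectral_moments(
    matrix: np.ndarray, kmax: int = 15, property_name: str = ""
) -> SpectralMoments:
    """Trace series mu_k = tr(M^k), k = 0..kmax (mu_0 = node count)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    n = m.shape[0]
    mu = np.empty(kmax + 1)
    mu[0] = n
    power = np.eye(n)
    for k in range(1, kmax + 1):
        power = power @ m
        mu[k] = np.trace(power)
    return SpectralMoments(mu=mu, property_name=property_name)


def signed_log(x: np.ndarray) -> np.ndarray:
    """sign(x) * log1p(|x|): a magnitude squash that keeps the sign.

    High-order moments grow geometrically; this transform keeps them on a
    modelling-friendly scale without losing sign information.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x))


def featurize_2d(
    dataset: LabeledDataset | Sequence[SequenceRecord],
    properties: Sequence[str] = INDEX_CODES,
    partition: dict[str, str] | None = None,
    kmax: int = 15,
    include_diagonal: bool = True,
    log_scale: bool = False,
    drop_constant: bool = True,
) -> DescriptorMatrix:
    """Spectral-moment descriptor matrix: ``kmax + 1`` columns per property.

    Columns are named ``MU<k>_2D_<Property>``.  ``log_scale`` applies the
    signed-log transform, recommended when the moments feed a classifier.
    """
    if not properties:
        raise ValueError("at least one weighting property is required")
    if isinstance(dataset, LabeledDataset):
        records = dataset.records
        labels = dataset.labels
    else:
        records = list(dataset)
        labels = None

    tables = [get_index(p) for p in properties]
    names = [f"MU{k}_2D_{t.name}" for t in tables for k in range(kmax + 1)]
    out = np.empty((len(records), len(names)))
    for r, rec in enumerate(records):
        col = 0
        for table in tables:
            graph = nandy_embed(rec, table, partition)
            m = build_matrix(graph, include_diagonal=include_diagonal)
            mu = spectral_moments(m, kmax=kmax, property_name=table.name).mu
            out[r, col : col + kmax + 1] = signed_log(mu) if log_scale else mu
            col += kmax + 1

    df = pd.DataFrame(out, index=[rec.id for rec in records], columns=names)
    if drop_constant and len(records) > 1:
        constant = (df.nunique(axis=0) <= 1).to_numpy()
        if constant.any():
            df = df.loc[:, ~constant]
    return DescriptorMatrix(df, labels)
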