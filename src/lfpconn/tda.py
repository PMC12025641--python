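"""Persistent homology of connectivity networks.

A connectivity matrix (coherence or partial correlation, both bounded by 1)
is mapped to a dissimilarity (1 - C, or 1 - |rho|), from which the
Vietoris-Rips filtration is built: a simplex enters at the largest pairwise
dissimilarity among its vertices.  Dimension-0 features (connected
components) are born at 0 and die at the minimum-spanning-tree edge
weights; dimension-1 features (loops) are paired by boundary-matrix
reduction over GF(2).  Diagrams are compared with the order-2 Wasserstein
distance under the sup-norm ground metric,

    d_W(D1, D2) = min_Gamma ( sum_{(x,y) in Gamma} ||x - y||_inf^2 )^{1/2},

where matchings may send points to their diagonal projections; the optimal
matching is solved exactly as an assignment problem.  Directed (asymmetric)
networks are not supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import minimum_spanning_tree

from .exceptions import ValidationError

__all__ = [
    "DissimilarityMatrix",
    "PersistenceDiagram",
    "dissimilarity_from_connectivity",
    "vr_persistence",
    "wasserstein_distance",
    "pairwise_diagram_distances",
    "group_distance_summary",
]


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=np.float64)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("dissimilarity matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValidationError(
                "dissimilarity must be symmetric; directed networks are unsupported"
            )
        if np.any(d < -1e-12):
            raise ValidationError("dissimilarities must be nonnegative")
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        self.values = np.maximum(d, 0.0)


def dissimilarity_from_connectivity(C, source: str = "coherence") -> DissimilarityMatrix:
    """Map a connectivity matrix to a dissimilarity: 1 - C, or 1 - |rho|."""
    vals = np.asarray(getattr(C, "values", C), dtype=np.float64)
    if source == "coherence":
        if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
            raise ValidationError("coherence values must lie in [0, 1]")
        d = 1.0 - np.clip(vals, 0.0, 1.0)
    elif source == "partial_correlation":
        if np.any(np.abs(vals) > 1 + 1e-9):
            raise ValidationError("partial correlations must lie in [-1, 1]")
        d = 1.0 - np.abs(np.clip(vals, -1.0, 1.0))
    else:
        raise ValueError("source must be 'coherence' or 'partial_correlation'")
    return DissimilarityMatrix(values=d, source=source)


@dataclass
class PersistenceDiagram:
    """Multiset of finite (birth, death) pairs for one homology dimension."""

    dimension: int
    pairs: np.ndarray  # (n, 2) with death > birth
    essential: np.ndarray = field(default_factory=lambda: np.empty(0))  # births

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.float64).reshape(-1, 2)
        self.essential = np.asarray(self.essential, dtype=np.float64).ravel()


def vr_persistence(D: DissimilarityMatrix | np.ndarray, maxdim: int = 1) -> list[PersistenceDiagram]:
    """Vietoris-Rips persistence diagrams in dimensions 0..maxdim (maxdim <= 1).

    H0: births at 0, deaths at the minimum-spanning-tree edge weights, one
    essential class.  H1: standard boundary-matrix reduction over GF(2) on
    edges and triangles, simplices ordered by filtration value with
    dimension and lexicographic tie-breaks; zero-persistence pairs dropped.
    """
    if maxdim not in (0, 1):
        raise ValueError("maxdim must be 0 or 1")
    if not isinstance(D, DissimilarityMatrix):
        D = DissimilarityMatrix(values=np.asarray(D, dtype=np.float64), source="coherence")
    d = D.values
    n = d.shape[0]

    # csgraph ignores zero-weight edges, so shift all weights by +1 (a
    # monotone transform that leaves the MST edge set unchanged) and shift
    # back; zero-dissimilarity merges give zero-persistence pairs, dropped.
    shifted = d + 1.0
    np.fill_diagonal(shifted, 0.0)
    mst = minimum_spanning_tree(shifted).toarray()
    deaths = np.sort(mst[mst > 0]) - 1.0
    deaths = deaths[deaths > 1e-15]
    h0_pairs = np.column_stack([np.zeros(len(deaths)), deaths])
    diagrams = [PersistenceDiagram(0, h0_pairs, essential=np.array([0.0]))]
    if maxdim == 0:
        return diagrams

    edges = [(d[i, j], i, j) for i, j in combinations(range(n), 2)]
    tris = [
        (max(d[i, j], d[i, k], d[j, k]), i, j, k)
        for i, j, k in combinations(range(n), 3)
    ]
    # global filtration order: value, then dimension (vertices implicit at 0)
    simplices = (
        [(w, 1, (i, j)) for w, i, j in edges]
        + [(w, 2, (i, j, k)) for w, i, j, k in tris]
    )
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index_of: dict[tuple, int] = {}
    values = []
    for pos, (w, _, verts) in enumerate(simplices):
        index_of[verts] = pos
        values.append(w)

    # reduction; columns as bitmasks over simplex positions
    low_to_col: dict[int, int] = {}
    columns: dict[int, int] = {}
    h1_pairs = []
    uf = list(range(n))

    def find(a: int) -> int:
        while uf[a] != a:
            uf[a] = uf[uf[a]]
            a = uf[a]
        return a

    creators_h1: set[int] = set()
    for pos, (w, dim, verts) in enumerate(simplices):
        if dim == 1:
            i, j = verts
            ri, rj = find(i), find(j)
            if ri != rj:
                uf[ri] = rj  # edge kills an H0 class (already in MST deaths)
            else:
                creators_h1.add(pos)  # edge creates a 1-cycle
        else:
            i, j, k = verts
            col = (
                (1 << index_of[(i, j)])
                | (1 << index_of[(i, k)])
                | (1 << index_of[(j, k)])
            )
            while col:
                low = col.bit_length() - 1
                if low in low_to_col:
                    col ^= columns[low_to_col[low]]
                else:
                    break
            if col:
                low = col.bit_length() - 1
                low_to_col[low] = pos
                columns[pos] = col
                birth, death = values[low], w
                if death > birth:
                    h1_pairs.append((birth, death))
                creators_h1.discard(low)
    essential_h1 = np.array(sorted(values[p] for p in creators_h1 if p not in low_to_col))
    # creators never killed are essential H1 classes (none for a full VR
    # complex on a finite metric space, kept for generality)
    diagrams.append(PersistenceDiagram(1, np.array(h1_pairs).reshape(-1, 2),
                                       essential=essential_h1))
    return diagrams


def wasserstein_distance(D1: PersistenceDiagram, D2: PersistenceDiagram, q: float = 2) -> float:
    """Order-q Wasserstein distance with sup-norm ground metric, solved exactly.

    Essential classes are excluded; each off-diagonal point may match the
    other diagram's points or its own diagonal projection (cost
    (death - birth)/2 in the sup norm).
    """
    if D1.dimension != D2.dimension:
        raise ValueError("diagrams must have the same homology dimension")
    a, b = D1.pairs, D2.pairs
    n1, n2 = len(a), len(b)
    if n1 == 0 and n2 == 0:
        return 0.0
    size = n1 + n2
    cost = np.zeros((size, size))
    if n1 and n2:
        diff = np.abs(a[:, None, :] - b[None, :, :]).max(axis=2)
        cost[:n1, :n2] = diff**q
    diag_a = (a[:, 1] - a[:, 0]) / 2.0 if n1 else np.empty(0)
    diag_b = (b[:, 1] - b[:, 0]) / 2.0 if n2 else np.empty(0)
    big = 1e18
    cost[:n1, n2:] = big
    cost[n1:, :n2] = big
    for i in range(n1):
        cost[i, n2 + i] = diag_a[i] ** q
    for j in range(n2):
        cost[n1 + j, j] = diag_b[j] ** q
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() ** (1.0 / q))


def pairwise_diagram_distances(diagrams: list[PersistenceDiagram], q: float = 2) -> np.ndarray:
    """Symmetric matrix of Wasserstein distances between trial diagrams."""
    n = len(diagrams)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = wasserstein_distance(diagrams[i], diagrams[j], q)
    return out


def group_distance_summary(distances: np.ndarray, groups) -> pd.DataFrame:
    """Group x group mean diagram distances.

    Within-group means exclude self-distances; a single-trial group's
    within-group mean is undefined and reported as NaN.
    """
    d = np.asarray(distances, dtype=np.float64)
    labels = np.asarray(groups)
    if len(labels) != d.shape[0]:
        raise ValueError("every trial must carry a group label")
    uniq = sorted(set(labels.tolist()))
    for g in uniq:
        if (labels == g).sum() == 0:  # pragma: no cover - cannot happen via set
            raise ValueError(f"empty group {g!r}")
    out = pd.DataFrame(index=uniq, columns=uniq, dtype=float)
    for gi in uniq:
        ii = np.flatnonzero(labels == gi)
        for gj in uniq:
            jj = np.flatnonzero(labels == gj)
            if gi == gj:
                if len(ii) < 2:
                    out.loc[gi, gj] = np.nan
                else:
                    sub = d[np.ix_(ii, ii)]
                    out.loc[gi, gj] = sub[np.triu_indices(len(ii), k=1)].mean()
            else:
                out.loc[gi, gj] = d[np.ix_(ii, jj)].mean()
    return out
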