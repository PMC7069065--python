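"""Morphometric similarity network construction, thresholding, and strength.

A subject's MSN is built in two steps.  Each morphometric feature is first
z-scored across regions, which removes the order-of-magnitude differences in
raw units (gray-matter volume is ~10^3 mm^3 while mean diffusivity is ~10^-3
mm^2/s).  The network edge between regions i and j is then the Pearson
correlation of the two regions' z-scored feature vectors; the diagonal is set
to zero.  Because every feature is zero-centered the edge-weight distribution
is approximately normal about zero.

Networks are compared at matched edge density: proportional thresholding
retains the k = round(d * n(n-1)/2) most-positive edges so every compared
network has the same edge count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FeatureTable

__all__ = [
    "MSNMatrix",
    "ThresholdedMSN",
    "zscore_features",
    "build_msn",
    "threshold_density",
    "nodal_strength",
    "graph_strength",
    "write_matrix",
    "DEFAULT_DENSITIES",
]

#: Density grid used throughout: 5% to 40% in 5% steps.
DEFAULT_DENSITIES: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.45, 0.05), 2))


@dataclass
class MSNMatrix:
    """A per-subject morphometric similarity network (weighted, unthresholded)."""

    subject_id: str
    model: str
    weights: np.ndarray  # (n, n), symmetric, zero diagonal, entries in [-1, 1]
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class ThresholdedMSN:
    """A density-thresholded MSN: weighted and binary forms at density d."""

    parent: MSNMatrix
    density: float
    weighted: np.ndarray
    binary: np.ndarray
    k_edges: int

    @property
    def n_regions(self) -> int:
        return self.weighted.shape[0]


def zscore_features(table: FeatureTable | np.ndarray) -> np.ndarray:
    """Z-score each feature across regions (sample SD, n-1 denominator).

    Raises if any feature is constant across regions (zero SD), naming it.
    """
    if isinstance(table, FeatureTable):
        values = table.values
        labels = table.feature_labels
    else:
        values = np.asarray(table, dtype=float)
        labels = tuple(f"feature_{i}" for i in range(values.shape[1]))
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance feature across regions: {labels[zero[0]]!r}")
    return (values - mean) / sd


def build_msn(
    normalized: np.ndarray,
    subject_id: str = "",
    model: str = "",
    region_labels: Sequence[str] | None = None,
) -> MSNMatrix:
    """Correlate every region pair's normalized feature vectors.

    ``normalized`` is the regions x features z-scored matrix; the result is the
    n x n matrix of Pearson correlations between region rows, diagonal zeroed.
    """
    z = np.asarray(normalized, dtype=float)
    if z.shape[1] < 3:
        raise ValueError("need at least 3 features for a meaningful region-pair correlation")
    row_sd = z.std(axis=1)
    flat = np.flatnonzero(row_sd == 0)
    if flat.size:
        name = region_labels[flat[0]] if region_labels else f"region {flat[0]}"
        raise ValueError(f"constant feature vector for {name!r}; correlation undefined")
    w = np.corrcoef(z)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return MSNMatrix(
        subject_id=subject_id,
        model=model,
        weights=w,
        region_labels=tuple(region_labels) if region_labels is not None else None,
    )


def _edge_order(weights: np.ndarray, rank_by: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted most-retainable first, ties by (i, j) ascending."""
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    key = -np.abs(w) if rank_by == "magnitude" else -w
    order = np.lexsort((ju, iu, key))  # primary: key; then i, then j
    return iu[order], ju[order], w[order]


def threshold_density(
    msn: MSNMatrix | np.ndarray, d: float, rank_by: str = "signed"
) -> ThresholdedMSN:
    """Retain the k = round(d * n(n-1)/2) strongest edges; zero the rest.

    Edges are ranked by signed weight (most positive first) by default;
    ``rank_by="magnitude"`` ranks by absolute weight for sensitivity analyses.
    k rounds half away from zero.  Ties at the cutoff are broken by ascending
    (i, j) edge index, so retained edge sets nest monotonically in d.
    """
    if not (0 < d <= 1):
        raise ValueError(f"density must be in (0, 1], got {d}")
    if rank_by not in ("signed", "magnitude"):
        raise ValueError(f"rank_by must be 'signed' or 'magnitude', got {rank_by!r}")
    parent = msn if isinstance(msn, MSNMatrix) else MSNMatrix("", "", np.asarray(msn, float))
    n = parent.n_regions
    n_pairs = n * (n - 1) // 2
    k = int(np.floor(d * n_pairs + 0.5))  # round half away from zero (d > 0)
    ii, jj, ww = _edge_order(parent.weights, rank_by)
    weighted = np.zeros_like(parent.weights)
    weighted[ii[:k], jj[:k]] = ww[:k]
    weighted += weighted.T
    binary = (weighted != 0).astype(float)
    return ThresholdedMSN(parent=parent, density=d, weighted=weighted, binary=binary, k_edges=k)


def _as_matrix(net: ThresholdedMSN | MSNMatrix | np.ndarray) -> np.ndarray:
    if isinstance(net, ThresholdedMSN):
        return net.weighted
    if isinstance(net, MSNMatrix):
        return net.weights
    return np.asarray(net, dtype=float)


def nodal_strength(net: ThresholdedMSN | MSNMatrix | np.ndarray) -> np.ndarray:
    """Sum of each node's edge weights (not normalized by edge count)."""
    return _as_matrix(net).sum(axis=1)


def graph_strength(net: ThresholdedMSN | MSNMatrix | np.ndarray) -> float:
    """Average nodal strength over the graph."""
    return float(nodal_strength(net).mean())


def write_matrix(
    matrix: np.ndarray, path: str | Path, region_labels: Sequence[str] | None = None
) -> Path:
    """Write an n x n matrix as TSV with region labels as header and index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = list(region_labels) if region_labels else list(range(matrix.shape[0]))
    df = pd.DataFrame(np.asarray(matrix), index=labels, columns=labels)
    df.index.name = "region"
    df.to_csv(path, sep="\t")
    return path
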