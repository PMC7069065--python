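"""Pairwise network-similarity statistics for comparing MSNs.

Four statistics quantify how similar two networks over the same parcellation
are: the Pearson correlation over all off-diagonal edge weights, the same
correlation restricted to edges nonzero in both networks, the Mantel statistic
(Pearson over one off-diagonal half — identical to the all-edge correlation on
symmetric zero-diagonal matrices, but conventionally reported as a guard
against the duplicated-half inflation worry), and, for binarized networks, the
proportion of the reference network's edges replicated in the second network.

Model differences in topology are summarized by paired-t effect sizes
r = sqrt(t^2 / (t^2 + df)) on per-subject graph strength, rather than
p values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from .network import MSNMatrix, ThresholdedMSN, _as_matrix

__all__ = [
    "SimilarityRecord",
    "EffectSizeRecord",
    "edge_correlation",
    "mantel_statistic",
    "replication_proportion",
    "paired_effect_size",
    "compare_networks",
]


@dataclass
class SimilarityRecord:
    """One (subject, network pair, density) row of similarity statistics."""

    subject_id: str
    pair: tuple[str, str]  # (reference/fuller label, comparison label)
    density: float
    r_all: float
    r_nonzero: float
    mantel_r: float
    prop_replicated: float
    mantel_p: float | None = None


@dataclass
class EffectSizeRecord:
    """Paired-t effect size for a model contrast at one density."""

    contrast: str
    density: float
    t: float
    df: int
    r_effect: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3:
        raise ValueError(f"need at least 3 element pairs for a correlation, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in edge-weight vector; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def edge_correlation(
    X: ThresholdedMSN | MSNMatrix | np.ndarray,
    Y: ThresholdedMSN | MSNMatrix | np.ndarray,
    mode: str = "all",
) -> float:
    """Pearson correlation between two networks' off-diagonal edge weights.

    ``mode="all"`` uses every off-diagonal element; ``mode="nonzero"`` keeps
    only elements nonzero in *both* networks (an element zeroed by thresholding
    in either network is excluded).
    """
    a, b = _as_matrix(X), _as_matrix(Y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    off = ~np.eye(a.shape[0], dtype=bool)
    if mode == "all":
        mask = off
    elif mode == "nonzero":
        mask = off & (a != 0) & (b != 0)
    else:
        raise ValueError(f"mode must be 'all' or 'nonzero', got {mode!r}")
    return _pearson(a[mask], b[mask])


def _check_symmetric(m: np.ndarray, name: str) -> None:
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric for the Mantel statistic")


def mantel_statistic(
    X: ThresholdedMSN | MSNMatrix | np.ndarray,
    Y: ThresholdedMSN | MSNMatrix | np.ndarray,
    n_perm: int = 0,
    seed: int | None = None,
    all_perms: bool = False,
) -> tuple[float, float | None]:
    """Mantel matrix correlation: Pearson r over the strictly-lower triangles.

    With ``n_perm > 0`` a permutation p-value is computed by simultaneously
    permuting the rows and columns of Y: p = (1 + #{|r_perm| >= |r|}) /
    (1 + n_perm).  With ``all_perms=True`` every node permutation is
    enumerated (small n only) and p is the exact proportion, identity
    included, without smoothing.
    """
    a, b = _as_matrix(X), _as_matrix(Y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    _check_symmetric(a, "X")
    _check_symmetric(b, "Y")
    n = a.shape[0]
    il = np.tril_indices(n, k=-1)
    r_obs = _pearson(a[il], b[il])

    p: float | None = None
    if all_perms:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            r_perm = _pearson(a[il], b[np.ix_(idx, idx)][il])
            count += abs(r_perm) >= abs(r_obs) - 1e-12
            total += 1
        p = count / total
    elif n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            r_perm = _pearson(a[il], b[np.ix_(idx, idx)][il])
            count += abs(r_perm) >= abs(r_obs) - 1e-12
        p = (1 + count) / (1 + n_perm)
    return r_obs, p


def replication_proportion(
    X_binary: ThresholdedMSN | np.ndarray, Y_binary: ThresholdedMSN | np.ndarray
) -> float:
    """Fraction of the reference network's edges present in the second network.

    X is the fuller/reference model's binary network:
    sum(x != 0 & y != 0) / sum(x != 0), over off-diagonal elements.
    """
    a = X_binary.binary if isinstance(X_binary, ThresholdedMSN) else np.asarray(X_binary)
    b = Y_binary.binary if isinstance(Y_binary, ThresholdedMSN) else np.asarray(Y_binary)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    off = ~np.eye(a.shape[0], dtype=bool)
    ref = (a != 0) & off
    denom = int(ref.sum())
    if denom == 0:
        raise ValueError("reference network has no edges; replication undefined")
    return float(((b != 0) & ref).sum() / denom)


def paired_effect_size(
    a: np.ndarray, b: np.ndarray, contrast: str = "", density: float = np.nan
) -> EffectSizeRecord:
    """Paired-t effect size r = sqrt(t^2/(t^2+df)) on subject-paired metrics."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D subject-paired vectors")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 subject pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    r_effect = float(np.sqrt(t * t / (t * t + df)))
    return EffectSizeRecord(contrast=contrast, density=density, t=t, df=df, r_effect=r_effect)


def compare_networks(
    X: ThresholdedMSN,
    Y: ThresholdedMSN,
    subject_id: str,
    pair: tuple[str, str],
    mantel_perms: int = 0,
    seed: int | None = None,
) -> SimilarityRecord:
    """All four similarity statistics for one thresholded network pair.

    X is the reference (fuller model, or first session); both networks must be
    thresholded at the same density.
    """
    if X.density != Y.density:
        raise ValueError(f"density mismatch: {X.density} vs {Y.density}")
    mantel_r, mantel_p = mantel_statistic(X, Y, n_perm=mantel_perms, seed=seed)
    return SimilarityRecord(
        subject_id=subject_id,
        pair=pair,
        density=X.density,
        r_all=edge_correlation(X, Y, mode="all"),
        r_nonzero=edge_correlation(X, Y, mode="nonzero"),
        mantel_r=mantel_r,
        prop_replicated=replication_proportion(X, Y),
        mantel_p=mantel_p,
    )
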