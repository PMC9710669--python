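"""Per-chunk mRMR feature ranking — the goodness function of the drift detector.

Each landmark window (chunk) of the stream is scored with minimum-redundancy
maximum-relevance: features are added greedily, the first maximizing mutual
information with the class, each next one maximizing relevance minus the mean
MI with the features already chosen (the MID "difference" scheme; the
quotient MIQ variant is available). Expression values are discretized into
equal-frequency bins before MI estimation.

All tie-breaks are by lowest feature index so a chunk always yields one
deterministic selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureSet




class SingleClassChunkError(ValueError):
    """Selection is undefined on a chunk containing a single class."""


@dataclass
class Chunk:
    """One landmark window: W instances with labels, in stream order."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("X width and feature_names mismatch")

    @property
    def n_classes_present(self) -> int:
        return len(np.unique(self.y))


def discretize(values: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Equal-frequency binning into levels 0..n_bins-1.

    Ties are broken by stable sample order (first occurrence gets the lower
    rank). If the vector has fewer distinct values than bins, levels collapse
    to the distinct values, with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    n = len(values)
    distinct = np.unique(values)
    if len(distinct) < n_bins:
        warnings.warn(
            f"only {len(distinct)} distinct value(s) for {n_bins} bins; "
            "collapsing to distinct-value levels", stacklevel=2)
        return np.searchsorted(distinct, values).astype(np.int64)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    I = sum_{a,b} p(a,b) log2( p(a,b) / (p(a) p(b)) ), from the empirical
    contingency table.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) == 0:
        raise ValueError("empty vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx, ky = int(xi.max()) + 1, int(yi.max()) + 1
    joint = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky)
    return _mi_from_table(joint)


def _mi_from_table(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def mrmr_rank(chunk: Chunk, n_select: int = 10, scheme: str = "difference",
              n_bins: int = 3) -> FeatureSet:
    """Greedy mRMR forward selection on one chunk.

    Returns exactly ``min(n_select, n_features)`` features in selection
    order. Relevance terms are computed once per chunk and redundancy terms
    cached; results are identical to naive per-step recomputation.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    if scheme not in ("difference", "quotient"):
        raise ValueError("scheme must be 'difference' or 'quotient'")
    if chunk.n_classes_present < 2:
        raise SingleClassChunkError(
            "selection undefined on a single-class chunk")

    n_feat = chunk.X.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features collapse silently
        disc = np.stack([discretize(chunk.X[:, j], n_bins)
                         for j in range(n_feat)], axis=1)
    relevance = np.array([mutual_information(disc[:, j], chunk.y)
                          for j in range(n_feat)])

    selected: list[int] = []
    red_cache = np.zeros((0, n_feat))  # rows: selected features, MI to all
    remaining = np.ones(n_feat, dtype=bool)
    k = min(n_select, n_feat)
    while len(selected) < k:
        if not selected:
            score = relevance.copy()
        else:
            mean_red = red_cache.mean(axis=0)
            if scheme == "difference":
                score = relevance - mean_red
            else:
                score = relevance / (mean_red + 1e-12)
        score = np.where(remaining, score, -np.inf)
        j = int(np.argmax(score))  # argmax takes the lowest index on ties
        selected.append(j)
        remaining[j] = False
        row = np.array([mutual_information(disc[:, j], disc[:, m])
                        for m in range(n_feat)])
        red_cache = np.vstack([red_cache, row])

    return FeatureSet([chunk.feature_names[j] for j in selected],
                      origin="chunk")
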