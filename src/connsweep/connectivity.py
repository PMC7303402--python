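"""Condition-specific weighted-correlation adjacency matrices.

For each condition the cleaned ROI series are correlated pairwise with
nonnegative per-scan weights (the clipped HRF-convolved block regressor),
Fisher z-transformed (atanh), and rectified: anticorrelations are set to
zero, not absolute-valued.  The result is one symmetric nonnegative
160 x 160 matrix per participant per condition with zero diagonal.

Correlations are capped at 1 - 1e-7 in magnitude before atanh so that
degenerate (duplicated-node) inputs stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

R_CAP = 1.0 - 1e-7
SYMMETRY_TOL = 1e-12


class UndefinedCorrelationError(ValueError):
    """A pairwise weighted correlation is undefined (zero weighted variance)."""


@dataclass(frozen=True)
class ConditionAdjacency:
    condition: str
    matrix: np.ndarray = field(repr=False)   # n x n, symmetric, >= 0, zero diag
    participant_id: str = ""

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if np.abs(m - m.T).max() > SYMMETRY_TOL:
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("adjacency entries must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def _weighted_moments(X: np.ndarray, w: np.ndarray):
    wsum = w.sum()
    mu = (w @ X) / wsum
    Xc = X - mu
    cov = (Xc * w[:, None]).T @ Xc / wsum
    return cov


def weighted_correlation(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation with frequency-weight semantics.

    r = cov_w(x, y) / sqrt(var_w(x) var_w(y)) using weighted means; the
    normalization cancels, so rescaling the weights leaves r unchanged.
    Uniform weights reduce to the ordinary Pearson r; 0/1 indicator
    weights reduce to Pearson r on the indicated subset.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    cov = _weighted_moments(np.column_stack([x, y]), w)
    vx, vy = cov[0, 0], cov[1, 1]
    if vx <= 0 or vy <= 0:
        raise UndefinedCorrelationError("zero weighted variance")
    r = cov[0, 1] / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def build_adjacency(
    ts: np.ndarray,
    weights: np.ndarray,
    condition: str = "",
    participant_id: str = "",
) -> ConditionAdjacency:
    """Rectified Fisher-z adjacency from a T x N series and per-scan weights.

    Pairwise weighted correlations -> |r| capped at 1 - 1e-7 -> z = atanh(r)
    -> negative z zeroed -> zero diagonal.  Raises
    :class:`UndefinedCorrelationError` naming the first offending node if
    any node has zero weighted variance.
    """
    X = np.asarray(ts, float)
    w = np.asarray(weights, float)
    if X.ndim != 2:
        raise ValueError("time series must be T x N")
    if len(w) != X.shape[0]:
        raise ValueError("weights length must match the number of scans")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    cov = _weighted_moments(X, w)
    var = np.diag(cov)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise UndefinedCorrelationError(
            f"zero weighted variance at node(s) {bad.tolist()}: "
            "pairwise correlations involving them are undefined"
        )
    denom = np.sqrt(np.outer(var, var))
    r = cov / denom
    r = np.clip(r, -R_CAP, R_CAP)
    z = np.arctanh(r)
    z[z < 0] = 0.0
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConditionAdjacency(condition=condition, matrix=z,
                              participant_id=participant_id)
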