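"""Hemodynamic regressors and per-scan condition weights.

Two artefacts are derived from the block design:

* *task regressors* — boxcars sampled at scan times and convolved with a
  canonical double-gamma hemodynamic response function (HRF); used to
  regress task co-activation out of the ROI series, and (unconvolved) for
  the task-motion correlation in QC;
* *condition weights* — the same convolved boxcars with negative values
  clipped to zero, used as nonnegative per-scan weights in the
  condition-specific weighted correlation.

The HRF is the canonical double-gamma: response gamma peaking near 6 s,
undershoot gamma near 16 s, peak:undershoot amplitude ratio 6, rescaled to
unit peak.  A scan counts as "on" for a block when its acquisition
midpoint falls inside the block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma

from .design import CONDITIONS, SessionDesign

# canonical double-gamma parameters (shape, scale in seconds)
_PEAK_SHAPE = 6.0
_UNDERSHOOT_SHAPE = 16.0
_DISPERSION = 1.0
_RATIO = 6.0

MIN_HRF_LENGTH_S = 32.0


@dataclass(frozen=True)
class HrfKernel:
    """Sampled HRF with unit peak."""

    dt: float                 # sample spacing, seconds
    values: np.ndarray        # finite support, values[0] == 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ConditionWeights:
    """Nonnegative per-scan weights for one condition."""

    condition: str
    weights: np.ndarray       # length n_volumes, >= 0, at least one > 0


def double_gamma(t: np.ndarray) -> np.ndarray:
    """Unnormalized canonical double-gamma evaluated at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    peak = _gamma.pdf(t, _PEAK_SHAPE, scale=_DISPERSION)
    under = _gamma.pdf(t, _UNDERSHOOT_SHAPE, scale=_DISPERSION)
    return peak - under / _RATIO


def hrf_kernel(tr: float, length: float = 32.0) -> HrfKernel:
    """Canonical HRF sampled every ``tr`` seconds over ``length`` seconds.

    Scaled to unit peak.  ``length`` must be at least 32 s so the
    undershoot has decayed to ~0 at the kernel end.
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    if length < MIN_HRF_LENGTH_S:
        raise ValueError(f"kernel length must be >= {MIN_HRF_LENGTH_S} s, got {length}")
    t = np.arange(0.0, length + 1e-9, tr)
    v = double_gamma(t)
    v = v / np.max(v)
    return HrfKernel(dt=tr, values=v)


def boxcar(design: SessionDesign, condition: str, tr: float, n_volumes: int) -> np.ndarray:
    """0/1 vector at scan resolution: scan midpoint inside a block => 1."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; valid: {CONDITIONS}")
    mids = (np.arange(n_volumes) + 0.5) * tr
    out = np.zeros(n_volumes)
    for b in design.blocks_of(condition):
        out[(mids >= b.onset) & (mids < b.onset + b.duration)] = 1.0
    return out


def block_regressor(
    design: SessionDesign, condition: str, tr: float, n_volumes: int
) -> np.ndarray:
    """HRF-convolved boxcar for ``condition``, truncated to ``n_volumes``.

    The unconvolved boxcar uses the scan-midpoint rule (see
    :func:`boxcar`); convolution is with :func:`hrf_kernel` at the same
    sample spacing.
    """
    box = boxcar(design, condition, tr, n_volumes)
    kern = hrf_kernel(tr)
    return np.convolve(box, kern.values)[:n_volumes]


def condition_weights(
    design: SessionDesign, condition: str, tr: float, n_volumes: int
) -> ConditionWeights:
    """Per-scan weights: convolved boxcar, negatives clipped to zero.

    Not renormalized — the weighted correlation is invariant to weight
    scale.  Raises if the condition never occurs (all-zero weights).
    """
    w = np.clip(block_regressor(design, condition, tr, n_volumes), 0.0, None)
    if not np.any(w > 0):
        raise ValueError(
            f"condition {condition!r} never occurs in the design: all weights zero"
        )
    return ConditionWeights(condition=condition, weights=w)
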