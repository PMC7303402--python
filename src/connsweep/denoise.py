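"""ROI time-series cleaning, in fixed order.

regression (nuisance PCs + realignment + convolved task regressors)
-> high-pass (discrete-cosine basis, cutoff 0.008 Hz)
-> linear detrend
-> despike (tanh soft-clip at 3 robust sd).

No low-pass is applied anywhere: condition-specific connectivity must not
smear signal across block boundaries.  An optional spike-regressor mode
adds one indicator column per high-FD frame to the confound matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

N_COMPCOR = 5
HP_CUTOFF_HZ = 0.008
DESPIKE_SD = 3.0
SPIKE_FD_MM = 0.5
_MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class ConfoundMatrix:
    """T x K design of nuisance regressors (no intercept column; the
    regression always adds one)."""

    matrix: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2:
            raise ValueError("confound matrix must be 2-D")
        keep = m.std(axis=0) > 0
        if not keep.all():
            dropped = [self.names[i] if self.names else str(i)
                       for i in np.flatnonzero(~keep)]
            warnings.warn(f"dropping constant confound columns: {dropped}",
                          stacklevel=2)
            object.__setattr__(self, "matrix", m[:, keep])
            if self.names:
                object.__setattr__(
                    self, "names",
                    tuple(n for n, k in zip(self.names, keep) if k))
        m = self.matrix
        if m.shape[1] and np.linalg.matrix_rank(m - m.mean(axis=0)) < m.shape[1]:
            raise ValueError("confound matrix is rank deficient after centering")


def nuisance_pca(nuisance_signals: np.ndarray, n_components: int = N_COMPCOR) -> np.ndarray:
    """First principal-component time courses of the nuisance channels.

    aCompCor-style: channels are mean-centered, components ordered by
    explained variance, and each component's sign is fixed so its
    largest-magnitude channel loading is positive.  If the channel matrix
    has rank below ``n_components`` the available components are returned
    with a warning.
    """
    X = np.asarray(nuisance_signals, dtype=float)
    if X.ndim != 2:
        raise ValueError("nuisance_signals must be T x M")
    T, M = X.shape
    if T <= M:
        raise ValueError(f"need more time points ({T}) than channels ({M})")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(T, M) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"nuisance channels have rank {rank} < {n_components}; "
            f"returning {k} components", stacklevel=2)
    comps = U[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            comps[:, j] = -comps[:, j]
    return comps


def regress_confounds(ts: np.ndarray, confounds: ConfoundMatrix | np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``ts`` on the confounds + intercept."""
    Y = np.asarray(ts, dtype=float)
    X = confounds.matrix if isinstance(confounds, ConfoundMatrix) else np.asarray(confounds, float)
    T = Y.shape[0]
    if X.shape[0] != T:
        raise ValueError("time dimensions of data and confounds differ")
    D = np.column_stack([np.ones(T), X])
    if T <= D.shape[1]:
        raise ValueError(f"T={T} <= number of regressors {D.shape[1]}")
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    return Y - D @ beta


def dct_basis(T: int, tr: float, cutoff_hz: float = HP_CUTOFF_HZ) -> np.ndarray:
    """Discrete-cosine columns with frequency below ``cutoff_hz``.

    Basis k (k >= 1) is cos(pi * k * (t + 1/2) / T) with frequency
    k / (2 T tr) Hz; the constant term is excluded (the regression adds
    its own intercept).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    K = int(np.floor(2 * T * tr * cutoff_hz))
    t = np.arange(T)
    return np.column_stack(
        [np.cos(np.pi * k * (t + 0.5) / T) for k in range(1, K + 1)]
    ) if K else np.empty((T, 0))


def highpass_dct(ts: np.ndarray, tr: float, cutoff_hz: float = HP_CUTOFF_HZ) -> np.ndarray:
    """Remove drifts below ``cutoff_hz`` by regressing out a DCT basis.

    Exact and phase-free; nothing above the cutoff is attenuated (no
    low-pass).  Raises when the basis would span the data.
    """
    Y = np.asarray(ts, dtype=float)
    T = Y.shape[0]
    B = dct_basis(T, tr, cutoff_hz)
    if B.shape[1] + 1 >= T:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz yields {B.shape[1]} basis functions for "
            f"T={T}: basis spans the data")
    return regress_confounds(Y, B)


def detrend_despike(ts: np.ndarray, despike_sd: float = DESPIKE_SD) -> np.ndarray:
    """Per-node linear detrend, then tanh soft-clipping of spikes.

    Despike: x <- m + s * tanh((x - m)/s) with m the node median and
    s = despike_sd * 1.4826 * MAD.  Values within ~1 robust sd are nearly
    unchanged; extreme spikes are compressed below ~despike_sd + epsilon
    robust sd.  Nodes with zero MAD are left as-is with a warning.
    """
    Y = np.asarray(ts, dtype=float)
    T = Y.shape[0]
    if T < 3:
        raise ValueError("need at least 3 time points")
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t - t.mean()])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Y = Y - X @ beta
    med = np.median(Y, axis=0)
    mad = np.median(np.abs(Y - med), axis=0)
    s = despike_sd * _MAD_TO_SD * mad
    zero = s <= 1e-12 * max(1.0, float(np.abs(Y).max()))
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} node(s) have zero MAD; despike skipped there",
            stacklevel=2)
    out = Y.copy()
    nz = ~zero
    out[:, nz] = med[nz] + s[nz] * np.tanh((Y[:, nz] - med[nz]) / s[nz])
    return out


def spike_regressors(fd: np.ndarray, threshold_mm: float = SPIKE_FD_MM) -> np.ndarray:
    """One indicator column per frame with FD above the threshold.

    Appending these to the confound matrix zeroes the flagged frames'
    residuals exactly (frame censoring by regression).  Raises when every
    frame is flagged.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    fd = np.asarray(fd, dtype=float)
    idx = np.flatnonzero(fd > threshold_mm)
    if len(idx) == len(fd):
        raise ValueError("all frames exceed the FD threshold: nothing left to analyze")
    cols = np.zeros((len(fd), len(idx)))
    cols[idx, np.arange(len(idx))] = 1.0
    return cols


def build_confounds(
    nuisance_signals: np.ndarray,
    realignment: np.ndarray,
    task_regressors: np.ndarray,
    spikes: np.ndarray | None = None,
) -> ConfoundMatrix:
    """Assemble the standard confound design.

    Columns: 5 nuisance PCs, 6 realignment parameters, the convolved
    motion and static task regressors, and optionally spike indicators.
    """
    pcs = nuisance_pca(nuisance_signals)
    parts = [pcs, np.asarray(realignment, float), np.asarray(task_regressors, float)]
    names = [f"compcor_{i}" for i in range(pcs.shape[1])]
    names += [f"rp_{i}" for i in range(6)]
    names += [f"task_{i}" for i in range(np.atleast_2d(task_regressors.T).shape[0])]
    if spikes is not None and spikes.size:
        parts.append(spikes)
        names += [f"spike_{i}" for i in range(spikes.shape[1])]
    return ConfoundMatrix(matrix=np.column_stack(parts), names=tuple(names))


def clean_timeseries(
    ts: np.ndarray,
    confounds: ConfoundMatrix,
    tr: float,
    hp_cutoff_hz: float = HP_CUTOFF_HZ,
    despike_sd: float = DESPIKE_SD,
) -> np.ndarray:
    """The full cleaning chain in fixed order."""
    out = regress_confounds(ts, confounds)
    out = highpass_dct(out, tr, hp_cutoff_hz)
    return detrend_despike(out, despike_sd)
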