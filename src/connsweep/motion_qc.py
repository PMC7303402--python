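"""Head-motion quality control.

Framewise displacement (FD) follows Jenkinson: for each consecutive pair
of rigid-body realignments the relative transform is formed and the RMS
displacement of a sphere of radius 80 mm centred at the isocentre is

    FD_t = sqrt( (R^2 / 5) * trace(A' A) + t' t ),

where A is the linear part and t the translation of (T_t T_{t-1}^{-1} - I).
Rotations are taken in radians (degrees cannot be detected — documented
contract).  Two summaries gate inclusion: mean FD over the session, and
the Pearson correlation between FD and the raw 0/1 task vector.  Values
with a within-group z-score beyond +-3 exclude the participant; a
separate pre-filter removes sessions whose realignment exceeds 3 mm or
3 degrees of maximum absolute motion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SessionDesign
from .design_weights import boxcar

log = logging.getLogger(__name__)

SPHERE_RADIUS_MM = 80.0
DEFAULT_Z_THRESHOLD = 3.0
MAX_TRANSLATION_MM = 3.0
MAX_ROTATION_DEG = 3.0


@dataclass(frozen=True)
class MotionSummary:
    participant_id: str
    fd_series: np.ndarray     # mm, fd_series[0] == 0
    mean_fd: float            # mm
    task_fd_corr: float       # Pearson r, or NaN when undefined
    z_mean_fd: float = float("nan")
    z_task_corr: float = float("nan")
    excluded: bool = False
    reason: str = ""


def _rigid_transform(params: np.ndarray) -> np.ndarray:
    """4x4 homogeneous transform from (tx, ty, tz, rx, ry, rz[rad])."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rx @ Ry @ Rz
    T[:3, 3] = (tx, ty, tz)
    return T


def framewise_displacement(
    realignment: np.ndarray, radius: float = SPHERE_RADIUS_MM
) -> np.ndarray:
    """Jenkinson FD series (mm) from a T x 6 realignment matrix.

    Columns: three translations (mm) then three rotations (radians).
    The first element is 0 by convention.
    """
    rp = np.asarray(realignment, dtype=float)
    if rp.ndim != 2 or rp.shape[1] != 6:
        raise ValueError(f"realignment must be T x 6, got shape {rp.shape}")
    if rp.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    fd = np.zeros(rp.shape[0])
    prev = _rigid_transform(rp[0])
    for i in range(1, rp.shape[0]):
        cur = _rigid_transform(rp[i])
        M = cur @ np.linalg.inv(prev) - np.eye(4)
        A = M[:3, :3]
        t = M[:3, 3]
        fd[i] = np.sqrt(radius**2 / 5.0 * np.trace(A.T @ A) + t @ t)
        prev = cur
    return fd


def task_motion_correlation(
    fd: np.ndarray,
    design: SessionDesign,
    tr: float,
    condition: str = "motion",
    convolved: bool = False,
) -> float:
    """Pearson r between the task on/off vector and the FD series.

    The task vector is the raw 0/1 boxcar of ``condition`` at scan
    resolution (the convolved variant is available as an option).  Returns
    NaN, with a warning, when either series has zero variance.
    """
    fd = np.asarray(fd, dtype=float)
    task = boxcar(design, condition, tr, len(fd))
    if convolved:
        from .design_weights import block_regressor

        task = block_regressor(design, condition, tr, len(fd))
    if np.std(fd) == 0 or np.std(task) == 0:
        warnings.warn(
            "task-FD correlation undefined: zero-variance series", stacklevel=2
        )
        return float("nan")
    return float(np.corrcoef(task, fd)[0, 1])


def flag_outliers(
    values: np.ndarray,
    groups: np.ndarray,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Within-group z-scores and |z| > threshold flags.

    z uses the group mean and the n-1 standard deviation.  A group with
    zero spread yields z = 0 (no exclusions there) and a logged warning.
    Exclusion is single-pass: the rule is applied once, never re-run on
    the surviving cohort.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    z = np.zeros_like(values)
    for g in np.unique(groups):
        m = groups == g
        if m.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 participants")
        sd = values[m].std(ddof=1)
        if sd == 0:
            log.warning("group %s has zero spread; no exclusions applied", g)
            continue
        z[m] = (values[m] - values[m].mean()) / sd
    return z, np.abs(z) > z_threshold


def max_motion_prefilter(
    realignment: np.ndarray,
    max_translation_mm: float = MAX_TRANSLATION_MM,
    max_rotation_deg: float = MAX_ROTATION_DEG,
) -> bool:
    """True when maximum absolute motion exceeds 3 mm or 3 degrees."""
    rp = np.asarray(realignment, dtype=float)
    trans_ok = np.abs(rp[:, :3]).max() <= max_translation_mm
    rot_ok = np.abs(np.degrees(rp[:, 3:])).max() <= max_rotation_deg
    return not (trans_ok and rot_ok)


def qc_cohort(
    summaries: list[MotionSummary],
    groups: dict[str, str],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Apply the within-group z > threshold exclusion to a cohort.

    The union of flags on mean FD and on the task-FD correlation excludes.
    Returns a QC report frame (one row per participant).
    """
    ids = [s.participant_id for s in summaries]
    grp = np.array([groups[i] for i in ids])
    mean_fd = np.array([s.mean_fd for s in summaries])
    task_r = np.array([s.task_fd_corr for s in summaries])
    z_fd, flag_fd = flag_outliers(mean_fd, grp, z_threshold)
    z_r, flag_r = flag_outliers(task_r, grp, z_threshold)
    rows = []
    for i, s in enumerate(summaries):
        reasons = []
        if flag_fd[i]:
            reasons.append(f"mean FD z={z_fd[i]:.2f}")
        if flag_r[i]:
            reasons.append(f"task-FD correlation z={z_r[i]:.2f}")
        rows.append(
            {
                "participant_id": s.participant_id,
                "group": grp[i],
                "mean_fd": mean_fd[i],
                "task_fd_corr": task_r[i],
                "z_mean_fd": z_fd[i],
                "z_task_corr": z_r[i],
                "excluded": bool(flag_fd[i] or flag_r[i]),
                "reason": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def summarize_motion(
    participant_id: str,
    realignment: np.ndarray,
    design: SessionDesign,
    tr: float,
    convolved_task: bool = False,
) -> MotionSummary:
    """FD series plus the two scalar summaries for one session."""
    fd = framewise_displacement(realignment)
    r = task_motion_correlation(fd, design, tr, convolved=convolved_task)
    return MotionSummary(
        participant_id=participant_id,
        fd_series=fd,
        mean_fd=float(fd.mean()),
        task_fd_corr=r,
    )
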