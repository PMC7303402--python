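"""Readers and writers for the pipeline's plain-text interchange formats.

All numeric interchange uses 6 significant digits.  Formats:

* ROI time series — TSV, header of node ids, one row per volume;
* nuisance channels — TSV, header of channel names;
* realignment parameters — six whitespace-delimited columns, no header
  (common realignment-tool dialect; translations mm, rotations radians);
* events — BIDS-events dialect TSV: onset, duration, trial_type (seconds);
* adjacency — full 160 x 160 TSV named ``{participant}_{condition}_adj.tsv``;
* participants — TSV: participant_id, group, age.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import Block, SessionDesign

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """An input file violates its declared format."""


def _check_finite(frame: pd.DataFrame, origin: str) -> None:
    arr = frame.to_numpy(float)
    bad = ~np.isfinite(arr)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{origin}: non-finite value at row {int(r) + 1}, "
            f"column {frame.columns[int(c)]!r}")


def read_timeseries(path: str | Path, n_nodes: int | None = None) -> np.ndarray:
    """T x N matrix from a headered TSV; validates against the atlas size."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if n_nodes is not None and frame.shape[1] != n_nodes:
        raise FormatError(
            f"{path}: {frame.shape[1]} columns but the atlas has {n_nodes} nodes")
    _check_finite(frame, str(path))
    return frame.to_numpy(float)


def write_timeseries(matrix: np.ndarray, path: str | Path,
                     prefix: str = "n") -> None:
    matrix = np.asarray(matrix, float)
    cols = [f"{prefix}{i:03d}" for i in range(matrix.shape[1])]
    pd.DataFrame(matrix, columns=cols).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_realignment(path: str | Path) -> np.ndarray:
    """T x 6 realignment parameters from whitespace-delimited text."""
    path = Path(path)
    try:
        rp = np.loadtxt(path, ndmin=2)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse realignment file ({exc})") from exc
    if rp.shape[1] != 6:
        raise FormatError(f"{path}: expected 6 columns, found {rp.shape[1]}")
    if not np.all(np.isfinite(rp)):
        r = int(np.argwhere(~np.isfinite(rp))[0][0])
        raise FormatError(f"{path}: non-finite value at row {r + 1}")
    return rp


def write_realignment(rp: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(rp, float), fmt="%.6g")


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"{path}: events TSV needs columns {sorted(required)}")
    return frame


def write_events(design: SessionDesign, path: str | Path) -> None:
    rows = [{"onset": b.onset, "duration": b.duration, "trial_type": b.condition}
            for b in design.blocks]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def design_from_events(events: pd.DataFrame, tr: float, n_volumes: int) -> SessionDesign:
    blocks = tuple(
        Block(onset=float(r.onset), duration=float(r.duration),
              condition=str(r.trial_type))
        for r in events.sort_values("onset").itertuples())
    return SessionDesign(tr=tr, n_volumes=n_volumes, blocks=blocks)


def write_adjacency(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix, float), fmt="%.6g", delimiter="\t")


def read_adjacency(path: str | Path) -> np.ndarray:
    m = np.loadtxt(path, delimiter="\t")
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"{path}: adjacency must be square")
    return m


def read_participants(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"participant_id", "group", "age"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: participants TSV needs columns {sorted(required)}")
    bad = ~frame["group"].isin(("HC", "PPV"))
    if bad.any():
        raise FormatError(
            f"{path}: unknown group {frame['group'][bad].iloc[0]!r} "
            "(expected HC or PPV)")
    return frame


def write_long_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_cohort(bundles, participants: pd.DataFrame, out_dir: str | Path) -> None:
    """Persist a simulated cohort in the pipeline's input layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants.to_csv(out / "participants.tsv", sep="\t", index=False,
                        float_format=FLOAT_FMT)
    for b in bundles:
        write_timeseries(b.roi_signals, out / f"{b.participant_id}_timeseries.tsv")
        write_timeseries(b.nuisance_signals, out / f"{b.participant_id}_nuisance.tsv",
                         prefix="ch")
        write_realignment(b.realignment, out / f"{b.participant_id}_rp.txt")
        write_events(b.design, out / f"{b.participant_id}_events.tsv")
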