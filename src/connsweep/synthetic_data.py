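"""Synthetic task-fMRI cohorts with known connectivity structure.

The generator emulates the study conditions end to end so that every
downstream stage has ground truth: a block design (27.5 s motion /
27.5 s static, 12 cycles, TR 2.45 s, 260 volumes), within-network
correlated BOLD whose coupling is modulated per (group, network,
condition), low-frequency drift, AR(1) autocorrelated noise, nuisance
channels, and head-motion traces partly locked to task onsets.

Signal model (latent-factor construction, positive semi-definite by
construction): each network has a shared latent AR(1) series L(t); node i
in that network is

    s_i(t) = noise_sd * ( sqrt(c_i(t)) L(t) + sqrt(1 - c_i(t)) e_i(t) ) + drift_i(t),

with e_i an idiosyncratic unit-variance AR(1) process and the coupling

    c(t) = base + sum_cond delta(group, network, cond) * x_cond(t)

modulated through the HRF-convolved block regressor x_cond (normalized to
unit peak).  At constant coupling c the expected correlation between two
same-network nodes is c.  Couplings leaving [0, 1) raise a ValueError.

Defaults mirror the study: 18 HC / 17 PPV, ages uniform on [20, 60],
AR(1) rho = 0.3, random-walk motion with step sd 0.02 mm / 2e-4 rad and a
task-locked motion component scaled by the motion-task coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import NETWORKS, Atlas
from .design import CONDITIONS, SessionDesign, make_design
from .design_weights import block_regressor

GROUPS = ("HC", "PPV")

__all__ = [
    "GROUPS", "EffectConfig", "SessionBundle", "simulate_cohort",
    "simulate_summary_cohort", "make_design",
]


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth effect structure of a simulated cohort.

    ``coupling_deltas`` maps (group, network, condition) to an additive
    change of within-network coupling while that condition's regressor is
    active; e.g. ``{("PPV", "sensorimotor", "motion"): 0.2}``.
    """

    base_coupling: float = 0.3
    coupling_deltas: dict[tuple[str, str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    motion_task_coupling: float = 0.3
    ar_rho: float = 0.3
    n_hc: int = 18
    n_ppv: int = 17
    n_nuisance: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.base_coupling < 1:
            raise ValueError("base coupling must be in [0, 1)")
        if not 0 <= self.motion_task_coupling <= 1:
            raise ValueError("motion-task coupling must be in [0, 1]")
        for key in self.coupling_deltas:
            g, net, cond = key
            if g not in GROUPS or net not in NETWORKS or cond not in CONDITIONS:
                raise ValueError(f"invalid coupling-delta key {key!r}")


@dataclass(frozen=True)
class SessionBundle:
    """One participant's simulated session."""

    participant_id: str
    group: str
    age: float
    roi_signals: np.ndarray       # T x 160
    nuisance_signals: np.ndarray  # T x M
    realignment: np.ndarray       # T x 6 (mm, mm, mm, rad, rad, rad)
    design: SessionDesign

    def __post_init__(self) -> None:
        T = self.design.n_volumes
        for name in ("roi_signals", "nuisance_signals", "realignment"):
            arr = getattr(self, name)
            if arr.shape[0] != T:
                raise ValueError(f"{name} has {arr.shape[0]} rows, expected {T}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")


def _ar1(rng: np.random.Generator, T: int, rho: float, size: int = 1) -> np.ndarray:
    """Unit-marginal-variance AR(1) series, shape (T, size)."""
    x = np.empty((T, size))
    x[0] = rng.standard_normal(size)
    innov = rng.standard_normal((T - 1, size)) * np.sqrt(1 - rho**2)
    for t in range(1, T):
        x[t] = rho * x[t - 1] + innov[t - 1]
    return x


def _coupling_series(
    effects: EffectConfig,
    group: str,
    network: str,
    regs: dict[str, np.ndarray],
    T: int,
) -> np.ndarray:
    c = np.full(T, effects.base_coupling)
    for (g, net, cond), delta in effects.coupling_deltas.items():
        if g == group and net == network:
            c = c + delta * regs[cond]
    if c.min() < 0 or c.max() >= 1:
        raise ValueError(
            f"coupling for ({group}, {network}) leaves [0, 1): "
            f"range [{c.min():.3f}, {c.max():.3f}]")
    return c


def _drift(rng: np.random.Generator, T: int, tr: float, amplitude: float,
           size: int) -> np.ndarray:
    """Two low-frequency cosines (0.002-0.006 Hz) with random phase."""
    t = np.arange(T) * tr
    out = np.zeros((T, size))
    for _ in range(2):
        f = rng.uniform(0.002, 0.006)
        phase = rng.uniform(0, 2 * np.pi, size)
        out += amplitude * np.cos(2 * np.pi * f * t[:, None] + phase)
    return out


def _simulate_bundle(
    rng: np.random.Generator,
    participant_id: str,
    group: str,
    age: float,
    atlas: Atlas,
    design: SessionDesign,
    effects: EffectConfig,
    regs: dict[str, np.ndarray],
) -> SessionBundle:
    T = design.n_volumes
    tr = design.tr
    roi = np.zeros((T, atlas.n_nodes))
    for net in NETWORKS:
        idx = atlas.nodes_of(net)
        c = _coupling_series(effects, group, net, regs, T)
        latent = _ar1(rng, T, effects.ar_rho, 1)[:, 0]
        eps = _ar1(rng, T, effects.ar_rho, len(idx))
        sig = (np.sqrt(c)[:, None] * latent[:, None]
               + np.sqrt(1 - c)[:, None] * eps)
        roi[:, idx] = effects.noise_sd * sig
    roi += _drift(rng, T, tr, effects.drift_amplitude, atlas.n_nodes)

    # nuisance channels: mixtures of drift + a global AR(1) + white noise
    global_noise = _ar1(rng, T, effects.ar_rho, 1)[:, 0]
    nuis = _drift(rng, T, tr, effects.drift_amplitude, effects.n_nuisance)
    nuis += rng.uniform(0.3, 1.0, effects.n_nuisance) * global_noise[:, None]
    nuis += 0.5 * rng.standard_normal((T, effects.n_nuisance))

    # head motion: random walk + task-locked component
    steps = rng.standard_normal((T, 6))
    steps[:, :3] *= 0.02      # mm
    steps[:, 3:] *= 2e-4      # rad
    rp = np.cumsum(steps, axis=0)
    amp = effects.motion_task_coupling * rng.uniform(0.5, 1.5)
    task = regs["motion"]
    rp[:, :3] += amp * 0.05 * task[:, None]
    rp[:, 3:] += amp * 5e-4 * task[:, None]

    return SessionBundle(
        participant_id=participant_id, group=group, age=age,
        roi_signals=roi, nuisance_signals=nuis, realignment=rp, design=design)


def simulate_cohort(
    atlas: Atlas,
    design: SessionDesign,
    effects: EffectConfig,
) -> tuple[list[SessionBundle], pd.DataFrame]:
    """Simulate a full cohort; deterministic given ``effects.seed``.

    Returns the session bundles plus a participants table (participant_id,
    group, age).  Participant streams come from spawned child seeds, so
    per-participant data do not depend on cohort size ordering.
    """
    root = np.random.SeedSequence(effects.seed)
    n_total = effects.n_hc + effects.n_ppv
    children = root.spawn(n_total + 1)
    meta_rng = np.random.default_rng(children[0])
    tr = design.tr
    T = design.n_volumes
    regs = {}
    for cond in CONDITIONS:
        r = block_regressor(design, cond, tr, T)
        regs[cond] = r / r.max() if r.max() > 0 else r
    bundles, rows = [], []
    labels = ["HC"] * effects.n_hc + ["PPV"] * effects.n_ppv
    ages = meta_rng.uniform(20, 60, n_total)
    for i, group in enumerate(labels):
        pid = f"sub-{i + 1:03d}"
        rng = np.random.default_rng(children[i + 1])
        bundles.append(
            _simulate_bundle(rng, pid, group, float(ages[i]), atlas, design,
                             effects, regs))
        rows.append({"participant_id": pid, "group": group,
                     "age": float(ages[i])})
    return bundles, pd.DataFrame(rows)


def simulate_summary_cohort(
    n_hc: int = 18,
    n_ppv: int = 17,
    levels: tuple[str, ...] = NETWORKS,
    subject_sd: float = 1.0,
    noise_sd: float = 1.0,
    cell_effects: dict[tuple[str, str], float] | None = None,
    measures: tuple[str, ...] = ("dc",),
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulate a long table of network summary values.

    A compact generative model for calibrating the statistics: value =
    subject intercept (sd ``subject_sd``) + cell effect + residual (sd
    ``noise_sd``), so the within-cell sd is sqrt(subject_sd^2 +
    noise_sd^2).  ``cell_effects`` maps (group, level) to an additive
    shift.  Ages are uniform on [20, 60], independent of group (a null
    covariate).
    """
    rng = np.random.default_rng(seed)
    cell_effects = cell_effects or {}
    rows = []
    n_total = n_hc + n_ppv
    groups = ["HC"] * n_hc + ["PPV"] * n_ppv
    ages = rng.uniform(20, 60, n_total)
    for i, group in enumerate(groups):
        pid = f"sub-{i + 1:03d}"
        for m in measures:
            intercept = rng.normal(0, subject_sd)
            resid = rng.normal(0, noise_sd, len(levels))
            for j, level in enumerate(levels):
                val = intercept + cell_effects.get((group, level), 0.0) + resid[j]
                rows.append({"participant": pid, "group": group,
                             "age": float(ages[i]), "network": level,
                             "measure": m, "value": float(val)})
    return pd.DataFrame(rows)
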