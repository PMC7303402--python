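"""Binary graph measures over a proportional-threshold cost sweep.

An adjacency matrix is binarized at each *cost* (edge density) by keeping
the k = round(cost * n(n-1)/2) strongest weights.  On each binary graph
three node measures are computed — degree centrality (DC), clustering
coefficient (CC), eccentricity (ECC) — plus global and local efficiency,
and each node curve is summarized by its trapezoidal area under the curve
(AUC) over the main cost grid.

Small-world screening compares real efficiency curves against
degree-preserving rewired nulls: a random null (Maslov–Sneppen double-edge
swaps) and a lattice null (swaps accepted only when they shrink the total
|i-j| edge span, pulling edges toward the diagonal).  The small-world
regime is the longest contiguous run of costs where

    E_glob(lattice) < E_glob(real) < E_glob(random)   and
    E_loc(random)   < E_loc(real)  < E_loc(lattice)     (strictly).

Cost grids: the main grid is 0.04-0.30 in steps of 0.01 (27 values); the
screening grid is 0.01-0.59 in steps of 0.02 (30 values; a 0.02 step from
0.01 cannot land on 0.60).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

MAIN_COST_GRID = np.round(np.arange(4, 31) * 0.01, 2)          # 27 costs
EFFICIENCY_COST_GRID = np.round(0.01 + 0.02 * np.arange(30), 2)  # 30 costs
DEFAULT_REWIRE_ITER = 100


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected binary graph as a boolean adjacency matrix."""

    adj: np.ndarray = field(repr=False)
    cost: float = float("nan")

    def __post_init__(self) -> None:
        a = self.adj
        if a.dtype != bool or a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adj must be a square boolean matrix")
        if not np.array_equal(a, a.T) or a.diagonal().any():
            raise ValueError("adj must be symmetric with empty diagonal")

    @property
    def n(self) -> int:
        return self.adj.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adj.sum()) // 2


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def proportional_threshold(weights: np.ndarray, cost: float) -> BinaryGraph:
    """Keep the k = round(cost * n(n-1)/2) strongest upper-triangle weights.

    Ties are broken by (row, column) lexical order for platform-independent
    reproducibility.  Zero weights are never kept even if k demands it
    (warning); cost values yielding k = 0 raise.
    """
    W = np.asarray(weights, float)
    n = W.shape[0]
    if not 0 < cost < 1:
        raise ValueError(f"cost must be in (0, 1), got {cost}")
    k = _round_half_up(cost * n * (n - 1) / 2)
    if k == 0:
        raise ValueError(f"cost {cost} keeps zero edges on {n} nodes")
    iu, ju = np.triu_indices(n, 1)
    vals = W[iu, ju]
    # stable sort on (-weight, row, col): lexsort with last key primary
    order = np.lexsort((ju, iu, -vals))
    top = order[:k]
    nonzero = vals[top] > 0
    if not nonzero.all():
        warnings.warn(
            f"cost {cost} demands {k} edges but only {int((vals > 0).sum())} "
            "positive weights exist; zero-weight entries dropped",
            stacklevel=2,
        )
        top = top[nonzero]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[top], ju[top]] = True
    adj |= adj.T
    return BinaryGraph(adj=adj, cost=cost)


def degree(g: BinaryGraph) -> np.ndarray:
    """Edges attaching each node to the rest of the network (row sums)."""
    return g.adj.sum(axis=1).astype(int)


def clustering(g: BinaryGraph) -> np.ndarray:
    """Fraction of each node's neighbor pairs that are themselves linked.

    Nodes with degree < 2 get 0.
    """
    A = g.adj.astype(float)
    k = A.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(k >= 2, tri / (k * (k - 1) / 2.0), 0.0)
    return cc


def distances(g: BinaryGraph) -> np.ndarray:
    """All-pairs shortest hop counts; np.inf marks unreachable pairs."""
    d = shortest_path(csr_matrix(g.adj), method="D", unweighted=True, directed=False)
    return d


def eccentricity(g: BinaryGraph, dist: np.ndarray | None = None) -> np.ndarray:
    """Max shortest-path distance per node, within its component.

    Disconnected graphs use the finite-distance (within-component)
    convention so that downstream AUCs stay finite; isolated nodes get 0.
    """
    d = distances(g) if dist is None else dist
    dd = d.copy()
    dd[~np.isfinite(dd)] = 0.0
    return dd.max(axis=1)


def global_efficiency(g: BinaryGraph, dist: np.ndarray | None = None) -> float:
    """Mean inverse shortest-path length over ordered pairs (inf -> 0)."""
    d = distances(g) if dist is None else dist
    n = g.n
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(g: BinaryGraph) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph."""
    A = g.adj
    n = g.n
    effs = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(A[i])
        if len(nb) < 2:
            continue
        sub = BinaryGraph(adj=A[np.ix_(nb, nb)].copy())
        effs[i] = global_efficiency(sub)
    return float(effs.mean())


def _edge_arrays(g: BinaryGraph) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(g.n, 1)
    m = g.adj[iu, ju]
    return iu[m].copy(), ju[m].copy()


def _rewire(
    g: BinaryGraph, n_iter: int, rng: np.random.Generator, lattice: bool
) -> BinaryGraph:
    """Degree-preserving double-edge swaps.

    ~``n_iter`` attempts per edge.  The lattice variant accepts a swap
    only when it strictly reduces the total |i-j| edge span.
    """
    u, v = _edge_arrays(g)
    E = len(u)
    if E < 2:
        warnings.warn("graph too sparse to rewire; returning a copy", stacklevel=2)
        return BinaryGraph(adj=g.adj.copy(), cost=g.cost)
    adj = g.adj.copy()
    attempts = n_iter * E
    e1s = rng.integers(0, E, size=attempts)
    e2s = rng.integers(0, E, size=attempts)
    flips = rng.random(attempts) < 0.5
    for e1, e2, flip in zip(e1s, e2s, flips):
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        c, d = u[e2], v[e2]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        if len({a, b, c, d}) < 4:
            continue
        if lattice:
            old = abs(a - b) + abs(c - d)
            new = abs(a - d) + abs(c - b)
            if new >= old:
                continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        u[e1], v[e1] = min(a, d), max(a, d)
        u[e2], v[e2] = min(c, b), max(c, b)
    return BinaryGraph(adj=adj, cost=g.cost)


def rewire_random(
    g: BinaryGraph, n_iter: int = DEFAULT_REWIRE_ITER, seed: int | np.random.Generator = 0
) -> BinaryGraph:
    """Maslov–Sneppen random null: degree sequence preserved exactly."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _rewire(g, n_iter, rng, lattice=False)


def rewire_lattice(
    g: BinaryGraph, n_iter: int = DEFAULT_REWIRE_ITER, seed: int | np.random.Generator = 0
) -> BinaryGraph:
    """Lattice null: swaps accepted only when the |i-j| edge span shrinks."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _rewire(g, n_iter, rng, lattice=True)


def edge_span(g: BinaryGraph) -> int:
    """Total |i - j| over edges (diagonal-proximity cost of the lattice null)."""
    u, v = _edge_arrays(g)
    return int(np.abs(u.astype(int) - v.astype(int)).sum())


def small_world_regime(
    real: dict[str, np.ndarray],
    random_null: dict[str, np.ndarray],
    lattice_null: dict[str, np.ndarray],
    grid: np.ndarray = EFFICIENCY_COST_GRID,
) -> tuple[float, float] | None:
    """Longest contiguous cost run with the strict small-world ordering.

    Each curve dict maps ``"e_glob"``/``"e_loc"`` to per-cost arrays
    (participant-averaged).  Returns (low, high) costs of the run, or
    None when no cost satisfies the ordering (e.g. real == random).
    """
    for d in (real, random_null, lattice_null):
        for key in ("e_glob", "e_loc"):
            if len(np.asarray(d[key])) != len(grid):
                raise ValueError("curve length does not match the cost grid")
    ok = (
        (lattice_null["e_glob"] < real["e_glob"])
        & (real["e_glob"] < random_null["e_glob"])
        & (random_null["e_loc"] < real["e_loc"])
        & (real["e_loc"] < lattice_null["e_loc"])
    )
    best_len, best_start = 0, -1
    run_len, run_start = 0, 0
    for i, flag in enumerate(ok):
        if flag:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    if best_len == 0:
        return None
    return float(grid[best_start]), float(grid[best_start + best_len - 1])


def auc_over_costs(values: np.ndarray, grid: np.ndarray = MAIN_COST_GRID) -> float:
    """Trapezoidal integral of a per-cost curve over the grid.

    A constant curve c integrates to c * (grid[-1] - grid[0]).
    """
    values = np.asarray(values, float)
    grid = np.asarray(grid, float)
    if values.shape[-1] != len(grid):
        raise ValueError(
            f"{values.shape[-1]} values for {len(grid)} costs: missing cost levels"
        )
    return np.trapezoid(values, grid, axis=-1)


def normalize_to_random(real_values: np.ndarray, random_values: np.ndarray) -> np.ndarray:
    """Elementwise real/random ratio per cost (pre-AUC normalization).

    Zero random values yield NaN at that cost, with a warning.
    """
    real_values = np.asarray(real_values, float)
    random_values = np.asarray(random_values, float)
    if real_values.shape != random_values.shape:
        raise ValueError("mismatched grids for normalization")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = real_values / random_values
    bad = random_values == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero random value(s): ratio undefined there",
            stacklevel=2,
        )
        out = np.where(bad, np.nan, out)
    return out


def metric_curves(
    weights: np.ndarray,
    grid: np.ndarray = MAIN_COST_GRID,
    include_efficiency: bool = False,
) -> dict[str, np.ndarray]:
    """DC/CC/ECC node curves (optionally efficiencies) over a cost grid.

    Returns arrays of shape (len(grid), n) for ``dc``, ``cc``, ``ecc``;
    with ``include_efficiency`` also length-len(grid) vectors ``e_glob``
    and ``e_loc`` (the local-efficiency loop dominates run time, so it is
    opt-in).
    """
    n = weights.shape[0]
    dc = np.zeros((len(grid), n))
    cc = np.zeros((len(grid), n))
    ecc = np.zeros((len(grid), n))
    eg = np.zeros(len(grid))
    el = np.zeros(len(grid))
    for i, cost in enumerate(grid):
        g = proportional_threshold(weights, cost)
        d = distances(g)
        dc[i] = degree(g)
        cc[i] = clustering(g)
        ecc[i] = eccentricity(g, d)
        if include_efficiency:
            eg[i] = global_efficiency(g, d)
            el[i] = local_efficiency(g)
    out = {"dc": dc, "cc": cc, "ecc": ecc}
    if include_efficiency:
        out["e_glob"] = eg
        out["e_loc"] = el
    return out


def efficiency_screen(
    weight_matrices: list[np.ndarray],
    grid: np.ndarray = EFFICIENCY_COST_GRID,
    n_iter: int = DEFAULT_REWIRE_ITER,
    seed: int = 0,
) -> dict[str, dict[str, np.ndarray]]:
    """Participant-averaged efficiency curves for real, random and lattice
    graphs over the screening grid.

    Each participant's graph is thresholded at each cost and rewired to
    its own random and lattice null (rewiring parameter ``n_iter``); the
    returned curves feed :func:`small_world_regime`.
    """
    rng = np.random.default_rng(seed)
    kinds = ("real", "random", "lattice")
    acc = {kind: {"e_glob": np.zeros(len(grid)), "e_loc": np.zeros(len(grid))}
           for kind in kinds}
    for W in weight_matrices:
        for i, cost in enumerate(grid):
            g = proportional_threshold(W, cost)
            variants = {
                "real": g,
                "random": rewire_random(g, n_iter, rng),
                "lattice": rewire_lattice(g, n_iter, rng),
            }
            for kind, gv in variants.items():
                d = distances(gv)
                acc[kind]["e_glob"][i] += global_efficiency(gv, d)
                acc[kind]["e_loc"][i] += local_efficiency(gv)
    for kind in kinds:
        for key in ("e_glob", "e_loc"):
            acc[kind][key] /= len(weight_matrices)
    return acc


def auc_table(curves: dict[str, np.ndarray], grid: np.ndarray = MAIN_COST_GRID) -> dict[str, np.ndarray]:
    """Per-node AUCs of the three node measures over the cost grid."""
    return {
        "auc_dc": auc_over_costs(curves["dc"].T, grid),
        "auc_cc": auc_over_costs(curves["cc"].T, grid),
        "auc_ecc": auc_over_costs(curves["ecc"].T, grid),
    }
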