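"""Six-network aggregation, condition deltas, connectivity decomposition.

Node AUCs are averaged (unweighted) over the member nodes of each of the
six functional networks, giving 6 networks x 3 measures = 18 summary
values per condition and 36 per participant.  Condition deltas are
motion - static (positive = higher during visual motion).

The sub-matrix decomposition asks *where* a focal network's degree comes
from: edges within the focal network, edges between the sensorimotor and
cerebellar networks specifically, or edges to the four remaining
networks.  Each reduced weight block is proportionally thresholded on its
own admissible pairs (round(cost * n_pairs) kept) and the retained edges
per focal node are AUC-summarized over the main cost grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import NETWORKS, Atlas
from .connectivity import ConditionAdjacency
from .graph_metrics import MAIN_COST_GRID, _round_half_up, auc_over_costs

MEASURES = ("dc", "cc", "ecc")
PARTITIONS = ("within", "pair", "rest")
FOCAL_NETWORKS = ("sensorimotor", "cerebellum")


@dataclass(frozen=True)
class DecompositionSpec:
    """Which focal network and which pair-partition of its edges."""

    focal: str
    partition: str

    def __post_init__(self) -> None:
        if self.focal not in FOCAL_NETWORKS:
            raise ValueError(
                f"focal network must be one of {FOCAL_NETWORKS}, got {self.focal!r}"
            )
        if self.partition not in PARTITIONS:
            raise ValueError(
                f"partition must be one of {PARTITIONS}, got {self.partition!r}"
            )


def network_means(auc: dict[str, np.ndarray], atlas: Atlas) -> pd.DataFrame:
    """Unweighted network means of per-node AUCs.

    ``auc`` maps ``auc_dc``/``auc_cc``/``auc_ecc`` to length-160 arrays.
    Returns a frame indexed by network with one column per measure
    (18 values).
    """
    rows = {}
    for net in NETWORKS:
        idx = atlas.nodes_of(net)
        if len(idx) == 0:
            raise ValueError(f"network {net!r} has no member nodes")
        rows[net] = {m: float(np.mean(np.asarray(auc[f"auc_{m}"])[idx]))
                     for m in MEASURES}
    out = pd.DataFrame.from_dict(rows, orient="index").loc[list(NETWORKS)]
    out.index.name = "network"
    return out


def condition_delta(
    motion: pd.DataFrame,
    static: pd.DataFrame,
    participant_motion: str = "",
    participant_static: str = "",
) -> pd.DataFrame:
    """Per-network motion - static deltas of the summary measures."""
    if participant_motion != participant_static:
        raise ValueError(
            f"participant mismatch: {participant_motion!r} vs {participant_static!r}"
        )
    if not motion.index.equals(static.index) or list(motion.columns) != list(static.columns):
        raise ValueError("summaries are not aligned")
    return motion - static


def _partition_block(
    atlas: Atlas, spec: DecompositionSpec
) -> tuple[np.ndarray, np.ndarray, bool]:
    """(focal ids, other-side ids, is_square) for the reduced block."""
    focal = atlas.nodes_of(spec.focal)
    if spec.partition == "within":
        return focal, focal, True
    if spec.partition == "pair":
        other = "cerebellum" if spec.focal == "sensorimotor" else "sensorimotor"
        return focal, atlas.nodes_of(other), False
    rest_nets = [n for n in NETWORKS if n not in FOCAL_NETWORKS]
    rest = np.concatenate([atlas.nodes_of(n) for n in rest_nets])
    return focal, np.sort(rest), False


def submatrix_degree(
    adjacency: ConditionAdjacency,
    atlas: Atlas,
    spec: DecompositionSpec,
    grid: np.ndarray = MAIN_COST_GRID,
) -> np.ndarray:
    """AUC of focal-node degree on the reduced weight block.

    The block is thresholded at each cost by keeping the
    round(cost * n_admissible_pairs) largest entries (ties by lexical
    block position); retained edges touching each focal node are counted
    and the per-cost counts are integrated over the grid.  Returns one
    AUC per focal node, in atlas order of the focal network.
    """
    focal, other, square = _partition_block(atlas, spec)
    W = adjacency.matrix[np.ix_(focal, other)]
    if square:
        iu, ju = np.triu_indices(len(focal), 1)
        vals = W[iu, ju]
    else:
        iu, ju = np.meshgrid(np.arange(len(focal)), np.arange(len(other)),
                             indexing="ij")
        iu, ju = iu.ravel(), ju.ravel()
        vals = W[iu, ju]
    n_pairs = len(vals)
    order = np.lexsort((ju, iu, -vals))
    n_positive = int((vals > 0).sum())
    counts = np.zeros((len(grid), len(focal)))
    warned = False
    for g, cost in enumerate(grid):
        k = _round_half_up(cost * n_pairs)
        top = order[:k]
        keep = vals[top] > 0
        if not keep.all() and not warned:
            warnings.warn(
                f"cost {cost} demands {k} edges but the block has only "
                f"{n_positive} positive weights; zeros dropped",
                stacklevel=2,
            )
            warned = True
        top = top[keep]
        counts[g] = np.bincount(iu[top], minlength=len(focal))
        if square:
            counts[g] += np.bincount(ju[top], minlength=len(focal))
    return auc_over_costs(counts.T, grid)


def decomposition_table(
    adjacencies: dict[str, ConditionAdjacency],
    atlas: Atlas,
    grid: np.ndarray = MAIN_COST_GRID,
) -> pd.DataFrame:
    """Mean focal-node degree AUC for every (condition, focal, partition).

    ``adjacencies`` maps condition name -> adjacency for one participant.
    """
    rows = []
    for condition, adj in adjacencies.items():
        for focal in FOCAL_NETWORKS:
            for part in PARTITIONS:
                aucs = submatrix_degree(adj, atlas, DecompositionSpec(focal, part), grid)
                rows.append(
                    {
                        "condition": condition,
                        "focal": focal,
                        "partition": part,
                        "mean_auc_dc": float(np.mean(aucs)),
                    }
                )
    return pd.DataFrame(rows)
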