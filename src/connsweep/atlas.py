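"""160-node functional atlas: coordinates, anatomical labels, network assignment.

The atlas assigns each of 160 spherical ROIs to one of six functional
networks (cingulo-opercular, fronto-parietal, default-mode, sensorimotor,
occipital, cerebellum).  All downstream aggregation — network-mean AUCs,
condition deltas, the sub-matrix connectivity decomposition — is framed by
this assignment, so node order is fixed by file row order and validated
once at load time.

The packaged fixture ``data/atlas160_synthetic.tsv`` carries the published
sensorimotor (33 nodes) and cerebellar (18 nodes) coordinates; the
remaining four networks are synthetic stand-ins with the canonical network
sizes, since their coordinates are not redistributable here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

NETWORKS: tuple[str, ...] = (
    "cingulo-opercular",
    "fronto-parietal",
    "default-mode",
    "sensorimotor",
    "occipital",
    "cerebellum",
)

N_NODES = 160
N_SENSORIMOTOR = 33
N_CEREBELLUM = 18

_COLUMNS = ("x", "y", "z", "label", "network")


class AtlasFormatError(ValueError):
    """Raised when an atlas file violates the expected format."""


@dataclass(frozen=True)
class Atlas:
    """Ordered 160-node atlas.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per node, columns ``x, y, z, label, network``; the index is
        the 0-based node id and equals the file row order.
    """

    table: pd.DataFrame = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> tuple[str, ...]:
        return NETWORKS

    def nodes_of(self, network: str) -> np.ndarray:
        """0-based node ids belonging to ``network`` (file order)."""
        if network not in NETWORKS:
            raise KeyError(
                f"unknown network {network!r}; valid networks: {', '.join(NETWORKS)}"
            )
        return np.flatnonzero((self.table["network"] == network).to_numpy())

    def network_of(self) -> pd.Series:
        """Node-id-indexed Series of network labels."""
        return self.table["network"]


def _validate(table: pd.DataFrame, origin: str) -> None:
    if list(table.columns) != list(_COLUMNS):
        raise AtlasFormatError(
            f"{origin}: expected columns {_COLUMNS}, found {tuple(table.columns)}"
        )
    bad = ~table["network"].isin(NETWORKS)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise AtlasFormatError(
            f"{origin}, line {line}: unknown network "
            f"{table['network'].iloc[line - 2]!r}; valid networks: "
            f"{', '.join(NETWORKS)}"
        )
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
            raise AtlasFormatError(
                f"{origin}, line {line}: non-numeric {col!r} coordinate"
            )
    if len(table) != N_NODES:
        raise AtlasFormatError(
            f"{origin}: expected {N_NODES} nodes, found {len(table)}"
        )
    n_sm = int((table["network"] == "sensorimotor").sum())
    n_cb = int((table["network"] == "cerebellum").sum())
    if n_sm != N_SENSORIMOTOR:
        raise AtlasFormatError(
            f"{origin}: sensorimotor network has {n_sm} nodes, expected {N_SENSORIMOTOR}"
        )
    if n_cb != N_CEREBELLUM:
        raise AtlasFormatError(
            f"{origin}: cerebellar network has {n_cb} nodes, expected {N_CEREBELLUM}"
        )
    for net in NETWORKS:
        if not (table["network"] == net).any():
            raise AtlasFormatError(f"{origin}: network {net!r} has no nodes")


def load_atlas(path: str | Path) -> Atlas:
    """Read an atlas TSV (columns x, y, z, label, network) and validate it.

    Row order defines node order (node ids 0..159).  Raises
    :class:`AtlasFormatError` naming the offending line on malformed rows,
    unknown network labels, or a wrong node count.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={"label": str, "network": str})
    except Exception as exc:  # header/row parse failures
        raise AtlasFormatError(f"{path}: cannot parse atlas TSV ({exc})") from exc
    _validate(table, str(path))
    table = table.copy()
    table[["x", "y", "z"]] = table[["x", "y", "z"]].astype(float)
    table.index.name = "node_id"
    return Atlas(table=table)


def default_atlas() -> Atlas:
    """The packaged 160-node atlas fixture (partly synthetic coordinates)."""
    with resources.as_file(
        resources.files("connsweep.data").joinpath("atlas160_synthetic.tsv")
    ) as p:
        return load_atlas(p)
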