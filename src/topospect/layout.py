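"""Sensor layouts: channel positions on the scalp and their neighbourhood graph.

The cluster-enhancement stage needs to know which channels are spatial
neighbours.  A :class:`SensorLayout` bundles channel identifiers, 3-D
positions (metres, head-centred) and a symmetric adjacency graph.  For
synthetic studies the layout is generated on a hemispherical grid;
for real caps it can be loaded from a positions CSV plus an edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

HEAD_RADIUS_M = 0.095


class LayoutError(ValueError):
    """Invalid sensor-layout construction or file."""


@dataclass
class SensorLayout:
    """Channel identities, positions and neighbour graph.

    Parameters
    ----------
    channels
        Ordered channel identifiers (e.g. ``["E1", ..., "E257"]``).
    positions
        ``(n_channels, 3)`` array of x/y/z positions in metres.
    graph
        Undirected :class:`networkx.Graph` over the channel ids.
        Symmetry is inherent; self-loops are rejected.
    """

    channels: list[str]
    positions: np.ndarray
    graph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.channels) != len(set(self.channels)):
            raise LayoutError("duplicate channel ids")
        if self.positions.shape != (len(self.channels), 3):
            raise LayoutError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.channels)} channels"
            )
        known = set(self.channels)
        for u, v in self.graph.edges():
            if u == v:
                raise LayoutError(f"self-edge on channel {u}")
            if u not in known or v not in known:
                raise LayoutError(f"edge ({u}, {v}) references unknown channel")
        # make sure isolated channels are still nodes
        self.graph.add_nodes_from(self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        return self.channels.index(channel)

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean ``(n, n)`` adjacency matrix in channel order."""
        idx = {c: i for i, c in enumerate(self.channels)}
        mat = np.zeros((self.n_channels, self.n_channels), dtype=bool)
        for u, v in self.graph.edges():
            mat[idx[u], idx[v]] = True
            mat[idx[v], idx[u]] = True
        return mat

    def subset(self, channels: list[str]) -> "SensorLayout":
        keep = set(channels)
        pos = np.array([self.positions[self.index(c)] for c in channels])
        g = self.graph.subgraph(keep).copy()
        return SensorLayout(list(channels), pos, g)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, positions_path: str | Path, edges_path: str | Path) -> None:
        """Write positions (channel,label,x,y,z) and a two-column edge list."""
        df = pd.DataFrame(
            {
                "channel": self.channels,
                "label": self.channels,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
            }
        )
        df.to_csv(positions_path, index=False)
        edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in self.graph.edges()),
                             columns=["a", "b"])
        edges.to_csv(edges_path, index=False)

    @classmethod
    def from_csv(cls, positions_path: str | Path,
                 edges_path: str | Path) -> "SensorLayout":
        df = pd.read_csv(positions_path)
        channels = [str(c) for c in df["channel"]]
        positions = df[["x", "y", "z"]].to_numpy(float)
        g = nx.Graph()
        g.add_nodes_from(channels)
        edges = pd.read_csv(edges_path)
        for a, b in edges.itertuples(index=False):
            g.add_edge(str(a), str(b))
        return cls(channels, positions, g)


def _hemisphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the upper unit hemisphere.

    Fibonacci lattice mapped to z in [0, 1]; z strictly above the equator
    midline so every sensor sits on the scalp.
    """
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    z = (i + 0.5) / n  # heights in (0, 1)
    phi = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_layout(n_channels: int = 257,
                 neighbour_radius: float | None = None,
                 seed: int = 0,
                 jitter: float = 0.0) -> SensorLayout:
    """Place ``n_channels`` sensors on a hemispherical grid and connect
    every pair closer than ``neighbour_radius``.

    Parameters
    ----------
    n_channels
        Number of sensors (>= 2).
    neighbour_radius
        Euclidean distance (metres) below which two sensors are
        neighbours.  Default: 1.6x the median nearest-neighbour spacing,
        which yields the ~6 neighbours per channel typical of dense caps.
    seed, jitter
        Optional uniform positional jitter (fraction of the grid
        spacing); ``jitter=0`` gives a fully deterministic grid.
    """
    if n_channels < 2:
        raise LayoutError("a layout needs at least 2 channels")
    pts = _hemisphere_points(n_channels) * HEAD_RADIUS_M
    if jitter > 0:
        rng = np.random.default_rng(seed)
        spacing = HEAD_RADIUS_M * np.sqrt(2 * np.pi / n_channels)
        pts = pts + rng.uniform(-1, 1, pts.shape) * jitter * spacing
    channels = [f"E{i + 1}" for i in range(n_channels)]

    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    if neighbour_radius is None:
        nn = np.where(np.eye(n_channels, dtype=bool), np.inf, d).min(axis=1)
        neighbour_radius = 1.6 * float(np.median(nn))
    if neighbour_radius <= 0:
        raise LayoutError("neighbour_radius must be positive")

    g = nx.Graph()
    g.add_nodes_from(channels)
    iu, ju = np.triu_indices(n_channels, k=1)
    for i, j in zip(iu[d[iu, ju] < neighbour_radius], ju[d[iu, ju] < neighbour_radius]):
        g.add_edge(channels[i], channels[j])
    return SensorLayout(channels, pts, g)
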