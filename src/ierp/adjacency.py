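"""Neighbour definitions on the [channel, mode, time] lattice.

Modes: two modes are neighbours iff the symmetric difference (XOR) of
their constituent-order sets has exactly one element — e.g. 2:5 and 3:5
differ only in order 2, so they are neighbours, whereas 2:5 and 3:6
differ in {2, 6} and are not.  By default the aggregated trend block
counts as a single pseudo-ordinal, so p:q and p:q+ are neighbours; the
expanded interpretation (trend = all slow orders individually) is
available via ``trend_as_block=False``.

Channels: neighbours iff their Euclidean distance is strictly below a
threshold (default 40 mm).  Time: adjacent bins.

Lattice: two nodes are adjacent iff they are neighbours in exactly one
active dimension and share coordinates in all others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ChannelLayout
from .modes import ModeLabel

__all__ = [
    "ChannelLayout",
    "AdjacencyGraph",
    "modes_are_neighbors",
    "channel_neighbors",
    "mode_adjacency_matrix",
    "build_lattice_adjacency",
    "layout_from_montage",
]

DIM_ORDER = ("channel", "mode", "time")


def modes_are_neighbors(a: ModeLabel, b: ModeLabel,
                        trend_as_block: bool = True,
                        k_plus_1: int | None = None) -> bool:
    """XOR rule: neighbours iff the symmetric difference of constituent
    sets has exactly one element."""
    sa = a.constituents(trend_as_block=trend_as_block, k_plus_1=k_plus_1)
    sb = b.constituents(trend_as_block=trend_as_block, k_plus_1=k_plus_1)
    return len(sa ^ sb) == 1


def mode_adjacency_matrix(labels: list[ModeLabel],
                          trend_as_block: bool = True,
                          k_plus_1: int | None = None) -> np.ndarray:
    n = len(labels)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if modes_are_neighbors(labels[i], labels[j],
                                   trend_as_block=trend_as_block,
                                   k_plus_1=k_plus_1):
                adj[i, j] = adj[j, i] = True
    return adj


def channel_neighbors(layout: ChannelLayout,
                      threshold_mm: float = 40.0) -> np.ndarray:
    """Boolean adjacency: distance strictly below ``threshold_mm``."""
    if layout.n_channels < 1:
        raise ValueError("layout must have at least one channel")
    diff = layout.coords[:, None, :] - layout.coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    adj = dist < threshold_mm
    np.fill_diagonal(adj, False)
    return adj


@dataclass
class AdjacencyGraph:
    """Undirected graph over the lattice nodes.

    Nodes are indexed row-major over the active dimensions in the fixed
    order (channel, mode, time); ``shape`` gives the extent of each
    active dimension in that order.  ``edges`` is an (E, 2) array with
    u < v in each row.
    """

    shape: tuple[int, ...]
    dims: tuple[str, ...]
    edges: np.ndarray
    _neighbors: list | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    def node_index(self, *coords: int) -> int:
        return int(np.ravel_multi_index(coords, self.shape))

    def node_coords(self, idx: int) -> tuple[int, ...]:
        return tuple(int(c) for c in np.unravel_index(idx, self.shape))

    def neighbors(self, idx: int) -> np.ndarray:
        if self._neighbors is None:
            nb = [[] for _ in range(self.n_nodes)]
            for u, v in self.edges:
                nb[u].append(v)
                nb[v].append(u)
            self._neighbors = [np.array(sorted(x), dtype=np.intp) for x in nb]
        return self._neighbors[idx]

    def adjacency_matrix(self) -> np.ndarray:
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        if self.edges.size:
            adj[self.edges[:, 0], self.edges[:, 1]] = True
            adj[self.edges[:, 1], self.edges[:, 0]] = True
        return adj


def _pair_edges(adj: np.ndarray) -> np.ndarray:
    iu, ju = np.nonzero(np.triu(adj, k=1))
    return np.stack([iu, ju], axis=1)


def build_lattice_adjacency(mode_labels: list[ModeLabel],
                            layout: ChannelLayout | None = None,
                            n_time: int = 1,
                            dims: tuple[str, ...] = ("mode", "time"),
                            channel_threshold_mm: float = 40.0,
                            trend_as_block: bool = True,
                            k_plus_1: int | None = None) -> AdjacencyGraph:
    """Assemble the 2-D or 3-D lattice graph.

    ``dims`` selects the active dimensions (subset of channel/mode/time,
    two or three of them, any order; the node layout always follows the
    canonical channel-mode-time order).  Two nodes are adjacent iff they
    are neighbours in exactly one active dimension and identical in the
    rest.
    """
    dims = tuple(dims)
    unknown = set(dims) - set(DIM_ORDER)
    if unknown:
        raise ValueError(f"unknown dimension(s): {sorted(unknown)}")
    if len(dims) not in (2, 3) or len(set(dims)) != len(dims):
        raise ValueError("dims must be 2 or 3 distinct dimensions")
    dims = tuple(d for d in DIM_ORDER if d in dims)

    per_dim_adj: list[np.ndarray] = []
    shape: list[int] = []
    for d in dims:
        if d == "channel":
            if layout is None:
                raise ValueError("channel dimension requires a layout")
            adj = channel_neighbors(layout, channel_threshold_mm)
        elif d == "mode":
            adj = mode_adjacency_matrix(mode_labels,
                                        trend_as_block=trend_as_block,
                                        k_plus_1=k_plus_1)
        else:
            n = int(n_time)
            adj = np.zeros((n, n), dtype=bool)
            idx = np.arange(n - 1)
            adj[idx, idx + 1] = adj[idx + 1, idx] = True
        per_dim_adj.append(adj)
        shape.append(adj.shape[0])

    shape_t = tuple(shape)
    n_nodes = int(np.prod(shape_t))
    all_edges = []
    # edges along dimension a: neighbour pairs in a x identity elsewhere
    for a, adj in enumerate(per_dim_adj):
        pairs = _pair_edges(adj)
        if pairs.size == 0:
            continue
        stride = int(np.prod(shape_t[a + 1:], dtype=int))
        # flat indices of all nodes whose coordinate along dim a is 0
        offsets = np.arange(n_nodes).reshape(shape_t).take(0, axis=a).ravel()
        u = pairs[:, 0:1] * stride + offsets[None, :]
        v = pairs[:, 1:2] * stride + offsets[None, :]
        all_edges.append(np.stack([u.ravel(), v.ravel()], axis=1))
    if all_edges:
        edges_arr = np.concatenate(all_edges, axis=0).astype(np.intp)
        edges_arr = np.unique(np.sort(edges_arr, axis=1), axis=0)
    else:
        edges_arr = np.empty((0, 2), dtype=np.intp)
    return AdjacencyGraph(shape=shape_t, dims=dims, edges=edges_arr)


def layout_from_montage(names: list[str],
                        montage: str = "standard_1020") -> ChannelLayout:
    """Resolve standard electrode names to 3-D positions (mm) through an
    MNE template montage."""
    import mne

    mont = mne.channels.make_standard_montage(montage)
    pos = mont.get_positions()["ch_pos"]
    coords = []
    for name in names:
        if name not in pos:
            raise KeyError(f"channel {name!r} not in montage {montage!r}")
        coords.append(np.asarray(pos[name]) * 1000.0)  # m -> mm
    return ChannelLayout(labels=list(names), coords=np.array(coords))
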