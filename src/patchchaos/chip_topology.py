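"""Chip topology: the patch network as a graph with planar coordinates.

The experimental habitat is a microfluidic chip of 50 chambers ("patches",
2 mm diameter) connected by channels; every patch communicates with three
neighbours except the single patch at the far-left and the single patch at
the far-right end of the chip.  All spatial statistics in this package
(Moran's I weights, correlation-vs-distance curves, PERMANOVA position
covariates) operate on this graph, so the topology is always an explicit
input.

The exact channel wiring of the physical chip is not machine-readable from
the publication; :func:`default_chip_layout` ships a *reconstruction* that
honours the published constraints (50 patches, degree 3 everywhere except
the two end patches, 2 mm spacing, pairwise graph distances spanning
1..13).  It is a plausible stand-in, not ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ChipGraph",
    "DistanceMatrix",
    "default_chip_layout",
    "load_chip_layout",
    "load_edge_list_csv",
    "min_path_distances",
]

#: centre-to-centre spacing of adjacent chambers, mm
PATCH_SPACING_MM = 2.0


@dataclass(frozen=True)
class ChipGraph:
    """Validated patch network.

    Parameters
    ----------
    patch_ids:
        Integer patch labels, ordered; this order fixes the row order of
        every abundance matrix and transition matrix downstream.
    adjacency:
        Frozen set of unordered ``(i, j)`` id pairs (``i < j``).
    coords:
        Mapping ``id -> (x, y)`` in mm; ``x`` runs along the chip's long
        axis (origin at the far-left patch), ``y`` across its width.
    """

    patch_ids: tuple[int, ...]
    adjacency: frozenset[tuple[int, int]]
    coords: dict[int, tuple[float, float]] = field(compare=False)

    def __post_init__(self) -> None:
        ids = self.patch_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if list(ids).count(i) > 1})
            raise ValueError(f"duplicate patch ids: {dupes}")
        idset = set(ids)
        for i, j in self.adjacency:
            if i == j:
                raise ValueError(f"self-loop on patch {i}")
            if i not in idset or j not in idset:
                raise ValueError(f"edge ({i}, {j}) references unknown patch")
            if i > j:
                raise ValueError(f"edge ({i}, {j}) not stored as (min, max)")
        missing = idset - set(self.coords)
        if missing:
            raise ValueError(f"patches without coordinates: {sorted(missing)}")
        g = self.to_networkx()
        if len(ids) > 1 and not nx.is_connected(g):
            comps = sorted(nx.connected_components(g), key=len)
            raise ValueError(
                f"graph is disconnected; smallest component: {sorted(comps[0])}"
            )

    @property
    def n_patches(self) -> int:
        return len(self.patch_ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.patch_ids)
        g.add_edges_from(self.adjacency)
        return g

    def degree(self, patch_id: int) -> int:
        return sum(patch_id in e for e in self.adjacency)

    def neighbors(self, patch_id: int) -> list[int]:
        out = []
        for i, j in self.adjacency:
            if i == patch_id:
                out.append(j)
            elif j == patch_id:
                out.append(i)
        return sorted(out)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 matrix in ``patch_ids`` order."""
        index = {p: k for k, p in enumerate(self.patch_ids)}
        a = np.zeros((self.n_patches, self.n_patches))
        for i, j in self.adjacency:
            a[index[i], index[j]] = 1.0
            a[index[j], index[i]] = 1.0
        return a

    def coord_array(self) -> np.ndarray:
        """(P, 2) array of (x, y) in ``patch_ids`` order."""
        return np.array([self.coords[p] for p in self.patch_ids], float)


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path distances in edge counts."""

    patch_ids: tuple[int, ...]
    d: np.ndarray  # (P, P) int

    def distance(self, i: int, j: int) -> int:
        idx = {p: k for k, p in enumerate(self.patch_ids)}
        return int(self.d[idx[i], idx[j]])


def _edges_frozen(edges) -> frozenset[tuple[int, int]]:
    out = set()
    for e in edges:
        i, j = int(e[0]), int(e[1])
        if i == j:
            raise ValueError(f"self-loop on patch {i}")
        out.add((min(i, j), max(i, j)))
    return frozenset(out)


def default_chip_layout() -> ChipGraph:
    """Reconstructed 50-patch chip.

    Layout: a far-left inlet patch and a far-right outlet patch joined by
    two parallel double-rows (two 2 x 12 ladders).  Every ladder patch has
    exactly three neighbours; the two end patches collect the four row
    ends on their side.  Pairwise graph distances span 1..13, matching the
    distance range over which the published correlation-distance curves
    extend.
    """
    n_cols = 12
    s = PATCH_SPACING_MM
    ids, coords, edges = [], {}, []
    left, right = 1, 50
    ids.append(left)
    coords[left] = (0.0, 1.5 * s)
    # rows 0..3 (y), columns 1..12 (x); ids 2..49 row-major
    def pid(row: int, col: int) -> int:
        return 2 + row * n_cols + (col - 1)

    for row in range(4):
        for col in range(1, n_cols + 1):
            p = pid(row, col)
            ids.append(p)
            coords[p] = (col * s, row * s)
            if col > 1:
                edges.append((pid(row, col - 1), p))
    # rungs pair rows (0,1) and (2,3) in every column: two ladders
    for col in range(1, n_cols + 1):
        edges.append((pid(0, col), pid(1, col)))
        edges.append((pid(2, col), pid(3, col)))
    ids.append(right)
    coords[right] = ((n_cols + 1) * s, 1.5 * s)
    for row in range(4):
        edges.append((left, pid(row, 1)))
        edges.append((pid(row, n_cols), right))
    return ChipGraph(tuple(sorted(ids)), _edges_frozen(edges), coords)


def load_chip_layout(config: str | Path | dict) -> ChipGraph:
    """Load a topology file (YAML or JSON) into a validated :class:`ChipGraph`.

    The file holds ``patches: [{id, x, y}, ...]`` and ``edges: [[i, j], ...]``.
    Raises ``ValueError`` on duplicate ids, self-loops, edges to unknown
    patches or a disconnected graph.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        data = json.loads(text) if text.lstrip().startswith("{") else yaml.safe_load(text)
    else:
        data = config
    try:
        patches = data["patches"]
        edges = data["edges"]
    except (KeyError, TypeError) as exc:
        raise ValueError("topology file needs 'patches' and 'edges' keys") from exc
    ids = [int(p["id"]) for p in patches]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patch ids in topology file")
    coords = {int(p["id"]): (float(p["x"]), float(p["y"])) for p in patches}
    return ChipGraph(tuple(sorted(ids)), _edges_frozen(edges), coords)


def load_edge_list_csv(path: str | Path, coords: dict[int, tuple[float, float]] | None = None) -> ChipGraph:
    """Build a ChipGraph from a two-column integer edge-list CSV.

    Coordinates default to a spring layout (positions are then only
    indicative; distance-based statistics remain exact since they use the
    graph, not the coordinates).
    """
    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("edge-list CSV needs two integer columns")
    edges = _edges_frozen(df.iloc[:, :2].to_numpy(int))
    ids = tuple(sorted({i for e in edges for i in e}))
    if coords is None:
        g = nx.Graph(list(edges))
        pos = nx.spring_layout(g, seed=0)
        coords = {i: (float(pos[i][0]), float(pos[i][1])) for i in ids}
    return ChipGraph(ids, edges, coords)


def min_path_distances(graph: ChipGraph) -> DistanceMatrix:
    """All-pairs shortest-path lengths (edge counts) on the patch network.

    Direct neighbours have distance 1.  Raises on a disconnected graph,
    naming an unreachable pair.
    """
    g = graph.to_networkx()
    n = graph.n_patches
    index = {p: k for k, p in enumerate(graph.patch_ids)}
    d = np.full((n, n), -1, dtype=int)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, length in lengths.items():
            d[index[src], index[dst]] = length
    if (d < 0).any():
        i, j = np.argwhere(d < 0)[0]
        raise ValueError(
            f"graph is disconnected: no path between patches "
            f"{graph.patch_ids[i]} and {graph.patch_ids[j]}"
        )
    return DistanceMatrix(graph.patch_ids, d)
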