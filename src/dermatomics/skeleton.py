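"""Skeleton-graph analysis of epidermal components.

Each epidermal component ("tree") is thinned to a 1-px skeleton, whose
pixels are classified by 8-neighbor count: junctions (>2 neighbors) and
endpoints (exactly 1) become graph vertices, the connected runs of
remaining pixels become weighted edges (weight = pixel count). On the
minimum spanning tree, the weighted diameter found by a two-pass Dijkstra
sweep is the epidermal *midline*; every other MST edge is a provisional
rete ridge, validated by a directional rule against the tissue boundary:
a ridge whose distal tip is strictly closer to the (outer) tissue boundary
than its base points the wrong way and is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import thin

#: components whose midline is shorter than this many pixels are rejected
MIN_MIDLINE_PX = 500

_SE8 = np.ones((3, 3), bool)


@dataclass
class Skeleton:
    """Thinned medial axis of one epidermal component."""

    mask: np.ndarray  # boolean raster, True on skeleton pixels
    component_id: int = 0

    @property
    def pixels(self) -> np.ndarray:
        return np.argwhere(self.mask)


@dataclass
class SkeletonNode:
    node_id: int
    kind: str  # "junction" | "endpoint"
    member_pixels: np.ndarray  # (k, 2) int
    centroid: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.centroid = tuple(self.member_pixels.mean(axis=0))


@dataclass
class Branch:
    branch_id: int
    pixels: np.ndarray  # (k, 2) int, excludes node pixels
    endpoints: tuple[int, int]  # node ids
    length: int = 0

    def __post_init__(self) -> None:
        self.length = len(self.pixels)


class RidgeStatus(Enum):
    PROVISIONAL = "provisional"
    VALID = "valid"
    REJECTED = "rejected"


@dataclass
class RidgeRecord:
    edge: tuple[int, int]
    branch: Branch
    base_node: int
    tip_node: int
    status: RidgeStatus
    reason: str = ""
    d_tip: float = float("nan")
    d_base: float = float("nan")


@dataclass
class EpidermisGraph:
    graph: nx.Graph
    nodes: dict[int, SkeletonNode]
    branches: dict[int, Branch]
    mst_edges: list[tuple[int, int]] = field(default_factory=list)
    midline_path: list[int] = field(default_factory=list)
    midline_edges: list[tuple[int, int]] = field(default_factory=list)
    midline_length: float = 0.0
    ridges: list[RidgeRecord] = field(default_factory=list)
    accepted: bool | None = None
    rejection_reason: str = ""

    @property
    def valid_ridges(self) -> list[RidgeRecord]:
        return [r for r in self.ridges if r.status is RidgeStatus.VALID]

    def midline_pixels(self) -> np.ndarray:
        """All skeleton pixels on the midline: branch pixels + node members."""
        parts = []
        for u, v in self.midline_edges:
            bid = self.graph.edges[u, v]["branch_id"]
            parts.append(self.branches[bid].pixels)
        for nid in self.midline_path:
            parts.append(self.nodes[nid].member_pixels)
        if not parts:
            return np.empty((0, 2), int)
        return np.unique(np.concatenate(parts), axis=0)


class BoundaryIndex:
    """k-d tree over the boundary pixels of a binary mask.

    Boundary pixels are mask pixels 8-adjacent to background *within* the
    raster (image edges do not count as background), so for tissue spanning
    the full frame the index is dominated by the outer tissue surface.
    """

    def __init__(self, mask: np.ndarray, scope: str = "tissue-boundary"):
        mask = mask.astype(bool)
        eroded = ndimage.binary_erosion(mask, _SE8, border_value=1)
        self.boundary_mask = mask & ~eroded
        self.boundary_pixels = np.argwhere(self.boundary_mask)
        self.scope = scope
        self._tree = (
            cKDTree(self.boundary_pixels) if len(self.boundary_pixels) else None
        )

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance from each query point to the nearest boundary pixel."""
        pts = np.atleast_2d(np.asarray(points, float))
        if self._tree is None:
            return np.full(len(pts), np.inf)
        d, _ = self._tree.query(pts)
        return np.atleast_1d(d)


def skeletonize_component(mask_component: np.ndarray) -> Skeleton:
    """Thin one 8-connected component to a 1-px skeleton (morphological thinning)."""
    return Skeleton(thin(mask_component.astype(bool)))


def _neighbor_counts(sk_mask: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), int)
    kernel[1, 1] = 0
    return ndimage.convolve(sk_mask.astype(int), kernel, mode="constant")


def detect_nodes_and_branches(
    sk: Skeleton,
) -> tuple[list[SkeletonNode], list[Branch]]:
    """Classify skeleton pixels into nodes and branches.

    Neighbor counts use the 3x3 kernel (center excluded) over skeleton pixels
    only. Clusters of 8-adjacent junction pixels merge into one junction node
    (thinning frequently emits junction clusters; merging prevents spurious
    zero-length branches); endpoint pixels stay individual nodes. Branches
    adjacent to anything other than exactly two distinct nodes are discarded.
    """
    m = sk.mask
    nb = _neighbor_counts(m)
    junction = m & (nb > 2)
    endpoint = m & (nb == 1)
    nodes: list[SkeletonNode] = []
    node_label = np.zeros(m.shape, int)  # node_id + 1
    nid = 0
    # junction clusters merge into one node; endpoints stay individual pixels
    lab, n = ndimage.label(junction, structure=_SE8)
    for k in range(1, n + 1):
        pix = np.argwhere(lab == k)
        nodes.append(SkeletonNode(nid, "junction", pix))
        node_label[tuple(pix.T)] = nid + 1
        nid += 1
    for r, c in np.argwhere(endpoint):
        nodes.append(SkeletonNode(nid, "endpoint", np.array([[r, c]])))
        node_label[r, c] = nid + 1
        nid += 1
    branch_mask = m & (node_label == 0)
    lab, nb_branches = ndimage.label(branch_mask, structure=_SE8)
    branches: list[Branch] = []
    bid = 0
    for k in range(1, nb_branches + 1):
        pix = np.argwhere(lab == k)
        adj = set()
        for r, c in pix:
            r0, r1 = max(r - 1, 0), min(r + 2, m.shape[0])
            c0, c1 = max(c - 1, 0), min(c + 2, m.shape[1])
            adj.update(int(v) - 1 for v in np.unique(node_label[r0:r1, c0:c1]) if v)
        if len(adj) == 2:
            u, v = sorted(adj)
            branches.append(Branch(bid, pix, (u, v)))
            bid += 1
    return nodes, branches


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_graph_and_mst(
    nodes: list[SkeletonNode], branches: list[Branch]
) -> EpidermisGraph:
    """Build the weighted graph and its minimum spanning forest.

    Parallel branches between the same node pair collapse to the lighter one
    (ties by branch_id). The MST is Kruskal over edges sorted by
    (weight, branch_id), giving a deterministic tie rule.
    """
    g = nx.Graph()
    node_map = {n.node_id: n for n in nodes}
    g.add_nodes_from(node_map)
    branch_map = {b.branch_id: b for b in branches}
    for b in sorted(branches, key=lambda b: (b.length, b.branch_id)):
        u, v = b.endpoints
        if not g.has_edge(u, v):  # first (lightest) parallel edge wins
            g.add_edge(u, v, weight=b.length, branch_id=b.branch_id)
    eg = EpidermisGraph(g, node_map, branch_map)
    uf = _UnionFind(g.nodes)
    edges = sorted(
        g.edges(data=True), key=lambda e: (e[2]["weight"], e[2]["branch_id"])
    )
    for u, v, _ in edges:
        if uf.union(u, v):
            eg.mst_edges.append((u, v))
    return eg


def longest_path(eg: EpidermisGraph) -> tuple[list[int], float]:
    """Weighted diameter of the MST via the two-pass Dijkstra sweep.

    From the lowest node id, find the farthest vertex (ties to the lowest
    id); from there, the farthest vertex again. The path between the two
    sweeps is the tree diameter. Stored on the graph and returned.
    """
    t = nx.Graph()
    t.add_nodes_from(eg.graph.nodes)
    for u, v in eg.mst_edges:
        t.add_edge(u, v, weight=eg.graph.edges[u, v]["weight"])
    if t.number_of_nodes() == 0:
        eg.midline_path, eg.midline_length = [], 0.0
        return [], 0.0

    def farthest(src: int) -> tuple[int, float]:
        dist = nx.single_source_dijkstra_path_length(t, src)
        best = max(dist.items(), key=lambda kv: (kv[1], -kv[0]))
        return best[0], best[1]

    start = min(t.nodes)
    a, _ = farthest(start)
    b, length = farthest(a)
    path = nx.dijkstra_path(t, a, b)
    if path[0] > path[-1]:  # canonical orientation
        path = path[::-1]
    eg.midline_path = path
    eg.midline_length = float(length)
    eg.midline_edges = [tuple(sorted(e)) for e in zip(path, path[1:])]
    return path, float(length)


def classify_and_validate(
    eg: EpidermisGraph,
    tissue_boundary: BoundaryIndex,
    min_path_px: int = MIN_MIDLINE_PX,
) -> EpidermisGraph:
    """Label MST edges as midline or ridge and validate ridges directionally.

    A component whose midline is shorter than ``min_path_px`` is rejected
    outright. Each non-midline MST edge is a provisional ridge; its *base*
    is the edge node nearer the midline (ties resolved toward a junction),
    its *tip* the other node. The ridge is valid iff the tip is not strictly
    closer to the tissue boundary than the base (d_tip >= d_base); otherwise
    it points toward the outer surface and is discarded.
    """
    if not eg.midline_path and eg.graph.number_of_nodes():
        longest_path(eg)
    if eg.midline_length < min_path_px:
        eg.accepted = False
        eg.rejection_reason = (
            f"midline {eg.midline_length:.0f} px < {min_path_px} px"
        )
        eg.ridges = []
        return eg
    eg.accepted = True
    midline_px = eg.midline_pixels()
    mid_tree = cKDTree(midline_px) if len(midline_px) else None
    midline_set = set(eg.midline_edges)
    on_midline = set(eg.midline_path)
    ridges: list[RidgeRecord] = []
    for u, v in eg.mst_edges:
        e = tuple(sorted((u, v)))
        if e in midline_set:
            continue
        bid = eg.graph.edges[u, v]["branch_id"]
        branch = eg.branches[bid]
        nu, nv = eg.nodes[u], eg.nodes[v]
        if u in on_midline and v not in on_midline:
            base, tip = u, v
        elif v in on_midline and u not in on_midline:
            base, tip = v, u
        else:
            du = mid_tree.query([nu.centroid])[0][0] if mid_tree else np.inf
            dv = mid_tree.query([nv.centroid])[0][0] if mid_tree else np.inf
            if du < dv:
                base, tip = u, v
            elif dv < du:
                base, tip = v, u
            else:  # tie: junction is the base
                base, tip = (u, v) if nu.kind == "junction" else (v, u)
        d_tip = float(tissue_boundary.distance([eg.nodes[tip].centroid])[0])
        d_base = float(tissue_boundary.distance([eg.nodes[base].centroid])[0])
        if d_tip < d_base:
            rec = RidgeRecord(
                e, branch, base, tip, RidgeStatus.REJECTED,
                reason=f"tip closer to boundary ({d_tip:.1f} < {d_base:.1f})",
                d_tip=d_tip, d_base=d_base,
            )
        else:
            rec = RidgeRecord(
                e, branch, base, tip, RidgeStatus.VALID,
                d_tip=d_tip, d_base=d_base,
            )
        ridges.append(rec)
    eg.ridges = ridges
    return eg


def analyze_component(
    component_mask: np.ndarray,
    tissue_boundary: BoundaryIndex,
    min_path_px: int = MIN_MIDLINE_PX,
    component_id: int = 0,
) -> EpidermisGraph:
    """Full per-component analysis: thin, graph, MST, midline, ridge validation."""
    sk = skeletonize_component(component_mask)
    sk.component_id = component_id
    nodes, branches = detect_nodes_and_branches(sk)
    if not nodes:
        eg = EpidermisGraph(nx.Graph(), {}, {})
        eg.accepted = False
        eg.rejection_reason = "no skeleton nodes"
        return eg
    eg = build_graph_and_mst(nodes, branches)
    longest_path(eg)
    return classify_and_validate(eg, tissue_boundary, min_path_px)
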