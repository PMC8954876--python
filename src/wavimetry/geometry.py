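"""Skeleton longest-path geometry and the arc-chord waviness ratio r_ec.

Each kept fragment is thinned to a one-pixel-wide skeleton, reduced to the
longest simple path of its pixel-adjacency graph (removing side branches),
and resampled:

* every ``s``-th skeleton pixel is selected (always retaining the last
  pixel), then ``s - 1`` equally spaced vertices are linearly interpolated
  back into each gap so the polygonal line has exactly as many vertices as
  the original path had pixels — subsampling smooths pixel-level staircase
  artifacts, oversampling restores the vertex budget;
* the geodesic-like length is the sum of consecutive-vertex distances — the
  curvilinear length of the fragment;
* the Euclidean-like length walks the polyline and sums chords between
  points spaced 100 units of geodesic length apart (with two fallbacks for
  short lines: a single first-to-last chord below 100 units, and a
  first/middle + middle/last two-chord sum below 200 units, the middle being
  the vertex nearest half the geodesic length).

r_ec = Euclidean-like / geodesic-like length: 1 for a straight fragment,
below 1 for a wavy one.  The shortfall from 1 measures the lamella's reserve
length — the slack it can recruit when the vessel wall stretches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.morphology import skeletonize as sk_skeletonize

from .extraction import FragmentRegion

log = logging.getLogger(__name__)

DEFAULT_S = 3
DEFAULT_STEP = 100.0

#: exhaustive DFS is used for longest-path search up to this many skeleton
#: pixels; beyond it, exact tree search / condensed-graph enumeration.
_BRUTE_FORCE_NODES = 24
_MAX_BRANCH_NODES = 20

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonPath:
    """Ordered simple path of 8-connected skeleton pixels."""

    pixels: list[tuple[int, int]]     # (row, col)
    region_id: int = 0
    slice_index: int = 0

    def __post_init__(self) -> None:
        if len(self.pixels) < 2:
            raise ValueError("a skeleton path needs at least 2 pixels")


@dataclass
class SampledPolyline:
    """Subpixel polygonal line from the s-subsample/oversample scheme."""

    vertices: np.ndarray              # (n, 2) float, (x, y)
    s: int


@dataclass
class WavinessRecord:
    """One fragment's measured lengths and waviness ratio."""

    stack_id: str
    slice_index: int
    region_id: int
    area: int
    euclid_like: float
    geodesic_like: float
    r_ec: float
    s: int


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

def skeletonize(region: FragmentRegion) -> np.ndarray:
    """One-pixel-wide, topology-preserving thinning of the region.

    Operates on the cropped region mask; returns a boolean mask in the same
    cropped frame (bbox offset available from ``region.bbox``).
    """
    if region.mask is None or not region.mask.any():
        raise ValueError("empty region cannot be skeletonized")
    # noise speckle can punch holes into a stroke; a lamella cross-section is
    # a solid curve, so holes are filled to keep the skeleton loop-free
    return sk_skeletonize(binary_fill_holes(region.mask))


# ---------------------------------------------------------------------------
# longest path
# ---------------------------------------------------------------------------

def _pixel_graph(skeleton: np.ndarray) -> nx.Graph:
    rows, cols = np.nonzero(skeleton)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    g = nx.Graph()
    g.add_nodes_from(pixels)
    for (r, c) in pixels:
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if q in pixels:
                g.add_edge((r, c), q)
    return g


def _prune_redundant_diagonals(g: nx.Graph) -> nx.Graph:
    """Drop diagonal edges whose endpoints share an orthogonal neighbor.

    Corner pixels of an 8-connected skeleton form triangles; removing the
    diagonal shortcut of each triangle canonicalizes the graph (usually into
    a tree) without disconnecting it, since the two endpoints remain joined
    through the shared orthogonal pixel.  Used before the path search on
    skeletons too large for exhaustive enumeration.
    """
    drop = []
    for (a, b) in g.edges:
        if a[0] != b[0] and a[1] != b[1]:  # diagonal
            if g.has_node((a[0], b[1])) or g.has_node((b[0], a[1])):
                drop.append((a, b))
    if drop:
        g = g.copy()
        g.remove_edges_from(drop)
    return g


def _brute_force_longest(g: nx.Graph) -> list[tuple[int, int]]:
    """Exhaustive DFS over simple paths; returns the best path, ties broken
    by the lexicographically smallest (start, end, path) tuple."""
    best: tuple[int, tuple, tuple] | None = None

    def consider(path: tuple) -> None:
        nonlocal best
        cand = (-len(path), path[0], path[-1], path)
        if best is None or cand < best:
            best = cand

    nodes = sorted(g.nodes)
    for start in nodes:
        stack = [(start, (start,), {start})]
        while stack:
            node, path, seen = stack.pop()
            extended = False
            for nb in sorted(g.neighbors(node)):
                if nb not in seen:
                    extended = True
                    stack.append((nb, path + (nb,), seen | {nb}))
            if not extended and len(path) >= 2:
                consider(path)
    if best is None:  # single node graph
        return nodes
    return list(best[3])


def _tree_longest(g: nx.Graph) -> list[tuple[int, int]]:
    """Exact longest path in a tree: best leaf pair by BFS from each leaf."""
    leaves = sorted(n for n in g.nodes if g.degree(n) <= 1)
    if len(leaves) <= 1:  # single node or malformed
        return sorted(g.nodes)
    if len(leaves) > 48:  # fall back to double sweep for pathological trees
        a = _farthest(g, leaves[0])
        b = _farthest(g, a)
        return nx.shortest_path(g, a, b)
    best = None
    for leaf in leaves:
        dist = nx.single_source_shortest_path_length(g, leaf)
        for other in leaves:
            if other == leaf:
                continue
            cand = (-dist[other], leaf, other)
            if best is None or cand < best:
                best = cand
    return nx.shortest_path(g, best[1], best[2])


def _farthest(g: nx.Graph, source) -> tuple[int, int]:
    dist = nx.single_source_shortest_path_length(g, source)
    dmax = max(dist.values())
    return min(n for n, d in dist.items() if d == dmax)


def _condense(g: nx.Graph) -> nx.MultiGraph:
    """Contract degree-2 chains into corridor edges carrying pixel lists."""
    hubs = sorted(n for n in g.nodes if g.degree(n) != 2)
    h = nx.MultiGraph()
    h.add_nodes_from(hubs)
    seen_edges = set()
    for hub in hubs:
        for nb in sorted(g.neighbors(hub)):
            if (hub, nb) in seen_edges:
                continue
            chain = [hub, nb]
            prev, cur = hub, nb
            while g.degree(cur) == 2 and cur not in hubs:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                chain.append(nxt)
                prev, cur = cur, nxt
            for a, b in zip(chain, chain[1:]):
                seen_edges.add((a, b))
                seen_edges.add((b, a))
            h.add_edge(chain[0], chain[-1], pixels=chain)
    return h


def _condensed_longest(g: nx.Graph) -> list[tuple[int, int]]:
    """Exact-on-branch-graph longest path with partial corridor extensions."""
    h = _condense(g)
    hubs = sorted(h.nodes)
    best: tuple[int, tuple, list] | None = None

    def consider(path: list) -> None:
        nonlocal best
        cand = (-len(path), tuple(path[:2]), path)
        if best is None or cand < best:
            best = cand

    for u in hubs:
        for v in hubs:
            if v < u:
                continue
            for edge_path in nx.all_simple_edge_paths(h, u, v):
                pix: list = []
                ok = True
                node = u
                used = set()
                for (a, b, k) in edge_path:
                    seq = h.edges[a, b, k]["pixels"]
                    if seq[0] != node:
                        seq = seq[::-1]
                    if pix and seq[0] != pix[-1]:
                        ok = False
                        break
                    body = seq if not pix else seq[1:]
                    if any(p in used for p in body):
                        ok = False
                        break
                    used.update(body)
                    pix.extend(body)
                    node = seq[-1]
                    used.add(seq[0])
                if not ok or len(pix) < 2:
                    continue
                consider(pix)
                # partial extensions into unused corridors whose far end is
                # already on the path (e.g. the loop of a lollipop skeleton)
                for endpoint, reverse in ((pix[-1], False), (pix[0], True)):
                    for (a, b, k) in h.edges(endpoint, keys=True):
                        seq = h.edges[a, b, k]["pixels"]
                        if seq[0] != endpoint:
                            seq = seq[::-1]
                        interior = seq[1:-1]
                        if not interior or any(p in used for p in interior):
                            continue
                        if reverse:
                            consider(interior[::-1] + pix)
                        else:
                            consider(pix + interior)
    if best is None:
        return _brute_force_longest(g)
    return best[2]


def longest_path(skeleton: np.ndarray, region_id: int = 0,
                 slice_index: int = 0) -> SkeletonPath:
    """Longest simple path in the skeleton's 8-adjacency pixel graph.

    Exact by exhaustive DFS on tiny graphs, by leaf-pair search on trees,
    and by branch-graph enumeration (with partial corridor extensions) on
    cyclic skeletons of at most 20 branch nodes; a double-sweep heuristic
    covers anything larger.  Ties are broken toward the lexicographically
    smallest start pixel.  A pure cycle (no endpoints) is opened at its
    lexicographically smallest pixel.
    """
    g = _pixel_graph(skeleton)
    if g.number_of_nodes() == 0:
        raise ValueError("empty skeleton")
    if g.number_of_nodes() == 1:
        raise ValueError("skeleton reduced to a single pixel")
    if not nx.is_connected(g):
        comp = max(nx.connected_components(g), key=lambda c: (len(c), ))
        log.debug("skeleton not connected; keeping largest component "
                  "(%d of %d pixels)", len(comp), g.number_of_nodes())
        g = g.subgraph(comp).copy()
        if g.number_of_nodes() == 1:
            raise ValueError("skeleton reduced to a single pixel")

    if all(d == 2 for _, d in g.degree):  # closed loop: open it
        p = min(g.nodes)
        q = min(g.neighbors(p))
        log.debug("cyclic skeleton opened at %s", (p,))
        g.remove_edge(p, q)

    n = g.number_of_nodes()
    if n <= _BRUTE_FORCE_NODES:
        path = _brute_force_longest(g)
    elif nx.is_tree(g):
        path = _tree_longest(g)
    elif nx.is_tree(pruned := _prune_redundant_diagonals(g)):
        path = _tree_longest(pruned)
    else:
        g = pruned
        if all(d == 2 for _, d in g.degree):  # pruning exposed a pure cycle
            p = min(g.nodes)
            g.remove_edge(p, min(g.neighbors(p)))
        if nx.is_tree(g):
            path = _tree_longest(g)
            if path[0] > path[-1]:
                path = path[::-1]
            return SkeletonPath(pixels=[tuple(p) for p in path],
                                region_id=region_id, slice_index=slice_index)
        branch_nodes = sum(1 for _, d in g.degree if d != 2)
        if n <= 10_000 and branch_nodes <= _MAX_BRANCH_NODES:
            path = _condensed_longest(g)
        else:
            a = _farthest(g, min(g.nodes))
            b = _farthest(g, a)
            path = nx.shortest_path(g, a, b)
    if path[0] > path[-1]:
        path = path[::-1]
    return SkeletonPath(pixels=[tuple(p) for p in path],
                        region_id=region_id, slice_index=slice_index)


# ---------------------------------------------------------------------------
# sampling and lengths
# ---------------------------------------------------------------------------

def subsample_oversample(path: SkeletonPath, s: int = DEFAULT_S) -> SampledPolyline:
    """Select every ``s``-th path pixel (keeping the last), then interpolate
    the skipped count of equally spaced vertices back into each gap.

    The result always has exactly as many vertices as the path has pixels;
    a trailing gap shorter than ``s`` receives proportionally fewer inserted
    vertices.  Paths shorter than ``s + 1`` pixels fall back to ``s = 1``.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    pix = np.asarray([(c, r) for r, c in path.pixels], dtype=float)  # (x, y)
    n = len(pix)
    if s == 1:
        return SampledPolyline(vertices=pix, s=1)
    if n < s + 1:
        log.debug("path of %d pixels shorter than s+1=%d: falling back to s=1",
                  n, s + 1)
        return SampledPolyline(vertices=pix, s=1)
    sel = list(range(0, n - 1, s)) + [n - 1]
    chunks = []
    for i, j in zip(sel, sel[1:]):
        gap = j - i
        seg = np.linspace(pix[i], pix[j], gap + 1)  # gap-1 interior vertices
        chunks.append(seg[:-1])
    chunks.append(pix[-1][None, :])
    vertices = np.concatenate(chunks, axis=0)
    assert len(vertices) == n
    return SampledPolyline(vertices=vertices, s=s)


def _as_vertices(poly) -> np.ndarray:
    v = poly.vertices if isinstance(poly, SampledPolyline) else np.asarray(poly, float)
    if len(v) < 2:
        raise ValueError("need at least 2 vertices")
    return v


def geodesic_like_length(poly) -> float:
    """Curvilinear length: sum of consecutive-vertex Euclidean distances."""
    v = _as_vertices(poly)
    return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())


def euclid_like_length(poly, step: float = DEFAULT_STEP) -> float:
    """End-to-end-like length: chord sum over marks every ``step`` units of
    geodesic length along the polyline.

    Short lines use the stated fallbacks: below one step, the single
    first-to-last chord; between one and two steps, first/middle plus
    middle/last chords where the middle is the vertex nearest half the
    geodesic length (ties to the earlier vertex).  The final vertex is
    always a mark, so no trailing portion of the curve is ignored.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    v = _as_vertices(poly)
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    total = float(seg.sum())
    if total < step:
        return float(np.linalg.norm(v[-1] - v[0]))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if total < 2 * step:
        mid = int(np.argmin(np.abs(cum - total / 2.0)))
        return float(np.linalg.norm(v[mid] - v[0])
                     + np.linalg.norm(v[-1] - v[mid]))
    positions = np.arange(0.0, total, step)
    xs = np.interp(positions, cum, v[:, 0])
    ys = np.interp(positions, cum, v[:, 1])
    marks = np.column_stack([xs, ys])
    marks = np.vstack([marks, v[-1]])
    return float(np.linalg.norm(np.diff(marks, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# fragment measurement
# ---------------------------------------------------------------------------

def measure_fragment(region: FragmentRegion, s: int = DEFAULT_S,
                     step: float = DEFAULT_STEP, stack_id: str = "stack",
                     ) -> WavinessRecord | None:
    """Skeletonize, reduce to the longest path, resample, and compute r_ec.

    Returns None (with a logged reason) for degenerate fragments whose
    skeleton collapses to a single pixel or whose polyline has zero length.
    """
    try:
        skel = skeletonize(region)
        path = longest_path(skel, region_id=region.region_id,
                            slice_index=region.slice_index)
    except ValueError as err:
        log.debug("fragment %s/%d skipped: %s", stack_id, region.region_id, err)
        return None
    poly = subsample_oversample(path, s=s)
    geo = geodesic_like_length(poly)
    if geo == 0.0:
        log.debug("fragment %s/%d skipped: zero geodesic length",
                  stack_id, region.region_id)
        return None
    euc = euclid_like_length(poly, step=step)
    return WavinessRecord(
        stack_id=stack_id, slice_index=region.slice_index,
        region_id=region.region_id, area=region.area,
        euclid_like=euc, geodesic_like=geo, r_ec=euc / geo, s=poly.s)
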