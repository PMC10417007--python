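"""Skeleton-to-graph conversion and centerline segment extraction.

A thinned vessel skeleton is interpreted as a graph whose nodes are
endpoints (8-neighborhood degree 1) and bifurcations (degree >= 3) and
whose edges are the ordered pixel chains between them.  Clusters of
adjacent junction pixels — a common thinning artifact — are condensed
into a single node at their centroid.  Isolated cycles with no node are
cut at their topmost-leftmost pixel.  Each edge becomes one centerline
segment: the unit on which the tortuosity index is computed.

Coordinates follow the package convention: (x, y) = (col, row), 0-based,
origin top-left.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .ridge import VesselSkeleton
from .tortuosity import smooth_polyline

__all__ = ["VesselGraph", "VesselSegment", "build_graph", "extract_segments", "apply_manual_points"]

logger = logging.getLogger(__name__)

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class VesselGraph:
    """Vessel network graph.

    ``graph`` is a :class:`networkx.MultiGraph`; node attributes carry
    ``pixels`` (the junction-cluster member pixels), ``pos`` (centroid
    (x, y)) and ``kind`` (endpoint / bifurcation / cycle_cut / manual);
    edge attribute ``pixels`` is the ordered (row, col) chain including
    the terminal node pixels.  ``subpixel`` maps skeleton pixels to
    sub-pixel centerline coordinates where the ridge detector provided
    them.
    """

    graph: nx.MultiGraph
    subpixel: dict = field(default_factory=dict)

    @property
    def n_endpoints(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["kind"] == "endpoint")

    @property
    def n_bifurcations(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if d["kind"] == "bifurcation")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class VesselSegment:
    """Ordered sub-pixel centerline polyline between two graph nodes."""

    points: np.ndarray  # (n, 2) of (x, y)
    edge_id: int
    length_px: float

    def __len__(self) -> int:
        return len(self.points)


def _neighbor_degree(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant") * skel


def build_graph(skeleton: VesselSkeleton | np.ndarray) -> VesselGraph:
    """Build the vessel graph of a 1-px-wide, 8-connected skeleton."""
    if isinstance(skeleton, VesselSkeleton):
        skel = skeleton.skeleton.astype(bool)
        subpixel = dict(skeleton.subpixel)
    else:
        skel = np.asarray(skeleton, dtype=bool)
        subpixel = {}

    deg = _neighbor_degree(skel)
    node_mask = skel & (deg != 2)
    # condense 8-connected clusters of node pixels into single nodes
    labels, n_clusters = ndimage.label(node_mask, structure=np.ones((3, 3), int))

    g = nx.MultiGraph()
    cluster_pixels: dict[int, list[tuple[int, int]]] = {i: [] for i in range(1, n_clusters + 1)}
    for r, c in zip(*np.nonzero(node_mask)):
        cluster_pixels[labels[r, c]].append((int(r), int(c)))
    for cid in range(1, n_clusters + 1):
        pix = sorted(cluster_pixels[cid])
        degs = [deg[r, c] for r, c in pix]
        kind = "bifurcation" if max(degs) >= 3 else "endpoint"
        arr = np.asarray(pix, dtype=float)
        g.add_node(cid, pixels=pix, pos=(float(arr[:, 1].mean()), float(arr[:, 0].mean())), kind=kind)

    nrows, ncols = skel.shape
    interior = skel & (deg == 2) & ~node_mask
    visited = np.zeros_like(skel, dtype=bool)
    direct_edges: set[frozenset] = set()

    def neighbors(r, c):
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and skel[rr, cc]:
                yield rr, cc

    # trace edges starting from each node pixel
    for cid in sorted(g.nodes):
        for r, c in g.nodes[cid]["pixels"]:
            for rr, cc in neighbors(r, c):
                if node_mask[rr, cc]:
                    other = labels[rr, cc]
                    if other != cid or (rr, cc) > (r, c):
                        key = frozenset([(r, c), (rr, cc)])
                        if other != cid and key not in direct_edges:
                            direct_edges.add(key)
                            g.add_edge(cid, int(other), pixels=[(r, c), (rr, cc)])
                    continue
                if visited[rr, cc]:
                    continue
                # walk through interior (degree-2) pixels
                path = [(r, c), (rr, cc)]
                visited[rr, cc] = True
                prev, cur = (r, c), (rr, cc)
                while True:
                    nxt = None
                    for nr, nc in neighbors(*cur):
                        if (nr, nc) == prev:
                            continue
                        if node_mask[nr, nc]:
                            nxt = (nr, nc)
                            break
                        if interior[nr, nc] and not visited[nr, nc]:
                            nxt = (nr, nc)
                    if nxt is None:
                        break
                    path.append(nxt)
                    if node_mask[nxt]:
                        break
                    visited[nxt] = True
                    prev, cur = cur, nxt
                end = path[-1]
                if node_mask[end]:
                    g.add_edge(cid, int(labels[end]), pixels=path)
                # else: dead-end walk into already-visited pixels (should not
                # occur on a thin skeleton); drop silently

    # isolated cycles: unvisited interior pixels with no node anywhere
    remaining = interior & ~visited
    comp_labels, n_comp = ndimage.label(remaining, structure=np.ones((3, 3), int))
    for comp in range(1, n_comp + 1):
        pix = sorted(zip(*np.nonzero(comp_labels == comp)))
        start = pix[0]  # topmost-leftmost
        nid = g.number_of_nodes() + 1
        g.add_node(nid, pixels=[start], pos=(float(start[1]), float(start[0])), kind="cycle_cut")
        path = [start]
        prev, cur = start, None
        for nr, nc in neighbors(*start):
            if comp_labels[nr, nc] == comp:
                cur = (nr, nc)
                break
        if cur is None:
            continue
        visited[start] = True
        while cur != start:
            visited[cur] = True
            path.append(cur)
            nxt = None
            for nr, nc in neighbors(*cur):
                if (nr, nc) != prev and comp_labels[nr, nc] == comp:
                    nxt = (nr, nc)
                    break
            if nxt is None:
                break
            prev, cur = cur, nxt
        path.append(start)
        g.add_edge(nid, nid, pixels=path)

    return VesselGraph(graph=g, subpixel=subpixel)


def _edge_sort_key(g: nx.MultiGraph, u, v, data):
    pix = data["pixels"]
    node_pix = min(min(g.nodes[u]["pixels"]), min(g.nodes[v]["pixels"]))
    return (node_pix, len(pix), tuple(pix))


def extract_segments(
    vessel_graph: VesselGraph,
    min_segment_points: int = 10,
    smoothing_window: int = 5,
    end_trim: int = 0,
) -> list[VesselSegment]:
    """Turn every graph edge into a smoothed sub-pixel centerline segment.

    Pixel chains adopt sub-pixel ridge coordinates where available and
    pixel centers elsewhere, are smoothed by a centered moving average
    (endpoints fixed), and edges shorter than ``min_segment_points``
    pixels are dropped.  Output order is deterministic: by the
    topmost-leftmost node pixel, then chain length.

    ``end_trim`` removes that many pixels from each chain end that
    terminates at a free endpoint (degree-1) node.  Detected ridges curl
    around the rounded cap at the end of a bright tube; trimming about
    twice the vessel profile scale removes the hook, which otherwise
    inflates the tangent-angle spread of the segment.  Ends at
    bifurcations are never trimmed.
    """
    g = vessel_graph.graph
    edges = sorted(
        ((u, v, d) for u, v, d in g.edges(data=True)),
        key=lambda e: _edge_sort_key(g, *e),
    )
    segments = []
    for edge_id, (u, v, d) in enumerate(edges):
        pix = d["pixels"]
        if end_trim > 0:
            lo = end_trim if g.nodes[u]["kind"] == "endpoint" else 0
            hi = end_trim if g.nodes[v]["kind"] == "endpoint" else 0
            # the stored chain runs from a u-pixel to a v-pixel
            if pix[0] not in g.nodes[u]["pixels"]:
                lo, hi = hi, lo
            if len(pix) - lo - hi >= min_segment_points:
                pix = pix[lo : len(pix) - hi if hi else None]
        if len(pix) < min_segment_points:
            continue
        pts = np.array(
            [vessel_graph.subpixel.get((r, c), (float(c), float(r))) for r, c in pix]
        )
        # drop accidental duplicate consecutive coordinates
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
        pts = pts[keep]
        if len(pts) < min_segment_points:
            continue
        sm = smooth_polyline(pts, window=smoothing_window)
        length = float(np.linalg.norm(np.diff(sm, axis=0), axis=1).sum())
        segments.append(VesselSegment(points=sm, edge_id=edge_id, length_px=length))
    return segments


def apply_manual_points(
    vessel_graph: VesselGraph, points: list[tuple[float, float, str]]
) -> VesselGraph:
    """Add or remove cut nodes at operator-chosen coordinates.

    Each entry is ``(x, y, action)`` with action ``add`` or ``remove``.
    Coordinates snap to the nearest skeleton pixel within 3 px; farther
    points are skipped with a warning.  ``add`` splits the containing
    edge at the snapped pixel; ``remove`` deletes a degree-2 cut node and
    merges its two edges.
    """
    g = vessel_graph.graph.copy()
    out = VesselGraph(graph=g, subpixel=vessel_graph.subpixel)
    for x, y, action in points:
        target, edge, idx = _snap_to_edge(g, float(x), float(y))
        if action == "add":
            if edge is None or idx is None:
                logger.warning("manual point (%.1f, %.1f) farther than 3 px from any edge; skipped", x, y)
                continue
            u, v, key = edge
            pix = g.edges[u, v, key]["pixels"]
            if idx <= 0 or idx >= len(pix) - 1:
                logger.warning("manual point (%.1f, %.1f) snaps to an existing node; skipped", x, y)
                continue
            nid = max(g.nodes) + 1 if g.nodes else 1
            g.add_node(nid, pixels=[pix[idx]], pos=(float(pix[idx][1]), float(pix[idx][0])), kind="manual")
            g.remove_edge(u, v, key)
            g.add_edge(u, nid, pixels=pix[: idx + 1])
            g.add_edge(nid, v, pixels=pix[idx:])
        elif action == "remove":
            if target is None:
                logger.warning("manual point (%.1f, %.1f) farther than 3 px from any node; skipped", x, y)
                continue
            if g.degree(target) != 2:
                logger.warning("node at (%.1f, %.1f) is not a degree-2 cut node; skipped", x, y)
                continue
            inc = list(g.edges(target, keys=True, data=True))
            (u1, v1, _, d1), (u2, v2, _, d2) = inc
            a = v1 if u1 == target else u1
            b = v2 if u2 == target else u2
            p1 = d1["pixels"] if d1["pixels"][-1] in g.nodes[target]["pixels"] else d1["pixels"][::-1]
            p2 = d2["pixels"] if d2["pixels"][0] in g.nodes[target]["pixels"] else d2["pixels"][::-1]
            g.remove_node(target)
            g.add_edge(a, b, pixels=p1 + p2[1:])
        else:
            raise ValueError(f"unknown manual-point action {action!r}")
    return out


def _snap_to_edge(g: nx.MultiGraph, x: float, y: float):
    """Nearest node (within 3 px) and nearest edge pixel (within 3 px)."""
    best_node, best_nd = None, 3.0
    for n, d in g.nodes(data=True):
        px, py = d["pos"]
        dist = np.hypot(px - x, py - y)
        if dist <= best_nd:
            best_node, best_nd = n, dist
    best_edge, best_idx, best_d = None, None, 3.0
    for u, v, key, d in g.edges(keys=True, data=True):
        pix = np.asarray(d["pixels"], dtype=float)
        dist = np.hypot(pix[:, 1] - x, pix[:, 0] - y)
        i = int(np.argmin(dist))
        if dist[i] <= best_d:
            best_edge, best_idx, best_d = (u, v, key), i, float(dist[i])
    return best_node, best_edge, best_idx
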