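"""Skeleton graph: components, endpoints/junctions, branches, classification.

A one-pixel-wide skeleton is decomposed into 8-connected components.  Within
a component, a pixel's degree is its count of skeleton 8-neighbors after
suppressing redundant diagonal edges (a diagonal adjacency that an axial
two-step path already covers — without this, the first pixel of every
axis-aligned branch reads as a junction and every branch loses a step to
the junction cluster).  Pixels of degree 1 are endpoints and pixels of
degree >= 3 are junction pixels.  Mutually 8-adjacent junction pixels
collapse into a single junction cluster (thinning leaves small "thick
spots" at branch meetings that would otherwise multiply branch counts).
Branches are the maximal degree-2 paths between nodes (endpoints or
junction clusters); a branch's geodesic length counts 1 per axial step and
sqrt(2) per diagonal step.

Components are classified:

* **network** — has at least one junction cluster (or is a closed loop,
  which is treated as a network with one branch: the cycle);
* **rod** — no junctions and more than ``punctate_max`` pixels;
* **punctate** — no junctions and at most ``punctate_max`` pixels.

The default ``punctate_max`` is 3 px: a skeleton object of <= 3 pixels has
no meaningful length and renders as a dot at typical 40x magnification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .skeletonize import SkeletonImage

SQRT2 = math.sqrt(2.0)
_EIGHT = np.ones((3, 3), dtype=int)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

PUNCTATE_MAX_DEFAULT = 3


class SkeletonIntegrityError(ValueError):
    """Raised when the input is not a valid 1-px-wide skeleton."""


@dataclass
class Branch:
    """A traced path between two nodes (or a closed loop)."""

    component_id: int
    start_node: int
    end_node: int
    length: float            # geodesic: 1 per axial step, sqrt(2) per diagonal
    n_pixels: int
    is_cycle: bool = False


@dataclass
class Component:
    """One 8-connected skeleton component with its nodes and branches."""

    component_id: int
    pixel_count: int
    n_endpoints: int
    n_junctions: int         # junction clusters, not junction pixels
    branches: List[Branch]
    klass: str               # "punctate" | "rod" | "network"

    @property
    def total_length(self) -> float:
        return sum(b.length for b in self.branches)

    @property
    def n_branches(self) -> int:
        return len(self.branches)


@dataclass
class SkeletonGraph:
    components: List[Component]
    punctate_max: int = PUNCTATE_MAX_DEFAULT

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def total_pixels(self) -> int:
        return sum(c.pixel_count for c in self.components)


@dataclass
class Census:
    """Per-class counts and length totals over one skeleton graph."""

    punctate_count: int
    rod_count: int
    network_count: int
    punctate_length: float
    rod_length: float
    network_length: float
    network_branch_counts: List[int]   # branches per network component

    @property
    def total_network_branch_count(self) -> int:
        return sum(self.network_branch_counts)


def _check_width(skel: np.ndarray) -> None:
    block = skel[:-1, :-1] & skel[:-1, 1:] & skel[1:, :-1] & skel[1:, 1:]
    if block.any():
        r, c = np.argwhere(block)[0]
        raise SkeletonIntegrityError(
            f"fully-set 2x2 block at ({r}, {c}): input is not 1 px wide"
        )


def _step_length(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    return SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def build_graph(
    skel: SkeletonImage,
    punctate_max: int = PUNCTATE_MAX_DEFAULT,
    check_width: bool = True,
) -> SkeletonGraph:
    """Trace a skeleton into per-component branch graphs and classify them.

    Deterministic: components, nodes and branches are enumerated in
    (row, col) scan order.
    """
    pixels = np.asarray(getattr(skel, "pixels", skel))
    if pixels.dtype != bool:
        raise TypeError("build_graph requires a boolean skeleton")
    if check_width:
        _check_width(pixels)

    labels, n_comp = ndi.label(pixels, structure=_EIGHT)
    if n_comp == 0:
        return SkeletonGraph(components=[], punctate_max=punctate_max)

    fg = set(map(tuple, np.argwhere(pixels)))

    # pixel adjacency with redundant diagonal edges suppressed: a diagonal
    # edge shortcuts nothing when an axial 2-step path exists through a
    # common neighbor, and counting it would turn the first pixel of every
    # axis-aligned branch into a spurious junction (truncating branch
    # lengths by one step per arm).  Suppression never disconnects anything
    # because the axial path remains.
    adj: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    for p in fg:
        nbrs = []
        for dr, dc in _OFFSETS:
            q = (p[0] + dr, p[1] + dc)
            if q not in fg:
                continue
            if dr != 0 and dc != 0 and (
                (p[0], q[1]) in fg or (q[0], p[1]) in fg
            ):
                continue
            nbrs.append(q)
        adj[p] = nbrs

    deg = {p: len(nbrs) for p, nbrs in adj.items()}
    junction_px = np.zeros_like(pixels)
    for p, d in deg.items():
        if d >= 3:
            junction_px[p] = True
    jlabels, _ = ndi.label(junction_px, structure=_EIGHT)

    # node ids: junction clusters get ids 1..J; endpoint/isolated pixels get
    # unique negative ids keyed by position (stable under scan order).
    def node_id(p: Tuple[int, int]) -> Optional[int]:
        j = jlabels[p]
        if j > 0:
            return int(j)
        if deg[p] != 2:
            return -(p[0] * pixels.shape[1] + p[1]) - 1
        return None  # chain pixel

    comp_sizes = ndi.sum_labels(pixels, labels, index=np.arange(1, n_comp + 1))
    comp_endpoints = np.zeros(n_comp + 1, dtype=int)
    comp_junctions: List[set] = [set() for _ in range(n_comp + 1)]
    for p in sorted(fg):
        lbl = labels[p]
        if deg[p] == 1:
            comp_endpoints[lbl] += 1
        elif deg[p] >= 3:
            comp_junctions[lbl].add(int(jlabels[p]))

    branches: Dict[int, List[Branch]] = {i: [] for i in range(1, n_comp + 1)}
    visited_edges = set()

    def neighbors(p):
        return adj[p]

    def edge_key(a, b):
        return (a, b) if a <= b else (b, a)

    # trace from every node pixel in scan order
    node_pixels = sorted(p for p in fg if deg[p] != 2)
    for p in node_pixels:
        for q in neighbors(p):
            if edge_key(p, q) in visited_edges:
                continue
            visited_edges.add(edge_key(p, q))
            length = _step_length(p, q)
            path_pixels = 0
            prev, cur = p, q
            while node_id(cur) is None:
                path_pixels += 1
                nxt = [n for n in neighbors(cur) if n != prev]
                # a degree-2 pixel has exactly one onward neighbor
                nx = nxt[0]
                visited_edges.add(edge_key(cur, nx))
                length += _step_length(cur, nx)
                prev, cur = cur, nx
            a, b = node_id(p), node_id(cur)
            if path_pixels == 0 and a == b and a is not None and a > 0:
                continue  # direct edge inside one junction cluster
            branches[int(labels[p])].append(
                Branch(
                    component_id=int(labels[p]),
                    start_node=a,
                    end_node=b,
                    length=length,
                    n_pixels=path_pixels,
                )
            )

    # isolated single pixels: a branch of length 0
    for p in node_pixels:
        if deg[p] == 0:
            nid = node_id(p)
            branches[int(labels[p])].append(
                Branch(
                    component_id=int(labels[p]),
                    start_node=nid,
                    end_node=nid,
                    length=0.0,
                    n_pixels=1,
                )
            )

    # pure cycles: components whose pixels are all degree 2
    has_node = np.zeros(n_comp + 1, dtype=bool)
    for p in node_pixels:
        has_node[labels[p]] = True
    for lbl in range(1, n_comp + 1):
        if has_node[lbl]:
            continue
        start = tuple(np.argwhere(labels == lbl)[0])
        length = 0.0
        prev, cur = None, start
        n_px = 0
        while True:
            n_px += 1
            nxt = [n for n in neighbors(cur) if n != prev]
            nx = nxt[0]
            length += _step_length(cur, nx)
            prev, cur = cur, nx
            if cur == start:
                break
        branches[lbl].append(
            Branch(
                component_id=lbl,
                start_node=0,
                end_node=0,
                length=length,
                n_pixels=n_px,
                is_cycle=True,
            )
        )

    components: List[Component] = []
    for lbl in range(1, n_comp + 1):
        n_junc = len(comp_junctions[lbl])
        size = int(comp_sizes[lbl - 1])
        is_cycle = any(b.is_cycle for b in branches[lbl])
        if n_junc >= 1 or is_cycle:
            klass = "network"
        elif size > punctate_max:
            klass = "rod"
        else:
            klass = "punctate"
        components.append(
            Component(
                component_id=lbl,
                pixel_count=size,
                n_endpoints=int(comp_endpoints[lbl]),
                n_junctions=n_junc,
                branches=branches[lbl],
                klass=klass,
            )
        )
    return SkeletonGraph(components=components, punctate_max=punctate_max)


def component_census(graph: SkeletonGraph) -> Census:
    """Counts and summed lengths by class; branch counts per network."""
    counts = {"punctate": 0, "rod": 0, "network": 0}
    lengths = {"punctate": 0.0, "rod": 0.0, "network": 0.0}
    net_branches: List[int] = []
    for comp in graph.components:
        counts[comp.klass] += 1
        lengths[comp.klass] += comp.total_length
        if comp.klass == "network":
            net_branches.append(comp.n_branches)
    return Census(
        punctate_count=counts["punctate"],
        rod_count=counts["rod"],
        network_count=counts["network"],
        punctate_length=lengths["punctate"],
        rod_length=lengths["rod"],
        network_length=lengths["network"],
        network_branch_counts=net_branches,
    )


def dump_branches_csv(graph: SkeletonGraph, path) -> None:
    """Debug dump: component_id, branch_id, length, n_pixels per branch."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["component_id", "branch_id", "length", "n_pixels"])
        for comp in graph.components:
            for i, b in enumerate(comp.branches):
                w.writerow([comp.component_id, i, f"{b.length:.6f}", b.n_pixels])
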