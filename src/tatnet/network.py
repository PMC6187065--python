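"""Skeleton-based TAT network analysis.

Binarized tubule masks are thinned to one-pixel skeletons, condensed into a
branch/junction graph, and summarised by the network metrics used to compare
tubule systems across cells and species: network density (skeleton length per
ROI area), junction density, and mean branch length.  Local skeleton
orientations, estimated with the structure tensor, are accumulated into a
length-weighted orientation histogram relative to the cell's major axis and
classified into the three canonical components of the transverse-axial tubule
system: axial (~0°), oblique (~45°) and transverse (~90°) tubules.

Graph semantics
---------------
Skeleton pixels are 8-connected.  A pixel with >= 3 skeleton neighbours is a
junction pixel; 8-connected junction pixels merge into one junction node.  A
pixel with <= 1 neighbour is an endpoint node.  Branches are the maximal
chains of 2-neighbour ("slab") pixels between node pixels; a branch's length
is the sum of its pixel steps (1 or sqrt(2) pixels) times the pixel size.
Pure cycles without any node pixel become a single self-edge anchored at an
arbitrary cycle pixel.  The sum of all branch lengths is the total skeleton
length, each pixel step counted exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter as ndi_gaussian
from skimage import feature
from skimage.morphology import skeletonize as _sk_skeletonize

from tatnet.simulate import fold_angle

_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


@dataclass
class Skeleton:
    """One-pixel-thin skeleton: pixel set plus physical pixel size (nm)."""

    pixels: set[tuple[int, int]]
    pixel_size: float  # nm
    shape: tuple[int, int]

    def to_image(self) -> np.ndarray:
        img = np.zeros(self.shape, dtype=bool)
        if self.pixels:
            rr, cc = zip(*self.pixels)
            img[list(rr), list(cc)] = True
        return img

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size / 1000.0


@dataclass
class Branch:
    """A skeleton branch: node ids, polyline pixels and length in μm."""

    node_a: int
    node_b: int
    pixels: list[tuple[int, int]]  # polyline incl. terminal node pixels
    length_um: float


@dataclass
class SkeletonGraph:
    """Junction/endpoint nodes and branch edges of a skeleton."""

    junctions: list[list[tuple[int, int]]]  # pixel clusters, one per junction node
    endpoints: list[tuple[int, int]]
    isolated: list[tuple[int, int]]
    branches: list[Branch]
    pixel_size: float  # nm
    pixel_weights: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def total_length_um(self) -> float:
        return sum(b.length_um for b in self.branches)

    @property
    def mean_branch_length_um(self) -> float:
        return self.total_length_um / self.n_branches if self.branches else 0.0


@dataclass
class NetworkMetrics:
    density: float  # μm / μm²
    junction_density: float  # n / μm²
    mean_branch_length: float  # μm
    n_branches: int
    roi_area: float  # μm²
    total_length: float  # μm
    n_junctions: int


@dataclass
class OrientationHistogram:
    """Length-weighted skeleton orientation histogram relative to the cell axis."""

    bin_edges: np.ndarray  # degrees, covering (-90, 90]
    weights: np.ndarray  # μm skeleton length per bin
    reference_angle: float  # degrees

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_length_um(self) -> float:
        return float(self.weights.sum())


@dataclass
class ComponentSummary:
    """Relative and absolute abundance of the AT / OT / TT components."""

    relative_fraction: dict[str, float]
    absolute_density: dict[str, float]  # μm / μm²
    unclassified_fraction: float
    total_density: float  # μm / μm²


# ---------------------------------------------------------------------------
# skeletonization and graph construction
# ---------------------------------------------------------------------------


def skeletonize(mask: np.ndarray, pixel_size: float) -> Skeleton:
    """Topology-preserving medial-axis thinning of a binary mask to 1 px.

    An empty mask yields an empty skeleton (not an error).
    """
    mask = np.asarray(mask, dtype=bool)
    thin = _sk_skeletonize(mask)
    pixels = set(zip(*map(list, np.nonzero(thin)))) if thin.any() else set()
    return Skeleton(pixels={(int(r), int(c)) for r, c in pixels},
                    pixel_size=pixel_size, shape=mask.shape)


def _neighbors(p: tuple[int, int], pixels: set) -> list[tuple[int, int]]:
    r, c = p
    return [(r + dr, c + dc) for dr, dc in _NEIGHBOR_OFFSETS if (r + dr, c + dc) in pixels]


def _step_um(p: tuple[int, int], q: tuple[int, int], ps_um: float) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1]) * ps_um


def _cluster_junction_pixels(jpix: set) -> list[list[tuple[int, int]]]:
    clusters = []
    seen: set = set()
    for p in sorted(jpix):
        if p in seen:
            continue
        stack, comp = [p], []
        seen.add(p)
        while stack:
            q = stack.pop()
            comp.append(q)
            for nb in _neighbors(q, jpix):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        clusters.append(sorted(comp))
    return clusters


def build_graph(skel: Skeleton, prune_spurs_px: float = 2.0) -> SkeletonGraph:
    """Condense a skeleton into its branch/junction graph.

    Terminal branches shorter than ``prune_spurs_px`` pixels (thinning spurs)
    are removed from the skeleton and the graph is rebuilt once; pass 0 to
    keep the raw topology.
    """
    graph = _build_graph_raw(skel)
    if prune_spurs_px > 0:
        thr_um = prune_spurs_px * skel.pixel_size_um
        spur_pixels: set = set()
        node_pix = {p for cl in graph.junctions for p in cl}
        for b in graph.branches:
            terminal = (b.node_a < 0 or b.node_b < 0)  # endpoint-anchored
            if terminal and b.length_um < thr_um:
                spur_pixels.update(p for p in b.pixels if p not in node_pix)
        # lone isolated pixels are spurs by definition
        spur_pixels.update(graph.isolated)
        if spur_pixels:
            # re-thin after removal: a pruned spur can leave its attachment
            # pixel as a redundant bump on an otherwise straight branch
            pruned = Skeleton(pixels=skel.pixels - spur_pixels,
                              pixel_size=skel.pixel_size, shape=skel.shape)
            pruned = skeletonize(pruned.to_image(), skel.pixel_size)
            graph = _build_graph_raw(pruned)
    return graph


def _build_graph_raw(skel: Skeleton) -> SkeletonGraph:
    pixels = skel.pixels
    ps_um = skel.pixel_size_um
    ncount = {p: len(_neighbors(p, pixels)) for p in pixels}
    jpix = {p for p, n in ncount.items() if n >= 3}
    endpoints = sorted(p for p, n in ncount.items() if n == 1)
    isolated = sorted(p for p, n in ncount.items() if n == 0)
    clusters = _cluster_junction_pixels(jpix)

    # node ids: junction clusters 0..J-1; endpoints get negative ids -1, -2, ...
    node_of: dict[tuple[int, int], int] = {}
    for i, cl in enumerate(clusters):
        for p in cl:
            node_of[p] = i
    for i, p in enumerate(endpoints):
        node_of[p] = -(i + 1)
    node_pixels = set(node_of)

    weights: dict[tuple[int, int], float] = {p: 0.0 for p in pixels}
    branches: list[Branch] = []
    visited_slab: set = set()
    direct_pairs: set = set()

    def add_branch(path: list[tuple[int, int]], a: int, b: int) -> None:
        length = 0.0
        for p, q in zip(path[:-1], path[1:]):
            d = _step_um(p, q, ps_um)
            length += d
            weights[p] += 0.5 * d
            weights[q] += 0.5 * d
        branches.append(Branch(node_a=a, node_b=b, pixels=path, length_um=length))

    # branches through slab pixels, started from node pixels
    for start in sorted(node_pixels):
        for q in _neighbors(start, pixels):
            if q in node_pixels:
                if node_of[q] != node_of[start]:
                    pair = tuple(sorted((start, q)))
                    if pair not in direct_pairs:
                        direct_pairs.add(pair)
                        add_branch([start, q], node_of[start], node_of[q])
                continue
            if q in visited_slab:
                continue
            path = [start, q]
            visited_slab.add(q)
            prev, cur = start, q
            while cur not in node_pixels:
                nbrs = [n for n in _neighbors(cur, pixels) if n != prev]
                if not nbrs:  # dangling slab (cannot happen for 2-neighbour pixels)
                    break
                nxt = nbrs[0]
                path.append(nxt)
                if nxt in node_pixels:
                    cur = nxt
                    break
                visited_slab.add(nxt)
                prev, cur = cur, nxt
            end_node = node_of.get(path[-1])
            if end_node is None:  # open chain ended off-node; treat last as endpoint
                end_node = node_of.setdefault(path[-1], -(len(endpoints) + len(node_of) + 1))
            add_branch(path, node_of[start], end_node)

    # pure cycles: leftover slab pixels with no node anywhere
    remaining = {p for p, n in ncount.items() if n == 2} - visited_slab
    while remaining:
        start = sorted(remaining)[0]
        path = [start]
        visited_slab.add(start)
        remaining.discard(start)
        prev, cur = None, start
        while True:
            nbrs = [n for n in _neighbors(cur, pixels) if n != prev]
            nxt = nbrs[0]
            if nxt == start:
                path.append(start)
                break
            path.append(nxt)
            visited_slab.discard(nxt)
            remaining.discard(nxt)
            prev, cur = cur, nxt
        cycle_id = -(10**6) - len(branches)  # anonymous anchor node for the loop
        add_branch(path, cycle_id, cycle_id)

    return SkeletonGraph(
        junctions=clusters,
        endpoints=endpoints,
        isolated=isolated,
        branches=branches,
        pixel_size=skel.pixel_size,
        pixel_weights=weights,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def network_metrics(
    graph: SkeletonGraph,
    roi_area: float,
    junction_merge_radius_um: float = 0.0,
    extra_length_um: float = 0.0,
    total_length_um: float | None = None,
) -> NetworkMetrics:
    """Network density, junction density and branch statistics for one ROI.

    ``junction_merge_radius_um`` > 0 counts junction nodes whose centroids lie
    within that distance as a single physical junction: thinning resolves an
    X-shaped tubule crossing into two nearby Y-junctions, which below the
    optical resolution limit are one structure.  ``extra_length_um`` adds a
    length correction (e.g. endpoint tip extension, see
    :func:`measure_tip_extension`) to the density numerator, and
    ``total_length_um`` replaces the raw pixel-step length altogether (e.g.
    with :func:`smoothed_total_length`).  None of these affect the graph
    topology itself.
    """
    if roi_area <= 0:
        raise ValueError("roi_area must be positive")
    base = graph.total_length_um if total_length_um is None else total_length_um
    total = base + extra_length_um
    n_junc = graph.n_junctions
    if junction_merge_radius_um > 0 and n_junc > 1:
        ps_um = graph.pixel_size / 1000.0
        cents = [
            (ps_um * sum(p[0] for p in cl) / len(cl),
             ps_um * sum(p[1] for p in cl) / len(cl))
            for cl in graph.junctions
        ]
        n_junc = _count_merged(cents, junction_merge_radius_um)
    return NetworkMetrics(
        density=total / roi_area,
        junction_density=n_junc / roi_area,
        mean_branch_length=(total / graph.n_branches) if graph.branches else 0.0,
        n_branches=graph.n_branches,
        roi_area=roi_area,
        total_length=total,
        n_junctions=n_junc,
    )


def _count_merged(points: list[tuple[float, float]], radius: float) -> int:
    """Number of single-linkage clusters at the given merge radius."""
    n = len(points)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if math.hypot(points[i][0] - points[j][0],
                          points[i][1] - points[j][1]) <= radius:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    return len({find(i) for i in range(n)})


def smoothed_total_length(graph: SkeletonGraph, window_um: float = 0.25) -> float:
    """Total branch length (μm) measured on smoothed branch polylines.

    Pixel-step chain lengths systematically over-measure smooth curves: the
    1/sqrt(2) staircase adds up to ~8% for oblique lines, and thinning of wide
    ribbons adds jagged wiggle on the scale of the ribbon width on top.
    Averaging each branch polyline with a moving window of ``window_um``
    (about one tubule width; endpoints kept fixed) before summing Euclidean
    steps removes most of this bias.  Branch topology and the raw per-step
    lengths in :class:`SkeletonGraph` are unaffected.
    """
    ps_um = graph.pixel_size / 1000.0
    half = max(int(round(window_um / ps_um / 2.0)), 1)
    total = 0.0
    for b in graph.branches:
        pts = np.asarray(b.pixels, dtype=float)
        n = len(pts)
        if n < 3:
            total += b.length_um
            continue
        sm = np.empty_like(pts)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            sm[i] = pts[lo:hi].mean(axis=0)
        sm[0], sm[-1] = pts[0], pts[-1]
        steps = np.sqrt(((sm[1:] - sm[:-1]) ** 2).sum(axis=1))
        total += float(steps.sum()) * ps_um
    return total


def measure_tip_extension(
    mask: np.ndarray, graph: SkeletonGraph, max_px: float = 20.0
) -> float:
    """Total endpoint tip-extension length (μm) of a skeleton within its mask.

    Thinning erodes every ribbon end by roughly half the ribbon width, so the
    skeleton systematically under-measures tubule length.  For each terminal
    branch the last branch direction is extrapolated from the endpoint, and
    the distance travelled while still inside the binary mask (up to
    ``max_px`` pixels) is returned, summed over all endpoints.
    """
    mask = np.asarray(mask, dtype=bool)
    ps_um = graph.pixel_size / 1000.0
    endpoints = set(graph.endpoints)
    total = 0.0
    for b in graph.branches:
        for pix, inward in ((b.pixels[0], b.pixels[: min(6, len(b.pixels))]),
                            (b.pixels[-1], b.pixels[-min(6, len(b.pixels)):][::-1])):
            if pix not in endpoints or len(inward) < 2:
                continue
            dr = pix[0] - inward[-1][0]
            dc = pix[1] - inward[-1][1]
            norm = math.hypot(dr, dc)
            if norm == 0:
                continue
            dr, dc = dr / norm, dc / norm
            dist = 0.0
            step = 0.5
            while dist + step <= max_px:
                r = int(round(pix[0] + (dist + step) * dr))
                c = int(round(pix[1] + (dist + step) * dc))
                if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
                    break
                dist += step
            total += dist * ps_um
    return total


# ---------------------------------------------------------------------------
# orientation analysis
# ---------------------------------------------------------------------------


def _pixel_orientations(
    skel: Skeleton, window_sigma: float, presmooth_sigma: float = 1.5
) -> dict[tuple[int, int], float]:
    """Local line orientation (degrees, (-90, 90]) per skeleton pixel.

    Structure tensor of the skeleton image with a Gaussian window; the line
    direction is perpendicular to the dominant gradient direction.  The binary
    skeleton is pre-smoothed (``presmooth_sigma`` px) before differentiation:
    gradients of the raw one-pixel staircase are biased by rasterisation
    harmonics by up to ~5°, which the pre-smoothing suppresses below 1°.
    Angles follow the package frame (x = columns, y = rows).
    """
    img = skel.to_image().astype(float)
    if presmooth_sigma > 0:
        img = ndi_gaussian(img, presmooth_sigma)
    Arr, Arc, Acc = feature.structure_tensor(img, sigma=window_sigma, order="rc",
                                             mode="constant")
    # dominant gradient direction from x (=col) axis; +90° → line direction
    grad = 0.5 * np.arctan2(2.0 * Arc, Acc - Arr)
    line = np.degrees(grad) + 90.0
    out = {}
    for p in skel.pixels:
        out[p] = fold_angle(float(line[p]))
    return out


def orientation_histogram(
    skel: Skeleton,
    reference_angle: float,
    bin_width: float = 5.0,
    window_sigma: float = 5.0,
    prune_spurs_px: float = 2.0,
) -> OrientationHistogram:
    """Length-weighted local-orientation histogram relative to the cell axis.

    Each skeleton pixel contributes its share of branch length (half of each
    incident pixel step) to the bin of its structure-tensor orientation, so
    the histogram mass equals the total skeleton length exactly.
    """
    if not skel.pixels:
        raise ValueError("cannot compute orientations of an empty skeleton")
    graph = build_graph(skel, prune_spurs_px=prune_spurs_px)
    orients = _pixel_orientations(skel, window_sigma)
    n_bins = int(round(180.0 / bin_width))
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    weights = np.zeros(n_bins)
    for p, w in graph.pixel_weights.items():
        if w == 0.0:
            continue
        rel = fold_angle(orients[p] - reference_angle)
        # bins are (lo, hi]: fold -90 to +90 handled by fold_angle
        idx = min(int(np.searchsorted(edges, rel, side="left")) - 1, n_bins - 1)
        idx = max(idx, 0)
        weights[idx] += w
    return OrientationHistogram(bin_edges=edges, weights=weights,
                                reference_angle=reference_angle)


CANONICAL = {"AT": 0.0, "OT": 45.0, "TT": 90.0}


def classify_components(
    hist: OrientationHistogram,
    roi_area: float,
    window: float = 22.5,
) -> ComponentSummary:
    """Assign orientation-histogram mass to the canonical TAT components.

    Orientations are folded to [0°, 90°] and each bin's mass is assigned to
    the nearest canonical component orientation (AT 0°, OT 45°, TT 90°) if it
    lies within ``window`` degrees; the default ±22.5° window classifies every
    pixel, while ±5° reproduces a strict peak-window reading.  Mass outside
    all windows is reported as the unclassified fraction.
    """
    if roi_area <= 0:
        raise ValueError("roi_area must be positive")
    length = {k: 0.0 for k in CANONICAL}
    unclassified = 0.0
    for center, w in zip(hist.bin_centers, hist.weights):
        folded = abs(fold_angle(center))
        comp, dist = None, None
        for k, ang in CANONICAL.items():
            d = abs(folded - ang)
            if dist is None or d < dist:
                comp, dist = k, d
        if dist is not None and dist <= window:
            length[comp] += float(w)
        else:
            unclassified += float(w)
    total = sum(length.values()) + unclassified
    classified = sum(length.values())
    rel = {k: (v / classified if classified > 0 else 0.0) for k, v in length.items()}
    absd = {k: v / roi_area for k, v in length.items()}
    return ComponentSummary(
        relative_fraction=rel,
        absolute_density=absd,
        unclassified_fraction=(unclassified / total if total > 0 else 0.0),
        total_density=total / roi_area,
    )
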