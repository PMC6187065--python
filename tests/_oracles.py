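"""Independent oracles used by the test suite.

These deliberately avoid the package's own graph/rendering code paths:
the skeleton-graph oracle classifies pixel-graph edges with networkx, and the
ribbon-rendering oracle integrates the ribbon indicator on a dense sub-pixel
grid before Gaussian blurring.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from scipy import ndimage

OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeleton_graph_oracle(pixels: set, pixel_size_nm: float) -> dict:
    """Junction/branch/length statistics by exhaustive neighbourhood enumeration.

    Pixel semantics: 8-connectivity; junction pixels have >= 3 neighbours and
    merge into junction nodes by connectivity; endpoint pixels (<= 1
    neighbour) are nodes.  Branch steps are (a) all adjacencies involving a
    slab (exactly-2-neighbour) pixel and (b) adjacencies between pixels of
    different nodes; intra-junction-cluster adjacencies are not branch steps.
    """
    ps_um = pixel_size_nm / 1000.0
    G = nx.Graph()
    G.add_nodes_from(pixels)
    for r, c in pixels:
        for dr, dc in OFFSETS:
            q = (r + dr, c + dc)
            if q in pixels:
                G.add_edge((r, c), q)
    deg = dict(G.degree())
    junction_pix = {p for p, d in deg.items() if d >= 3}
    endpoint_pix = {p for p, d in deg.items() if d == 1}
    slab_pix = {p for p, d in deg.items() if d == 2}

    # junction nodes: connected components of junction pixels
    jsub = G.subgraph(junction_pix)
    clusters = list(nx.connected_components(jsub))
    cluster_of = {}
    for i, cl in enumerate(clusters):
        for p in cl:
            cluster_of[p] = i
    node_of = dict(cluster_of)
    for i, p in enumerate(sorted(endpoint_pix)):
        node_of[p] = -(i + 1)

    # branch count: slab components + direct node-node adjacencies
    n_branches = nx.number_connected_components(G.subgraph(slab_pix)) if slab_pix else 0
    total = 0.0
    direct = 0
    for p, q in G.edges():
        in_nodes = p in node_of and q in node_of
        if in_nodes and node_of[p] == node_of[q]:
            continue  # intra-cluster step: not a branch step
        if in_nodes:
            direct += 1
        total += math.hypot(p[0] - q[0], p[1] - q[1]) * ps_um
    return {
        "n_junctions": len(clusters),
        "n_branches": n_branches + direct,
        "total_length_um": total,
    }


def ribbon_profile_oracle(
    width_nm: float,
    psf_fwhm_nm: float,
    pixel_size_nm: float,
    n_pixels: int,
    center_nm: float,
    background: float,
    peak: float,
    oversample: int = 8,
) -> np.ndarray:
    """Cross-profile of an infinite ribbon rendered through a Gaussian PSF.

    Dense sub-pixel integration of the ribbon indicator followed by 1D
    Gaussian convolution and pixel binning; pixel r is centred at
    ``r * pixel_size_nm``.
    """
    fine = pixel_size_nm / oversample
    x = (np.arange(n_pixels * oversample) - (oversample - 1) / 2.0) * fine
    ind = (np.abs(x - center_nm) <= width_nm / 2.0).astype(float)
    if psf_fwhm_nm > 0:
        sigma = psf_fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / fine
        ind = ndimage.gaussian_filter1d(ind, sigma)
    return background + peak * ind.reshape(-1, oversample).mean(axis=1)


def envelope_halfmax_width_nm(
    width_nm: float, psf_fwhm_nm: float, span_nm: float = 3000.0
) -> float:
    """Half-maximum envelope width of a ribbon's PSF-blurred cross profile."""
    prof = ribbon_profile_oracle(
        width_nm, psf_fwhm_nm, pixel_size_nm=0.5, n_pixels=int(span_nm / 0.5),
        center_nm=span_nm / 2.0, background=0.0, peak=1.0, oversample=4,
    )
    half = prof.max() / 2.0
    above = np.nonzero(prof >= half)[0]
    return float((above[-1] - above[0]) * 0.5)
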