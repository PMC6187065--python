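"""Ground-truthed synthetic data: TAT micrographs, Ca2+ transients, AP traces.

The generator emulates the statistical structure of tubule-network micrographs
of atrial myocytes — sparse anisotropic curvilinear networks dominated by
segments parallel to the cell axis (axial tubules, AT), with oblique (~45°, OT)
and transverse (~90°, TT) minorities — rendered through a Gaussian PSF with
Poisson shot noise and Gaussian read noise, together with mono-exponentially
decaying Ca2+ transients (systolic and caffeine-evoked) and stimulus-locked
action-potential-shaped dF/F upstrokes.

Coordinate convention used throughout the package: physical coordinates
``(x, y)`` in micrometres map onto pixel indices as ``col = x / pixel_size``
and ``row = y / pixel_size``.  An orientation is the angle
``atan2(dy, dx)`` of a direction ``(dx, dy)`` in this frame, folded into
``(-90, 90]`` degrees.  All randomness flows through one explicit seed per
artifact; no global RNG state is touched.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import nearest_points
from shapely.strtree import STRtree

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class NetworkSpec:
    """Geometry of a synthetic TAT network inside a single cell.

    Defaults are the study conditions emulated throughout: a cell-wide network
    of density ~0.37 μm/μm² dominated by axial tubules with relative component
    length fractions (AT, OT, TT) = (0.62, 0.23, 0.15), AT tubules wider than
    TT tubules (250 vs 200 nm), and a junction density in the few-0.01/μm²
    range.
    """

    cell_length: float = 80.0  # μm, along the major axis
    cell_width: float = 15.0  # μm
    axis_angle: float = 0.0  # degrees, cell major axis vs image rows (x axis)
    frac_at: float = 0.62
    frac_ot: float = 0.23
    frac_tt: float = 0.15
    target_density: float = 0.368  # μm tubule length per μm² cell area
    segment_length_mean: float = 6.0  # μm
    segment_length_sd: float = 2.5  # μm
    angle_jitter_sd: float = 6.0  # degrees
    tubule_width_at: float = 250.0  # nm, true physical ribbon width
    tubule_width_tt: float = 200.0  # nm
    junction_rate: float = 0.01  # expected seeded T-junctions per μm²

    def validate(self) -> None:
        fr = (self.frac_at, self.frac_ot, self.frac_tt)
        if any(f < 0 for f in fr):
            raise ValueError("component fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {sum(fr)}")
        if self.target_density <= 0:
            raise ValueError("target_density must be positive")
        if self.tubule_width_at <= 0 or self.tubule_width_tt <= 0:
            raise ValueError("tubule widths must be positive")
        if self.cell_length <= 0 or self.cell_width <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.segment_length_mean <= 0:
            raise ValueError("segment_length_mean must be positive")
        # A ribbon network cannot occupy more than ~half the cell area without
        # ceasing to be a sparse network; reject physically infeasible requests.
        mean_width_um = 0.5 * (self.tubule_width_at + self.tubule_width_tt) / 1000.0
        if self.target_density * mean_width_um > 0.5:
            raise ValueError(
                f"target_density {self.target_density} μm/μm² is infeasible for "
                f"tubules of ~{mean_width_um * 1000:.0f} nm width (area fill > 50%)"
            )


@dataclass
class ImagingSpec:
    """Forward imaging model: pixel grid, Gaussian PSF, counts and noise.

    ``pixel_size`` defaults to the STED regime (16.23 nm); the confocal regime
    uses 114 nm.  ``tubule_peak_signal`` is the signal (above background) of an
    infinitely wide tubule; finite tubules peak lower after PSF blurring.
    """

    pixel_size: float = 16.23  # nm
    psf_fwhm: float = 60.0  # nm
    background_level: float = 20.0  # counts
    tubule_peak_signal: float = 180.0  # counts above background
    read_noise_sd: float = 3.0  # counts
    shot_noise: bool = True
    bit_depth: int = 16
    seed: int = 0

    STED_PIXEL_NM = 16.23
    CONFOCAL_PIXEL_NM = 114.0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class TransientSpec:
    """Mono-exponential systolic and caffeine-evoked Ca2+ transients.

    The generator enforces ``k_syst >= k_caff >= 0``: the caffeine-evoked
    transient decays without the SERCA re-uptake component, so its rate cannot
    exceed the systolic one.  Default rates sit in the atrial-myocyte regime
    (caffeine decay ~0.68 s⁻¹).
    """

    k_syst: float = 2.0  # s^-1
    k_caff: float = 0.68  # s^-1
    amplitude: float = 1.5  # dF/F0 units
    baseline: float = 1.0  # F0 units
    sample_rate: float = 100.0  # Hz
    duration: float = 8.0  # s
    noise_sd: float = 0.0  # dF/F0 units
    seed: int = 0

    def validate(self) -> None:
        if not (self.k_syst >= self.k_caff >= 0):
            raise ValueError(
                f"require k_syst >= k_caff >= 0, got k_syst={self.k_syst}, "
                f"k_caff={self.k_caff}"
            )
        if self.sample_rate <= 2.0 * self.k_syst:
            raise ValueError("sample_rate must exceed 2 * k_syst")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class APTraceSpec:
    """Stimulus-locked optical action-potential upstroke (dF/F)."""

    stim_end_time: float = 5.0  # ms
    true_onset_delay: float = 2.0  # ms
    upstroke_tau: float = 1.0  # ms
    amplitude: float = 0.15  # dF/F
    sample_interval: float = 0.1  # ms
    noise_sd: float = 0.0  # dF/F
    duration: float = 30.0  # ms
    seed: int = 0

    def validate(self) -> None:
        if self.true_onset_delay < 0:
            raise ValueError("true_onset_delay must be non-negative")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.upstroke_tau <= 0:
            raise ValueError("upstroke_tau must be positive")
        if self.stim_end_time < 0 or self.stim_end_time >= self.duration:
            raise ValueError("stim_end_time must lie inside the trace")


# ---------------------------------------------------------------------------
# segment container
# ---------------------------------------------------------------------------

CANONICAL_ANGLES = {"AT": 0.0, "OT": 45.0, "TT": 90.0}


@dataclass
class Segment:
    x0: float
    y0: float
    x1: float
    y1: float
    component: str  # AT / OT / TT
    width_nm: float

    @property
    def length(self) -> float:
        return math.hypot(self.x1 - self.x0, self.y1 - self.y0)

    @property
    def angle(self) -> float:
        """Orientation in degrees, folded into (-90, 90]."""
        a = math.degrees(math.atan2(self.y1 - self.y0, self.x1 - self.x0))
        return fold_angle(a)


@dataclass
class SegmentSet:
    """Ground-truth tubule geometry: segments, cell outline and truth totals."""

    segments: list[Segment]
    cell_mask_polygon: list[tuple[float, float]]  # μm
    truth: dict = field(default_factory=dict)

    def total_length(self, component: str | None = None) -> float:
        return sum(
            s.length
            for s in self.segments
            if component is None or s.component == component
        )

    @property
    def cell_polygon(self) -> Polygon:
        return Polygon(self.cell_mask_polygon)

    def recompute_truth(self) -> dict:
        """Independent recomputation of the truth block from the geometry."""
        area = self.cell_polygon.area
        out = {
            "total_length_um": self.total_length(),
            "length_at_um": self.total_length("AT"),
            "length_ot_um": self.total_length("OT"),
            "length_tt_um": self.total_length("TT"),
            "junction_count": count_junctions(self.segments),
            "density_um_per_um2": self.total_length() / area,
            "cell_area_um2": area,
        }
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "segments": [asdict(s) for s in self.segments],
                "cell_mask_polygon": list(map(list, self.cell_mask_polygon)),
                "truth": self.truth,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SegmentSet":
        d = json.loads(text)
        return cls(
            segments=[Segment(**s) for s in d["segments"]],
            cell_mask_polygon=[tuple(p) for p in d["cell_mask_polygon"]],
            truth=d["truth"],
        )


def fold_angle(a: float) -> float:
    """Fold an angle in degrees into the orientation range (-90, 90]."""
    a = (a + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


def count_junctions(segments: list[Segment], merge_tol_um: float = 0.5) -> int:
    """Count physical junctions: places where two tubule ribbons touch.

    Two segments form a junction wherever their centrelines come closer than
    the sum of their ribbon half-widths — crossings, seeded T-contacts, and
    near-misses that fuse once rendered at physical width all count alike.
    Contact points closer than ``merge_tol_um`` are merged into one junction.
    """
    lines = [LineString([(s.x0, s.y0), (s.x1, s.y1)]) for s in segments]
    pts: list[tuple[float, float]] = []
    tree = STRtree(lines)
    for i, li in enumerate(lines):
        contact_buf = li.buffer(1.0)  # generous query pad; exact test below
        for j in tree.query(contact_buf):
            j = int(j)
            if j <= i:
                continue
            contact_um = 0.5 * (segments[i].width_nm + segments[j].width_nm) / 1000.0
            if li.distance(lines[j]) >= contact_um:
                continue
            a, b = nearest_points(li, lines[j])
            pts.append((0.5 * (a.x + b.x), 0.5 * (a.y + b.y)))
    merged: list[tuple[float, float]] = []
    for p in pts:
        if not any(math.hypot(p[0] - q[0], p[1] - q[1]) < merge_tol_um for q in merged):
            merged.append(p)
    return len(merged)


# ---------------------------------------------------------------------------
# geometry generation
# ---------------------------------------------------------------------------

_MAX_SEGMENTS = 50_000


def _cell_polygon(spec: NetworkSpec, margin: float = 2.0) -> tuple[Polygon, float, float]:
    """Rectangle of cell_length x cell_width, rotated by axis_angle.

    Returned together with the field-of-view extents (μm) that contain it with
    ``margin`` padding on every side.
    """
    L, W = spec.cell_length, spec.cell_width
    th = math.radians(spec.axis_angle)
    c, s = math.cos(th), math.sin(th)
    corners = []
    for dx, dy in ((-L / 2, -W / 2), (L / 2, -W / 2), (L / 2, W / 2), (-L / 2, W / 2)):
        corners.append((dx * c - dy * s, dx * s + dy * c))
    xs = [p[0] for p in corners]
    ys = [p[1] for p in corners]
    shift_x = margin - min(xs)
    shift_y = margin - min(ys)
    poly = Polygon([(x + shift_x, y + shift_y) for x, y in corners])
    fov_x = max(xs) - min(xs) + 2 * margin
    fov_y = max(ys) - min(ys) + 2 * margin
    return poly, fov_x, fov_y


def _component_width(spec: NetworkSpec, component: str) -> float:
    if component == "AT":
        return spec.tubule_width_at
    if component == "TT":
        return spec.tubule_width_tt
    return 0.5 * (spec.tubule_width_at + spec.tubule_width_tt)


def _clip_to_polygon(
    x0: float, y0: float, x1: float, y1: float, poly: Polygon
) -> tuple[float, float, float, float] | None:
    line = LineString([(x0, y0), (x1, y1)]).intersection(poly)
    if line.is_empty:
        return None
    if hasattr(line, "geoms"):  # multi-part: keep the longest piece
        line = max(line.geoms, key=lambda g: g.length)
    if not isinstance(line, LineString) or line.length < 1e-6:
        return None
    (a, b), (c, d) = line.coords[0], line.coords[-1]
    return a, b, c, d


def _runs_alongside(
    cand: LineString,
    cand_angle: float,
    segments: list[Segment],
    lines: list[LineString],
    min_sep_um: float = 0.3,
    max_angle_deg: float = 15.0,
) -> bool:
    """True if the candidate runs nearly parallel to an existing segment at
    sub-resolution distance.  Two membrane tubules do not travel side by side
    closer than their own diameter for any length — such a pair would be one
    tubule — so candidates like this are simulation artifacts, not network
    geometry."""
    for seg, line in zip(segments, lines):
        dang = abs(fold_angle(cand_angle - seg.angle))
        if dang > max_angle_deg:
            continue
        if cand.distance(line) < min_sep_um:
            return True
    return False


def generate_network_geometry(spec: NetworkSpec, seed: int = 0) -> SegmentSet:
    """Draw a ground-truthed segment set matching the network specification.

    Segment midpoints are uniform in the cell mask (rejection sampling);
    orientations are drawn per component around the canonical angles 0°, ±45°
    and 90° relative to the cell axis, each with Gaussian jitter.  Candidates
    that would run alongside an existing segment at sub-resolution separation
    are redrawn (see :func:`_runs_alongside`).  Segments are added until the
    realized tubule length reaches ``target_density`` × cell area, then
    T-junction branches are seeded at ``junction_rate`` per μm².
    Deterministic for a given spec and seed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    poly, _, _ = _cell_polygon(spec)
    area = poly.area
    target_length = spec.target_density * area
    minx, miny, maxx, maxy = poly.bounds

    if target_length / max(spec.segment_length_mean * 0.25, 1e-6) > _MAX_SEGMENTS:
        raise ValueError("requested density is infeasible for this cell area")

    frac = {"AT": spec.frac_at, "OT": spec.frac_ot, "TT": spec.frac_tt}
    realized = {"AT": 0.0, "OT": 0.0, "TT": 0.0}

    def next_component() -> str:
        # largest shortfall against the target share of the length realized so
        # far: keeps realized fractions on target even as T-branches are added
        tot = sum(realized.values())
        return max(("AT", "OT", "TT"), key=lambda k: frac[k] * (tot + 1.0) - realized[k])

    segments: list[Segment] = []
    lines: list[LineString] = []
    rejects = 0
    total = 0.0
    while total < target_length:
        component = next_component()
        length = float(
            np.clip(
                rng.normal(spec.segment_length_mean, spec.segment_length_sd),
                0.5,
                4.0 * spec.segment_length_mean,
            )
        )
        # uniform midpoint inside the cell mask
        while True:
            mx = rng.uniform(minx, maxx)
            my = rng.uniform(miny, maxy)
            if poly.contains(Point(mx, my)):
                break
        canonical = CANONICAL_ANGLES[component]
        if component == "OT" and rng.random() < 0.5:
            canonical = -canonical
        ang = math.radians(
            spec.axis_angle + canonical + rng.normal(0.0, spec.angle_jitter_sd)
        )
        dx, dy = 0.5 * length * math.cos(ang), 0.5 * length * math.sin(ang)
        clipped = _clip_to_polygon(mx - dx, my - dy, mx + dx, my + dy, poly)
        if clipped is None:
            continue
        seg = Segment(*clipped, component=component, width_nm=_component_width(spec, component))
        cand = LineString([(seg.x0, seg.y0), (seg.x1, seg.y1)])
        if rejects < 40 and _runs_alongside(cand, seg.angle, segments, lines):
            rejects += 1
            continue
        rejects = 0
        segments.append(seg)
        lines.append(cand)
        total += seg.length
        realized[component] += seg.length
        if len(segments) > _MAX_SEGMENTS:
            raise ValueError("requested density is infeasible for this cell area")

    # seeded T-junctions: branches growing off a host segment of another component,
    # with orientation (and hence length budget) drawn from the component mixture
    n_t = rng.poisson(spec.junction_rate * area)
    n_primary = len(segments)
    lengths = np.array([s.length for s in segments])
    p_host = lengths / lengths.sum()
    for _ in range(int(n_t)):
        comp = next_component()
        hosts = [i for i in range(n_primary) if segments[i].component != comp]
        if hosts:
            w = lengths[hosts] / lengths[hosts].sum()
            host = segments[int(rng.choice(hosts, p=w))]
        else:
            host = segments[int(rng.choice(n_primary, p=p_host))]
        t = rng.uniform(0.1, 0.9)
        px = host.x0 + t * (host.x1 - host.x0)
        py = host.y0 + t * (host.y1 - host.y0)
        blen = float(
            np.clip(
                rng.normal(0.5 * spec.segment_length_mean, spec.segment_length_sd),
                0.5,
                2.0 * spec.segment_length_mean,
            )
        )
        canonical = CANONICAL_ANGLES[comp]
        if comp == "OT" and rng.random() < 0.5:
            canonical = -canonical
        ang = math.radians(
            spec.axis_angle + canonical + rng.normal(0.0, spec.angle_jitter_sd)
        )
        sign = 1.0 if rng.random() < 0.5 else -1.0
        clipped = _clip_to_polygon(
            px, py, px + sign * blen * math.cos(ang), py + sign * blen * math.sin(ang),
            poly,
        )
        if clipped is None:
            continue
        seg = Segment(*clipped, component=comp, width_nm=_component_width(spec, comp))
        cand = LineString([(seg.x0, seg.y0), (seg.x1, seg.y1)])
        if _runs_alongside(cand, seg.angle, segments, lines):
            continue
        segments.append(seg)
        lines.append(cand)
        realized[comp] += seg.length

    out = SegmentSet(
        segments=segments,
        cell_mask_polygon=[(float(x), float(y)) for x, y in poly.exterior.coords[:-1]],
    )
    out.truth = out.recompute_truth()
    return out


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


def _segment_coverage(canvas: np.ndarray, seg: Segment, pixel_size_nm: float) -> None:
    """Accumulate (max-combine) the anti-aliased ribbon indicator of one segment.

    The ribbon is a flat-capped rectangle of the segment's physical width (so
    its axial extent equals the true segment length).  Pixel coverage is
    approximated by the product of two smooth edge profiles
    ``clip(r - d + 1/2, 0, 1)``, one lateral (``d`` = distance to the
    centreline, ``r`` = ribbon half-width) and one axial (distance inside the
    segment ends); each factor is exact for a straight edge crossing a square
    pixel parallel to one side and accurate to a few percent otherwise.
    """
    ps_um = pixel_size_nm / 1000.0
    r_px = (seg.width_nm / 2.0) / pixel_size_nm
    x0, y0 = seg.x0 / ps_um, seg.y0 / ps_um  # pixel units (col, row)
    x1, y1 = seg.x1 / ps_um, seg.y1 / ps_um
    pad = r_px + 1.5
    rmin = max(int(math.floor(min(y0, y1) - pad)), 0)
    rmax = min(int(math.ceil(max(y0, y1) + pad)) + 1, canvas.shape[0])
    cmin = max(int(math.floor(min(x0, x1) - pad)), 0)
    cmax = min(int(math.ceil(max(x0, x1) + pad)) + 1, canvas.shape[1])
    if rmin >= rmax or cmin >= cmax:
        return
    rows, cols = np.mgrid[rmin:rmax, cmin:cmax]
    px, py = cols.astype(float), rows.astype(float)
    vx, vy = x1 - x0, y1 - y0
    length = math.hypot(vx, vy)
    if length < 1e-9:
        return
    ux, uy = vx / length, vy / length
    t = (px - x0) * ux + (py - y0) * uy  # axial coordinate, px
    d = np.abs((px - x0) * uy - (py - y0) * ux)  # lateral distance, px
    lateral = np.clip(r_px - d + 0.5, 0.0, 1.0)
    axial = np.clip(np.minimum(t, length - t) + 0.5, 0.0, 1.0)
    cov = lateral * axial
    np.maximum(canvas[rmin:rmax, cmin:cmax], cov, out=canvas[rmin:rmax, cmin:cmax])


def render_image(
    segs: SegmentSet,
    imaging: ImagingSpec,
    fov_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a segment set into a noisy micrograph plus a pixel-space truth mask.

    Each tubule is drawn as a ribbon of its physical width, the ribbon union is
    convolved with an isotropic Gaussian PSF of ``psf_fwhm``, scaled to
    ``tubule_peak_signal`` over ``background_level``, then Poisson shot noise
    and Gaussian read noise are applied and the image is quantised to
    ``bit_depth``.  Returns ``(image, truth_mask)`` where the mask marks pixels
    whose centre lies inside a true ribbon.

    Raises ``ValueError`` if an explicit ``fov_shape`` (rows, cols) does not
    contain the cell.
    """
    imaging.validate()
    ps_um = imaging.pixel_size / 1000.0
    minx, miny, maxx, maxy = segs.cell_polygon.bounds
    need_rows = int(math.ceil((maxy + 1.0) / ps_um))
    need_cols = int(math.ceil((maxx + 1.0) / ps_um))
    if fov_shape is None:
        shape = (need_rows, need_cols)
    else:
        shape = tuple(fov_shape)
        if shape[0] < need_rows or shape[1] < need_cols:
            raise ValueError(
                f"field of view {shape} is smaller than the cell "
                f"(needs at least {(need_rows, need_cols)} pixels)"
            )

    coverage = np.zeros(shape, dtype=float)
    for seg in segs.segments:
        _segment_coverage(coverage, seg, imaging.pixel_size)
    truth_mask = coverage >= 0.5

    sigma_px = imaging.psf_fwhm / FWHM_PER_SIGMA / imaging.pixel_size
    blurred = ndimage.gaussian_filter(coverage, sigma_px) if sigma_px > 0 else coverage
    signal = imaging.background_level + imaging.tubule_peak_signal * blurred

    rng = np.random.default_rng(imaging.seed)
    if imaging.shot_noise:
        signal = rng.poisson(np.clip(signal, 0.0, None)).astype(float)
    if imaging.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, imaging.read_noise_sd, size=signal.shape)

    vmax = 2**imaging.bit_depth - 1
    dtype = np.uint8 if imaging.bit_depth == 8 else np.uint16
    image = np.clip(np.rint(signal), 0, vmax).astype(dtype)
    return image, truth_mask


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def _transient(
    t: np.ndarray, t_up: float, rise: float, k: float, amp: float, base: float
) -> np.ndarray:
    """Piecewise transient: flat baseline, linear upstroke, exponential decay."""
    t_peak = t_up + rise
    y = np.full_like(t, base)
    up = (t >= t_up) & (t < t_peak)
    y[up] = base + amp * (t[up] - t_up) / rise
    dec = t >= t_peak
    y[dec] = base + amp * np.exp(-k * (t[dec] - t_peak))
    return y


def generate_transients(spec: TransientSpec) -> dict:
    """Generate systolic and caffeine-evoked Ca2+ transients with ground truth.

    Both decays follow ``A exp(-k (t - t_peak)) + C`` with ``k = k_syst`` for
    the electrically evoked (systolic) transient and ``k = k_caff`` for the
    caffeine-evoked one.  Returns a dict with ``time_s``, ``systolic``,
    ``caffeine`` arrays and a ``truth`` block; the truth carries a
    ``fit_window_too_short`` flag when the trace does not cover three caffeine
    decay time constants.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, 1.0 / spec.sample_rate)
    t_up = 0.05 * spec.duration
    syst = _transient(t, t_up, rise=0.03, k=spec.k_syst, amp=spec.amplitude, base=spec.baseline)
    caff = _transient(t, t_up, rise=0.20, k=spec.k_caff, amp=spec.amplitude, base=spec.baseline)
    if spec.noise_sd > 0:
        syst = syst + rng.normal(0.0, spec.noise_sd, size=t.shape)
        caff = caff + rng.normal(0.0, spec.noise_sd, size=t.shape)
    too_short = (
        spec.k_caff <= 0 or (spec.duration - (t_up + 0.20)) < 3.0 / spec.k_caff
    )
    return {
        "time_s": t,
        "systolic": syst,
        "caffeine": caff,
        "truth": {
            "k_syst": spec.k_syst,
            "k_caff": spec.k_caff,
            "amplitude": spec.amplitude,
            "baseline": spec.baseline,
            "peak_time_systolic_s": t_up + 0.03,
            "peak_time_caffeine_s": t_up + 0.20,
            "fit_window_too_short": bool(too_short),
        },
    }


def generate_ap_trace(spec: APTraceSpec) -> dict:
    """Generate a stimulus-locked optical AP upstroke with ground truth.

    The trace is flat at zero dF/F until ``stim_end_time + true_onset_delay``,
    then rises as a saturating exponential ``A (1 - exp(-dt / tau))``.  The
    truth block records the onset time and the analytic maximum slope
    ``amplitude / upstroke_tau`` (attained at onset); ``no_ap`` flags a trace
    without an upstroke.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, spec.sample_interval)
    onset = spec.stim_end_time + spec.true_onset_delay
    y = np.zeros_like(t)
    after = t >= onset
    y[after] = spec.amplitude * (1.0 - np.exp(-(t[after] - onset) / spec.upstroke_tau))
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=t.shape)
    threshold = 0.04  # the onset-detection convention; crossing lags the
    # membrane onset by tau * ln(A / (A - thr)) on the saturating exponential
    if spec.amplitude > threshold:
        crossing_delay = spec.true_onset_delay + spec.upstroke_tau * math.log(
            spec.amplitude / (spec.amplitude - threshold)
        )
    else:
        crossing_delay = None
    return {
        "time_ms": t,
        "dff": y,
        "stim_end_ms": spec.stim_end_time,
        "truth": {
            "onset_time_ms": onset,
            "onset_delay_ms": spec.true_onset_delay,
            "threshold_crossing_delay_ms": crossing_delay,
            "amplitude": spec.amplitude,
            "max_slope_per_ms": (
                spec.amplitude / spec.upstroke_tau if spec.amplitude > 0 else 0.0
            ),
            "no_ap": bool(spec.amplitude <= 0),
        },
    }
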