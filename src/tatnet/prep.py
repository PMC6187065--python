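"""Micrograph preprocessing: cell-axis estimation and binarization.

Reproduces the chain raw micrograph → background-subtracted, smoothed,
thresholded binary mask restricted to the analysis ROI (cell interior minus
nuclei minus a border strip excluding the surface sarcolemma).  All spatial
parameters are specified in physical units (nm / μm) and converted by the
pixel size, so the same configuration applies to super-resolution (16.23 nm)
and confocal (114 nm) data alike.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, restoration

log = logging.getLogger("tatnet.prep")


@dataclass
class PreprocessParams:
    """Parameters of the binarization chain, in physical units.

    ``threshold_mode='otsu'`` computes Otsu's threshold within the ROI
    (reproducible default); ``'fixed'`` honours a predefined threshold in
    image counts.  ``exclude_margin`` is the width of the strip eroded from
    the cell border to exclude the surface sarcolemma.
    """

    smooth_sigma: float | None = None  # nm; None → 1 pixel; 0 disables smoothing
    background_radius: float = 2500.0  # nm rolling-ball radius (~10x tubule width);
    #                                    0 skips subtraction (flat-background data)
    threshold_mode: str = "otsu"  # 'fixed' or 'otsu'
    fixed_threshold: float = 0.0  # counts, used when threshold_mode == 'fixed'
    exclude_margin: float = 1.0  # μm

    def validate(self) -> None:
        if self.smooth_sigma is not None and self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be non-negative")
        if self.background_radius != 0 and self.background_radius <= (self.smooth_sigma or 0.0):
            raise ValueError("background_radius must exceed smooth_sigma (or be 0 to skip)")
        if self.exclude_margin < 0:
            raise ValueError("exclude_margin must be non-negative")
        if self.threshold_mode not in ("fixed", "otsu"):
            raise ValueError("threshold_mode must be 'fixed' or 'otsu'")


@dataclass
class CellROI:
    """Cell mask, nucleus masks and the cell's major-axis angle (degrees)."""

    mask: np.ndarray
    nucleus_masks: list[np.ndarray] = field(default_factory=list)
    major_axis_angle: float = 0.0

    def analysis_mask(self, exclude_margin_px: int = 0) -> np.ndarray:
        """Cell mask minus nuclei minus an eroded border strip."""
        m = self.mask.astype(bool)
        if exclude_margin_px > 0:
            m = ndimage.binary_erosion(m, structure=morphology.disk(exclude_margin_px))
        for nm in self.nucleus_masks:
            m = m & ~nm.astype(bool)
        return m


def estimate_major_axis(mask: np.ndarray) -> float:
    """Major-axis angle of a binary mask from its second central moments.

    Returns the angle of the principal eigenvector of the covariance matrix of
    the mask's pixel coordinates, in degrees in ``(-90, 90]``, measured from
    the image row direction (x = columns) with y = rows, i.e. the same frame
    as segment orientations in :mod:`tatnet.simulate`.

    Raises ``ValueError`` on an empty mask or when the two eigenvalues are
    (numerically) degenerate, in which case no axis is defined.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot estimate the major axis of an empty mask")
    rows, cols = np.nonzero(mask)
    x = cols - cols.mean()
    y = rows - rows.mean()
    mu20 = float(np.mean(x * x))
    mu02 = float(np.mean(y * y))
    mu11 = float(np.mean(x * y))
    # eigenvalues of [[mu20, mu11], [mu11, mu02]]
    disc = math.hypot(mu20 - mu02, 2.0 * mu11)
    lam1 = 0.5 * (mu20 + mu02 + disc)
    lam2 = 0.5 * (mu20 + mu02 - disc)
    if disc <= 1e-9 * max(lam1, 1e-12):
        raise ValueError("mask is isotropic: major axis is undefined")
    angle = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    _ = lam2
    return angle


def _rolling_ball_background(image: np.ndarray, radius_px: float) -> np.ndarray:
    """Rolling-ball background; large radii run on a shrunken image.

    For radii above 16 px the image is block-averaged so the effective radius
    stays at ~16 px and the estimated background is resized back — the same
    speed/accuracy trade-off large-radius rolling-ball implementations make.
    Background varies on scales far above the shrink factor, so the
    approximation error is negligible against tubule-scale signal.
    """
    if radius_px <= 16:
        return restoration.rolling_ball(image, radius=radius_px)
    from skimage.transform import resize
    shrink = int(math.ceil(radius_px / 16.0))
    pad_r = (-image.shape[0]) % shrink
    pad_c = (-image.shape[1]) % shrink
    padded = np.pad(image, ((0, pad_r), (0, pad_c)), mode="edge")
    small = padded.reshape(padded.shape[0] // shrink, shrink,
                           padded.shape[1] // shrink, shrink).mean(axis=(1, 3))
    bg_small = restoration.rolling_ball(small, radius=radius_px / shrink)
    bg = resize(bg_small, padded.shape, order=1, mode="edge",
                anti_aliasing=False)
    return bg[: image.shape[0], : image.shape[1]]


def preprocess(
    image: np.ndarray,
    roi: CellROI,
    params: PreprocessParams,
    pixel_size: float = 16.23,
) -> np.ndarray:
    """Binarize a micrograph within the analysis ROI.

    Rolling-ball background subtraction, Gaussian smoothing and thresholding
    (Otsu within the ROI, or a fixed predefined threshold), restricted to
    ``roi.mask`` minus nuclei minus the surface-membrane exclusion strip.

    ``pixel_size`` is in nm and converts the physical parameters to pixels.
    With a fixed threshold of 0.5 the operation is idempotent on an already
    binary {0, 1} input (background radius permitting).
    """
    params.validate()
    log.debug("preprocess: pixel_size=%g nm, params=%r", pixel_size, params)
    image = np.asarray(image, dtype=float)
    if image.shape != roi.mask.shape:
        raise ValueError("image and ROI mask shapes differ")

    margin_px = int(round(params.exclude_margin * 1000.0 / pixel_size))
    analysis = roi.analysis_mask(margin_px)

    if params.background_radius > 0:
        radius_px = max(params.background_radius / pixel_size, 1.0)
        work = image - _rolling_ball_background(image, radius_px)
    else:
        work = image.copy()

    if params.smooth_sigma is None:
        sigma_px = 1.0
    else:
        sigma_px = params.smooth_sigma / pixel_size
    if sigma_px > 0:
        work = ndimage.gaussian_filter(work, sigma_px)

    if params.threshold_mode == "fixed":
        thr = params.fixed_threshold
        lo, hi = float(work.min()), float(work.max())
        if not (lo <= thr <= hi):
            raise ValueError(
                f"fixed threshold {thr} outside image dynamic range [{lo:.3g}, {hi:.3g}]"
            )
    else:
        vals = work[analysis] if analysis.any() else work.ravel()
        if np.ptp(vals) == 0:
            raise ValueError("Otsu threshold undefined on a constant image")
        thr = filters.threshold_otsu(vals)

    return (work > thr) & analysis
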