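"""Optical action-potential metrics from voltage-dye fluorescence traces.

Stimulus-aligned dF/F traces recorded at surface sarcolemma (SS), transverse
tubule (TT) or axial tubule (AT) scan sites yield three metrics: the AP
amplitude (peak dF/F above the pre-stimulus baseline), the AP onset (latency
from the end of the stimulus to the first crossing of a 4% dF/F threshold,
sub-sample interpolated), and the maximum upstroke slope (dF/F per ms, on a
locally smoothed derivative).  The scan-site label never enters the
computation — identical traces give identical metrics regardless of label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

DEFAULT_THRESHOLD = 0.04  # dF/F


@dataclass
class APRecord:
    """A stimulus-aligned optical AP trace."""

    time: np.ndarray  # ms, uniform
    dff: np.ndarray  # dF/F, baseline-normalized
    stim_end: float  # ms
    site_label: str = "SS"  # SS | TT | AT

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.time.size != self.dff.size:
            raise ValueError("time and dff differ in length")
        d = np.diff(self.time)
        if self.time.size < 4 or np.any(d <= 0) or np.ptp(d) > 1e-6 * d.mean():
            raise ValueError("time must be uniform and strictly increasing")
        if not (self.time[0] < self.stim_end <= self.time[-1]):
            raise ValueError("stim_end must lie within the trace")
        if self.site_label not in ("SS", "TT", "AT"):
            raise ValueError(f"unknown site label {self.site_label!r}")


@dataclass
class APMetrics:
    amplitude: float  # dF/F above baseline
    onset: float | None  # ms after stim_end; None when no threshold crossing
    max_slope: float  # dF/F per ms
    baseline: float  # dF/F
    amplitude_raw: float  # peak dF/F without baseline subtraction


def ap_metrics(
    rec: APRecord,
    threshold: float = DEFAULT_THRESHOLD,
    smooth_samples: int = 5,
) -> APMetrics:
    """Amplitude, onset and maximum slope of a stimulus-locked AP upstroke.

    * amplitude: max post-stimulus dF/F minus the pre-stimulus baseline mean
      (the unsubtracted peak is also reported as ``amplitude_raw``);
    * onset: linearly interpolated first crossing of baseline + ``threshold``
      after ``stim_end``, minus ``stim_end``; ``None`` when never crossed;
    * max_slope: maximum derivative of the locally smoothed trace between
      stimulus end and the post-stimulus peak (``smooth_samples``-point
      Savitzky-Golay window, order 2).
    """
    t, y = rec.time, rec.dff
    pre = t < rec.stim_end
    baseline = float(y[pre].mean()) if pre.any() else 0.0
    post = t >= rec.stim_end
    tp, yp = t[post], y[post]
    amplitude = max(float(yp.max()) - baseline, 0.0)

    # onset: first crossing of baseline + threshold, sub-sample interpolated
    level = baseline + threshold
    onset: float | None = None
    above = yp >= level
    if above.any() and amplitude > 0:
        i = int(np.argmax(above))
        if i == 0:
            onset = float(tp[0] - rec.stim_end)
        else:
            y0, y1 = yp[i - 1], yp[i]
            frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
            onset = float(tp[i - 1] + frac * (tp[i] - tp[i - 1]) - rec.stim_end)

    # max slope over the upstroke window (stim end -> peak); smooth_samples <= 1
    # uses the raw forward difference (exact in the fine-sampling limit)
    dt = float(t[1] - t[0])
    i_peak = int(np.argmax(yp))
    if smooth_samples <= 1 or yp.size <= 4:
        upstroke = np.diff(yp[: max(i_peak + 1, 2)]) / dt
    else:
        win = max(3, smooth_samples | 1)  # odd window
        win = min(win, yp.size if yp.size % 2 == 1 else yp.size - 1)
        deriv = savgol_filter(yp, window_length=win, polyorder=2, deriv=1, delta=dt)
        upstroke = deriv[: max(i_peak + 1, 2)]
    max_slope = float(upstroke.max()) if upstroke.size else 0.0

    return APMetrics(
        amplitude=amplitude,
        onset=onset,
        max_slope=max_slope,
        baseline=baseline,
        amplitude_raw=float(yp.max()),
    )
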