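"""Ca2+ transient decay fitting, SERCA/NCX flux partitioning, current densities.

The rate of cytosolic Ca2+ decay during a systolic transient (k_syst) reflects
all extrusion pathways; during a caffeine-evoked transient SERCA re-uptake is
functionally removed, so its decay rate (k_caff) isolates the non-SERCA
pathways (predominantly NCX, plus PMCA and mitochondria).  The SERCA-dependent
rate is then k_SERCA = k_syst - k_caff and the fractional contributions to
extrusion are frac_SERCA = k_SERCA / k_syst and 1 - frac_SERCA.  Membrane
currents are normalised to cell capacitance (a measure of surface area) to
give peak (pA/pF) and integrated (pC/pF) densities; the integral of the
caffeine-evoked inward NCX current serves as a proxy for SR Ca2+ content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass
class Trace:
    """A time series: fluorescence transient or membrane current."""

    time: np.ndarray  # s
    value: np.ndarray
    kind: str = "systolic"  # systolic | caffeine | current
    capacitance: float | None = None  # pF, for kind == 'current'

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.size != self.value.size:
            raise ValueError("time and value differ in length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.kind not in ("systolic", "caffeine", "current"):
            raise ValueError(f"unknown trace kind {self.kind!r}")


@dataclass
class MonoExpFit:
    """A * exp(-k (t - t_peak)) + C fitted to the decay phase of a transient."""

    A: float
    k: float  # s^-1
    C: float
    t_peak: float  # s
    fit_window: tuple[float, float]
    residual_rms: float
    converged: bool
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class FluxPartition:
    """Decay-rate decomposition into SERCA and non-SERCA extrusion."""

    k_syst: float
    k_caff: float
    k_serca: float
    frac_serca: float
    frac_non_serca: float


@dataclass
class CurrentDensity:
    """Capacitance-normalised current metrics over an analysis window."""

    peak_density: float  # pA/pF (signed extremum)
    integral_density: float  # pC/pF
    sr_content_proxy: float | None  # pC/pF, from the caffeine-evoked current
    window: tuple[float, float]
    capacitance: float  # pF


FARADAY_C_PER_MOL = 96485.332

def charge_to_mol_ca(charge_pc: float) -> float:
    """Convert an integrated Ca2+ charge (pC) to moles of Ca2+.

    Divalent carrier: n = Q / (2 F).  Offered as an optional report column;
    the capacitance-normalised integral remains the core metric.
    """
    return charge_pc * 1e-12 / (2.0 * FARADAY_C_PER_MOL)


def fit_monoexp(
    trace: Trace,
    window_end: float | None = None,
    start_at_fraction_of_peak: float | None = None,
) -> MonoExpFit:
    """Fit a mono-exponential to the decay phase of a Ca2+ transient.

    The fit window runs from the sample of peak value to ``window_end`` (trace
    end by default).  ``start_at_fraction_of_peak`` (e.g. 0.9) instead starts
    the window where the decaying trace first falls to that fraction of the
    peak-minus-end amplitude, which is more robust to peak noise.

    A non-decaying trace (fitted k <= 0, or no identifiable decay phase) is
    returned as a flagged failure.
    """
    t, y = trace.time, trace.value
    if t.size < 10:
        raise ValueError("need at least 10 samples")
    i_peak = int(np.argmax(y))
    if i_peak >= t.size - 10:
        return _failed_fit(t, "no decay phase: peak is at the end of the trace")
    t_end = float(t[-1]) if window_end is None else float(window_end)
    if t_end <= t[i_peak]:
        raise ValueError("fit window ends before the transient peak")
    i_start = i_peak
    if start_at_fraction_of_peak is not None:
        tail = float(y[t <= t_end][-1])
        level = tail + start_at_fraction_of_peak * (y[i_peak] - tail)
        below = np.nonzero(y[i_peak:] <= level)[0]
        if below.size:
            i_start = i_peak + int(below[0])
    sel = (t >= t[i_start]) & (t <= t_end)
    ts, ys = t[sel], y[sel]
    if ts.size < 10:
        return _failed_fit(t, "fewer than 10 samples in the decay window")
    if np.ptp(ys) == 0:
        return _failed_fit(t, "trace is constant over the decay window")
    t0 = float(ts[0])

    # log-linear initial guess on the baseline-subtracted decay
    c0 = float(ys.min())
    a0 = max(float(ys[0] - c0), 1e-12)
    pos = ys - c0 > 0.05 * a0
    if pos.sum() >= 2:
        slope, _ = np.polyfit(ts[pos] - t0, np.log(ys[pos] - c0 + 1e-300), 1)
        k0 = max(-float(slope), 1e-3)
    else:
        k0 = 1.0

    def model(tt: np.ndarray, a: float, k: float, c: float) -> np.ndarray:
        return a * np.exp(-k * (tt - t0)) + c

    try:
        popt, _ = optimize.curve_fit(model, ts, ys, p0=[a0, k0, c0], maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return _failed_fit(t, f"fit did not converge: {exc}")
    a, k, c = map(float, popt)
    resid = ys - model(ts, a, k, c)
    fit = MonoExpFit(
        A=a, k=k, C=c, t_peak=float(t[i_peak]),
        fit_window=(t0, t_end),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=True,
    )
    if k <= 0 or a <= 0:
        fit.flagged = True
        fit.flag_reason = "trace does not decay (fitted k <= 0 or A <= 0)"
    return fit


def _failed_fit(t: np.ndarray, reason: str) -> MonoExpFit:
    return MonoExpFit(
        A=float("nan"), k=float("nan"), C=float("nan"), t_peak=float("nan"),
        fit_window=(float(t[0]), float(t[-1])), residual_rms=float("nan"),
        converged=False, flagged=True, flag_reason=reason,
    )


def partition_fluxes(fit_syst: MonoExpFit, fit_caff: MonoExpFit) -> FluxPartition:
    """Partition Ca2+ extrusion into SERCA and non-SERCA fractions.

    Requires k_syst >= k_caff > 0; a caffeine decay faster than the systolic
    one violates the model assumption that caffeine only removes the SERCA
    component, and is rejected.
    """
    for f, name in ((fit_syst, "systolic"), (fit_caff, "caffeine")):
        if f.flagged or not f.converged:
            raise ValueError(f"{name} fit is flagged: {f.flag_reason}")
    k_s, k_c = fit_syst.k, fit_caff.k
    if k_c <= 0:
        raise ValueError("k_caff must be positive")
    if k_s < k_c:
        raise ValueError(
            f"k_syst ({k_s:.4g} s^-1) < k_caff ({k_c:.4g} s^-1): violates the "
            "assumption that caffeine removes only the SERCA component of decay"
        )
    k_serca = k_s - k_c
    frac = k_serca / k_s
    return FluxPartition(
        k_syst=k_s, k_caff=k_c, k_serca=k_serca,
        frac_serca=frac, frac_non_serca=1.0 - frac,
    )


def current_density(
    trace: Trace,
    window: tuple[float, float],
    is_caffeine_response: bool = False,
) -> CurrentDensity:
    """Capacitance-normalised peak and integrated current over a window.

    Peak is the signed extremum (largest magnitude) within the window divided
    by capacitance (pA/pF); the integral is the trapezoidal charge over the
    window divided by capacitance (pC/pF, with current in pA and time in s).
    When the trace is a caffeine-evoked inward NCX current, the integrated
    density is also reported as ``sr_content_proxy``.
    """
    if trace.kind != "current":
        raise ValueError("current_density requires a trace of kind 'current'")
    if trace.capacitance is None or trace.capacitance <= 0:
        raise ValueError("capacitance (pF) must be set and positive")
    t0, t1 = window
    if t0 < trace.time[0] - 1e-12 or t1 > trace.time[-1] + 1e-12 or t1 <= t0:
        raise ValueError("analysis window lies outside the trace")
    sel = (trace.time >= t0) & (trace.time <= t1)
    ts, ys = trace.time[sel], trace.value[sel]
    peak = float(ys[np.argmax(np.abs(ys))]) / trace.capacitance
    integral = float(np.trapezoid(ys, ts)) / trace.capacitance
    return CurrentDensity(
        peak_density=peak,
        integral_density=integral,
        sr_content_proxy=integral if is_caffeine_response else None,
        window=(float(t0), float(t1)),
        capacitance=float(trace.capacitance),
    )
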