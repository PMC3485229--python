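"""Bolus-kinetic parameter extraction from a processed time-intensity trace.

The method is model-free half-intensity tracing.  The anchor T_half is
the first time the intensity reaches the median of the analysis window.
From there the curve is traced backward while the intensity keeps
strictly decreasing (the destination is T_arrival) and forward while it
keeps strictly increasing (the destination is T_peak, the FIRST peak --
later recirculation peaks may be higher and are reported separately as
T_max / I_max).  From these anchors:

    T_rising = T_peak - T_arrival
    BFI      = (I_peak - I_arrival) / T_rising
    MTT      = int tau I(T_arrival + tau) dtau / int I(T_arrival + tau) dtau
               over tau in [0, 20 s], on the baseline-zeroed trace

with tau the time since bolus arrival.  MTT is the center of gravity of
the dynamic curve; BFI is the slope of the first peak.  All parameters
are relative (arbitrary intensity units), suitable for qualitative
comparison rather than absolute flow quantification.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .config import PipelineConfig
from .preprocess import Trace, estimate_baseline, preprocess_trace

log = logging.getLogger("cbfmap")

#: reason codes for invalid records
REASON_OK = "ok"
REASON_FLAT = "flat"
REASON_TRUNCATED = "truncated peak"
REASON_NO_MASS = "no mass"
REASON_ZERO_RISE = "zero rise"


@dataclass
class KineticParams:
    """Per-trace result record; times in seconds, intensities in a.u."""

    t_half: float = np.nan
    t_arrival: float = np.nan
    t_peak: float = np.nan
    t_rising: float = np.nan
    i_arrival: float = np.nan
    i_peak: float = np.nan
    t_max: float = np.nan
    i_max: float = np.nan
    mtt: float = np.nan
    bfi: float = np.nan
    baseline: float = np.nan
    valid: bool = False
    reason: str = REASON_OK

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def find_t_half(trace: Trace) -> tuple[int, float]:
    """Index and time of the half-intensity anchor.

    The earliest sample whose intensity is equal to or greater than the
    median intensity of the analysis window (even-length windows use
    the mean of the two central order statistics).

    Raises
    ------
    ValueError
        On a flat trace, where the median equals every value and the
        anchor is meaningless.
    """
    I = trace.I
    # relative tolerance: smoothing/interpolation float fuzz on a constant
    # trace must still register as flat
    if np.ptp(I) <= 1e-9 * max(1.0, float(np.max(np.abs(I)))):
        raise ValueError(REASON_FLAT)
    med = np.median(I)
    idx = int(np.argmax(I >= med))
    return idx, float(trace.t[idx])


def trace_to_arrival(trace: Trace, t_half_idx: int) -> tuple[int, float, float]:
    """Trace backward from T_half down the upslope to the bolus foot.

    Steps backward while each earlier sample is strictly lower than the
    current one; stops at the first non-decrease.  Returns
    ``(index, t_arrival, i_arrival)``.
    """
    I = trace.I
    j = t_half_idx
    if j == 0:
        warnings.warn(
            "T_half at the first sample; T_arrival set equal to T_half",
            stacklevel=2,
        )
    while j > 0 and I[j - 1] < I[j]:
        j -= 1
    return j, float(trace.t[j]), float(I[j])


def trace_to_peak(trace: Trace, t_half_idx: int) -> tuple[int, float, float]:
    """Trace forward from T_half up the upslope to the first peak.

    Steps forward while each later sample is strictly higher; stops at
    the first non-increase.  This yields the FIRST peak, not the global
    maximum.  Returns ``(index, t_peak, i_peak)``.

    Raises
    ------
    ValueError
        When T_half falls on the last sample, so the peak is truncated
        by the end of the acquisition.
    """
    I = trace.I
    n = len(I)
    if t_half_idx == n - 1:
        raise ValueError(REASON_TRUNCATED)
    j = t_half_idx
    while j < n - 1 and I[j + 1] > I[j]:
        j += 1
    return j, float(trace.t[j]), float(I[j])


def rising_time(t_arrival: float, t_peak: float) -> float:
    """T_rising = T_peak - T_arrival (duration of the first-pass rise)."""
    dt = t_peak - t_arrival
    if dt < 0:
        raise ValueError("t_peak precedes t_arrival")
    return dt


def mean_transit_time(
    trace: Trace,
    t_arrival: float,
    window: float = 20.0,
    baseline: float = 0.0,
) -> float:
    """Center of gravity of the baseline-zeroed curve after arrival.

    MTT = int tau I dt / int I dt for tau in [0, window] (tau = time
    since arrival), by trapezoidal quadrature on the trace's grid.  If
    the trace ends before the full window, the integral is clipped to
    the available extent with a warning.

    Raises
    ------
    ValueError
        When the integrated signal mass is not positive ("no mass").
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    i0 = int(np.searchsorted(trace.t, t_arrival - 1e-9))
    tau = trace.t[i0:] - trace.t[i0]
    if tau[-1] < window - 1e-9:
        warnings.warn(
            f"trace extends only {tau[-1]:.3f} s past arrival; "
            f"MTT window clipped from {window} s",
            stacklevel=2,
        )
    sel = tau <= window + 1e-9
    tau = tau[sel]
    y = trace.I[i0 : i0 + len(tau)] - baseline
    den = float(np.trapezoid(y, tau))
    if den <= 0:
        raise ValueError(REASON_NO_MASS)
    num = float(np.trapezoid(tau * y, tau))
    return num / den


def blood_flow_index(
    i_arrival: float, i_peak: float, t_rising: float
) -> float:
    """BFI = (I_peak - I_arrival) / T_rising: slope of the first peak."""
    if t_rising <= 0:
        raise ValueError(REASON_ZERO_RISE)
    return (i_peak - i_arrival) / t_rising


def kinetics_from_processed(
    trace: Trace, mtt_window: float = 20.0
) -> KineticParams:
    """All kinetic parameters from an already smoothed/interpolated trace.

    Any stage failure returns an invalid record carrying the reason
    code; parameters computed before the failure are retained.
    """
    p = KineticParams()
    p.t_max = float(trace.t[int(np.argmax(trace.I))])
    p.i_max = float(np.max(trace.I))
    try:
        ih, p.t_half = find_t_half(trace)
    except ValueError as e:
        p.reason = str(e)
        return p
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ia, p.t_arrival, p.i_arrival = trace_to_arrival(trace, ih)
    except ValueError as e:  # pragma: no cover - arrival cannot fail today
        p.reason = str(e)
        return p
    try:
        ip, p.t_peak, p.i_peak = trace_to_peak(trace, ih)
    except ValueError as e:
        p.reason = str(e)
        return p
    p.t_rising = rising_time(p.t_arrival, p.t_peak)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p.baseline = estimate_baseline(trace, p.t_arrival)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p.mtt = mean_transit_time(
                trace, p.t_arrival, window=mtt_window, baseline=p.baseline
            )
    except ValueError as e:
        p.reason = str(e)
        return p
    try:
        p.bfi = blood_flow_index(p.i_arrival, p.i_peak, p.t_rising)
    except ValueError as e:
        p.reason = str(e)
        return p
    p.valid = True
    return p


def analyze_trace(
    trace: Trace, config: PipelineConfig | None = None
) -> KineticParams:
    """Full single-trace pipeline: smooth, interpolate, extract parameters.

    The input is a raw trace on the native frame grid (already
    restricted to the analysis window); preprocessing and tracing
    follow ``config``.  Failures yield an invalid record with a reason
    code rather than an exception.
    """
    config = config or PipelineConfig()
    if len(trace) > config.n_frames:
        trace = Trace(trace.t[: config.n_frames], trace.I[: config.n_frames])
    processed = preprocess_trace(trace, config)
    return kinetics_from_processed(processed, mtt_window=config.mtt_window)
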