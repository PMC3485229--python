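"""Assembly of pixelwise parametric blood-flow maps.

Every QC-passed pixel's time series is analyzed independently (no
spatial coupling) and the four kinetic parameters are assembled into
spatial maps on the stack's pixel grid.  Masked or failed pixels hold
NaN in the float maps.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import PipelineConfig
from .io_stack import AcquisitionStack
from .kinetics import kinetics_from_processed
from .preprocess import (
    Trace,
    interpolate_stack_frames,
    qc_mask,
    select_analysis_window,
    smooth_stack_frames,
)

log = logging.getLogger("cbfmap")

#: parameter names, map attribute order
PARAM_NAMES = ("t_arrival", "t_rising", "mtt", "bfi")


@dataclass
class ParameterMapSet:
    """Four parameter maps plus QC mask on one pixel grid.

    ``t_arrival_map``, ``t_rising_map`` and ``mtt_map`` are in seconds;
    ``bfi_map`` is in intensity units per second.  ``t_peak_map`` is
    kept as well so that the identity t_rising = t_peak - t_arrival is
    checkable per pixel.  Invalid pixels hold NaN.
    """

    t_arrival_map: np.ndarray
    t_rising_map: np.ndarray
    mtt_map: np.ndarray
    bfi_map: np.ndarray
    qc: np.ndarray
    t_peak_map: np.ndarray | None = None
    display_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.qc.shape
        for name in PARAM_NAMES:
            if getattr(self, f"{name}_map").shape != shape:
                raise ValueError("all maps must share one spatial shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.qc.shape


def compute_maps(
    stack: AcquisitionStack, config: PipelineConfig | None = None
) -> ParameterMapSet:
    """Run the kinetic analysis in every QC-passed pixel of a stack.

    The stack is restricted to the first ``config.n_frames`` frames,
    smoothed and interpolated pixelwise, and traced per pixel.  The
    result is deterministic given the stack and configuration.
    Per-pixel analysis failures become masked (NaN) pixels, never
    exceptions.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = select_analysis_window(stack, config.n_frames)
    qc = qc_mask(
        win,
        config.qc_snr_threshold,
        window=config.smoothing_window,
        order=config.smoothing_order,
    )

    smoothed = smooth_stack_frames(
        win.frames.astype(float), config.smoothing_window, config.smoothing_order
    )
    t_fine, fine = interpolate_stack_frames(smoothed, win.times, config.interp_dt)
    log.info(
        "preprocess: %d frames -> %d interpolated samples (%.2f s)",
        win.n_frames,
        len(t_fine),
        time.perf_counter() - t0,
    )

    rows, cols = win.shape
    maps = {
        name: np.full((rows, cols), np.nan) for name in PARAM_NAMES + ("t_peak",)
    }
    valid = np.zeros((rows, cols), dtype=bool)
    t1 = time.perf_counter()
    for r, c in np.argwhere(qc):
        trace = Trace(t_fine, fine[:, r, c])
        p = kinetics_from_processed(trace, mtt_window=config.mtt_window)
        if p.valid:
            valid[r, c] = True
            maps["t_arrival"][r, c] = p.t_arrival
            maps["t_rising"][r, c] = p.t_rising
            maps["mtt"][r, c] = p.mtt
            maps["bfi"][r, c] = p.bfi
            maps["t_peak"][r, c] = p.t_peak

    qc_final = qc & valid
    log.info(
        "kinetics: %d/%d pixels valid (%.2f s)",
        int(qc_final.sum()),
        qc_final.size,
        time.perf_counter() - t1,
    )
    result = ParameterMapSet(
        t_arrival_map=maps["t_arrival"],
        t_rising_map=maps["t_rising"],
        mtt_map=maps["mtt"],
        bfi_map=maps["bfi"],
        qc=qc_final,
        t_peak_map=maps["t_peak"],
        metadata={"config": config.to_mapping()},
    )
    for name in PARAM_NAMES:
        arr = getattr(result, f"{name}_map")
        if np.isfinite(arr).any():
            lo, hi = auto_display_range(arr)
            result.display_ranges[name] = (lo, hi)
    return result


def auto_display_range(map_values: np.ndarray) -> tuple[float, float]:
    """Robust (1st, 99th) percentile range over valid pixels."""
    vals = map_values[np.isfinite(map_values)]
    if vals.size == 0:
        raise ValueError("no valid pixels")
    lo, hi = np.percentile(vals, [1, 99])
    return float(lo), float(hi)


def scale_for_display(
    map_values: np.ndarray, value_range: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Linear 8-bit rendering of a parameter map.

    Maps [lo, hi] onto gray [0, 255] with clipping outside; the range
    actually used is returned for the map legend.  ``value_range=None``
    selects the robust auto range (1st-99th percentile of valid
    pixels).  A degenerate auto range (constant map) renders mid-gray
    with a warning; an explicit degenerate range is an error.
    """
    if value_range is None:
        lo, hi = auto_display_range(map_values)
        if lo >= hi:
            warnings.warn(
                "degenerate range: constant map rendered mid-gray",
                stacklevel=2,
            )
            img = np.full(map_values.shape, 128, dtype=np.uint8)
            return img, (lo, hi)
    else:
        lo, hi = float(value_range[0]), float(value_range[1])
        if lo >= hi:
            raise ValueError("degenerate range: lo must be < hi")
    with np.errstate(invalid="ignore"):
        scaled = (map_values - lo) / (hi - lo)
        scaled = np.clip(scaled, 0.0, 1.0)
    img = np.where(
        np.isfinite(map_values), np.round(scaled * 255), 0
    ).astype(np.uint8)
    return img, (lo, hi)


def normalize_bfi(bfi_map: np.ndarray, mode: str = "analysis") -> np.ndarray:
    """BFI normalization policy.

    ``display`` divides by the maximum over valid pixels so each image
    is self-normalized into (0, 1]; ``analysis`` returns the map
    unchanged, because inter-hemisphere comparisons must not be
    normalized per image.
    """
    if mode == "analysis":
        return bfi_map.copy()
    if mode != "display":
        raise ValueError(f"unknown mode {mode!r}")
    finite = np.isfinite(bfi_map)
    if not finite.any():
        raise ValueError("no valid pixels")
    peak = np.nanmax(bfi_map)
    if peak <= 0:
        raise ValueError("non-positive maximum; cannot normalize")
    return bfi_map / peak
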