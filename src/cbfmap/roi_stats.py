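"""Bregma-referenced ROI geometry, contralateral mirroring and statistics.

ROIs are placed in millimetres relative to the bregma landmark.  Axis
sign convention (declared, since image orientation is metadata): with
the nose toward the top of the image, *posterior* offsets increase the
row index and *left-lateral* offsets decrease the column index (the
animal's left appears on the image's left).  The standard protocol ROI
is 2 x 2 mm centered 2 mm posterior and 2 mm lateral from bregma;
mirroring across the sagittal midline column yields the contralateral
control region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

log = logging.getLogger("cbfmap")


@dataclass(frozen=True)
class RoiSpec:
    """A rectangular pixel footprint with its mm-space description.

    ``rows`` and ``cols`` are half-open index ranges [start, stop).
    """

    center_mm: tuple[float, float]  # (posterior+, left-lateral+)
    size_mm: tuple[float, float]  # (height, width)
    rows: tuple[int, int]
    cols: tuple[int, int]

    def __post_init__(self) -> None:
        if self.rows[1] <= self.rows[0] or self.cols[1] <= self.cols[0]:
            raise ValueError("ROI footprint is empty")

    @property
    def footprint(self) -> tuple[slice, slice]:
        return slice(*self.rows), slice(*self.cols)

    @property
    def n_pixels(self) -> int:
        return (self.rows[1] - self.rows[0]) * (self.cols[1] - self.cols[0])


def _span(center_px: float, n: int, bregma_px: float) -> tuple[int, int]:
    """Integer [start, stop) of ``n`` pixels covering ``center_px``.

    Half-pixel ties are rounded away from bregma so the footprint
    always covers the nominal extent on the far side.
    """
    start_f = center_px - n / 2
    frac = start_f - math.floor(start_f)
    if abs(frac - 0.5) < 1e-9:
        start = (
            math.ceil(start_f) if center_px >= bregma_px else math.floor(start_f)
        )
    else:
        start = round(start_f)
    return int(start), int(start) + n


def make_roi(
    center_mm: tuple[float, float],
    size_mm: tuple[float, float],
    *,
    pixel_size: float,
    bregma_px: tuple[int, int],
    image_shape: tuple[int, int] | None = None,
) -> RoiSpec:
    """Convert a mm-space ROI description into a pixel footprint.

    ``center_mm`` is (posterior, left-lateral) offset from bregma;
    ``size_mm`` is (height, width).  The pixel count per side is the
    ceiling of size over pixel size, so a 2 mm ROI at 0.1 mm/pixel is
    exactly 20 pixels and the footprint never undercovers the nominal
    area.
    """
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("pixel_size must be a positive number of mm/pixel")
    if bregma_px is None:
        raise ValueError("bregma_px metadata is required for ROI placement")
    ap, ml = center_mm
    height, width = size_mm
    if height <= 0 or width <= 0:
        raise ValueError("size_mm must be positive")
    row_c = bregma_px[0] + ap / pixel_size
    col_c = bregma_px[1] - ml / pixel_size  # left-lateral decreases column
    n_rows = max(1, math.ceil(height / pixel_size - 1e-9))
    n_cols = max(1, math.ceil(width / pixel_size - 1e-9))
    rows = _span(row_c, n_rows, bregma_px[0])
    cols = _span(col_c, n_cols, bregma_px[1])
    roi = RoiSpec(tuple(center_mm), tuple(size_mm), rows, cols)
    if image_shape is not None:
        _check_bounds(roi, image_shape)
    return roi


def _check_bounds(roi: RoiSpec, shape: tuple[int, int]) -> None:
    if (
        roi.rows[0] < 0
        or roi.cols[0] < 0
        or roi.rows[1] > shape[0]
        or roi.cols[1] > shape[1]
    ):
        raise ValueError(
            f"ROI rows {roi.rows} cols {roi.cols} outside image {shape}"
        )


def mirror_roi(
    roi: RoiSpec,
    midline_col: int,
    image_shape: tuple[int, int] | None = None,
) -> RoiSpec:
    """Reflect a footprint across the sagittal midline column.

    Pixel column c maps to ``2 * midline_col - c``, so a footprint
    abutting the midline abuts it from the other side and the area is
    preserved exactly.  Mirroring twice is the identity.
    """
    c0, c1 = roi.cols
    new_cols = (2 * midline_col - (c1 - 1), 2 * midline_col - c0 + 1)
    ap, ml = roi.center_mm
    mirrored = RoiSpec((ap, -ml), roi.size_mm, roi.rows, new_cols)
    if image_shape is not None:
        _check_bounds(mirrored, image_shape)
    return mirrored


def roi_mean_params(maps, roi: RoiSpec, label: str = "roi") -> list[dict]:
    """Mean, SEM and pixel counts of each parameter over a footprint.

    Masked (NaN) pixels are excluded; their count is reported.  SEM
    uses the sample standard deviation (ddof = 1) over n valid pixels.

    Raises
    ------
    ValueError
        When the footprint holds zero valid pixels for every parameter.
    """
    from .mapping import PARAM_NAMES

    _check_bounds(roi, maps.shape)
    rows = []
    any_valid = False
    for name in PARAM_NAMES:
        vals = getattr(maps, f"{name}_map")[roi.footprint].ravel()
        finite = vals[np.isfinite(vals)]
        n = finite.size
        if n:
            any_valid = True
        mean = float(np.mean(finite)) if n else float("nan")
        if n >= 2:
            sem = float(np.std(finite, ddof=1) / np.sqrt(n))
        elif n == 1:
            sem = 0.0
        else:
            sem = float("nan")
        rows.append(
            {
                "roi": label,
                "parameter": name,
                "mean": mean,
                "sem": sem,
                "n_pixels": n,
                "n_masked": vals.size - n,
            }
        )
    if not any_valid:
        raise ValueError("ROI contains no valid pixels")
    return rows


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    paired: bool
    degenerate: bool = False


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    *,
    welch: bool = False,
) -> TTestResult:
    """Two-tailed Student t-test between two groups of ROI values.

    The unpaired test pools variances (classical Student); a Welch
    variant is available behind ``welch=True``.  The paired test acts
    on per-subject differences and requires equal lengths.  Degenerate
    zero-variance inputs resolve by convention: equal constant groups
    give t = 0, p = 1; a constant nonzero paired difference gives
    p = 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if paired and len(x) != len(y):
        raise ValueError("paired test requires equal group lengths")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")

    if paired:
        d = x - y
        if np.std(d, ddof=1) == 0:
            if np.all(d == 0):
                return TTestResult(0.0, len(d) - 1, 1.0, True, True)
            sign = float(np.sign(d[0]))
            return TTestResult(sign * np.inf, len(d) - 1, 0.0, True, True)
        res = stats.ttest_rel(x, y)
        return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), True)

    if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
        df = len(x) + len(y) - 2
        if np.mean(x) == np.mean(y):
            return TTestResult(0.0, df, 1.0, False, True)
        sign = float(np.sign(np.mean(x) - np.mean(y)))
        return TTestResult(sign * np.inf, df, 0.0, False, True)
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), False)
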