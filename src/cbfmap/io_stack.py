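"""Reading and writing of image stacks, traces, parameter maps and reports.

Stacks are multi-page grayscale TIFFs (or directories of single-page
TIFFs in lexicographic frame order) holding 12-bit values in 16-bit
samples.  Exact parameter maps are written as ``.npy`` float arrays;
8-bit PNGs carry the display rendering, with the value range used for
the grayscale recorded in a plain-text sidecar.

Coordinate convention throughout the package: (row, col) with row 0 at
the image top, matching TIFF sample order.  Frame k is at
``t = k * frame_interval`` with t = 0 at the first acquired frame.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger("cbfmap")

#: Gray value written to PNG pixels that carry no valid parameter.
MASK_SENTINEL_GRAY = 0


@dataclass
class AcquisitionStack:
    """A (time x rows x cols) intensity stack with acquisition metadata.

    Parameters
    ----------
    frames : ndarray
        Intensities, shape (n_frames, rows, cols), arbitrary units.
    frame_interval : float
        Seconds per frame; must be positive.
    pixel_size : float, optional
        mm per pixel (isotropic); required only for ROI geometry.
    bregma_px : (int, int), optional
        Pixel coordinate (row, col) of the bregma landmark.
    midline_col : int, optional
        Column index of the sagittal midline.
    bit_depth : int
        Bit depth of the raw data (default 12).
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float | None = None
    bregma_px: tuple[int, int] | None = None
    midline_col: int | None = None
    bit_depth: int = 12
    strict_range: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) array")
        if self.frames.shape[0] < 2:
            raise ValueError("stack must contain at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if np.issubdtype(self.frames.dtype, np.integer):
            vmax = int(self.frames.max(initial=0))
            vmin = int(self.frames.min(initial=0))
            if vmin < 0:
                raise ValueError("raw intensities must be >= 0")
            limit = 2**self.bit_depth - 1
            if vmax > limit:
                msg = (
                    f"stack contains values up to {vmax}, above the "
                    f"{self.bit_depth}-bit limit {limit}"
                )
                if self.strict_range:
                    raise ValueError(msg)
                warnings.warn(msg, stacklevel=2)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, cols)."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, t = 0 at the first frame."""
        return np.arange(self.n_frames) * self.frame_interval


def read_stack(
    path: str | Path,
    frame_interval: float,
    *,
    pixel_size: float | None = None,
    bregma_px: tuple[int, int] | None = None,
    midline_col: int | None = None,
    bit_depth: int = 12,
    strict_range: bool = True,
) -> AcquisitionStack:
    """Read a multi-page TIFF (or a directory of single-page TIFFs).

    Frames from a directory are ordered lexicographically by filename.
    Intensities are preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        pages = [tifffile.imread(f) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
        frames = np.stack(pages)
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    return AcquisitionStack(
        frames,
        frame_interval,
        pixel_size=pixel_size,
        bregma_px=bregma_px,
        midline_col=midline_col,
        bit_depth=bit_depth,
        strict_range=strict_range,
    )


def write_stack(stack: AcquisitionStack, path: str | Path) -> None:
    """Write a stack as a multi-page 16-bit TIFF, value-exact."""
    frames = stack.frames
    if not np.issubdtype(frames.dtype, np.integer):
        frames = np.round(frames).astype(np.uint16)
    else:
        frames = frames.astype(np.uint16)
    tifffile.imwrite(Path(path), frames, photometric="minisblack")


# -- parameter maps -----------------------------------------------------


def write_parameter_maps(maps, out_dir: str | Path) -> dict[str, Path]:
    """Write a :class:`~cbfmap.mapping.ParameterMapSet` to ``out_dir``.

    Per parameter: ``<name>.npy`` preserves exact float values (masked
    pixels are NaN) and ``<name>.png`` is the 8-bit display rendering.
    ``<name>_scale.txt`` records the value range mapped onto gray 0-255
    and the sentinel gray used for masked pixels.  The QC mask is
    written as ``qc.png`` (255 = valid) and pipeline metadata as
    ``metadata.json``.
    """
    from .mapping import scale_for_display  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in ("t_arrival", "t_rising", "mtt", "bfi"):
        arr = getattr(maps, f"{name}_map")
        npy = out_dir / f"{name}.npy"
        np.save(npy, arr)
        written[f"{name}.npy"] = npy

        rng = maps.display_ranges.get(name)
        img, (lo, hi) = scale_for_display(arr, rng)
        img = np.where(np.isfinite(arr), img, MASK_SENTINEL_GRAY).astype(np.uint8)
        png = out_dir / f"{name}.png"
        iio.imwrite(png, img)
        written[f"{name}.png"] = png

        sidecar = out_dir / f"{name}_scale.txt"
        unit = "a.u./s" if name == "bfi" else "s"
        sidecar.write_text(
            f"map: {name}\n"
            f"display_range_lo: {lo!r}\n"
            f"display_range_hi: {hi!r}\n"
            f"unit: {unit}\n"
            f"mask_sentinel_gray: {MASK_SENTINEL_GRAY}\n"
        )
        written[f"{name}_scale.txt"] = sidecar

    qc_png = out_dir / "qc.png"
    iio.imwrite(qc_png, (maps.qc.astype(np.uint8) * 255))
    written["qc.png"] = qc_png

    meta = out_dir / "metadata.json"
    meta.write_text(json.dumps(maps.metadata, indent=2, default=str))
    written["metadata.json"] = meta
    log.info("wrote %d map files to %s", len(written), out_dir)
    return written


def read_parameter_map(path: str | Path) -> np.ndarray:
    """Read back an exact float map written by :func:`write_parameter_maps`."""
    return np.load(Path(path))


# -- traces and reports -------------------------------------------------


def read_trace_csv(path: str | Path):
    """Read a two-column (t, I) delimited text file into a Trace."""
    from .preprocess import Trace

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace CSV must have two columns: time, intensity")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    i = df.iloc[:, 1].to_numpy(dtype=float)
    return Trace(t, i)


def write_trace_csv(trace, path: str | Path) -> None:
    pd.DataFrame({"t_s": trace.t, "intensity": trace.I}).to_csv(
        Path(path), index=False
    )


def write_roi_report(rows, path: str | Path) -> None:
    """Write ROI summary records as CSV, one row per ROI per parameter.

    ``rows`` is an iterable of mappings with keys roi, parameter, mean,
    sem, n_pixels, n_masked (plus optional test-result columns).
    """
    columns = ["roi", "parameter", "mean", "sem", "n_pixels", "n_masked"]
    df = pd.DataFrame(list(rows))
    if df.empty:
        df = pd.DataFrame(columns=columns)
    else:
        extra = [c for c in df.columns if c not in columns]
        df = df[[c for c in columns if c in df.columns] + extra]
    df.to_csv(Path(path), index=False, float_format="%.10g")


def read_roi_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
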