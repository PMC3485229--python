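"""Pipeline configuration: acquisition and analysis constants.

Defaults follow the acquisition protocol the method was developed for:
12-bit frames every 580 ms, the initial 40 frames analyzed, traces
interpolated to an 11.6 ms grid, and a 20 s post-arrival window for the
mean transit time.  Every key is validated on load and unknown keys are
rejected so that a typo in a YAML file cannot silently fall back to a
default.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

log = logging.getLogger("cbfmap")


@dataclass
class PipelineConfig:
    """All tunable constants of the mapping pipeline.

    Attributes
    ----------
    frame_interval : float
        Seconds between acquired frames (default 0.58 s).
    pixel_size : float or None
        Image scale in mm per pixel (isotropic).  Required only for
        ROI geometry; plain map generation works without it.
    bit_depth : int
        Sample bit depth of raw stacks (default 12; values are stored
        in 16-bit TIFF samples).
    n_frames : int
        Number of initial frames used for map generation (default 40).
    smoothing_window : int
        Savitzky-Golay window length in frames, odd (default 7).
    smoothing_order : int
        Savitzky-Golay polynomial order (default 3).
    interp_dt : float
        Time step of the interpolated trace in seconds (default 0.0116,
        i.e. 11.6 ms, 1/50 of the frame interval).
    mtt_window : float
        Length in seconds of the post-arrival integration window for
        the mean transit time (default 20.0).
    qc_snr_threshold : float
        Minimum bolus amplitude over robust noise scale for a pixel to
        receive kinetic parameters (default 5.0).
    strict_range : bool
        If True, raw stack values above 2**bit_depth - 1 raise; if
        False they only warn.
    """

    frame_interval: float = 0.58
    pixel_size: float | None = None
    bit_depth: int = 12
    n_frames: int = 40
    smoothing_window: int = 7
    smoothing_order: int = 3
    interp_dt: float = 0.0116
    mtt_window: float = 20.0
    qc_snr_threshold: float = 5.0
    strict_range: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.bit_depth < 1 or self.bit_depth > 16:
            raise ValueError("bit_depth must be in [1, 16]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd")
        if self.smoothing_window <= self.smoothing_order:
            raise ValueError("smoothing_window must exceed smoothing_order")
        if self.smoothing_order < 1:
            raise ValueError("smoothing_order must be >= 1")
        if self.interp_dt <= 0:
            raise ValueError("interp_dt must be > 0")
        if self.mtt_window <= 0:
            raise ValueError("mtt_window must be > 0")
        if self.qc_snr_threshold < 0:
            raise ValueError("qc_snr_threshold must be >= 0")

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    # -- serialization ---------------------------------------------------

    # YAML section -> (key -> dataclass field)
    _SCHEMA = {
        "acquisition": {
            "frame_interval": "frame_interval",
            "pixel_size": "pixel_size",
            "bit_depth": "bit_depth",
        },
        "analysis": {"n_frames": "n_frames"},
        "smoothing": {"window": "smoothing_window", "order": "smoothing_order"},
        "interpolation": {"dt": "interp_dt"},
        "mtt": {"window_s": "mtt_window"},
        "qc": {"snr_threshold": "qc_snr_threshold"},
        "io": {"strict_range": "strict_range"},
    }

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        """Build a config from a nested mapping, rejecting unknown keys."""
        kwargs: dict[str, Any] = {}
        for section, content in data.items():
            if section not in cls._SCHEMA:
                raise KeyError(f"unknown config section: {section!r}")
            if not isinstance(content, Mapping):
                raise TypeError(f"config section {section!r} must be a mapping")
            for key, value in content.items():
                try:
                    field = cls._SCHEMA[section][key]
                except KeyError:
                    raise KeyError(
                        f"unknown config key: {section}.{key}"
                    ) from None
                kwargs[field] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def to_mapping(self) -> dict[str, dict[str, Any]]:
        """Nested-dict form, inverse of :meth:`from_mapping`."""
        out: dict[str, dict[str, Any]] = {}
        for section, keys in self._SCHEMA.items():
            out[section] = {k: getattr(self, f) for k, f in keys.items()}
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False)

    def log_effective(self) -> None:
        """Echo the effective configuration to the log, one line."""
        flat = {
            f"{s}.{k}": v
            for s, content in self.to_mapping().items()
            for k, v in content.items()
        }
        log.info("config %s", " ".join(f"{k}={v}" for k, v in flat.items()))


DEFAULT_CONFIG = PipelineConfig()
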