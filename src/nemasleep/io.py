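"""File formats, configuration and provenance.

Image stacks are multi-page grayscale TIFF (8- or 16-bit); tabular
outputs are UTF-8 CSV with a '#'-prefixed provenance header line naming
the configuration hash and seed, so any result file can be traced back
to the exact run that produced it. Nested statistics go to JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile
import yaml

from .motion import ImageStack, MotionTrace
from .scoring import ScoringConfig

__all__ = [
    "RunConfig",
    "WormRecord",
    "read_stack",
    "iter_frames",
    "write_stack",
    "trace_to_csv",
    "trace_from_csv",
    "write_table",
    "read_manifest",
]


@dataclass(frozen=True)
class RunConfig:
    """Reproducible-run configuration.

    frame intervals default to the acquisition rates of the behavioral
    (0.2 FPS) and calcium (~0.17 FPS) recordings.
    """

    frame_interval_behavior: float = 5.0
    frame_interval_calcium: float = 5.88
    pixel_size: float = 0.4
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    blur_sigma: float = 2.0
    sg_window_heavy: int = 120
    sg_window_light: int = 20
    min_prominence: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_behavior <= 0 or self.frame_interval_calcium <= 0:
            raise ValueError("frame intervals must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scoring" in d and isinstance(d["scoring"], dict):
            d["scoring"] = ScoringConfig(**d["scoring"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class WormRecord:
    """One worm in a run manifest."""

    worm_id: str
    group: str
    source: str                      # trace CSV or TIFF stack path
    roi: tuple[int, int, int, int] | None = None  # half-open (r0, c0, r1, c1)

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group label must be non-empty")
        if self.roi is not None:
            r0, c0, r1, c1 = self.roi
            if r1 <= r0 or c1 <= c0:
                raise ValueError("ROI must be half-open with positive extent")


def _check_crop(crop, shape) -> tuple[int, int, int, int]:
    r0, c0, r1, c1 = crop
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"crop {crop} exceeds frame bounds {shape}")
    return r0, c0, r1, c1


def iter_frames(path, crop=None) -> Iterator[np.ndarray]:
    """Lazily yield (optionally cropped) frames of a multi-page TIFF.

    Pages are read one at a time, so memory use is independent of the
    number of frames.
    """
    with tifffile.TiffFile(path) as tif:
        first = tif.pages[0]
        shape, dtype = first.shape, first.dtype
        for page in tif.pages:
            if page.shape != shape or page.dtype != dtype:
                raise ValueError("mixed page shape or bit depth in stack")
            frame = page.asarray()
            if crop is not None:
                r0, c0, r1, c1 = _check_crop(crop, frame.shape)
                frame = frame[r0:r1, c0:c1]
            yield frame


def read_stack(path, crop=None, frame_interval: float = 5.0,
               pixel_size: float = 1.0, channel: str = "") -> ImageStack:
    """Read a multi-page grayscale TIFF into an ImageStack."""
    frames = np.stack(list(iter_frames(path, crop)))
    bit_depth = 8 if frames.dtype == np.uint8 else 16
    return ImageStack(frames=frames, frame_interval=frame_interval,
                      pixel_size=pixel_size, channel=channel, bit_depth=bit_depth)


def write_stack(path, stack: ImageStack) -> None:
    """Write an ImageStack as a multi-page TIFF."""
    tifffile.imwrite(path, stack.frames)


def _provenance_line(provenance: dict | None) -> str:
    if not provenance:
        return ""
    fields = " ".join(f"{k}={v}" for k, v in sorted(provenance.items()))
    return f"# {fields}\n"


def trace_to_csv(trace: MotionTrace, path, provenance: dict | None = None) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(trace)),
        "time_s": trace.time_s,
        "speed": trace.speed,
        "missing": trace.missing.astype(int),
    })
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_line(provenance))
        df.to_csv(fh, index=False)


def trace_from_csv(path, frame_interval: float | None = None) -> MotionTrace:
    df = pd.read_csv(path, comment="#")
    time_s = df["time_s"].to_numpy(dtype=float)
    if frame_interval is None:
        frame_interval = float(np.median(np.diff(time_s))) if len(df) > 1 else 1.0
    return MotionTrace(time_s=time_s,
                       speed=df["speed"].to_numpy(dtype=float),
                       missing=df["missing"].to_numpy(dtype=bool),
                       frame_interval=frame_interval)


def write_table(df: pd.DataFrame, path, provenance: dict | None = None,
                float_format: str = "%.6g") -> None:
    """Write a results table as CSV with a provenance comment header."""
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_line(provenance))
        df.to_csv(fh, index=False, float_format=float_format)


def read_manifest(path) -> list[WormRecord]:
    """Read a worm manifest CSV (worm_id, group, source[, r0, c0, r1, c1])."""
    df = pd.read_csv(path, comment="#")
    records = []
    for _, row in df.iterrows():
        roi = None
        if {"r0", "c0", "r1", "c1"}.issubset(df.columns) and not pd.isna(row.get("r0")):
            roi = (int(row["r0"]), int(row["c0"]), int(row["r1"]), int(row["c1"]))
        records.append(WormRecord(worm_id=str(row["worm_id"]),
                                  group=str(row["group"]),
                                  source=str(row["source"]), roi=roi))
    return records
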