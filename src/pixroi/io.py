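"""Stack and table I/O: multi-frame TIFF reading/writing, label maps, CSV
tables and the JSON run manifest.

The on-disk conventions are deliberately plain: grayscale multi-frame TIFF
with axes ``(frame, row, col)`` for a single channel or
``(frame, channel, row, col)`` for two-channel exports; label maps as
single-frame uint8 TIFF with 0=background, 1=netotic, 2=necrotic; tables as
headed CSV. The frame interval is user-supplied metadata (default 15 min),
never parsed from vendor TIFF tags.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig

__all__ = [
    "VideoStack",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "write_outputs",
]

log = logging.getLogger(__name__)

#: label codes of the pixel class map
BACKGROUND, NETOTIC, NECROTIC = 0, 1, 2


@dataclass
class VideoStack:
    """One channel of a time-lapse video.

    ``data`` is indexed ``(frame, row, col)`` in arbitrary nonnegative
    intensity units; ``frame_interval`` is minutes per frame; ``t0`` is the
    acquisition start in minutes.
    """

    data: np.ndarray
    frame_interval: float = 15.0
    channel_name: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be (frame, row, col), got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("a video stack needs at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("stack intensities must be nonnegative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 minutes")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of every frame, minutes."""
        return self.t0 + self.frame_interval * np.arange(self.n_frames, dtype=float)

    def with_data(self, data: np.ndarray) -> "VideoStack":
        return VideoStack(
            data=data,
            frame_interval=self.frame_interval,
            channel_name=self.channel_name,
            t0=self.t0,
        )


def read_stack(
    path: str | Path,
    channel: int = 0,
    frame_interval: float = 15.0,
    channel_name: str = "",
    t0: float = 0.0,
) -> VideoStack:
    """Read one channel of a multi-frame TIFF as a :class:`VideoStack`.

    3-D files are treated as single-channel ``(T, H, W)``; 4-D files as
    ``(T, C, H, W)``. Anything else is rejected with the layout found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"single-frame stack (shape {arr.shape}); need >= 2 frames")
    if arr.ndim == 3:
        n_channels = 1
        if channel != 0:
            raise ValueError(
                f"channel {channel} out of range: axis layout (T, H, W)={arr.shape} has 1 channel"
            )
        data = arr
    elif arr.ndim == 4:
        n_channels = arr.shape[1]
        if not 0 <= channel < n_channels:
            raise ValueError(
                f"channel {channel} out of range: axis layout (T, C, H, W)={arr.shape} "
                f"has {n_channels} channels"
            )
        data = arr[:, channel]
    else:
        raise ValueError(f"unsupported TIFF layout with shape {arr.shape}")
    if data.shape[0] < 2:
        raise ValueError(f"single-frame stack (shape {arr.shape}); need >= 2 frames")
    return VideoStack(
        data=data, frame_interval=frame_interval, channel_name=channel_name, t0=t0
    )


def write_stack(path: str | Path, *channels: VideoStack | np.ndarray) -> Path:
    """Write one or more aligned channels to a multi-frame TIFF.

    One channel is written ``(T, H, W)``; several are stacked to
    ``(T, C, H, W)``. Dtypes are preserved bit-exactly.
    """
    if not channels:
        raise ValueError("need at least one channel")
    arrays = [c.data if isinstance(c, VideoStack) else np.asarray(c) for c in channels]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"channels disagree in shape: {sorted(shapes)}")
    out = arrays[0] if len(arrays) == 1 else np.stack(arrays, axis=1)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, out)
    return path


def write_labels(path: str | Path, labels: np.ndarray) -> Path:
    """Write a pixel class map as a single-frame uint8 TIFF."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"label map must be 2-D, got shape {labels.shape}")
    bad = np.setdiff1d(np.unique(labels), [BACKGROUND, NETOTIC, NECROTIC])
    if bad.size:
        raise ValueError(f"label values outside {{0, 1, 2}}: {bad.tolist()}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.astype(np.uint8))
    return path


def read_labels(path: str | Path) -> np.ndarray:
    labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise ValueError(f"label map must be 2-D, got shape {labels.shape}")
    return labels


def write_outputs(
    out_dir: str | Path,
    labels: np.ndarray | None = None,
    tables: Mapping[str, pd.DataFrame] | None = None,
    config: RunConfig | None = None,
    seed: int | None = None,
    extra: Mapping[str, object] | None = None,
) -> dict:
    """Write a run's outputs plus a JSON manifest; return the manifest.

    The manifest records the configuration, the seed and every file written,
    so a run can be reproduced from the manifest alone. Apart from the
    timestamp it is a pure function of its inputs.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc

    files: dict[str, str] = {}
    if labels is not None:
        write_labels(out_dir / "labels.tif", labels)
        files["labels"] = "labels.tif"
    for name, table in (tables or {}).items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False)
        files[name] = fname

    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": seed if seed is not None else (config.seed if config else None),
        "files": files,
        "extra": dict(extra) if extra else {},
        "created": datetime.now(timezone.utc).isoformat(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
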