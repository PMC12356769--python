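"""Run configuration for the NET quantification pipeline.

A single :class:`RunConfig` carries every tunable constant of the analysis:
the temporal smoothing width, the three trace-classification thresholds, the
trace sampling size, the component-area gates used for the cell census, the
lifetime levels, the RNG seed and the pixel connectivity. Defaults follow the
published protocol for PMA-stimulated neutrophils imaged every 15 minutes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of one analysis run.

    Parameters
    ----------
    smoothing_sigma : float
        Width (in frames) of the temporal Gaussian applied to every pixel
        trace. ``0`` disables smoothing.
    rescaled_max_threshold : float
        A pixel can only be netotic or necrotic when the maximum of its
        background-rescaled trace strictly exceeds this value.
    time_fraction_threshold : float
        Fraction of post-extremum steps that must be strictly increasing
        (necrotic rule) or strictly decreasing (netotic rule).
    final_fraction_threshold : float
        Necrotic pixels must end above this fraction of their trace maximum.
    n_sample_pixels : int
        Number of netotic pixels sampled for the kinetic summary curves.
    kernel_area_bounds : (int, int)
        Inclusive pixel-area gate for valid nuclei in the Hoechst/DAPI
        channel at frame 0.
    necrotic_area_bounds : (int, int)
        Inclusive pixel-area gate for valid necrotic components.
    lifetime_fractions : sequence of float
        Levels the normalized curves must decay to from 1; the first default
        (0.5) is the reported NET half-life, the second (0.2) the
        80%-lifetime.
    seed : int
        Seed for every stochastic step (trace sampling).
    connectivity : {4, 8}
        Pixel connectivity used for connected components.
    """

    smoothing_sigma: float = 1.0
    rescaled_max_threshold: float = 5.0
    time_fraction_threshold: float = 0.5
    final_fraction_threshold: float = 0.9
    n_sample_pixels: int = 1000
    kernel_area_bounds: tuple[int, int] = (1000, 4000)
    necrotic_area_bounds: tuple[int, int] = (5000, 10000)
    lifetime_fractions: tuple[float, ...] = (0.5, 0.2)
    seed: int = 0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.rescaled_max_threshold <= 0:
            raise ValueError("rescaled_max_threshold must be > 0")
        for name in ("time_fraction_threshold", "final_fraction_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_sample_pixels < 1:
            raise ValueError("n_sample_pixels must be >= 1")
        for name in ("kernel_area_bounds", "necrotic_area_bounds"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi:
                raise ValueError(f"{name} must satisfy 0 <= min < max, got {(lo, hi)}")
            setattr(self, name, (int(lo), int(hi)))
        fr = tuple(float(f) for f in self.lifetime_fractions)
        if not fr or any(not 0.0 < f < 1.0 for f in fr):
            raise ValueError("lifetime_fractions must be proportions in (0, 1)")
        self.lifetime_fractions = fr
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        self.seed = int(self.seed)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel_area_bounds"] = list(d["kernel_area_bounds"])
        d["necrotic_area_bounds"] = list(d["necrotic_area_bounds"])
        d["lifetime_fractions"] = list(d["lifetime_fractions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("kernel_area_bounds", "necrotic_area_bounds", "lifetime_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)
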