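"""Seeded two-channel synthetic time-lapse videos with known ground truth.

The generator emulates one microscope field of view of PMA-stimulated
neutrophils imaged every 15 minutes for 10-15 hours: a Hoechst/DAPI channel
showing all nuclei from frame 0, and a Sytox channel in which

* *netotic* cells light up over a NET-sized footprint after an onset time,
  rise to a peak and then decay exponentially with a configurable half-life
  (NET release followed by dispersal/degradation);
* *necrotic* cells light up over a large lysed footprint, rise quickly to
  90% of their amplitude and then creep monotonically to 100% by the final
  frame (DNA stays in place, the signal plateaus);
* *quiescent* cells appear only in the DAPI channel.

Background pixels carry ``background_level`` plus additive Gaussian noise
clipped at zero, every frame is multiplied by a per-frame drift factor, and
all randomness derives from a single seed, so identical scenes give
bit-identical stacks. Footprints are rasterized disks; nucleus areas target
the 1000-4000 px census gate and necrotic footprints the 5000-10000 px
gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk

from .io import BACKGROUND, NECROTIC, NETOTIC, VideoStack

__all__ = [
    "CellSpec",
    "SyntheticScene",
    "SceneCounts",
    "GroundTruth",
    "drift_profile",
    "generate_video",
    "random_scene",
]

KINDS = ("netotic", "necrotic", "quiescent")


@dataclass
class CellSpec:
    """One simulated cell.

    ``kernel_area`` is the nucleus footprint (DAPI); ``lysed_area`` the
    post-lysis Sytox footprint (NET extent for netotic cells, swollen lysed
    cell for necrotic ones). ``peak_amplitude`` is the background-rescaled
    peak, i.e. the trace maximum in multiples of the background level.
    """

    kind: str
    center: tuple[int, int]
    kernel_area: float
    lysed_area: float | None = None
    onset_time: float = 60.0  # minutes
    peak_amplitude: float = 8.0  # x background
    decay_half_life: float | None = None  # minutes, netotic only

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kernel_area <= 0:
            raise ValueError("kernel_area must be > 0")
        if self.kind != "quiescent":
            if self.lysed_area is None or self.lysed_area <= 0:
                raise ValueError(f"{self.kind} cells need a positive lysed_area")
            if self.peak_amplitude <= 1:
                raise ValueError("peak_amplitude must exceed 1 (the background)")
        if self.kind == "netotic":
            if self.decay_half_life is None or self.decay_half_life <= 0:
                raise ValueError("netotic cells need decay_half_life > 0")

    @property
    def sytox_area(self) -> float:
        return self.kernel_area if self.kind == "quiescent" else float(self.lysed_area)


@dataclass
class SyntheticScene:
    """Layout and acquisition parameters of one simulated field of view."""

    height: int
    width: int
    n_frames: int
    cells: list[CellSpec] = field(default_factory=list)
    frame_interval: float = 15.0  # minutes
    background_level: float = 100.0
    background_noise_sd: float = 5.0
    drift_curve: np.ndarray | None = None  # per-frame multiplicative scalar
    seed: int = 0
    rise_duration: float = 30.0  # minutes from onset to peak
    dapi_amplitude: float = 6.0  # nucleus brightness, x background
    overlap_tolerance: int = 0  # tolerated overlapping pixels

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.background_level <= 0:
            raise ValueError("background_level must be > 0")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if self.drift_curve is not None:
            self.drift_curve = np.asarray(self.drift_curve, dtype=float)
            if self.drift_curve.shape != (self.n_frames,):
                raise ValueError(
                    f"drift_curve must have length n_frames={self.n_frames}, "
                    f"got {self.drift_curve.shape}"
                )
            if np.any(self.drift_curve <= 0):
                raise ValueError("all drift factors must be > 0")
        duration = self.frame_interval * (self.n_frames - 1)
        for cell in self.cells:
            if not 0 <= cell.onset_time < duration:
                raise ValueError(
                    f"onset_time {cell.onset_time} outside video span [0, {duration})"
                )

    @property
    def times(self) -> np.ndarray:
        return self.frame_interval * np.arange(self.n_frames, dtype=float)


@dataclass
class SceneCounts:
    initial_cells: int
    necrotic: int
    netotic: int
    quiescent: int = 0


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    class_map: np.ndarray  # (H, W) labels over {0, 1, 2}
    counts: SceneCounts
    half_lives: list[float]  # per netotic cell, minutes
    netotic_mask: np.ndarray  # (H, W) boolean, the true netotic pixel set
    netotic_areas: list[int]  # rasterized per-NET areas, px
    necrotic_areas: list[int]
    kernel_areas: list[int]


def drift_profile(kind: str, n_frames: int, magnitude: float = 0.0) -> np.ndarray:
    """Per-frame multiplicative intensity drift.

    ``none`` gives all ones; ``linear`` ramps from ``1-magnitude`` to
    ``1+magnitude``; ``sinusoid`` oscillates within the same band. Values
    stay in ``[1-magnitude, 1+magnitude]``; magnitude must be < 1 so all
    factors remain positive.
    """
    if not 0.0 <= magnitude < 1.0:
        raise ValueError(f"magnitude must lie in [0, 1), got {magnitude}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if kind == "none":
        return np.ones(n_frames)
    if kind == "linear":
        return np.linspace(1.0 - magnitude, 1.0 + magnitude, n_frames)
    if kind == "sinusoid":
        t = np.arange(n_frames, dtype=float)
        return 1.0 + magnitude * np.sin(2.0 * np.pi * t / max(n_frames, 2))
    raise ValueError(f"unknown drift kind {kind!r}")


def _disk_footprint(center: tuple[int, int], area: float, shape: tuple[int, int]):
    """Rasterize a disk of the requested area fully inside ``shape``."""
    radius = math.sqrt(area / math.pi)
    r, c = center
    H, W = shape
    if not (radius <= r <= H - 1 - radius and radius <= c <= W - 1 - radius):
        raise ValueError(
            f"footprint (center {center}, radius {radius:.1f}) extends outside "
            f"the {H}x{W} frame"
        )
    return draw_disk((r, c), radius, shape=shape)


def _sytox_profile(cell: CellSpec, times: np.ndarray, rise_duration: float) -> np.ndarray:
    """Unit-amplitude Sytox time course of one cell (0 before onset, 1 at
    peak)."""
    f = np.zeros_like(times)
    onset = cell.onset_time
    peak_t = onset + rise_duration
    rising = (times >= onset) & (times < peak_t)
    f[rising] = (times[rising] - onset) / rise_duration
    after = times >= peak_t
    if cell.kind == "netotic":
        f[after] = 2.0 ** (-(times[after] - peak_t) / cell.decay_half_life)
    elif cell.kind == "necrotic":
        # fast rise to 90% of amplitude, then a monotone creep to 100% at the
        # final frame: the plateau stays above 90% of the maximum throughout
        # and remains strictly increasing, as slowly lysing cells keep
        # accumulating dye.
        f[rising] *= 0.9
        span = times[-1] - peak_t
        if span > 0:
            f[after] = 0.9 + 0.1 * (times[after] - peak_t) / span
        else:
            f[after] = 0.9
    return f


def generate_video(scene: SyntheticScene) -> tuple[VideoStack, VideoStack, GroundTruth]:
    """Render a scene into (DAPI stack, Sytox stack, ground truth).

    The RNG is fully determined by ``scene.seed``: the same scene yields
    bit-identical stacks. Raises if Sytox footprints overlap beyond
    ``scene.overlap_tolerance`` (ground-truth classes must be unambiguous).
    """
    H, W, T = scene.height, scene.width, scene.n_frames
    times = scene.times
    rng = np.random.default_rng(scene.seed)
    drift = (
        scene.drift_curve if scene.drift_curve is not None else np.ones(T)
    )

    class_map = np.zeros((H, W), dtype=np.uint8)
    occupancy = np.zeros((H, W), dtype=np.int32)
    sytox = np.full((T, H, W), scene.background_level, dtype=float)
    dapi = np.full((T, H, W), scene.background_level, dtype=float)

    half_lives: list[float] = []
    netotic_areas: list[int] = []
    necrotic_areas: list[int] = []
    kernel_areas: list[int] = []
    n_net = n_nec = n_qui = 0

    for cell in scene.cells:
        kr, kc = _disk_footprint(cell.center, cell.kernel_area, (H, W))
        kernel_areas.append(len(kr))
        dapi[:, kr, kc] = scene.background_level * scene.dapi_amplitude

        if cell.kind == "quiescent":
            occupancy[kr, kc] += 1
            n_qui += 1
            continue

        fr, fc = _disk_footprint(cell.center, cell.lysed_area, (H, W))
        occupancy[fr, fc] += 1
        amplitude = (cell.peak_amplitude - 1.0) * scene.background_level
        profile = _sytox_profile(cell, times, scene.rise_duration)
        sytox[:, fr, fc] += amplitude * profile[:, None]
        if cell.kind == "netotic":
            class_map[fr, fc] = NETOTIC
            half_lives.append(float(cell.decay_half_life))
            netotic_areas.append(len(fr))
            n_net += 1
        else:
            class_map[fr, fc] = NECROTIC
            necrotic_areas.append(len(fr))
            n_nec += 1

    n_overlap = int((occupancy > 1).sum())
    if n_overlap > scene.overlap_tolerance:
        raise ValueError(
            f"{n_overlap} overlapping footprint pixels exceed the tolerance "
            f"({scene.overlap_tolerance}); ground-truth classes would be ambiguous"
        )

    if scene.background_noise_sd > 0:
        sytox += rng.normal(0.0, scene.background_noise_sd, sytox.shape)
        dapi += rng.normal(0.0, scene.background_noise_sd, dapi.shape)
    np.clip(sytox, 0.0, None, out=sytox)
    np.clip(dapi, 0.0, None, out=dapi)
    sytox *= drift[:, None, None]
    dapi *= drift[:, None, None]

    truth = GroundTruth(
        class_map=class_map,
        counts=SceneCounts(
            initial_cells=len(scene.cells),
            necrotic=n_nec,
            netotic=n_net,
            quiescent=n_qui,
        ),
        half_lives=half_lives,
        netotic_mask=class_map == NETOTIC,
        netotic_areas=netotic_areas,
        necrotic_areas=necrotic_areas,
        kernel_areas=kernel_areas,
    )
    dapi_stack = VideoStack(
        data=dapi, frame_interval=scene.frame_interval, channel_name="hoechst"
    )
    sytox_stack = VideoStack(
        data=sytox, frame_interval=scene.frame_interval, channel_name="sytox"
    )
    return dapi_stack, sytox_stack, truth


def random_scene(
    n_netotic: int = 3,
    n_necrotic: int = 2,
    n_quiescent: int = 0,
    height: int = 256,
    width: int = 256,
    n_frames: int = 61,
    frame_interval: float = 15.0,
    decay_half_life: float = 360.0,
    seed: int = 0,
    background_level: float = 100.0,
    background_noise_sd: float = 5.0,
    drift_curve: np.ndarray | None = None,
    onset_range: tuple[float, float] = (45.0, 120.0),
    rise_duration: float = 30.0,
    peak_amplitude_range: tuple[float, float] = (7.0, 9.0),
    kernel_area_range: tuple[float, float] = (1500.0, 3500.0),
    netotic_area_range: tuple[float, float] = (2000.0, 4500.0),
    necrotic_area_range: tuple[float, float] = (5500.0, 9500.0),
    margin: int = 4,
) -> SyntheticScene:
    """Place non-overlapping cells at random and return the scene.

    All areas sit inside the census gates with margin for rasterization.
    Every netotic cell in the scene shares ``decay_half_life``: a scene
    stands for one field of view of one experimental condition. Placement
    uses rejection sampling; a scene too crowded to place raises.
    """
    rng = np.random.default_rng(seed)
    kinds = (
        ["netotic"] * n_netotic + ["necrotic"] * n_necrotic + ["quiescent"] * n_quiescent
    )
    placed: list[tuple[float, float, float]] = []  # row, col, radius
    cells: list[CellSpec] = []
    for kind in kinds:
        kernel_area = float(rng.uniform(*kernel_area_range))
        if kind == "netotic":
            area = float(rng.uniform(*netotic_area_range))
        elif kind == "necrotic":
            area = float(rng.uniform(*necrotic_area_range))
        else:
            area = kernel_area
        radius = math.sqrt(area / math.pi)
        lo_r, hi_r = radius + margin, height - 1 - radius - margin
        lo_c, hi_c = radius + margin, width - 1 - radius - margin
        if lo_r >= hi_r or lo_c >= hi_c:
            raise ValueError(f"field {height}x{width} too small for a {area:.0f}-px footprint")
        for _ in range(20000):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all(
                math.hypot(r - pr, c - pc) >= radius + prad + margin
                for pr, pc, prad in placed
            ):
                placed.append((r, c, radius))
                break
        else:
            raise RuntimeError(
                f"could not place {len(placed) + 1} footprints in a "
                f"{height}x{width} field; reduce cell count or size"
            )
        cells.append(
            CellSpec(
                kind=kind,
                center=(int(round(r)), int(round(c))),
                kernel_area=kernel_area,
                lysed_area=None if kind == "quiescent" else area,
                onset_time=float(rng.uniform(*onset_range)),
                peak_amplitude=float(rng.uniform(*peak_amplitude_range)),
                decay_half_life=decay_half_life if kind == "netotic" else None,
            )
        )
    return SyntheticScene(
        height=height,
        width=width,
        n_frames=n_frames,
        cells=cells,
        frame_interval=frame_interval,
        background_level=background_level,
        background_noise_sd=background_noise_sd,
        drift_curve=drift_curve,
        seed=seed,
        rise_duration=rise_duration,
    )
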