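"""Cell census and net span.

The initial number of cells in a field of view is counted from the first
Hoechst/DAPI frame: Otsu threshold, connected components, and an inclusive
area gate (1000-4000 px) selecting valid cell kernels. Necrotic cells are
counted from the necrotic region of the pixel class map with a 5000-10000 px
gate. Under the simplifying assumption that every initial cell resolves to
either NETosis or necrosis, the netotic count is the difference. The net
span divides the total netotic pixel coverage by that count — a deliberate
underestimate of the per-cell NET extent, since NETs overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .classify import PixelClassMap
from .config import RunConfig
from .io import NECROTIC, NETOTIC, VideoStack

__all__ = [
    "CellCounts",
    "NetSpan",
    "count_components",
    "initial_cell_count",
    "necrotic_cell_count",
    "cell_counts",
    "net_span",
]

log = logging.getLogger(__name__)


@dataclass
class CellCounts:
    initial_cells: int
    necrotic_cells: int
    netotic_cells: int

    def __post_init__(self) -> None:
        if min(self.initial_cells, self.necrotic_cells, self.netotic_cells) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class NetSpan:
    total_net_area: int  # px labelled netotic
    span_per_cell: float  # px per netotic cell
    underestimate: bool = True  # overlapping NETs are not apportioned


def count_components(
    binary: np.ndarray,
    area_bounds: tuple[int, int],
    connectivity: int = 8,
) -> int:
    """Number of connected components whose pixel area lies within the
    inclusive ``area_bounds``. An empty mask counts 0."""
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {binary.shape}")
    lo, hi = area_bounds
    if not 0 <= lo < hi:
        raise ValueError(f"invalid area bounds {area_bounds}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if not binary.any():
        return 0
    labels = cc_label(binary, connectivity=1 if connectivity == 4 else 2)
    areas = np.bincount(labels.ravel())[1:]
    areas = areas[areas > 0]
    inside = (areas >= lo) & (areas <= hi)
    n_out = int((~inside).sum())
    if n_out:
        log.info("%d component(s) outside the area gate %s", n_out, area_bounds)
    return int(inside.sum())


def initial_cell_count(dapi: VideoStack, cfg: RunConfig | None = None) -> int:
    """Count valid cell kernels in the first DAPI frame (Otsu foreground,
    kernel area gate)."""
    cfg = cfg or RunConfig()
    frame = np.asarray(dapi.data[0], dtype=float)
    if frame.min() == frame.max():
        raise ValueError("degenerate first DAPI frame: zero intensity range")
    mask = frame > threshold_otsu(frame)
    return count_components(mask, cfg.kernel_area_bounds, cfg.connectivity)


def necrotic_cell_count(labels: PixelClassMap | np.ndarray, cfg: RunConfig | None = None) -> int:
    """Count valid necrotic components of the pixel class map."""
    cfg = cfg or RunConfig()
    arr = labels.labels if isinstance(labels, PixelClassMap) else np.asarray(labels)
    return count_components(arr == NECROTIC, cfg.necrotic_area_bounds, cfg.connectivity)


def cell_counts(
    dapi: VideoStack,
    labels: PixelClassMap | np.ndarray,
    cfg: RunConfig | None = None,
) -> CellCounts:
    """Initial / necrotic / netotic census of one field of view.

    ``netotic = initial - necrotic``, floored at 0 with a warning when noise
    makes the necrotic count exceed the initial one.
    """
    cfg = cfg or RunConfig()
    initial = initial_cell_count(dapi, cfg)
    necrotic = necrotic_cell_count(labels, cfg)
    netotic = initial - necrotic
    if netotic < 0:
        log.warning(
            "necrotic count (%d) exceeds initial count (%d); flooring netotic at 0",
            necrotic,
            initial,
        )
        netotic = 0
    return CellCounts(initial_cells=initial, necrotic_cells=necrotic, netotic_cells=netotic)


def net_span(labels: PixelClassMap | np.ndarray, counts: CellCounts) -> NetSpan:
    """Total netotic coverage divided by the estimated netotic cell count."""
    if counts.netotic_cells <= 0:
        raise ValueError("net span undefined: zero estimated netotic cells")
    arr = labels.labels if isinstance(labels, PixelClassMap) else np.asarray(labels)
    total = int((arr == NETOTIC).sum())
    return NetSpan(total_net_area=total, span_per_cell=total / counts.netotic_cells)
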