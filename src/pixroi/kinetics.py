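"""NET degradation kinetics: netotic trace sampling, peak alignment,
normalization, median/quartile summary curves, 50%/80%-lifetimes and the
endpoint NET-area measurement.

The kinetic analysis works on *raw smoothed* Sytox traces (the
background-rescaled signal is used only for classification). A fixed number
of pixels labelled netotic (default 1000) is sampled uniformly without
replacement; each trace is aligned to its peaking time so that degradation
can be compared across cells that underwent NETosis at different moments,
normalized between 0 (minimal value before the peak) and 1 (the peak), and
summarized pointwise by the median and the 25%/75% quartile curves. The
reported NET half-life of a field of view is the time the normalized median
curve needs to fall from 1 to 0.5; the 80%-lifetime is the fall to 0.2.
Level crossings are linearly interpolated between frames; curves that never
reach a level are reported censored, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .classify import PixelClassMap
from .config import RunConfig
from .io import NETOTIC, VideoStack

__all__ = [
    "TraceSet",
    "SummaryCurves",
    "LifetimeResult",
    "sample_netotic",
    "normalize_traces",
    "align_and_summarize",
    "lifetime",
    "half_life_report",
    "net_area_endpoint",
    "DecayKinetics",
]

log = logging.getLogger(__name__)


@dataclass
class TraceSet:
    """Sampled per-pixel Sytox time series with their peaking times."""

    traces: np.ndarray  # (n, T)
    pixel_coords: np.ndarray  # (n, 2) row, col
    peak_times: np.ndarray  # (n,) frame index of each trace's (earliest) max
    frame_interval: float
    seed: int = 0
    n_requested: int = 0
    exhausted: bool = False  # fewer netotic pixels than requested
    normalized: bool = False

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0]


@dataclass
class SummaryCurves:
    """Peak-aligned pointwise median/Q1/Q3 curves on a relative time axis."""

    time_axis: np.ndarray  # minutes relative to peak
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    coverage: np.ndarray  # traces contributing to each time point
    normalized: bool = False
    frame_interval: float = 15.0

    def from_peak(self) -> "SummaryCurves":
        """The post-peak part of the curves (relative time >= 0)."""
        keep = self.time_axis >= 0
        return SummaryCurves(
            time_axis=self.time_axis[keep],
            median=self.median[keep],
            q1=self.q1[keep],
            q3=self.q3[keep],
            coverage=self.coverage[keep],
            normalized=self.normalized,
            frame_interval=self.frame_interval,
        )


@dataclass
class LifetimeResult:
    """Time for the normalized curves to decay from 1 to a target level.

    ``fraction=0.5`` reports the 50%-lifetime (the half-life) and
    ``fraction=0.2`` the 80%-lifetime of the median, Q1 and Q3 curves, in
    minutes from the peak. A curve that never reaches the level within the
    observation span is censored; ``observed_span`` records how long it was
    followed.
    """

    fraction: float
    lifetime_median: float | None
    lifetime_q1: float | None
    lifetime_q3: float | None
    censored_median: bool
    censored_q1: bool
    censored_q3: bool
    observed_span: float  # minutes of post-peak observation


def sample_netotic(
    smoothed: VideoStack,
    labels: PixelClassMap | np.ndarray,
    n: int = 1000,
    seed: int = 0,
) -> TraceSet:
    """Sample up to ``n`` netotic pixels uniformly without replacement and
    collect their raw (unscaled, smoothed) Sytox traces and peaking times."""
    label_arr = labels.labels if isinstance(labels, PixelClassMap) else np.asarray(labels)
    coords = np.argwhere(label_arr == NETOTIC)
    if coords.shape[0] == 0:
        raise ValueError("no NETs detected: zero pixels classified as netotic")
    rng = np.random.default_rng(seed)
    exhausted = coords.shape[0] < n
    if exhausted:
        log.warning(
            "only %d netotic pixels available, %d requested: taking all",
            coords.shape[0],
            n,
        )
        chosen = coords
    else:
        idx = rng.choice(coords.shape[0], size=n, replace=False)
        chosen = coords[idx]
    traces = smoothed.data[:, chosen[:, 0], chosen[:, 1]].T.astype(float)
    peak_times = np.argmax(traces, axis=1)  # earliest on ties
    return TraceSet(
        traces=traces,
        pixel_coords=chosen,
        peak_times=peak_times,
        frame_interval=smoothed.frame_interval,
        seed=seed,
        n_requested=n,
        exhausted=exhausted,
    )


def normalize_traces(ts: TraceSet) -> TraceSet:
    """Normalize each trace between 0 (minimal value before its peak) and 1
    (its maximum): ``y' = (y - min_prepeak) / (max - min_prepeak)``.

    Post-peak values may map below 0 (no clipping). Flat traces
    (max == min_prepeak) are dropped with a logged count; all traces flat is
    an error.
    """
    n, T = ts.traces.shape
    idx = np.arange(T)[None, :]
    prepeak = idx <= ts.peak_times[:, None]
    min_prepeak = np.where(prepeak, ts.traces, np.inf).min(axis=1)
    max_val = np.take_along_axis(ts.traces, ts.peak_times[:, None], axis=1)[:, 0]
    denom = max_val - min_prepeak
    keep = denom > 0
    n_flat = int((~keep).sum())
    if n_flat == n:
        raise ValueError("all traces are flat; nothing to normalize")
    if n_flat:
        log.info("dropping %d flat trace(s) before normalization", n_flat)
    traces = (ts.traces[keep] - min_prepeak[keep, None]) / denom[keep, None]
    return TraceSet(
        traces=traces,
        pixel_coords=ts.pixel_coords[keep],
        peak_times=ts.peak_times[keep],
        frame_interval=ts.frame_interval,
        seed=ts.seed,
        n_requested=ts.n_requested,
        exhausted=ts.exhausted,
        normalized=True,
    )


def align_and_summarize(ts: TraceSet, min_coverage: float = 0.25) -> SummaryCurves:
    """Shift each trace so its peak sits at relative time 0 and summarize
    pointwise by median/Q1/Q3 over the traces covering each relative time.

    Relative times covered by fewer than ``min_coverage`` of the traces are
    trimmed, so the quartiles are never computed from a handful of
    outlier-length traces.
    """
    n, T = ts.traces.shape
    if n == 0:
        raise ValueError("empty trace set")
    p_max = int(ts.peak_times.max())
    p_min = int(ts.peak_times.min())
    offsets = np.arange(-p_max, T - p_min)  # relative frame indices
    L = offsets.size
    grid = np.full((n, L), np.nan)
    for i in range(n):
        start = p_max - int(ts.peak_times[i])
        grid[i, start : start + T] = ts.traces[i]

    coverage = np.sum(~np.isnan(grid), axis=0)
    keep = coverage >= max(1.0, min_coverage * n)
    grid = grid[:, keep]
    offsets = offsets[keep]
    coverage = coverage[keep]

    median = np.nanmedian(grid, axis=0)
    q1 = np.nanpercentile(grid, 25, axis=0)
    q3 = np.nanpercentile(grid, 75, axis=0)
    return SummaryCurves(
        time_axis=offsets * ts.frame_interval,
        median=median,
        q1=q1,
        q3=q3,
        coverage=coverage,
        normalized=ts.normalized,
        frame_interval=ts.frame_interval,
    )


def lifetime(
    curve: np.ndarray,
    level: float,
    frame_interval: float,
) -> float | None:
    """Minutes from the peak until a peak-normalized curve first decays to
    ``level``, linearly interpolated between the bracketing frames.

    The curve must start at its maximum (relative time 0 = the peak).
    Returns ``None`` when the level is never reached within the curve
    (censored).
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1 or curve.size < 1:
        raise ValueError("curve must be a nonempty 1-D array")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    if curve[0] < np.nanmax(curve) - 1e-9:
        raise ValueError("curve is not peaked at relative time 0")
    below = np.where(curve <= level)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return 0.0
    y0, y1 = curve[i - 1], curve[i]
    frac = (y0 - level) / (y0 - y1)  # y0 > level >= y1, so y0 > y1
    return float((i - 1 + frac) * frame_interval)


def half_life_report(
    curves: SummaryCurves, cfg: RunConfig | None = None
) -> list[LifetimeResult]:
    """Apply :func:`lifetime` at each configured fraction to the normalized
    median, Q1 and Q3 curves; one :class:`LifetimeResult` per fraction."""
    cfg = cfg or RunConfig()
    if not curves.normalized:
        raise ValueError("half_life_report needs normalized summary curves")
    post = curves.from_peak()
    if post.time_axis.size == 0 or post.time_axis[0] != 0:
        raise ValueError("curves do not cover relative time 0 (the peak)")
    span = float(post.time_axis[-1])
    results = []
    for fraction in cfg.lifetime_fractions:
        # the configured fraction is the target level: decay from 1 to .5 or .2
        level = float(fraction)
        lt = {
            name: lifetime(curve, level, curves.frame_interval)
            for name, curve in (("median", post.median), ("q1", post.q1), ("q3", post.q3))
        }
        results.append(
            LifetimeResult(
                fraction=level,
                lifetime_median=lt["median"],
                lifetime_q1=lt["q1"],
                lifetime_q3=lt["q3"],
                censored_median=lt["median"] is None,
                censored_q1=lt["q1"] is None,
                censored_q3=lt["q3"] is None,
                observed_span=span,
            )
        )
    return results


def net_area_endpoint(frame: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Per-component Sytox-positive areas of a single frame, in pixels.

    Otsu threshold -> binary mask -> connected components: the endpoint
    NET-area distribution (the assay quantified at minute 200). Invariant to
    global intensity scaling of the frame.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {frame.shape}")
    if frame.min() == frame.max():
        raise ValueError("degenerate frame: zero intensity range")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = frame > threshold_otsu(frame)
    labels = cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    areas = np.bincount(labels.ravel())[1:]
    return areas[areas > 0]


class DecayKinetics(BaseEstimator):
    """Summary-curve and lifetime estimator over netotic pixel traces.

    ``fit`` takes an ``(n_traces, n_frames)`` matrix of raw smoothed Sytox
    traces (rows are sampled netotic pixels), aligns them at their peaks,
    normalizes, and exposes the summary curves and lifetimes as fitted
    attributes; ``half_life_`` is the 50%-lifetime of the normalized median
    curve, the per-field-of-view headline number.
    """

    def __init__(
        self,
        frame_interval: float = 15.0,
        fractions: tuple[float, ...] = (0.5, 0.2),
        min_coverage: float = 0.25,
    ):
        self.frame_interval = frame_interval
        self.fractions = fractions
        self.min_coverage = min_coverage

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError(f"expected (n_traces, n_frames>=2), got {X.shape}")
        n = X.shape[0]
        ts = TraceSet(
            traces=X,
            pixel_coords=np.zeros((n, 2), dtype=int),
            peak_times=np.argmax(X, axis=1),
            frame_interval=self.frame_interval,
            n_requested=n,
        )
        norm = normalize_traces(ts)
        self.curves_raw_ = align_and_summarize(ts, self.min_coverage)
        self.curves_norm_ = align_and_summarize(norm, self.min_coverage)
        cfg = RunConfig(lifetime_fractions=tuple(self.fractions))
        self.lifetimes_ = half_life_report(self.curves_norm_, cfg)
        self.half_life_ = self.lifetimes_[0].lifetime_median
        self.n_features_in_ = X.shape[1]
        return self

    def score(self, X=None, y=None):  # pragma: no cover - convenience only
        check_is_fitted(self, "half_life_")
        return 0.0 if self.half_life_ is None else -self.half_life_
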