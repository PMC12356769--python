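"""The pixROI three-class per-pixel classifier.

Each pixel of the Sytox channel is assigned to one of three regions of
interest from the *shape* of its background-rescaled trace alone:

* **necrotic** — the rescaled maximum strictly exceeds the gate (default 5),
  the trace spends more than half of the steps after its minimum strictly
  increasing, and it ends above 90% of its maximum: the signal rises and
  plateaus, as for a lysed cell whose DNA stays put.
* **netotic** — the rescaled maximum exceeds the gate, the trace spends more
  than half of the steps after its maximum strictly decreasing, and it ends
  below its maximum: the signal peaks and decays, as for a NET that spreads
  and is degraded.
* **background** — everything else.

The necrotic rule is tested first: a high plateau can satisfy both rules
(a final value can be below the maximum yet above 90% of it) and the
plateau reading wins. Increasing/decreasing time is measured on the signs
of the discrete derivative; zero-derivative steps count only in the
denominator; an extremum on the last frame leaves an empty window and a
fraction of 0. Ties in argmax/argmin resolve to the earliest frame.

:class:`PixROIClassifier` is the vectorized implementation over trace
matrices; :func:`oracle_classify` is a deliberately naive per-pixel
transliteration of the same rules kept for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import RunConfig
from .io import BACKGROUND, NECROTIC, NETOTIC
from .preprocess import RescaledStack

__all__ = [
    "TraceFeatures",
    "trace_features",
    "classify_trace",
    "PixROIClassifier",
    "PixelClassMap",
    "classify_stack",
    "oracle_classify",
]


@dataclass
class PixelClassMap:
    """H x W label field over {background=0, netotic=1, necrotic=2} plus the
    configuration snapshot that produced it."""

    labels: np.ndarray
    params: RunConfig

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"label map must be 2-D, got {self.labels.shape}")

    def class_counts(self) -> dict[str, int]:
        return {
            "background": int((self.labels == BACKGROUND).sum()),
            "netotic": int((self.labels == NETOTIC).sum()),
            "necrotic": int((self.labels == NECROTIC).sum()),
        }


@dataclass
class TraceFeatures:
    """Shape summary of one rescaled trace."""

    max_val: float
    min_val: float
    argmax_t: int
    argmin_t: int
    final_val: float
    frac_increasing_after_min: float
    frac_decreasing_after_max: float


def trace_features(trace) -> TraceFeatures:
    """Compute the classification features of a single trace.

    The discrete derivative is ``d[t] = x[t+1] - x[t]``;
    ``frac_increasing_after_min`` is the share of steps at or after the
    (earliest) minimum with ``d > 0``, and symmetrically for the maximum
    with ``d < 0``. An extremum on the last frame yields 0.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("trace must be 1-D with length >= 2")
    T = x.size
    argmax_t = int(np.argmax(x))
    argmin_t = int(np.argmin(x))
    d = np.diff(x)

    steps_after_min = T - 1 - argmin_t
    steps_after_max = T - 1 - argmax_t
    frac_inc = (
        float(np.count_nonzero(d[argmin_t:] > 0)) / steps_after_min
        if steps_after_min > 0
        else 0.0
    )
    frac_dec = (
        float(np.count_nonzero(d[argmax_t:] < 0)) / steps_after_max
        if steps_after_max > 0
        else 0.0
    )
    return TraceFeatures(
        max_val=float(x[argmax_t]),
        min_val=float(x[argmin_t]),
        argmax_t=argmax_t,
        argmin_t=argmin_t,
        final_val=float(x[-1]),
        frac_increasing_after_min=frac_inc,
        frac_decreasing_after_max=frac_dec,
    )


def classify_trace(f: TraceFeatures, cfg: RunConfig | None = None) -> int:
    """Apply the three-class criteria to one trace's features.

    All comparisons are strict; the necrotic rule has precedence. Total
    function: anything not necrotic or netotic is background.
    """
    cfg = cfg or RunConfig()
    gate = f.max_val > cfg.rescaled_max_threshold
    if (
        gate
        and f.frac_increasing_after_min > cfg.time_fraction_threshold
        and f.final_val > cfg.final_fraction_threshold * f.max_val
    ):
        return NECROTIC
    if (
        gate
        and f.frac_decreasing_after_max > cfg.time_fraction_threshold
        and f.final_val < f.max_val
    ):
        return NETOTIC
    return BACKGROUND


class PixROIClassifier(ClassifierMixin, BaseEstimator):
    """Vectorized trace-shape classifier over an (n_pixels, n_frames) matrix.

    Rule-based: ``fit`` only records the trace length and the class set;
    ``predict`` applies the criteria. Parameters mirror the corresponding
    :class:`~pixroi.config.RunConfig` thresholds.
    """

    def __init__(
        self,
        rescaled_max_threshold: float = 5.0,
        time_fraction_threshold: float = 0.5,
        final_fraction_threshold: float = 0.9,
    ):
        self.rescaled_max_threshold = rescaled_max_threshold
        self.time_fraction_threshold = time_fraction_threshold
        self.final_fraction_threshold = final_fraction_threshold

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError(f"expected (n_pixels, n_frames>=2), got shape {X.shape}")
        self.classes_ = np.array([BACKGROUND, NETOTIC, NECROTIC])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError(f"expected (n_pixels, n_frames>=2), got shape {X.shape}")
        n, T = X.shape

        argmax_t = np.argmax(X, axis=1)  # earliest on ties
        argmin_t = np.argmin(X, axis=1)
        max_val = np.take_along_axis(X, argmax_t[:, None], axis=1)[:, 0]
        final_val = X[:, -1]

        d = np.diff(X, axis=1)  # (n, T-1)
        # suffix counts: pos_suffix[:, t] = #{s >= t : d[s] > 0}
        pos_suffix = np.cumsum((d > 0)[:, ::-1], axis=1)[:, ::-1]
        neg_suffix = np.cumsum((d < 0)[:, ::-1], axis=1)[:, ::-1]

        def _suffix_frac(suffix: np.ndarray, start: np.ndarray) -> np.ndarray:
            steps = (T - 1) - start
            idx = np.minimum(start, T - 2)
            count = np.take_along_axis(suffix, idx[:, None], axis=1)[:, 0]
            return np.where(steps > 0, count / np.maximum(steps, 1), 0.0)

        frac_inc = _suffix_frac(pos_suffix, argmin_t)
        frac_dec = _suffix_frac(neg_suffix, argmax_t)

        gate = max_val > self.rescaled_max_threshold
        necrotic = (
            gate
            & (frac_inc > self.time_fraction_threshold)
            & (final_val > self.final_fraction_threshold * max_val)
        )
        netotic = (
            ~necrotic
            & gate
            & (frac_dec > self.time_fraction_threshold)
            & (final_val < max_val)
        )
        labels = np.zeros(n, dtype=np.uint8)
        labels[netotic] = NETOTIC
        labels[necrotic] = NECROTIC
        return labels


def _as_trace_array(rescaled: RescaledStack | np.ndarray) -> np.ndarray:
    data = rescaled.data if isinstance(rescaled, RescaledStack) else np.asarray(rescaled)
    if data.ndim != 3:
        raise ValueError(f"rescaled stack must be (T, H, W), got {data.shape}")
    return data


def classify_stack(rescaled: RescaledStack | np.ndarray, cfg: RunConfig | None = None) -> PixelClassMap:
    """Classify every pixel of a background-rescaled stack."""
    cfg = cfg or RunConfig()
    data = _as_trace_array(rescaled)
    T, H, W = data.shape
    X = data.reshape(T, H * W).T
    clf = PixROIClassifier(
        rescaled_max_threshold=cfg.rescaled_max_threshold,
        time_fraction_threshold=cfg.time_fraction_threshold,
        final_fraction_threshold=cfg.final_fraction_threshold,
    ).fit(X)
    labels = clf.predict(X).reshape(H, W)
    return PixelClassMap(labels=labels, params=cfg)


def oracle_classify(rescaled: RescaledStack | np.ndarray, cfg: RunConfig | None = None) -> PixelClassMap:
    """Nested-loop reference implementation of :func:`classify_stack`.

    Slow by construction; exists so the vectorized path can be checked
    pixel-for-pixel against a plain transliteration of the criteria.
    """
    cfg = cfg or RunConfig()
    data = _as_trace_array(rescaled)
    T, H, W = data.shape
    labels = np.zeros((H, W), dtype=np.uint8)
    for r in range(H):
        for c in range(W):
            labels[r, c] = classify_trace(trace_features(data[:, r, c]), cfg)
    return PixelClassMap(labels=labels, params=cfg)
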