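"""Normalization stage: temporal smoothing, common-background estimation and
the background-rescaled signal.

Global contrast drift (lamp flicker, focus drift, outlier frames) moves every
pixel of a frame by a common multiplicative factor. The pipeline therefore
estimates a *common background* — pixels that were never part of a cell or a
NET, obtained by intersecting the below-Otsu-threshold regions of all
non-trivial frames — and divides each frame by the spatial mean of that
region. The resulting dimensionless, background-rescaled traces carry only
biological intensity changes and feed the per-pixel classifier; they are not
used by the kinetic analysis, which works on raw smoothed traces.

Estimators operate on matrices of per-pixel traces (n_pixels x n_frames), so
they compose with scikit-learn pipelines; the module-level functions wrap
them for whole :class:`~pixroi.io.VideoStack` videos.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import VideoStack

__all__ = [
    "TemporalSmoother",
    "BackgroundRescaler",
    "CommonBackground",
    "RescaledStack",
    "smooth_temporal",
    "estimate_common_background",
    "rescale",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# temporal smoothing
# ---------------------------------------------------------------------------
class TemporalSmoother(TransformerMixin, BaseEstimator):
    """Gaussian smoothing of each row of a trace matrix along time.

    Parameters
    ----------
    sigma : float
        Kernel width in frames; ``0`` is the identity. Reflect boundary.
    """

    def __init__(self, sigma: float = 1.0):
        self.sigma = sigma

    def fit(self, X, y=None):
        X = np.asarray(X)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        self.n_features_in_ = X.shape[-1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        if self.sigma == 0:
            return X.copy()
        return ndimage.gaussian_filter1d(X, self.sigma, axis=-1, mode="reflect")


def smooth_temporal(stack: VideoStack, sigma: float) -> VideoStack:
    """Smooth every pixel's time series with a Gaussian of width ``sigma``
    frames (reflect boundary); spatial content is untouched."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return stack.with_data(np.array(stack.data, dtype=float))
    data = ndimage.gaussian_filter1d(
        np.asarray(stack.data, dtype=float), sigma, axis=0, mode="reflect"
    )
    return stack.with_data(data)


# ---------------------------------------------------------------------------
# common background
# ---------------------------------------------------------------------------
@dataclass
class CommonBackground:
    """Pixels never part of a cell or a NET, plus the per-frame mean
    intensity over them (the time-variable scaling curve)."""

    mask: np.ndarray  # (H, W) or (n_pixels,) boolean
    mean_curve: np.ndarray  # (T,) positive
    n_trivial_frames: int = 0
    fallback_whole_frame: bool = False


@dataclass
class RescaledStack:
    """Dimensionless background-rescaled traces, ``(frame, row, col)``."""

    data: np.ndarray
    source: VideoStack | None = None


def _frame_is_trivial(
    values: np.ndarray,
    minority_fraction: float,
    separability: float,
) -> tuple[bool, float]:
    """Decide whether a frame carries a usable foreground/background split.

    A frame is trivial when it is constant, when the Otsu split leaves less
    than ``minority_fraction`` of the pixels on either side, or when Otsu's
    between-class separability (between-class variance over total variance,
    scale-invariant) falls below ``separability`` — i.e. the histogram is
    effectively unimodal, as in a frame containing only background noise.
    """
    vmin = values.min()
    vmax = values.max()
    if vmin == vmax:
        return True, float(vmin)
    thr = float(threshold_otsu(values))
    below = values < thr
    p0 = below.mean()
    if p0 < minority_fraction or p0 > 1.0 - minority_fraction:
        return True, thr
    mu0 = values[below].mean()
    mu1 = values[~below].mean()
    total_var = values.var()
    if total_var == 0:
        return True, thr
    eta = p0 * (1.0 - p0) * (mu1 - mu0) ** 2 / total_var
    return eta < separability, thr


class BackgroundRescaler(TransformerMixin, BaseEstimator):
    """Estimate the common background of a trace matrix and rescale by it.

    ``fit`` intersects the below-Otsu regions of all non-trivial frames
    (columns) into ``mask_`` and averages each frame over it into
    ``mean_curve_``; ``transform`` divides every trace by that curve.

    Parameters
    ----------
    minority_fraction : float
        An Otsu split leaving less than this fraction of pixels on either
        side marks the frame trivial.
    separability_threshold : float
        Minimum Otsu between-class separability (eta in [0, 1]) for a frame
        to count as non-trivial. Pure Gaussian noise scores ~0.64; genuinely
        bimodal frames score >0.9.
    eps_scale : float
        The mean curve is floored at ``eps_scale * max(X)`` to avoid
        division blow-ups on pathological inputs.
    """

    def __init__(
        self,
        minority_fraction: float = 0.01,
        separability_threshold: float = 0.75,
        eps_scale: float = 1e-6,
    ):
        self.minority_fraction = minority_fraction
        self.separability_threshold = separability_threshold
        self.eps_scale = eps_scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"expected (n_pixels, n_frames), got shape {X.shape}")
        n_pixels, n_frames = X.shape
        if n_frames < 2:
            raise ValueError("need at least 2 frames")

        mask = np.ones(n_pixels, dtype=bool)
        n_trivial = 0
        any_nonconstant = False
        for t in range(n_frames):
            col = X[:, t]
            if col.min() != col.max():
                any_nonconstant = True
            trivial, thr = _frame_is_trivial(
                col, self.minority_fraction, self.separability_threshold
            )
            if trivial:
                n_trivial += 1
                continue
            mask &= col < thr

        self.fallback_whole_frame_ = False
        if n_trivial == n_frames:
            if not any_nonconstant:
                raise ValueError(
                    "all frames are spatially constant; no background statistics "
                    "can be estimated from this video"
                )
            log.warning(
                "no frame showed a foreground/background split; treating the "
                "whole field as background"
            )
            mask = np.ones(n_pixels, dtype=bool)
            self.fallback_whole_frame_ = True
        elif not mask.any():
            raise ValueError(
                "common-background intersection is empty; use a larger field of "
                "view or fewer/smaller cells"
            )

        mean_curve = X[mask].mean(axis=0)
        eps = self.eps_scale * float(X.max())
        self.mask_ = mask
        self.mean_curve_ = np.maximum(mean_curve, eps)
        self.n_trivial_frames_ = n_trivial
        self.n_features_in_ = n_frames
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_curve_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean_curve_.shape[0]:
            raise ValueError(
                f"frame count mismatch: traces have {X.shape[-1]} frames, "
                f"mean curve has {self.mean_curve_.shape[0]}"
            )
        return X / self.mean_curve_


def estimate_common_background(stack: VideoStack, **kwargs) -> CommonBackground:
    """Common-background mask and mean scaling curve of a (smoothed) video."""
    T, H, W = stack.shape
    X = stack.data.reshape(T, H * W).T
    est = BackgroundRescaler(**kwargs).fit(X)
    return CommonBackground(
        mask=est.mask_.reshape(H, W),
        mean_curve=est.mean_curve_,
        n_trivial_frames=est.n_trivial_frames_,
        fallback_whole_frame=est.fallback_whole_frame_,
    )


def rescale(stack: VideoStack, bg: CommonBackground) -> RescaledStack:
    """Divide each frame by the mean common-background signal of that frame."""
    if stack.n_frames != bg.mean_curve.shape[0]:
        raise ValueError(
            f"frame count mismatch: stack has {stack.n_frames} frames, "
            f"mean curve has {bg.mean_curve.shape[0]}"
        )
    data = np.asarray(stack.data, dtype=float) / bg.mean_curve[:, None, None]
    return RescaledStack(data=data, source=stack)
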