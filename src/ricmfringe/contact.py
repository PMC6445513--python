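"""Intensity-based contact-radius reference and model-vs-intensity regression.

An adhering probe's contact zone appears as a flat dark core of the mean
radial profile.  Growing a 1-D region outward from the profile center
until the intensity rises by a set fraction of the profile amplitude gives
a model-free contact-radius estimate.  Sweeping the threshold and
regressing the model-based radius on the intensity-based one quantifies
their agreement (slope ~ 1, small negative intercept: region growing
stops late and overestimates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RegionGrowingResult",
    "RegressionResult",
    "region_grow_radius",
    "threshold_sweep",
    "compare_model_vs_intensity",
]


@dataclass(frozen=True)
class RegionGrowingResult:
    """Radius reached at one threshold; ``grew_to_edge`` flags a sweep
    that never triggered the stopping criterion."""

    threshold: float
    radius: float
    grew_to_edge: bool


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit c_model = slope * c_intensity + intercept (radii in um)."""

    slope: float
    intercept: float
    adjusted_r2: float
    n: int


def region_grow_radius(
    mean_profile: np.ndarray,
    threshold: float,
    u: float,
    *,
    center_window: int = 3,
) -> RegionGrowingResult:
    """1-D region growing along the mean radial profile.

    Starting from the center reference intensity ``I0`` (mean of the first
    ``center_window`` radial samples - the innermost samples are noisy
    because radial averaging degenerates near r = 0), positions are
    accepted outward while ``profile[r] - I0 < threshold * amplitude``
    with amplitude = max - min of the profile.  The radius is the last
    accepted pixel radius times the pixel length ``u``.
    """
    profile = np.asarray(mean_profile, dtype=float)
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    amplitude = profile.max() - profile.min()
    if amplitude == 0:
        raise ValueError("constant profile has undefined amplitude")
    i0 = profile[: max(1, center_window)].mean()
    exceeded = (profile - i0) >= threshold * amplitude
    if not exceeded.any():
        return RegionGrowingResult(
            threshold=threshold, radius=len(profile) * u, grew_to_edge=True
        )
    stop = int(np.argmax(exceeded))  # first index violating the criterion
    # index j holds pixel radius j + 1; last accepted radius is `stop` px
    return RegionGrowingResult(threshold=threshold, radius=stop * u, grew_to_edge=False)


def threshold_sweep(
    mean_profile: np.ndarray,
    u: float,
    thresholds=None,
) -> list[RegionGrowingResult]:
    """Region-growing radius for each threshold.

    Defaults to 40 uniformly spaced thresholds from 1% to 40% of the
    profile amplitude.
    """
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.40, 40)
    return [region_grow_radius(mean_profile, float(t), u) for t in thresholds]


def compare_model_vs_intensity(pairs) -> RegressionResult:
    """OLS of the model-based on the intensity-based contact radius.

    ``pairs`` is an iterable of (c_intensity, c_model) in um.  Adjusted
    R^2 uses the standard single-predictor correction
    ``1 - (1 - R^2) (n - 1) / (n - 2)``.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (c_intensity, c_model) pairs")
    c_int, c_model = arr[:, 0], arr[:, 1]
    if np.ptp(c_int) == 0:
        raise ValueError("degenerate predictor: all c_intensity equal")
    fit = stats.linregress(c_int, c_model)
    n = len(arr)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept), adjusted_r2=float(adj), n=n
    )
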