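"""Radial sampling and template-bank correlation at candidate positions.

At each candidate pixel the image is sampled along ``m`` rays of length
``r_max`` pixels; the directional profiles are averaged into ``p_mean``,
which suppresses noise and favors radially symmetric positions.  Two gates
remove false positives before matching: a minimum amplitude ``a`` of
``p_mean`` (correlation is amplitude-blind) and a minimum mean correlation
``t2`` of the individual rays with ``p_mean`` (a radial-symmetry test).
Surviving positions are Pearson-correlated against the whole template bank
and the best index and correlation are written into a map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import TemplateBank

__all__ = [
    "RadialSampleSet",
    "MatchConstraints",
    "CorrelationMap",
    "radial_sample",
    "pearson",
    "circular_symmetry",
    "match_position",
    "build_correlation_map",
]

# ray i of m points along (sin(2*pi*i/m), cos(2*pi*i/m)) in (x, y): i=0 -> +y


@dataclass(frozen=True)
class RadialSampleSet:
    """Directional profiles around one position.

    ``samples`` is (m, r_max) with NaN marking out-of-bounds points;
    ``mean_profile[j]`` averages the in-bounds samples at pixel radius
    ``j + 1``; ``amplitude`` = max - min of the mean profile; ``coverage``
    = fraction of sample points inside the image.
    """

    samples: np.ndarray
    mean_profile: np.ndarray
    amplitude: float
    coverage: float


@dataclass(frozen=True)
class MatchConstraints:
    """Amplitude gate ``a`` (fraction of image range) and symmetry gate ``t2``."""

    a: float = 0.05
    t2: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.a <= 1):
            raise ValueError("amplitude threshold a must lie in [0, 1]")
        if not (-1 <= self.t2 <= 1):
            raise ValueError("circular-correlation threshold t2 must lie in [-1, 1]")


@dataclass
class CorrelationMap:
    """Best correlation / best template index per evaluated pixel.

    Unevaluated or rejected positions hold NaN (correlation) and -1
    (index).
    """

    best_corr: np.ndarray
    best_template: np.ndarray


def _ray_directions(m: int) -> tuple[np.ndarray, np.ndarray]:
    ang = 2.0 * np.pi * np.arange(m) / m
    return np.sin(ang), np.cos(ang)  # (dx, dy)


def _sample_batch(
    image: np.ndarray, xs: np.ndarray, ys: np.ndarray, m: int, r_max: int
) -> np.ndarray:
    """Bilinear radial samples for many positions: (N, m, r_max), NaN out of bounds."""
    dx, dy = _ray_directions(m)
    rr = np.arange(1, r_max + 1, dtype=float)
    cx = xs[:, None, None] + rr[None, None, :] * dx[None, :, None]
    cy = ys[:, None, None] + rr[None, None, :] * dy[None, :, None]
    vals = ndimage.map_coordinates(
        image, [cy.ravel(), cx.ravel()], order=1, mode="constant", cval=np.nan
    )
    return vals.reshape(len(xs), m, r_max)


def radial_sample(image: np.ndarray, x: float, y: float, m: int, r_max: int) -> RadialSampleSet:
    """Sample ``m`` directional profiles of length ``r_max`` px around (x, y).

    Non-integer sample coordinates are bilinearly interpolated;
    out-of-bounds points are NaN-flagged and excluded from the mean.  The
    returned ``coverage`` lets callers reject border positions (the
    matcher rejects coverage < 0.5 rather than zero-padding, which would
    fabricate symmetry).
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise ValueError(f"position ({x}, {y}) outside image of shape {image.shape}")
    samples = _sample_batch(image, np.array([float(x)]), np.array([float(y)]), m, r_max)[0]
    finite = np.isfinite(samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_profile = np.nanmean(samples, axis=0)
    coverage = float(finite.mean())
    valid = np.isfinite(mean_profile)
    amplitude = float(mean_profile[valid].max() - mean_profile[valid].min()) if valid.any() else 0.0
    return RadialSampleSet(
        samples=samples, mean_profile=mean_profile, amplitude=amplitude, coverage=coverage
    )


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention r = 0.

    A constant vector carries no shape information, so treating it as
    uncorrelated (rather than undefined) prevents flat image regions from
    matching flat-contact templates spuriously.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if u.size < 2:
        raise ValueError("vectors must have length >= 2")
    du = u - u.mean()
    dv = v - v.mean()
    den = np.sqrt((du**2).sum() * (dv**2).sum())
    if den == 0:
        return 0.0
    return float(np.clip((du * dv).sum() / den, -1.0, 1.0))


def circular_symmetry(sampleset: RadialSampleSet) -> float:
    """Mean Pearson correlation of the individual rays with ``p_mean``.

    Rays with any out-of-bounds sample are excluded.  High values indicate
    radial symmetry; asymmetric clutter scores low and is gated by ``t2``.
    """
    samples = sampleset.samples
    ok = np.isfinite(samples).all(axis=1)
    if not ok.any() or not np.isfinite(sampleset.mean_profile).all():
        return 0.0
    return float(_row_correlations(samples[ok], sampleset.mean_profile).mean())


def _row_correlations(rows: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row with ``ref`` (zero variance -> 0)."""
    dref = ref - ref.mean()
    nref = np.sqrt((dref**2).sum())
    drows = rows - rows.mean(axis=1, keepdims=True)
    nrows = np.sqrt((drows**2).sum(axis=1))
    den = nrows * nref
    num = drows @ dref
    out = np.zeros(len(rows))
    nz = den > 0
    out[nz] = np.clip(num[nz] / den[nz], -1.0, 1.0)
    return out


def _bank_correlations(mean_profile: np.ndarray, bank: TemplateBank) -> np.ndarray:
    """Pearson correlation of one mean profile against every bank template."""
    r = mean_profile.size
    mu = mean_profile.mean()
    sd = mean_profile.std()
    if sd == 0:
        return np.zeros(len(bank))
    z = (mean_profile - mu) / sd
    return np.clip(bank.zvalues @ z / r, -1.0, 1.0)


def match_position(
    sampleset: RadialSampleSet,
    bank: TemplateBank,
    constraints: MatchConstraints,
    image_range: float,
) -> tuple[int, float] | None:
    """Best bank template at one position, or None if the gates reject it.

    Rejection reasons: coverage < 0.5, amplitude < a * image_range, or
    circular symmetry < t2.  Ties in correlation break to the lowest bank
    index.
    """
    if len(bank) == 0:
        raise ValueError("template bank is empty")
    if sampleset.coverage < 0.5:
        return None
    if sampleset.amplitude < constraints.a * image_range:
        return None
    if circular_symmetry(sampleset) < constraints.t2:
        return None
    corr = _bank_correlations(sampleset.mean_profile, bank)
    best = int(np.argmax(corr))  # argmax returns the lowest index on ties
    return best, float(corr[best])


def build_correlation_map(
    image: np.ndarray,
    candidates,
    bank: TemplateBank,
    constraints: MatchConstraints,
    m: int = 90,
    *,
    chunk: int = 512,
) -> CorrelationMap:
    """Evaluate :func:`match_position` at every candidate pixel.

    Pure function of its inputs: per-position evaluations are independent,
    so any execution order (or parallel backend) yields identical output.
    Rejected/unevaluated pixels keep the NaN / -1 sentinels.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    r_max = bank.config.r_max
    best_corr = np.full((h, w), np.nan)
    best_template = np.full((h, w), -1, dtype=np.int64)
    positions = np.asarray(candidates.positions, dtype=np.int64)
    if len(positions) == 0:
        return CorrelationMap(best_corr=best_corr, best_template=best_template)
    if positions[:, 0].max() >= w or positions[:, 1].max() >= h:
        raise ValueError("candidate positions outside image")

    image_range = float(image.max() - image.min())
    zbank = bank.zvalues
    r = bank.values.shape[1]

    for start in range(0, len(positions), chunk):
        block = positions[start : start + chunk]
        xs = block[:, 0].astype(float)
        ys = block[:, 1].astype(float)
        samples = _sample_batch(image, xs, ys, m, r_max)  # (N, m, r_max)
        finite = np.isfinite(samples)
        coverage = finite.mean(axis=(1, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mp = np.nanmean(samples, axis=1)  # (N, r_max)
        mp_ok = np.isfinite(mp).all(axis=1)
        amp = np.where(
            mp_ok, np.nanmax(mp, axis=1) - np.nanmin(mp, axis=1), 0.0
        )
        pass1 = (coverage >= 0.5) & mp_ok & (amp >= constraints.a * image_range)
        if not pass1.any():
            continue

        # radial-symmetry gate on the survivors (rows fully in bounds only)
        idx = np.nonzero(pass1)[0]
        sub = samples[idx]  # (Np, m, r_max)
        rows_ok = finite[idx].all(axis=2)  # (Np, m)
        sub = np.where(rows_ok[:, :, None], sub, 0.0)
        s0 = sub - sub.mean(axis=2, keepdims=True)
        mp0 = mp[idx] - mp[idx].mean(axis=1, keepdims=True)
        num = np.einsum("nmr,nr->nm", s0, mp0)
        den = np.sqrt((s0**2).sum(axis=2)) * np.sqrt((mp0**2).sum(axis=1))[:, None]
        row_corr = np.zeros_like(num)
        nzden = den > 0
        row_corr[nzden] = np.clip(num[nzden] / den[nzden], -1.0, 1.0)
        n_ok = rows_ok.sum(axis=1)
        circ = np.where(
            n_ok > 0, (row_corr * rows_ok).sum(axis=1) / np.maximum(n_ok, 1), 0.0
        )
        idx = idx[circ >= constraints.t2]
        if len(idx) == 0:
            continue

        prof = mp[idx]
        mu = prof.mean(axis=1, keepdims=True)
        sd = prof.std(axis=1, keepdims=True)
        nz = sd[:, 0] > 0
        z = np.zeros_like(prof)
        z[nz] = (prof[nz] - mu[nz]) / sd[nz]
        corr = np.clip(z @ zbank.T / r, -1.0, 1.0)  # (N_pass, N_bank)
        best = corr.argmax(axis=1)
        bx = block[idx, 0]
        by = block[idx, 1]
        best_corr[by, bx] = corr[np.arange(len(idx)), best]
        best_corr[by[~nz], bx[~nz]] = np.nan  # zero-variance profiles stay rejected
        best_template[by, bx] = best
        best_template[by[~nz], bx[~nz]] = -1
    return CorrelationMap(best_corr=best_corr, best_template=best_template)
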