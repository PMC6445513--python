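"""Physical forward model for RICM fringe profiles of spherical probes.

Reflection interference contrast microscopy (RICM) images a sphere resting
on (or hovering above) a glass coverslip as a set of concentric interference
fringes.  The radial intensity profile follows the classical two-beam
interference model with a finite illumination aperture: the fringes are a
cosine in the optical path length ``2 k h(r)`` damped by a sinc envelope,
where ``h(r)`` is the sphere-coverslip gap at radial distance ``r`` and
``k = 2 pi n / lambda`` is the wavenumber in the medium.

An elastic probe adhering to the surface flattens over a circular contact
zone of radius ``r_c``; inside that zone ``h = 0`` and the profile is flat.
From the contact radius, the particle radius, and the probe's elastic
constants, the adhesion energy follows from Johnson-Kendall-Roberts (JKR)
contact mechanics.

This module provides the template generator used for matching (a bank of
theoretical radial profiles over a grid of particle height ``d``, particle
radius ``p`` and empirical decay ``dec``) and the derived physical
quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OpticalConfig",
    "TemplateParams",
    "RadialTemplate",
    "ParameterGrid",
    "TemplateBank",
    "aperture_angle",
    "wavenumber",
    "height_profile",
    "template_intensity",
    "apply_decay",
    "decay_factor",
    "generate_template",
    "build_bank",
    "contact_radius",
    "relative_height",
    "adhesion_energy",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Fixed optical and imaging constants of an RICM setup.

    Parameters
    ----------
    u : float
        Pixel length in um/px.
    wavelength : float
        Illumination wavelength in um (in vacuo).
    ina : float
        Illumination numerical aperture (dimensionless); must satisfy
        ``0 < ina < n`` for the aperture half-angle to be defined.
    n : float
        Refractive index of the immersion/sample medium.
    theta : float
        Interferometric phase shift in radians (``pi`` for the usual
        glass/medium/probe reflection geometry: dark contact zone).
    r_max : int
        Radial extent of generated templates in pixels (>= 2).
    """

    u: float = 0.067
    wavelength: float = 0.53
    ina: float = 0.67
    n: float = 1.332
    theta: float = math.pi
    r_max: int = 100

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("pixel length u must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (0 < self.ina < self.n):
            raise ValueError(
                f"invalid optics: need 0 < INA < n, got INA={self.ina}, n={self.n}"
            )
        if int(self.r_max) != self.r_max or self.r_max < 2:
            raise ValueError("r_max must be an integer >= 2")

    @property
    def alpha(self) -> float:
        """Aperture half-angle ``asin(INA / n)`` in radians."""
        return aperture_angle(self)

    @property
    def k(self) -> float:
        """Wavenumber ``2 pi n / lambda`` in um^-1."""
        return wavenumber(self)


def aperture_angle(config: OpticalConfig) -> float:
    """Illumination aperture half-angle ``alpha = asin(INA / n)``.

    Returns
    -------
    float
        Angle in radians, in the open interval (0, pi/2).
    """
    return math.asin(config.ina / config.n)


def wavenumber(config: OpticalConfig) -> float:
    """Wavenumber in the medium, ``k = 2 pi n / lambda`` (um^-1)."""
    return 2.0 * math.pi * config.n / config.wavelength


def height_profile(r, d: float, p: float):
    """Sphere-coverslip gap ``h(r) = max(0, d + p - sqrt(p^2 - r^2))``.

    The probe is modelled as a perfect sphere of radius ``p`` whose lowest
    point sits at height ``d`` above the coverslip; for touching or
    indenting probes (``d <= 0``) the clamp at zero crops the sphere,
    producing the flat circular contact zone.

    Parameters
    ----------
    r : float or ndarray
        Radial distance from the symmetry axis, um.  Must satisfy
        ``0 <= r <= p``.
    d : float
        Particle height above the surface, um; may be negative (contact).
    p : float
        Particle radius, um (> 0).

    Returns
    -------
    float or ndarray
        Gap height in um, >= 0, non-decreasing in ``r``.
    """
    r_arr = np.asarray(r, dtype=float)
    if p <= 0:
        raise ValueError("particle radius p must be positive")
    if np.any(r_arr < 0):
        raise ValueError("radial distance r must be non-negative")
    if np.any(r_arr > p):
        raise ValueError(f"radial distance exceeds sphere radius (r > p = {p} um)")
    h = np.maximum(0.0, d + p - np.sqrt(p * p - r_arr * r_arr))
    return h if h.ndim else float(h)


def template_intensity(r, d: float, p: float, config: OpticalConfig):
    """Dimensionless RICM fringe intensity at radius ``r``.

    Evaluates ``sinc(y) * cos(2 k h(r) (1 - sin^2(alpha/2)) + theta)`` with
    ``y = 2 k h(r) sin^2(alpha/2)``.  The sinc envelope is the
    finite-aperture (INA) damping of the fringe contrast; the cosine
    carries the interference phase.  Values lie in [-1, 1].
    """
    h = np.asarray(height_profile(r, d, p), dtype=float)
    alpha = aperture_angle(config)
    k = wavenumber(config)
    s2 = math.sin(alpha / 2.0) ** 2
    y = 2.0 * k * h * s2
    # np.sinc is the normalized sinc: sin(pi x) / (pi x)
    vals = np.sinc(y / np.pi) * np.cos(2.0 * k * h * (1.0 - s2) + config.theta)
    return vals if vals.ndim else float(vals)


def decay_factor(r_px, dec: float, r_max: int):
    """Empirical fringe attenuation ``exp(-dec * (r / r_max)^2)``.

    ``r_px`` is the radial distance in pixels.  ``dec = 0`` is the
    identity; ``dec = 10`` attenuates the profile edge by ``e^-10``.
    """
    if dec < 0:
        raise ValueError("decay strength dec must be >= 0")
    r_arr = np.asarray(r_px, dtype=float)
    out = np.exp(-dec * (r_arr / float(r_max)) ** 2)
    return out if out.ndim else float(out)


def apply_decay(values: np.ndarray, dec: float, r_max: int) -> np.ndarray:
    """Attenuate a radial template sampled at pixel radii 1..len(values).

    Entry ``j`` (radius ``j + 1`` px) is multiplied by
    ``exp(-dec * ((j + 1) / r_max)^2)``; the output magnitude is pointwise
    <= the input magnitude.
    """
    values = np.asarray(values, dtype=float)
    radii = np.arange(1, values.shape[-1] + 1)
    return values * decay_factor(radii, dec, r_max)


@dataclass(frozen=True)
class TemplateParams:
    """Parameters of one theoretical radial profile.

    ``d``: particle height above the surface (um, <= 0 means contact);
    ``p``: particle radius (um, > 0); ``dec``: empirical decay strength
    (dimensionless, >= 0).
    """

    d: float
    p: float
    dec: float = 0.0

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError("particle radius p must be positive")
        if self.dec < 0:
            raise ValueError("decay strength dec must be >= 0")
        if abs(self.d) > self.p:
            raise ValueError(
                f"indentation |d|={abs(self.d)} um exceeds particle radius p={self.p} um"
            )


@dataclass(frozen=True)
class RadialTemplate:
    """A theoretical intensity profile sampled at pixel radii 1..r_max.

    ``values[j]`` is the (decayed) model intensity at pixel radius
    ``j + 1``; the on-axis value (r = 0) is not stored.  All entries lie
    in [-1, 1].
    """

    params: TemplateParams
    values: np.ndarray


def generate_template(params: TemplateParams, config: OpticalConfig) -> RadialTemplate:
    """Build one radial template from the forward model.

    The sphere must cover the sampled radial extent
    (``p >= r_max * u``); smaller spheres would require extrapolating the
    height profile beyond the sphere's equator.
    """
    if params.p < config.r_max * config.u:
        raise ValueError(
            f"particle radius p={params.p} um smaller than template extent "
            f"r_max*u={config.r_max * config.u} um"
        )
    r_um = np.arange(1, config.r_max + 1) * config.u
    vals = template_intensity(r_um, params.d, params.p, config)
    vals = apply_decay(vals, params.dec, config.r_max)
    return RadialTemplate(params=params, values=vals)


def _range_values(triplet: Sequence[float]) -> tuple[float, ...]:
    """Expand a [min, step, max] triplet into an inclusive value tuple."""
    lo, step, hi = (float(x) for x in triplet)
    if step <= 0 or hi < lo:
        raise ValueError(f"invalid range triplet {triplet!r}")
    count = int(round((hi - lo) / step)) + 1
    vals = np.round(lo + step * np.arange(count), 10)
    if abs(vals[-1] - hi) > 1e-9:
        raise ValueError(f"range triplet {triplet!r} does not land on its maximum")
    return tuple(float(v) for v in vals)


@dataclass(frozen=True)
class ParameterGrid:
    """Search-space grid over (d, p, dec); all lists strictly increasing."""

    d_values: tuple[float, ...]
    p_values: tuple[float, ...]
    dec_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals in (
            ("d_values", self.d_values),
            ("p_values", self.p_values),
            ("dec_values", self.dec_values),
        ):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, tuple(float(v) for v in arr))

    @classmethod
    def from_ranges(cls, d_range, p_range, dec_range) -> "ParameterGrid":
        """Build the grid from [min, step, max] triplets."""
        return cls(
            d_values=_range_values(d_range),
            p_values=_range_values(p_range),
            dec_values=_range_values(dec_range),
        )

    @classmethod
    def default(cls) -> "ParameterGrid":
        """The standard search space: d in [-0.45, 0] um step 0.01,
        p in [10, 30] um step 1, dec in [0, 10] step 1 (10626 points)."""
        return cls.from_ranges([-0.45, 0.01, 0.0], [10, 1, 30], [0, 1, 10])

    def __len__(self) -> int:
        return len(self.d_values) * len(self.p_values) * len(self.dec_values)


@dataclass
class TemplateBank:
    """Pre-computed templates for every grid point, lexicographic in (d, p, dec).

    ``values`` is an (N, r_max) matrix, one template per row;
    ``params_table`` is an (N, 3) matrix of the generating (d, p, dec).
    The index -> parameter mapping is bijective and stable.
    """

    config: OpticalConfig
    grid: ParameterGrid
    values: np.ndarray
    params_table: np.ndarray
    _zvalues: np.ndarray | None = field(default=None, repr=False, compare=False)
    _diff_signs: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return self.values.shape[0]

    def lookup(self, index: int) -> TemplateParams:
        """Parameters that generated template ``index``."""
        d, p, dec = self.params_table[index]
        return TemplateParams(d=float(d), p=float(p), dec=float(dec))

    def index_of(self, params: TemplateParams) -> int:
        """Inverse of :meth:`lookup` (exact grid values required)."""
        i_d = self.grid.d_values.index(params.d)
        i_p = self.grid.p_values.index(params.p)
        i_dec = self.grid.dec_values.index(params.dec)
        n_p = len(self.grid.p_values)
        n_dec = len(self.grid.dec_values)
        return (i_d * n_p + i_p) * n_dec + i_dec

    @property
    def zvalues(self) -> np.ndarray:
        """Row-standardized templates (zero mean, unit population std).

        Zero-variance rows standardize to all-zero so their Pearson
        correlation with anything is 0.
        """
        if self._zvalues is None:
            mu = self.values.mean(axis=1, keepdims=True)
            sd = self.values.std(axis=1, keepdims=True)
            safe = np.where(sd > 0, sd, 1.0)
            z = (self.values - mu) / safe
            z[sd[:, 0] == 0] = 0.0
            self._zvalues = z
        return self._zvalues

    @property
    def diff_signs(self) -> np.ndarray:
        """Signs of successive radial differences, int8 (N, r_max - 1)."""
        if self._diff_signs is None:
            self._diff_signs = np.sign(np.diff(self.values, axis=1)).astype(np.int8)
        return self._diff_signs

    def to_csv(self, path) -> None:
        """Export the bank as plain text: one template per row with its params."""
        header = "d_um,p_um,dec," + ",".join(
            f"r{j}" for j in range(1, self.values.shape[1] + 1)
        )
        table = np.hstack([self.params_table, self.values])
        np.savetxt(path, table, delimiter=",", header=header, comments="")


def build_bank(grid: ParameterGrid, config: OpticalConfig) -> TemplateBank:
    """Pre-calculate the template for every grid point.

    Raises a :class:`ValueError` naming the offending grid point if any
    combination violates the template-parameter invariants.
    """
    r_max = config.r_max
    for p in grid.p_values:
        if p < r_max * config.u:
            raise ValueError(
                f"grid point p={p} um violates p >= r_max*u = {r_max * config.u} um"
            )
    for d in grid.d_values:
        for p in grid.p_values:
            if abs(d) > p:
                raise ValueError(f"grid point (d={d}, p={p}) violates |d| <= p")

    d_arr = np.asarray(grid.d_values)
    p_arr = np.asarray(grid.p_values)
    dec_arr = np.asarray(grid.dec_values)
    r_um = np.arange(1, r_max + 1) * config.u

    # the (d, p) -> intensity map is independent of dec: compute once per pair
    n_d, n_p, n_dec = len(d_arr), len(p_arr), len(dec_arr)
    base = np.empty((n_d, n_p, r_max))
    for i_p, p in enumerate(p_arr):
        h = np.maximum(0.0, d_arr[:, None] + p - np.sqrt(p * p - r_um * r_um)[None, :])
        alpha = aperture_angle(config)
        k = wavenumber(config)
        s2 = math.sin(alpha / 2.0) ** 2
        y = 2.0 * k * h * s2
        base[:, i_p, :] = np.sinc(y / np.pi) * np.cos(
            2.0 * k * h * (1.0 - s2) + config.theta
        )

    decay = np.exp(
        -dec_arr[:, None] * (np.arange(1, r_max + 1)[None, :] / r_max) ** 2
    )  # (n_dec, r_max)
    values = (base[:, :, None, :] * decay[None, None, :, :]).reshape(-1, r_max)

    dd, pp, cc = np.meshgrid(d_arr, p_arr, dec_arr, indexing="ij")
    params_table = np.column_stack([dd.ravel(), pp.ravel(), cc.ravel()])
    return TemplateBank(config=config, grid=grid, values=values, params_table=params_table)


def contact_radius(d: float, p: float) -> float:
    """Radius of the flat contact circle, ``r_c = sqrt(2 p |d| - d^2)``.

    The intersection of a sphere of radius ``p`` indenting the coverslip
    plane by ``|d|`` (for ``d < 0``); zero for non-touching probes
    (``d >= 0``).  Consistent with the radius at which
    :func:`height_profile` first becomes positive.
    """
    if p <= 0:
        raise ValueError("particle radius p must be positive")
    if abs(d) > p:
        raise ValueError(f"indentation |d|={abs(d)} exceeds particle radius p={p}")
    if d >= 0:
        return 0.0
    return math.sqrt(2.0 * p * (-d) - d * d)


def relative_height(offset: float, i: int, config: OpticalConfig) -> float:
    """Particle height modulo the interference period.

    Because the fringe phase is periodic in the gap height, only
    ``d_relative = offset + i * lambda / (2 n) * (1 - sin^2(alpha/2))``
    for integer ``i`` is determined by a single-wavelength measurement.
    For adhering probes the contact zone removes the ambiguity and
    ``i = 0`` applies.
    """
    alpha = aperture_angle(config)
    s2 = math.sin(alpha / 2.0) ** 2
    return offset + i * config.wavelength / (2.0 * config.n) * (1.0 - s2)


def adhesion_energy(r_c: float, p: float, e_modulus: float, poisson: float) -> float:
    """JKR adhesion energy from the contact geometry, in J/m^2.

    ``W_adh = r_c^3 * [4 E / (3 (1 - v^2))] / (6 pi p^2)``, with the
    contact radius ``r_c`` and particle radius ``p`` given in um and
    converted to meters internally; ``e_modulus`` (Young's modulus) in Pa
    and Poisson ratio ``v`` in [0, 1).
    """
    if not (0 <= poisson < 1):
        raise ValueError("Poisson ratio must satisfy 0 <= v < 1")
    if e_modulus <= 0:
        raise ValueError("Young's modulus must be positive")
    if p <= 0:
        raise ValueError("particle radius p must be positive")
    if r_c < 0:
        raise ValueError("contact radius must be >= 0")
    rc_m = r_c * 1e-6
    p_m = p * 1e-6
    reduced = 4.0 * e_modulus / (3.0 * (1.0 - poisson**2))
    return rc_m**3 * reduced / (6.0 * math.pi * p_m**2)
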