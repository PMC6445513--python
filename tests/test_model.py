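"""Forward-model unit and property tests.

Expected values are frozen from independent scalar evaluation of the
optical formulas (math-module compositions, numerical root finding), not
from the vectorized implementation under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.signal import argrelextrema

from ricmfringe import (
    OpticalConfig,
    ParameterGrid,
    TemplateParams,
    adhesion_energy,
    aperture_angle,
    apply_decay,
    build_bank,
    contact_radius,
    generate_template,
    height_profile,
    relative_height,
    template_intensity,
    wavenumber,
)


class TestOptics:
    def test_aperture_angle_table_values(self, cfg_table):
        assert aperture_angle(cfg_table) == pytest.approx(math.asin(0.67 / 1.332))
        assert aperture_angle(cfg_table) == pytest.approx(0.527069, abs=1e-6)
        # cross-check: sin(alpha) * n recovers the INA
        assert math.sin(aperture_angle(cfg_table)) * 1.332 == pytest.approx(0.67)

    def test_aperture_angle_vanishing_ina(self):
        cfg = OpticalConfig(ina=1e-9)
        assert aperture_angle(cfg) == pytest.approx(0.0, abs=1e-8)

    def test_invalid_optics_rejected(self):
        with pytest.raises(ValueError, match="INA"):
            OpticalConfig(ina=1.4, n=1.332)

    def test_wavenumber(self, cfg_table):
        assert wavenumber(cfg_table) == pytest.approx(2 * math.pi * 1.332 / 0.53)
        assert wavenumber(OpticalConfig(wavelength=2 * math.pi, n=1.0, ina=0.5)) == pytest.approx(1.0)
        half = OpticalConfig(wavelength=1.06)
        assert wavenumber(half) == pytest.approx(wavenumber(cfg_table) / 2)


class TestHeightProfile:
    def test_contact_point(self):
        assert height_profile(0.0, 0.0, 10.0) == 0.0
        assert height_profile(0.0, 0.1, 10.0) == pytest.approx(0.1)

    def test_clamped_inside_contact_zone(self):
        # root of d + p - sqrt(p^2 - r^2) at d=-0.2, p=10 is ~1.98997 um
        r = np.linspace(0, 1.98, 50)
        assert np.all(height_profile(r, -0.2, 10.0) == 0)
        assert height_profile(2.1, -0.2, 10.0) > 0

    def test_out_of_sphere_error(self):
        with pytest.raises(ValueError, match="sphere"):
            height_profile(10.5, 0.0, 10.0)

    @given(
        d=st.floats(-0.45, 0.5),
        p=st.floats(8.0, 30.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_monotone(self, d, p):
        r = np.linspace(0, p * 0.9, 200)
        h = height_profile(r, d, p)
        assert np.all(h >= 0)
        assert np.all(np.diff(h) >= -1e-12)
        assert h[0] == pytest.approx(max(0.0, d))


class TestContactRadius:
    def test_no_indentation(self):
        assert contact_radius(0.0, 10.0) == 0.0
        assert contact_radius(0.3, 17.0) == 0.0

    def test_frozen_values(self):
        assert contact_radius(-0.2, 10.0) == pytest.approx(math.sqrt(3.96))
        assert contact_radius(-0.45, 30.0) == pytest.approx(math.sqrt(26.7975))

    def test_invalid_indentation(self):
        with pytest.raises(ValueError, match="indentation"):
            contact_radius(-11.0, 10.0)

    @given(d=st.floats(-0.45, -0.01), p=st.floats(8.0, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_matches_height_profile_root(self, d, p):
        """r_c equals the radius at which the clamped gap first opens."""
        rc = contact_radius(d, p)
        root = brentq(lambda r: d + p - math.sqrt(p * p - r * r), 0, p * 0.99, xtol=1e-12)
        assert rc == pytest.approx(root, abs=1e-9)


def _intensity_oracle(r: float, d: float, p: float, cfg: OpticalConfig) -> float:
    """Scalar composition of the height, aperture, and fringe formulas."""
    h = max(0.0, d + p - math.sqrt(p * p - r * r))
    alpha = math.asin(cfg.ina / cfg.n)
    k = 2 * math.pi * cfg.n / cfg.wavelength
    s2 = math.sin(alpha / 2) ** 2
    y = 2 * k * h * s2
    envelope = math.sin(y) / y if y != 0 else 1.0
    return envelope * math.cos(2 * k * h * (1 - s2) + cfg.theta)


class TestTemplateIntensity:
    def test_contact_zone_value_is_cos_theta(self, cfg_table):
        assert template_intensity(0.5, -0.1, 10.0, cfg_table) == pytest.approx(-1.0)
        bright = OpticalConfig(theta=0.0)
        assert template_intensity(0.5, -0.1, 10.0, bright) == pytest.approx(1.0)

    @pytest.mark.parametrize("r", [0.1, 0.5, 1.0, 3.3, 6.7])
    @pytest.mark.parametrize("d,p", [(0.0, 10.0), (-0.3, 22.0), (0.2, 15.0)])
    def test_matches_scalar_oracle(self, r, d, p, cfg_table):
        expected = _intensity_oracle(r, d, p, cfg_table)
        assert template_intensity(r, d, p, cfg_table) == pytest.approx(expected, abs=1e-12)

    def test_envelope_bound(self, cfg_table):
        r = np.linspace(0, 6.7, 500)
        vals = template_intensity(r, 0.0, 10.0, cfg_table)
        assert np.all(np.abs(vals) <= 1.0)

    def test_ina_limit_gives_pure_cosine(self):
        """As INA -> 0 the sinc envelope tends to 1 uniformly."""
        cfg = OpticalConfig(ina=1e-6)
        r = np.linspace(0.1, 6.7, 300)
        vals = template_intensity(r, 0.0, 10.0, cfg)
        k = wavenumber(cfg)
        h = height_profile(r, 0.0, 10.0)
        assert np.allclose(vals, np.cos(2 * k * h + math.pi), atol=1e-9)


class TestDecay:
    def test_identity_at_zero(self):
        v = np.linspace(-1, 1, 100)
        assert np.array_equal(apply_decay(v, 0.0, 100), v)

    def test_edge_attenuation(self):
        v = np.ones(100)
        out = apply_decay(v, 10.0, 100)
        assert out[-1] == pytest.approx(math.exp(-10.0))

    def test_strictly_decreasing_factor(self):
        out = apply_decay(np.ones(100), 3.0, 100)
        assert np.all(np.diff(out) < 0)

    def test_negative_dec_rejected(self):
        with pytest.raises(ValueError, match="dec"):
            apply_decay(np.ones(10), -1.0, 10)


class TestTemplates:
    def test_flat_contact_zone(self, cfg_table):
        """Inside r_c the gap is zero, so the profile is cos(theta) times decay."""
        params = TemplateParams(d=-0.45, p=10.0, dec=3.0)
        tpl = generate_template(params, cfg_table)
        rc = contact_radius(-0.45, 10.0)
        radii = np.arange(1, 101)
        inside = radii * cfg_table.u <= rc
        assert inside.sum() > 10
        expected = -np.exp(-3.0 * (radii[inside] / 100) ** 2)
        assert np.allclose(tpl.values[inside], expected, atol=1e-12)
        # first deviation occurs at the next pixel radius
        first_out = int(np.nonzero(~inside)[0][0])
        assert abs(tpl.values[first_out] - (-math.exp(-3.0 * ((first_out + 1) / 100) ** 2))) > 1e-6

    def test_values_bounded(self, cfg_table):
        tpl = generate_template(TemplateParams(d=-0.1, p=15.0, dec=0.0), cfg_table)
        assert np.all(np.abs(tpl.values) <= 1.0)

    def test_sphere_must_cover_sampling_extent(self, cfg_table):
        with pytest.raises(ValueError, match="r_max"):
            generate_template(TemplateParams(d=0.0, p=5.0), cfg_table)

    def test_fringe_spacing_shrinks_outward(self, cfg_table):
        """The sphere's gap grows superlinearly, so fringes compress outward."""
        tpl = generate_template(TemplateParams(d=0.0, p=10.0, dec=0.0), cfg_table)
        (maxima,) = argrelextrema(tpl.values, np.greater)
        assert len(maxima) >= 4
        spacing = np.diff(maxima)
        # pixel quantization jitters extrema by up to 1 px
        assert np.all(np.diff(spacing) <= 1)
        assert spacing[0] > 2 * spacing[-1]


class TestBank:
    def test_default_grid_size(self, cfg_table):
        grid = ParameterGrid.default()
        assert (len(grid.d_values), len(grid.p_values), len(grid.dec_values)) == (46, 21, 11)
        bank = build_bank(grid, cfg_table)
        assert len(bank) == 46 * 21 * 11 == 10626

    def test_singleton_grid(self, cfg_table):
        grid = ParameterGrid(d_values=(0.0,), p_values=(12.0,), dec_values=(1.0,))
        bank = build_bank(grid, cfg_table)
        assert len(bank) == 1
        tpl = generate_template(TemplateParams(d=0.0, p=12.0, dec=1.0), cfg_table)
        assert np.allclose(bank.values[0], tpl.values)

    def test_lookup_roundtrip(self, bank_small, grid_small):
        for index in [0, 7, len(bank_small) - 1]:
            params = bank_small.lookup(index)
            assert bank_small.index_of(params) == index

    def test_bank_rows_match_generator(self, bank_small, cfg_small):
        rng = np.random.default_rng(0)
        for index in rng.integers(0, len(bank_small), 5):
            params = bank_small.lookup(int(index))
            tpl = generate_template(params, cfg_small)
            assert np.allclose(bank_small.values[index], tpl.values, atol=1e-12)

    def test_offending_grid_point_named(self, cfg_table):
        grid = ParameterGrid(d_values=(0.0,), p_values=(5.0,), dec_values=(0.0,))
        with pytest.raises(ValueError, match="p=5"):
            build_bank(grid, cfg_table)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            ParameterGrid(d_values=(0.0, -0.1), p_values=(10.0,), dec_values=(0.0,))
        with pytest.raises(ValueError, match="non-empty"):
            ParameterGrid(d_values=(), p_values=(10.0,), dec_values=(0.0,))


class TestDerivedQuantities:
    def test_relative_height_identity_and_linearity(self, cfg_table):
        assert relative_height(-0.2, 0, cfg_table) == -0.2
        period = (0.53 / (2 * 1.332)) * (1 - math.sin(math.asin(0.67 / 1.332) / 2) ** 2)
        steps = [relative_height(0.0, i, cfg_table) for i in range(-3, 4)]
        assert np.allclose(np.diff(steps), period)
        assert period == pytest.approx(0.185449, abs=1e-6)

    def test_adhesion_energy_values(self):
        assert adhesion_energy(0.0, 10.0, 4e4, 0.5) == 0.0
        # 40 kPa probe, 2 um contact on a 10 um sphere
        w = adhesion_energy(2.0, 10.0, 4e4, 0.5)
        expected = 2 * 4e4 * (2e-6) ** 3 / (9 * math.pi * (1 - 0.25) * (10e-6) ** 2)
        assert w == pytest.approx(expected)
        assert w == pytest.approx(3.018e-4, rel=1e-3)

    def test_adhesion_energy_cubic_in_contact_radius(self):
        assert adhesion_energy(4.0, 10.0, 4e4, 0.5) == pytest.approx(
            8 * adhesion_energy(2.0, 10.0, 4e4, 0.5)
        )

    def test_invalid_poisson(self):
        with pytest.raises(ValueError, match="Poisson"):
            adhesion_energy(1.0, 10.0, 4e4, 1.0)
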