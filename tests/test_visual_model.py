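import itertools

import numpy as np
import pytest
from scipy.integrate import quad

from eggdiscrim.spectral_core import CANONICAL_GRID, Spectrum
from eggdiscrim.synthetic_data import (
    GradientSpec,
    eggshell_spectrum,
    make_visual_system,
    reference_geometry,
)
from eggdiscrim.visual_model import (
    ChromaticityPoint,
    NoiseVector,
    ReceptorCatches,
    VisualSystem,
    achromatic_contrast,
    chromatic_basis,
    chromatic_contrast,
    gradient_projection,
    jnd_coordinates,
    mean_catches,
    quantum_catches,
    receptor_noise,
)


def random_catches(rng, label=""):
    return ReceptorCatches(Q=rng.uniform(0.1, 10.0, 4), Q_D=rng.uniform(0.1, 10.0), label=label)


class TestQuantumCatches:
    def test_normalized_product_gives_unit_catch(self, vs_default):
        # flat reflectance = 1, sensitivity*illuminant normalized to integrate to 1
        grid = CANONICAL_GRID
        vs = vs_default
        norm_sens = {}
        for name in vs.receptor_names:
            prod = vs.sensitivities[name].values * vs.illuminant.values
            area = np.trapezoid(prod, grid)
            norm_sens[name] = Spectrum(
                grid, vs.sensitivities[name].values / area, label=name, kind="sensitivity"
            )
        d_area = np.trapezoid(vs.double_cone.values * vs.illuminant.values, grid)
        vs2 = VisualSystem(
            receptor_names=vs.receptor_names,
            sensitivities=norm_sens,
            double_cone=Spectrum(grid, vs.double_cone.values / d_area, kind="sensitivity"),
            illuminant=vs.illuminant,
            densities=vs.densities,
            weber_ref=vs.weber_ref,
            weber_double=vs.weber_double,
        )
        flat = Spectrum(grid, np.ones_like(grid), label="flat")
        c = quantum_catches(flat, vs2)
        np.testing.assert_allclose(c.Q, 1.0, atol=1e-12)
        assert c.Q_D == pytest.approx(1.0)

    def test_doubling_illuminant_doubles_catches(self, vs_default):
        vs = vs_default
        grid = vs.grid
        vs2 = VisualSystem(
            receptor_names=vs.receptor_names,
            sensitivities=vs.sensitivities,
            double_cone=vs.double_cone,
            illuminant=Spectrum(grid, 2.0 * vs.illuminant.values, kind="irradiance"),
            densities=vs.densities,
            weber_ref=vs.weber_ref,
            weber_double=vs.weber_double,
        )
        refl = eggshell_spectrum(GradientSpec("natural_bluegreen_brown", 0.5), grid)
        c1 = quantum_catches(refl, vs)
        c2 = quantum_catches(refl, vs2)
        np.testing.assert_allclose(c2.Q, 2.0 * c1.Q, rtol=1e-12)
        assert c2.Q_D == pytest.approx(2.0 * c1.Q_D)

    def test_against_adaptive_quadrature_oracle(self):
        # Gaussian sensitivity (peak 500 nm, sd 30) x flat illuminant x ramp
        # reflectance, integrated on a 0.1 nm grid, vs scipy adaptive quad.
        grid = np.arange(300.0, 700.0001, 0.1)
        sens = lambda wl: np.exp(-0.5 * ((wl - 500.0) / 30.0) ** 2)
        refl = lambda wl: wl / 700.0
        gauss = Spectrum(grid, sens(grid), kind="sensitivity")
        vs = VisualSystem(
            receptor_names=("U", "S", "M", "L"),
            sensitivities={n: gauss for n in ("U", "S", "M", "L")},
            double_cone=gauss,
            illuminant=Spectrum(grid, np.ones_like(grid), kind="irradiance"),
            densities=np.ones(4),
            weber_ref=0.1,
            weber_double=0.1,
        )
        c = quantum_catches(Spectrum(grid, refl(grid)), vs)
        oracle, _ = quad(lambda wl: refl(wl) * sens(wl), 300, 700, limit=200)
        np.testing.assert_allclose(c.Q, oracle, rtol=1e-6)

    def test_requires_common_grid(self, vs_default):
        s = Spectrum(np.arange(300, 701, 5.0), np.full(81, 0.5))
        with pytest.raises(ValueError, match="grid"):
            quantum_catches(s, vs_default)


class TestReceptorNoise:
    def test_square_root_density_rule(self, vs_default):
        nv = receptor_noise(vs_default)  # densities 1:2:2:4, w_ref 0.1
        np.testing.assert_allclose(
            nv.omega, [0.2, 0.1 * np.sqrt(2), 0.1 * np.sqrt(2), 0.1], atol=1e-12
        )
        assert nv.omega_D == 0.1

    def test_equal_densities_give_reference_weber(self, vs_default):
        vs = vs_default
        vs2 = VisualSystem(
            receptor_names=vs.receptor_names,
            sensitivities=vs.sensitivities,
            double_cone=vs.double_cone,
            illuminant=vs.illuminant,
            densities=np.full(4, 3.0),
            weber_ref=0.07,
            weber_double=0.1,
        )
        np.testing.assert_allclose(receptor_noise(vs2).omega, 0.07)

    def test_density_scale_invariance(self, vs_default):
        vs = vs_default
        vs2 = VisualSystem(
            receptor_names=vs.receptor_names,
            sensitivities=vs.sensitivities,
            double_cone=vs.double_cone,
            illuminant=vs.illuminant,
            densities=10.0 * vs.densities,
            weber_ref=vs.weber_ref,
            weber_double=vs.weber_double,
        )
        np.testing.assert_allclose(
            receptor_noise(vs2).omega, receptor_noise(vs).omega, atol=1e-14
        )


class TestChromaticContrast:
    def test_zero_for_identical_stimuli(self, rng, noise_default):
        a = random_catches(rng)
        assert chromatic_contrast(a, a, noise_default) == 0.0

    def test_dichromat_closed_form(self):
        noise = NoiseVector(omega=np.array([0.1, 0.1]), omega_D=0.1)
        a = ReceptorCatches(Q=np.array([1.2, 1.0]), Q_D=1.0)
        b = ReceptorCatches(Q=np.array([1.0, 1.0]), Q_D=1.0)
        expected = np.log(1.2) / np.sqrt(0.02)
        assert chromatic_contrast(a, b, noise) == pytest.approx(expected, abs=1e-9)
        assert chromatic_contrast(a, b, noise) == pytest.approx(1.2892, abs=1e-4)

    def test_trichromat_closed_form(self, rng):
        w = np.array([0.2, 0.15, 0.1])
        noise = NoiseVector(omega=w, omega_D=0.1)
        Qa, Qb = rng.uniform(0.5, 2.0, 3), rng.uniform(0.5, 2.0, 3)
        df = np.log(Qa) - np.log(Qb)
        num = (
            w[0] ** 2 * (df[2] - df[1]) ** 2
            + w[1] ** 2 * (df[2] - df[0]) ** 2
            + w[2] ** 2 * (df[0] - df[1]) ** 2
        )
        den = (w[0] * w[1]) ** 2 + (w[0] * w[2]) ** 2 + (w[1] * w[2]) ** 2
        expected = np.sqrt(num / den)
        a = ReceptorCatches(Q=Qa, Q_D=1.0)
        b = ReceptorCatches(Q=Qb, Q_D=1.0)
        assert chromatic_contrast(a, b, noise) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_nonnegativity(self, rng, noise_default):
        for _ in range(20):
            a, b = random_catches(rng), random_catches(rng)
            d1 = chromatic_contrast(a, b, noise_default)
            d2 = chromatic_contrast(b, a, noise_default)
            assert d1 >= 0
            assert d1 == pytest.approx(d2, abs=1e-12)

    def test_triangle_inequality(self, rng, noise_default):
        for _ in range(50):
            a, b, c = (random_catches(rng) for _ in range(3))
            dab = chromatic_contrast(a, b, noise_default)
            dbc = chromatic_contrast(b, c, noise_default)
            dac = chromatic_contrast(a, c, noise_default)
            assert dac <= dab + dbc + 1e-12

    def test_per_receptor_rescaling_invariance(self, rng, noise_default):
        a, b = random_catches(rng), random_catches(rng)
        scale = rng.uniform(0.5, 2.0, 4)
        a2 = ReceptorCatches(Q=a.Q * scale, Q_D=a.Q_D)
        b2 = ReceptorCatches(Q=b.Q * scale, Q_D=b.Q_D)
        assert chromatic_contrast(a2, b2, noise_default) == pytest.approx(
            chromatic_contrast(a, b, noise_default), abs=1e-12
        )

    def test_non_positive_catch_rejected(self):
        with pytest.raises(ValueError, match="non-positive quantum catch"):
            ReceptorCatches(Q=np.array([1.0, 0.0, 1.0, 1.0]), Q_D=1.0)


class TestAchromaticContrast:
    def test_zero_for_equal_double_cone(self):
        a = ReceptorCatches(Q=np.ones(4), Q_D=2.0)
        b = ReceptorCatches(Q=np.full(4, 3.0), Q_D=2.0)
        assert achromatic_contrast(a, b, 0.1) == 0.0

    def test_ln_e_over_weber(self):
        a = ReceptorCatches(Q=np.ones(4), Q_D=np.e)
        b = ReceptorCatches(Q=np.ones(4), Q_D=1.0)
        assert achromatic_contrast(a, b, 0.1) == pytest.approx(10.0, abs=1e-12)

    def test_symmetric(self, rng):
        a, b = random_catches(rng), random_catches(rng)
        assert achromatic_contrast(a, b, 0.1) == pytest.approx(
            achromatic_contrast(b, a, 0.1), abs=1e-14
        )

    def test_invariant_to_chromatic_perturbation(self, rng):
        a, b = random_catches(rng), random_catches(rng)
        a2 = ReceptorCatches(Q=a.Q * rng.uniform(0.5, 2, 4), Q_D=a.Q_D)
        assert achromatic_contrast(a2, b, 0.1) == achromatic_contrast(a, b, 0.1)


class TestJndCoordinates:
    def test_identical_stimuli_identical_coordinates(self, rng, noise_default):
        a = random_catches(rng)
        p1 = jnd_coordinates(a, noise_default)
        p2 = jnd_coordinates(a, noise_default)
        np.testing.assert_array_equal(p1.coords, p2.coords)

    def test_achromatic_shift_projected_out(self, rng, noise_default):
        a = random_catches(rng)
        scaled = ReceptorCatches(Q=a.Q * 7.3, Q_D=a.Q_D)
        p1 = jnd_coordinates(a, noise_default)
        p2 = jnd_coordinates(scaled, noise_default)
        np.testing.assert_allclose(p1.coords, p2.coords, atol=1e-9)

    def test_isometry_100_random_pairs(self, rng, noise_default, basis_default):
        for _ in range(100):
            a, b = random_catches(rng), random_catches(rng)
            pa = jnd_coordinates(a, noise_default, basis_default)
            pb = jnd_coordinates(b, noise_default, basis_default)
            assert pa.distance(pb) == pytest.approx(
                chromatic_contrast(a, b, noise_default), abs=1e-9
            )

    def test_basis_orthonormal(self, basis_default):
        np.testing.assert_allclose(
            basis_default.T @ basis_default, np.eye(3), atol=1e-12
        )


class TestMeanCatches:
    def test_geometric_mean(self):
        a = ReceptorCatches(Q=np.array([1.0, 2.0, 4.0, 8.0]), Q_D=1.0)
        b = ReceptorCatches(Q=np.array([4.0, 2.0, 1.0, 2.0]), Q_D=4.0)
        m = mean_catches([a, b])
        np.testing.assert_allclose(m.Q, np.sqrt(a.Q * b.Q))
        assert m.Q_D == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_catches([])


class TestGradientProjection:
    def _axes_setup(self, vs_default):
        return reference_geometry(vs_default)

    def test_origin_maps_to_zero(self, vs_default):
        _, axes, noise, basis = self._axes_setup(vs_default)
        preds, _ = gradient_projection(
            [axes.origin],
            bluegreen_end=ChromaticityPoint(axes.origin.coords - axes.bluegreen_brown),
            brown_end=ChromaticityPoint(axes.origin.coords + axes.bluegreen_brown),
            green_end=ChromaticityPoint(axes.origin.coords + axes.green_purple),
            purple_end=ChromaticityPoint(axes.origin.coords - axes.green_purple),
            origin=axes.origin,
        )
        assert preds[0].x_bgbr == pytest.approx(0.0, abs=1e-12)
        assert preds[0].chromatic_contrast == pytest.approx(0.0, abs=1e-12)

    def test_unit_step_along_first_axis(self, vs_default):
        _, axes, noise, basis = self._axes_setup(vs_default)
        o = axes.origin
        point = ChromaticityPoint(o.coords + axes.bluegreen_brown)
        preds, _ = gradient_projection(
            [point],
            bluegreen_end=ChromaticityPoint(o.coords - axes.bluegreen_brown),
            brown_end=ChromaticityPoint(o.coords + axes.bluegreen_brown),
            green_end=ChromaticityPoint(o.coords + axes.green_purple),
            purple_end=ChromaticityPoint(o.coords - axes.green_purple),
            origin=o,
        )
        p = preds[0]
        assert p.x_bgbr == pytest.approx(1.0, abs=1e-9)
        assert p.x_gp == pytest.approx(0.0, abs=1e-9)
        assert p.chromatic_contrast == pytest.approx(1.0, abs=1e-9)

    def test_pythagoras_matches_direct_contrast(self, rng, vs_default):
        host_catches, axes, noise, basis = self._axes_setup(vs_default)
        for _ in range(30):
            c = random_catches(rng)
            pt = jnd_coordinates(c, noise, basis)
            d = pt.coords - axes.origin.coords
            x = np.array(
                [d @ axes.bluegreen_brown, d @ axes.green_purple, d @ axes.uv_axis]
            )
            ds = chromatic_contrast(c, host_catches, noise)
            assert np.sqrt(np.sum(x**2)) == pytest.approx(ds, abs=1e-9)

    def test_degenerate_axes_rejected(self, vs_default):
        _, axes, noise, basis = self._axes_setup(vs_default)
        o = axes.origin
        a = ChromaticityPoint(o.coords - axes.bluegreen_brown)
        b = ChromaticityPoint(o.coords + axes.bluegreen_brown)
        with pytest.raises(ValueError, match="degenerate"):
            gradient_projection([], a, b, b, a, origin=o)

    def test_uv_direction_sets_sign(self, vs_default):
        host_catches, axes, noise, basis = self._axes_setup(vs_default)
        Q2 = host_catches.Q.copy()
        Q2[0] *= 1.5  # more UV catch
        up = jnd_coordinates(ReceptorCatches(Q=Q2, Q_D=host_catches.Q_D), noise, basis)
        d = up.coords - axes.origin.coords
        assert d @ axes.uv_axis > 0
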