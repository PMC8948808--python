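import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emsckit import (
    EMSCModelSpec,
    SpectraSet,
    build_design,
    correct,
    fit,
    fit_correct,
    orthogonalize_constituent,
    relative_content,
    residual_matrix,
    write_parameters,
)
from emsckit.errors import IllPosedError, NearZeroScalingError
from helpers import make_basic_spec


def _single(axis, values, id_="x"):
    return SpectraSet(axis, np.atleast_2d(values), [id_])


class TestFit:
    def test_self_fit_recovers_identity(self, axis, rng):
        ref = rng.uniform(0.1, 1.0, len(axis))
        spec = EMSCModelSpec(reference=ref, polynomial_order=0)
        p = fit(spec, _single(axis, ref))[0]
        assert p.b == pytest.approx(1.0, abs=1e-12)
        assert p.a == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(p.residual, 0, atol=1e-12)

    def test_affine_construction_recovered(self, axis, rng):
        ref = rng.uniform(0.1, 1.0, len(axis))
        spec = EMSCModelSpec(reference=ref, polynomial_order=0)
        p = fit(spec, _single(axis, 2.0 * ref + 0.5))[0]
        assert p.b == pytest.approx(2.0, abs=1e-10)
        assert p.a == pytest.approx(0.5, abs=1e-10)
        np.testing.assert_allclose(p.residual, 0, atol=1e-10)

    def test_full_generating_parameters_recovered(self, axis, rng):
        """Spectra synthesized from the model return the generating
        parameters exactly (full-rank design, no noise)."""
        ref = rng.uniform(0.1, 1.0, len(axis))
        ana = orthogonalize_constituent(
            rng.normal(size=len(axis)),
            build_design(EMSCModelSpec(reference=ref, polynomial_order=2), axis),
        )
        intf = rng.normal(size=len(axis))
        spec = EMSCModelSpec(
            reference=ref, polynomial_order=2, analytes=[ana], interferents=[intf]
        )
        design = build_design(spec, axis)
        truth = np.array([1.7, 0.3, -0.2, 0.1, 0.8, -0.4])
        z = design.columns @ truth
        p = fit(spec, _single(axis, z))[0]
        np.testing.assert_allclose(p.coefficients, truth, atol=1e-8)

    def test_pseudo_inverse_oracle_agreement(self, random_set, rng):
        ana = rng.normal(size=random_set.n_channels)
        spec = make_basic_spec(random_set, analytes=[ana])
        design = build_design(spec, random_set.axis)
        params = fit(spec, random_set)
        oracle = np.linalg.pinv(design.columns) @ random_set.absorbance.T
        for i, p in enumerate(params):
            np.testing.assert_allclose(p.coefficients, oracle[:, i], atol=1e-8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_pseudo_inverse_oracle_random_designs(self, seed):
        rng = np.random.default_rng(seed)
        n_ch = int(rng.integers(12, 60))
        from emsckit import WavenumberAxis

        ax = WavenumberAxis(np.linspace(1000.0, 2000.0, n_ch))
        ref = rng.uniform(0.1, 1.0, n_ch)
        n_ana = int(rng.integers(0, 3))
        spec = EMSCModelSpec(
            reference=ref,
            polynomial_order=int(rng.integers(0, 3)),
            analytes=[rng.normal(size=n_ch) for _ in range(n_ana)],
        )
        data = SpectraSet(ax, rng.normal(size=(3, n_ch)), ["a", "b", "c"])
        design = build_design(spec, ax)
        oracle = np.linalg.pinv(design.columns) @ data.absorbance.T
        for i, p in enumerate(fit(spec, data)):
            np.testing.assert_allclose(p.coefficients, oracle[:, i], atol=1e-8)

    def test_rank_deficient_raises_unless_forced(self, axis, rng):
        ref = rng.uniform(0.1, 1.0, len(axis))
        spec = EMSCModelSpec(
            reference=ref, polynomial_order=0, analytes=[ref]  # exact duplicate
        )
        data = _single(axis, ref)
        with pytest.raises(IllPosedError):
            fit(spec, data)
        p = fit(spec, data, force=True)[0]
        assert p.ill_conditioned

    def test_group_mean_analyte_pitfall_underestimates_scaling(self, two_group):
        """With the first-group mean as reference and the second-group mean
        as a (collinear) analyte, the scaling parameter collapses for the
        second group and turns negative for some of its spectra."""
        spectra, labels, _ = two_group
        red = spectra.absorbance[labels == 0].mean(axis=0)
        blue = spectra.absorbance[labels == 1].mean(axis=0)
        spec = EMSCModelSpec(reference=red, polynomial_order=2, analytes=[blue])
        b = np.array([p.b for p in fit(spec, spectra)])
        assert np.median(b[labels == 0]) > 0.8  # first group: b near 1
        assert np.median(b[labels == 1]) < 0.3  # second group: collapsed
        assert np.any(b[labels == 1] < 0)


class TestCorrect:
    def test_inverts_affine_transform(self, axis, rng):
        ref = rng.uniform(0.1, 1.0, len(axis))
        spec = EMSCModelSpec(reference=ref, polynomial_order=0)
        data = _single(axis, 1.8 * ref + 0.3)
        out = fit_correct(spec, data)
        np.testing.assert_allclose(out.spectra.absorbance[0], ref, atol=1e-12)

    def test_removes_interferent_contribution(self, axis, rng):
        ref = rng.uniform(0.1, 1.0, len(axis))
        intf = rng.normal(size=len(axis))
        spec = EMSCModelSpec(reference=ref, polynomial_order=0, interferents=[intf])
        data = _single(axis, ref + 0.3 * intf)
        out = fit_correct(spec, data)
        np.testing.assert_allclose(out.spectra.absorbance[0], ref, atol=1e-10)

    def test_orthogonal_analyte_leaves_correction_unchanged(self, random_set, rng):
        base = make_basic_spec(random_set)
        design = build_design(base, random_set.axis)
        ana = orthogonalize_constituent(rng.normal(size=random_set.n_channels), design)
        with_ana = make_basic_spec(random_set, analytes=[ana])
        c0 = fit_correct(base, random_set).spectra.absorbance
        c1 = fit_correct(with_ana, random_set).spectra.absorbance
        np.testing.assert_allclose(c0, c1, atol=1e-10)

    def test_orthogonal_interferent_shifts_by_g_zint_over_b(self, random_set, rng):
        base = make_basic_spec(random_set)
        design = build_design(base, random_set.axis)
        intf = orthogonalize_constituent(rng.normal(size=random_set.n_channels), design)
        with_int = make_basic_spec(random_set, interferents=[intf])
        c0 = fit_correct(base, random_set).spectra.absorbance
        out = fit_correct(with_int, random_set)
        for i, p in enumerate(out.params):
            expected = c0[i] - p.g[0] * intf / p.b
            np.testing.assert_allclose(out.spectra.absorbance[i], expected,
                                       atol=1e-10)

    def test_correction_idempotent(self, random_set):
        spec = make_basic_spec(random_set)
        once = fit_correct(spec, random_set).spectra
        params2 = fit(spec, once)
        for p in params2:
            assert p.b == pytest.approx(1.0, abs=1e-8)
            assert p.a == pytest.approx(0.0, abs=1e-8)
        twice = correct(spec, once, params2).spectra
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-8)

    def test_zero_b_raises_with_spectrum_id(self, axis, rng):
        ref = rng.uniform(0.1, 1.0, len(axis))
        spec = EMSCModelSpec(reference=ref, polynomial_order=0)
        data = _single(axis, np.full(len(axis), 0.7), id_="flatliner")
        params = fit(spec, data)
        params[0].b = 0.0
        params[0].b_near_zero = True
        with pytest.raises(NearZeroScalingError, match="flatliner"):
            correct(spec, data, params)

    def test_near_zero_b_emits_missing_row(self, axis, rng):
        ref = rng.uniform(0.1, 1.0, len(axis))
        spec = EMSCModelSpec(reference=ref, polynomial_order=0)
        data = SpectraSet(
            axis, np.vstack([ref, np.full(len(axis), 0.7)]), ["good", "flat"]
        )
        params = fit(spec, data)
        params[1].b = 1e-15
        params[1].b_near_zero = True
        out = correct(spec, data, params)
        assert out.dropped_ids == ["flat"]
        assert np.all(np.isnan(out.spectra.absorbance[1]))
        assert np.all(np.isfinite(out.spectra.absorbance[0]))


class TestResiduals:
    def test_reconstruction_identity(self, random_set, rng):
        spec = make_basic_spec(random_set, analytes=[rng.normal(size=random_set.n_channels)])
        params = fit(spec, random_set)
        design = build_design(spec, random_set.axis)
        resid = residual_matrix(random_set, spec, params)
        recon = np.vstack([design.columns @ p.coefficients for p in params])
        np.testing.assert_allclose(recon + resid, random_set.absorbance, atol=1e-12)

    def test_perfect_model_data_zero_residuals(self, axis, rng):
        ref = rng.uniform(0.1, 1.0, len(axis))
        spec = EMSCModelSpec(reference=ref, polynomial_order=1)
        design = build_design(spec, axis)
        data = _single(axis, design.columns @ np.array([1.2, 0.1, -0.05]))
        resid = residual_matrix(data, spec, fit(spec, data))
        np.testing.assert_allclose(resid, 0, atol=1e-12)

    def test_corrected_residuals_are_raw_residuals_over_b(self, random_set):
        """Refitting the corrected spectra with the same model yields
        residuals equal to eps/b of the raw fit, which is why PCA on
        corrected spectra and PCA on residuals are practically the same."""
        spec = make_basic_spec(random_set)
        params = fit(spec, random_set)
        corrected = correct(spec, random_set, params).spectra
        params2 = fit(spec, corrected)
        for p_raw, p_cor in zip(params, params2):
            np.testing.assert_allclose(
                p_cor.residual, p_raw.residual / p_raw.b, atol=1e-10
            )


class TestRelativeContent:
    def test_zero_analyte_gives_zero_ratio(self, axis, rng):
        ref = rng.uniform(0.1, 1.0, len(axis))
        ana = orthogonalize_constituent(
            rng.normal(size=len(axis)),
            build_design(EMSCModelSpec(reference=ref, polynomial_order=0), axis),
        )
        spec = EMSCModelSpec(reference=ref, polynomial_order=0, analytes=[ana])
        p = fit(spec, _single(axis, 1.3 * ref))[0]
        ratios = relative_content(p)
        assert ratios["f_over_b"][0] == pytest.approx(0.0, abs=1e-10)

    def test_thickness_invariance(self, axis, rng):
        """Doubling a spectrum (thickness x2) leaves f/b unchanged when the
        analyte contribution scales with the spectrum."""
        ref = rng.uniform(0.1, 1.0, len(axis))
        ana = rng.normal(size=len(axis))
        spec = EMSCModelSpec(reference=ref, polynomial_order=0, analytes=[ana])
        base = ref + 0.25 * ana
        r1 = relative_content(fit(spec, _single(axis, base))[0])
        r2 = relative_content(fit(spec, _single(axis, 2.0 * base))[0])
        np.testing.assert_allclose(r1["f_over_b"], r2["f_over_b"], atol=1e-10)

    def test_near_zero_b_raises(self, axis, rng):
        ref = rng.uniform(0.1, 1.0, len(axis))
        spec = EMSCModelSpec(reference=ref, polynomial_order=0)
        p = fit(spec, _single(axis, ref))[0]
        p.b_near_zero = True
        with pytest.raises(NearZeroScalingError):
            relative_content(p)

    def test_mixture_ratio_affine_in_concentration(self):
        """On a noise-free mixture series, f/b is an affine function of the
        true solute concentration."""
        from emsckit import MixtureScenario, make_mixture_series

        data, conc, truth = make_mixture_series(
            MixtureScenario(seed=7, noise_sigma=0.0)
        )
        spec = EMSCModelSpec(
            reference=truth["solvent_spectrum"],
            polynomial_order=0,
            analytes=[truth["solute_spectrum"]],
        )
        x = np.array([p.f[0] / p.b for p in fit(spec, data)])
        r = np.corrcoef(x, conc)[0, 1]
        assert r**2 > 0.999


class TestParameterTable:
    def test_written_table_round_trips_key_columns(self, random_set, tmp_path, rng):
        spec = make_basic_spec(random_set, analytes=[rng.normal(size=random_set.n_channels)])
        params = fit(spec, random_set)
        path = tmp_path / "params.csv"
        write_parameters(params, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "id,a,b,p_1,p_2,f_0,b_near_zero,ill_conditioned"
        first = lines[1].split(",")
        assert first[0] == random_set.ids[0]
        assert float(first[2]) == pytest.approx(params[0].b, rel=1e-10)
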