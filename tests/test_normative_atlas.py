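import dataclasses

import numpy as np
import pytest

import relaxnorm as rn
from relaxnorm.errors import ConfigurationError, DegenerateMaskError, DesignError
from oracles import ols_normal_equations


def _prob_map(values):
    return rn.VolumeGrid(np.asarray(values, dtype=float))


def _full_mask(shape=(4, 4, 4)):
    return rn.AnalysisMask(rn.VolumeGrid(np.ones(shape, dtype=bool)), 0.5, 1)


class TestWmMask:
    def test_mean_probability_rule(self):
        shape = (4, 4, 4)
        a = np.zeros(shape)
        b = np.zeros(shape)
        a[0, 0, 0], b[0, 0, 0] = 0.4, 0.8  # mean 0.6 -> in
        a[1, 1, 1], b[1, 1, 1] = 0.5, 0.5  # mean exactly 0.5 -> out (strict)
        mask = rn.build_wm_mask([_prob_map(a), _prob_map(b)], threshold=0.5)
        assert mask.mask.data[0, 0, 0]
        assert not mask.mask.data[1, 1, 1]
        assert mask.n_voxels == 1

    def test_all_certain_wm_keeps_whole_region(self):
        region = np.zeros((4, 4, 4))
        region[1:3, 1:3, 1:3] = 1.0
        mask = rn.build_wm_mask([_prob_map(region)] * 3)
        np.testing.assert_array_equal(mask.mask.data, region > 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            rn.build_wm_mask([])

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ConfigurationError):
            rn.build_wm_mask([_prob_map(np.full((4, 4, 4), 1.5))])

    def test_empty_result_is_degenerate(self):
        with pytest.raises(DegenerateMaskError):
            rn.build_wm_mask([_prob_map(np.zeros((4, 4, 4)))])


class TestFitAtlas:
    def test_voxelwise_ols_matches_normal_equations(self, rng):
        """Implementation (vectorized lstsq) vs closed-form per-voxel solver."""
        n = 9
        ages = rng.integers(20, 62, size=n)
        while len(np.unique(ages)) < 3:
            ages = rng.integers(20, 62, size=n)
        volumes = [rn.VolumeGrid(rng.normal(1.0, 0.2, size=(5, 5, 5))) for _ in range(n)]
        atlas = rn.fit_atlas(volumes, list(ages), _full_mask((5, 5, 5)))
        a = ages - ages.mean()
        X = np.column_stack([np.ones(n), a, a * a])
        for idx in [(0, 0, 0), (2, 3, 4), (4, 4, 4)]:
            y = np.array([v.data[idx] for v in volumes])
            beta, ssr = ols_normal_equations(X, y)
            assert atlas.beta0.data[idx] == pytest.approx(beta[0], abs=1e-8)
            assert atlas.beta_age.data[idx] == pytest.approx(beta[1], abs=1e-8)
            assert atlas.beta_age2.data[idx] == pytest.approx(beta[2], abs=1e-8)
            assert atlas.rmse.data[idx] == pytest.approx(np.sqrt(ssr / (n - 3)), abs=1e-8)

    def test_noiseless_phantom_recovers_generative_coefficients(self, small_spec, small_labels):
        """Noiseless cohort: the fitted model equals the generative quadratic,
        re-centered at the cohort mean age."""
        spec = dataclasses.replace(small_spec, noise_sd=0.0)
        ages = [25, 30, 35, 40, 45, 50, 55, 60]
        volumes = [rn.generate_subject(spec, small_labels, a) for a in ages]
        wm_mask = rn.build_wm_mask([rn.wm_probability_map(small_labels)])
        atlas = rn.fit_atlas(volumes, ages, wm_mask)
        # perfect fit everywhere -> all voxels flagged degenerate for z scoring
        assert atlas.mask.n_voxels == 0
        beta_age, beta_age2 = spec.age_coeffs
        d = np.mean(ages) - spec.ref_age  # shift between the two centerings
        inmask = wm_mask.mask.data & (small_labels.data == 2)  # WM voxels
        wm_baseline = spec.baseline_r1["wm"]
        np.testing.assert_allclose(
            atlas.beta0.data[inmask],
            wm_baseline + beta_age * d + beta_age2 * d * d,
            atol=1e-8,
        )
        np.testing.assert_allclose(
            atlas.beta_age.data[inmask], beta_age + 2 * beta_age2 * d, atol=1e-8
        )
        np.testing.assert_allclose(atlas.beta_age2.data[inmask], beta_age2, atol=1e-8)
        np.testing.assert_allclose(atlas.rmse.data[inmask], 0.0, atol=1e-8)

    def test_constant_voxels_are_flagged_degenerate(self, rng):
        n, shape = 6, (4, 4, 4)
        ages = [25, 30, 40, 45, 50, 60]
        volumes = [rn.VolumeGrid(rng.normal(1.0, 0.1, size=shape)) for _ in range(n)]
        for v in volumes:
            v.data[0, 0, 0] = 1.07  # identical across subjects -> rmse 0
        atlas = rn.fit_atlas(volumes, ages, _full_mask(shape))
        assert not atlas.mask.mask.data[0, 0, 0]
        assert atlas.rmse.data[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert atlas.beta0.data[0, 0, 0] == pytest.approx(1.07, abs=1e-12)
        assert atlas.mask.mask.data[1:].all()

    def test_all_constant_cohort_fits_perfectly_with_empty_mask(self):
        volumes = [rn.VolumeGrid(np.full((4, 4, 4), 1.07)) for _ in range(6)]
        atlas = rn.fit_atlas(volumes, [25, 30, 40, 45, 50, 60], _full_mask())
        assert atlas.mask.n_voxels == 0
        np.testing.assert_allclose(atlas.beta0.data, 1.07, atol=1e-12)
        np.testing.assert_allclose(atlas.beta_age.data, 0.0, atol=1e-12)
        np.testing.assert_allclose(atlas.beta_age2.data, 0.0, atol=1e-12)
        np.testing.assert_allclose(atlas.rmse.data, 0.0, atol=1e-12)

    def test_nan_voxels_are_excluded(self, rng):
        volumes = [rn.VolumeGrid(rng.normal(1.0, 0.1, size=(4, 4, 4))) for _ in range(6)]
        volumes[2].data[1, 1, 1] = np.nan  # e.g. an invalid VFA fit
        atlas = rn.fit_atlas(volumes, [25, 30, 40, 45, 50, 60], _full_mask())
        assert not atlas.mask.mask.data[1, 1, 1]

    def test_too_few_distinct_ages_rejected(self, rng):
        volumes = [rn.VolumeGrid(rng.normal(size=(4, 4, 4))) for _ in range(6)]
        with pytest.raises(DesignError):
            rn.fit_atlas(volumes, [30, 30, 30, 40, 40, 40], _full_mask())

    def test_length_mismatch_rejected(self, rng):
        volumes = [rn.VolumeGrid(rng.normal(size=(4, 4, 4))) for _ in range(6)]
        with pytest.raises(ConfigurationError):
            rn.fit_atlas(volumes, [30, 40, 50], _full_mask())

    def test_rmse_denominator_convention_switch(self, rng):
        n = 8
        ages = [25, 28, 33, 39, 44, 50, 55, 61]
        volumes = [rn.VolumeGrid(rng.normal(1.0, 0.2, size=(4, 4, 4))) for _ in range(n)]
        df_atlas = rn.fit_atlas(volumes, ages, _full_mask(), rmse_denominator="df")
        n_atlas = rn.fit_atlas(volumes, ages, _full_mask(), rmse_denominator="n")
        ratio = df_atlas.rmse.data / n_atlas.rmse.data
        np.testing.assert_allclose(ratio[np.isfinite(ratio)], np.sqrt(n / (n - 3)))


class TestPredict:
    def test_centering_identity_is_bitwise(self, small_atlas):
        expected = rn.predict(small_atlas, small_atlas.ref_age)
        inmask = small_atlas.mask.mask.data
        np.testing.assert_array_equal(
            expected.data[inmask], small_atlas.beta0.data[inmask]
        )

    def test_hand_arithmetic_example(self):
        shape = (4, 4, 4)
        mask = _full_mask(shape)
        grid = mask.mask
        atlas = rn.NormativeAtlas(
            beta0=grid.like(np.full(shape, 1.0)),
            beta_age=grid.like(np.full(shape, 0.01)),
            beta_age2=grid.like(np.full(shape, -0.001)),
            rmse=grid.like(np.full(shape, 0.15)),
            ref_age=39.0,
            mask=mask,
            n_subjects=25,
        )
        value = rn.predict(atlas, 41).data[0, 0, 0]
        assert value == pytest.approx(1.0 + 0.02 - 0.004, abs=1e-12)

    def test_extrapolation_warns(self, small_atlas):
        with pytest.warns(UserWarning, match="extrapolat"):
            rn.predict(small_atlas, int(small_atlas.ref_age) + 70)


class TestPersistence:
    def test_save_load_round_trip(self, small_atlas, tmp_path):
        outdir = rn.save_atlas(small_atlas, tmp_path / "atlas")
        back = rn.load_atlas(outdir)
        assert back.ref_age == small_atlas.ref_age
        assert back.n_subjects == small_atlas.n_subjects
        np.testing.assert_array_equal(back.mask.mask.data, small_atlas.mask.mask.data)
        inmask = small_atlas.mask.mask.data
        np.testing.assert_allclose(
            back.rmse.data[inmask], small_atlas.rmse.data[inmask], rtol=1e-6
        )
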