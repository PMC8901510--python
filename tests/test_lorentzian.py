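"""Two-pool Lorentzian background model: evaluation and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cestquant as cq
from cestquant.lorentzian import (
    PARAM_NAMES,
    FitConfig,
    FitSubsets,
    LorentzianPool,
    TwoPoolLorentzianModel,
)


class TestLorentzianValue:
    def test_amplitude_at_center(self):
        pool = LorentzianPool(0.8, 2.0, 0.0)
        assert cq.lorentzian_value(pool, 0.0) == pytest.approx(0.8, abs=1e-15)

    def test_half_maximum_at_half_width(self):
        # FWHM definition: value is A/2 at center +- L/2
        pool = LorentzianPool(0.8, 2.0, 0.0)
        np.testing.assert_allclose(cq.lorentzian_value(pool, [1.0, -1.0]), 0.4)

    def test_plugin_arithmetic(self):
        pool = LorentzianPool(0.1, 30.0, 0.0)
        assert cq.lorentzian_value(pool, 15.0) == pytest.approx(0.05, abs=1e-15)

    def test_invalid_pool_rejected(self):
        with pytest.raises(ValueError):
            LorentzianPool(-0.1, 2.0, 0.0)
        with pytest.raises(ValueError):
            LorentzianPool(0.1, 0.0, 0.0)


class TestZrefValue:
    def test_no_pools_gives_unity(self):
        p = dict(zip(PARAM_NAMES, [0, 1, 0, 0, 30, 0, 0]))
        offs = np.linspace(-50, 50, 11)
        np.testing.assert_allclose(cq.zref_value(p, offs), 1.0)

    def test_water_only_at_center(self):
        p = [0.8, 2.0, 0.0, 0.0, 30.0, 0.0, 0.0]
        assert cq.zref_value(p, 0.0) == pytest.approx(0.2, abs=1e-15)

    def test_baseline_at_infinity(self):
        p = [0.8, 2.0, 0.0, 0.1, 30.0, 0.0, 0.05]
        assert cq.zref_value(p, 1e7) == pytest.approx(1.05, abs=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(delta=st.integers(-64, 64).map(lambda n: n / 64),
           x=st.integers(0, 1280).map(lambda n: n / 64))
    def test_single_pool_symmetric_about_center(self, delta, x):
        # dyadic-rational centers and offsets make delta +- x exact in
        # floating point, so the mirror identity holds bit-for-bit
        p = [0.7, 1.5, delta, 0.0, 30.0, 0.0, 0.0]
        assert cq.zref_value(p, delta + x) == cq.zref_value(p, delta - x)


class TestFitSubsets:
    def test_defaults_are_disjoint_and_resolve(self, schedule):
        subsets = FitSubsets()
        idx = subsets.indices_in(schedule)
        assert len(idx) == 25  # 7 DS + 18 MT points

    def test_overlapping_subsets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            FitSubsets(ds_offsets=(0.0, 1.0), mt_offsets=(1.0, 10.0))

    def test_missing_offset_raises_before_fitting(self, schedule):
        subsets = FitSubsets(ds_offsets=(0.0, 0.33), mt_offsets=(10.0, -10.0, 20.0,
                                                                 -20.0, 30.0, -30.0))
        z = np.ones(len(schedule))
        with pytest.raises(ValueError, match="not present"):
            TwoPoolLorentzianModel(schedule.offsets, z, subsets=subsets)


TRUE_PARAMS = dict(zip(PARAM_NAMES, (0.85, 1.4, 0.05, 0.10, 30.0, 0.0, 0.0)))


class TestFitRecovery:
    def test_noiseless_roundtrip_recovers_parameters(self, schedule):
        z = cq.zref_value(TRUE_PARAMS, schedule.offsets)
        res = cq.fit_two_pool(schedule.offsets, z)
        assert res.converged
        for name, true in TRUE_PARAMS.items():
            est = res.params_dict[name]
            assert abs(est - true) / max(abs(true), 1.0) < 1e-3, name

    def test_noiseless_residual_is_tiny(self, schedule):
        z = cq.zref_value(TRUE_PARAMS, schedule.offsets)
        res = cq.fit_two_pool(schedule.offsets, z)
        assert res.residual_rms < 1e-6

    def test_flat_spectrum_gives_zero_amplitudes(self, schedule):
        res = cq.fit_two_pool(schedule.offsets, np.ones(len(schedule)))
        assert res.converged
        assert res.params_dict["a_water"] < 1e-4
        assert res.params_dict["a_mt"] < 1e-4
        assert abs(res.params_dict["b"]) < 1e-4

    def test_shifted_water_center_recovered(self, schedule):
        p = dict(TRUE_PARAMS, d_water=0.3)
        z = cq.zref_value(p, schedule.offsets)
        res = cq.fit_two_pool(schedule.offsets, z)
        assert res.params_dict["d_water"] == pytest.approx(0.3, abs=0.01)

    def test_sentinel_fit_on_nonfinite_data(self, schedule):
        z = cq.zref_value(TRUE_PARAMS, schedule.offsets)
        z[schedule.index_of([0.25])[0]] = np.nan
        res = cq.fit_two_pool(schedule.offsets, z)
        assert not res.converged
        assert np.all(np.isnan(res.params))

    def test_standard_errors_positive_for_noisy_fit(self, schedule):
        rng = np.random.default_rng(5)
        z = cq.zref_value(TRUE_PARAMS, schedule.offsets) + rng.normal(0, 0.002, len(schedule))
        res = cq.fit_two_pool(schedule.offsets, z)
        assert res.converged
        assert np.all(res.bse > 0)
        # with this noise level the amplitude must still be well resolved
        assert res.bse[0] < 0.05

    def test_summary_contains_estimates(self, schedule):
        z = cq.zref_value(TRUE_PARAMS, schedule.offsets)
        text = cq.fit_two_pool(schedule.offsets, z).summary()
        assert "a_water" in text and "converged: True" in text

    def test_agrees_with_lmfit_oracle(self, schedule):
        # independent optimiser + model formulation as the cross-check
        lmfit = pytest.importorskip("lmfit")

        z = cq.zref_value(TRUE_PARAMS, schedule.offsets)
        rng = np.random.default_rng(9)
        z = z + rng.normal(0, 0.001, len(schedule))
        subsets = FitSubsets()
        idx = subsets.indices_in(schedule)
        x, y = schedule.offsets[idx], z[idx]

        def model(params, x):
            v = params.valuesdict()
            lw = lambda a, l, d: a * (l * l / 4) / (l * l / 4 + (x - d) ** 2)
            return 1 - lw(v["aw"], v["lw"], v["dw"]) - lw(v["am"], v["lm"], v["dm"]) + v["b"]

        params = lmfit.Parameters()
        for name, init, lo, hi in [("aw", 0.8, 0, 1), ("lw", 1.5, 0.3, 10),
                                   ("dw", 0, -1, 1), ("am", 0.1, 0, 1),
                                   ("lm", 40, 10, 300), ("dm", 0, -4, 4),
                                   ("b", 0, -0.2, 0.2)]:
            params.add(name, value=init, min=lo, max=hi)
        ref = lmfit.minimize(lambda p: model(p, x) - y, params)
        ours = cq.fit_two_pool(schedule.offsets, z)
        ref_vec = [ref.params[k].value for k in ("aw", "lw", "dw", "am", "lm", "dm", "b")]
        np.testing.assert_allclose(ours.params, ref_vec, rtol=1e-4, atol=1e-6)


class TestFitVolume:
    def test_recovers_mt_amplitude_map(self, small_noiseless_fits, small_noiseless_phantom):
        _, _, truth = small_noiseless_phantom
        fitted = small_noiseless_fits.map("a_mt")
        true = truth.pool_amplitudes["mt"]
        ok = small_noiseless_fits.converged
        r = np.corrcoef(fitted[ok], true[ok])[0, 1]
        # spatial structure (3 tissue levels) must be reproduced essentially exactly
        assert r > 0.99

    def test_convergence_fraction_complete_on_noiseless_phantom(self, small_noiseless_fits):
        assert small_noiseless_fits.convergence_fraction == 1.0

    def test_empty_mask_does_no_work(self, small_noiseless_zvol):
        import dataclasses

        zvol = dataclasses.replace(small_noiseless_zvol,
                                   mask=np.zeros(small_noiseless_zvol.spatial_shape, bool))
        fits = cq.fit_volume(zvol)
        assert not fits.converged.any()
        assert np.all(np.isnan(fits.params))

    def test_voxel_with_nonfinite_subset_value_is_sentinel(self, small_noiseless_zvol, schedule):
        import dataclasses

        z = small_noiseless_zvol.z.copy()
        z[0, 0, 0, schedule.index_of([0.0])[0]] = np.nan
        zvol = dataclasses.replace(small_noiseless_zvol, z=z)
        fits = cq.fit_volume(zvol)
        assert not fits.converged[0, 0, 0]
        assert np.all(np.isnan(fits.params[0, 0, 0]))
        assert fits.converged[1, 1, 1]
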