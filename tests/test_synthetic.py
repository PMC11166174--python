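"""Synthetic-data generator: scenarios, input function, phantoms, noise."""

import numpy as np
import pytest

from maglpet import (
    PhantomSpec,
    ValidationError,
    add_noise,
    extract_roi_tac,
    fit_monoexp,
    generate_input_function,
    generate_phantom,
    generate_regional_tacs,
    make_scenario,
    percent_reduction,
)
from maglpet.kinetics import TimeActivityCurve


class TestInputFunction:
    def test_default_extinct_by_15_min(self):
        inp, meta = generate_input_function()
        assert meta["extinct_by_15min"]
        assert meta["fraction_at_15min"] < 0.01

    def test_zero_amplitudes_give_zero_curve(self):
        inp, _ = generate_input_function(A1=0.0, A2=0.0, require_extinct_by=None)
        t = np.linspace(0, 90, 50)
        assert np.all(inp(t) == 0.0)

    def test_peak_matches_dense_grid_search(self):
        inp, _ = generate_input_function()
        t_peak, v_peak = inp.peak()
        t = np.linspace(0.0, 30.0, 300001)
        cp = inp(t)
        i = np.argmax(cp)
        assert t_peak == pytest.approx(t[i], abs=1e-3)
        assert v_peak == pytest.approx(cp[i], rel=1e-8)

    def test_slow_input_flagged(self):
        with pytest.warns(UserWarning):
            _, meta = generate_input_function(A1=5.0, A2=0.0, lam1=0.05, lam2=1.0)
        assert not meta["extinct_by_15min"]


class TestScenarios:
    def test_healthy_recovery_within_5_percent(self):
        tacs, truth = generate_regional_tacs(make_scenario("healthy"))
        for region, tac in tacs.items():
            kh_true = truth[region]["kh_per_h"]
            fit = fit_monoexp(tac)
            assert abs(fit.kh - kh_true) / kh_true < 0.05

    def test_healthy_peaks_in_reported_band(self):
        tacs, _ = generate_regional_tacs(make_scenario("healthy"))
        peaks = np.array([t.values.max() for t in tacs.values()])
        assert np.all((peaks > 1.55) & (peaks < 1.95))

    def test_non_hydrolyzable_probe_plateaus(self, schedule):
        tacs, _ = generate_regional_tacs(make_scenario("hppc_like"))
        tac = tacs["cerebral_cortex"]
        v20 = tac.values[schedule.frame_containing(20.0)]
        v90 = tac.values[-1]
        assert abs(v90 - v20) / v20 < 0.05

    def test_blocked_scenario_reduces_uptake(self):
        tacs_h, _ = generate_regional_tacs(make_scenario("healthy"))
        tacs_b, _ = generate_regional_tacs(make_scenario("blocked"))
        assert (tacs_b["cerebral_cortex"].values.max()
                < tacs_h["cerebral_cortex"].values.max())

    def test_stroke_contrast_recovered_noise_free(self):
        tacs, truth = generate_regional_tacs(make_scenario("mcao_3_4h"))
        fit_i = fit_monoexp(tacs["ipsilateral"]).kh
        fit_c = fit_monoexp(tacs["contralateral"]).kh
        assert abs(percent_reduction(fit_i, fit_c) - 34.0) < 5.0
        assert truth["ipsilateral"]["kh_per_h"] == pytest.approx(0.41)
        assert truth["contralateral"]["kh_per_h"] == pytest.approx(0.62)

    def test_same_seed_bit_identical(self):
        a, _ = generate_regional_tacs(make_scenario("healthy", noise=0.05, seed=7))
        b, _ = generate_regional_tacs(make_scenario("healthy", noise=0.05, seed=7))
        for region in a:
            assert np.array_equal(a[region].values, b[region].values)

    def test_different_seed_differs(self):
        a, _ = generate_regional_tacs(make_scenario("healthy", noise=0.05, seed=7))
        b, _ = generate_regional_tacs(make_scenario("healthy", noise=0.05, seed=8))
        assert not np.array_equal(a["striatum"].values, b["striatum"].values)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValidationError):
            make_scenario("no_such_condition")

    def test_noisy_recovery_bias_and_spread(self):
        # 5 % frame noise, 100 seeds: |mean bias| < 5 %, SD in the range of
        # the reported inter-animal scatter (0.05-0.08 1/h around 0.7)
        fits = []
        for seed in range(100):
            tacs, truth = generate_regional_tacs(
                make_scenario("healthy", noise=0.05, seed=seed))
            fits.append(fit_monoexp(tacs["cerebral_cortex"]).kh)
        fits = np.array(fits)
        assert abs(fits.mean() - 0.66) / 0.66 < 0.05
        assert fits.std(ddof=1) < 2 * 0.08


class TestPhantom:
    def test_zero_noise_round_trip(self):
        img, masks, truth = generate_phantom(PhantomSpec(shape=(16, 16, 8)))
        for mask_name, region in [("contralateral", "contralateral"),
                                  ("ipsilateral_lesion", "ipsilateral")]:
            tac = extract_roi_tac(img, masks[mask_name])
            assert np.abs(tac.values - truth["regional_tacs"][region].values).max() < 1e-12

    def test_delivery_ratio_matches_spec(self):
        img, masks, _ = generate_phantom(PhantomSpec(shape=(16, 16, 8)))
        early = img.data[..., 2:10].mean(axis=3)
        ratio = early[masks["ipsilateral_lesion"]].mean() / early[masks["contralateral"]].mean()
        assert abs(ratio - 0.30) / 0.30 < 0.05

    def test_labels_partition_brain(self):
        pspec = PhantomSpec(shape=(16, 16, 8))
        labels = pspec.label_volume()
        _, masks, _ = generate_phantom(pspec)
        combined = (masks["contralateral"] | masks["ipsilateral_intact"]
                    | masks["ipsilateral_lesion"])
        assert np.array_equal(combined, masks["brain"])
        assert np.array_equal(masks["brain"], labels > 0)

    def test_ground_truth_maps_follow_labels(self):
        img, masks, truth = generate_phantom(PhantomSpec(shape=(16, 16, 8)))
        assert np.all(truth["kh_map"][masks["ipsilateral_lesion"]] == 0.41)
        assert np.all(truth["kh_map"][masks["contralateral"]] == 0.62)
        assert np.all(np.isnan(truth["kh_map"][~masks["brain"]]))


class TestAddNoise:
    def test_zero_level_is_identity(self, schedule):
        tac = TimeActivityCurve(schedule, np.linspace(1, 2, 26))
        out = add_noise(tac, 0.0, seed=1)
        assert np.array_equal(out.values, tac.values)

    def test_seed_reproducibility(self, schedule):
        tac = TimeActivityCurve(schedule, np.linspace(1, 2, 26))
        a = add_noise(tac, 0.05, seed=3)
        b = add_noise(tac, 0.05, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_empirical_sd_matches_nominal(self, schedule):
        # 10^4 replicates of a constant frame at 5 %: SD within 3 % of nominal
        tac = TimeActivityCurve(schedule, np.full(26, 1.0))
        rng = np.random.default_rng(11)
        frame = schedule.durations == 5.0
        draws = np.array([add_noise(tac, 0.05, rng=rng).values[-1]
                          for _ in range(10_000)])
        nominal = 0.05 * 1.0 / np.sqrt(5.0)
        assert abs(draws.std(ddof=1) - nominal) / nominal < 0.03

    def test_negative_level_rejected(self, schedule):
        tac = TimeActivityCurve(schedule, np.ones(26))
        with pytest.raises(ValidationError):
            add_noise(tac, -0.1)
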