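"""Generator behaviour: scenarios, outcomes, traces, stacks, tables."""

import numpy as np
import pandas as pd
import pytest

from granulekit import fcs, synthetic
from granulekit.synthetic import (
    EventParams,
    make_scenario,
    sample_diameters,
    simulate_depletion_blot,
    simulate_fcs,
    simulate_fusion_outcomes,
    simulate_lipid_table,
    simulate_secretion,
    simulate_stack,
    simulate_trace,
    two_step_profile,
)


class TestScenarios:
    def test_syt7_only_single_population_with_half_activation_10(self):
        cfg = make_scenario("syt7_only", 1)
        assert len(cfg.populations) == 1
        assert cfg.populations[0].k_half == 10.0

    def test_untreated_has_two_populations_weights_sum_to_one(self):
        cfg = make_scenario("untreated", 1)
        assert len(cfg.populations) == 2
        assert sum(p.weight for p in cfg.populations) == pytest.approx(1.0)

    def test_override_replaces_named_field_only(self):
        cfg = make_scenario("ffa", 1, {"k_half": 20})
        assert cfg.populations[0].k_half == 20
        assert cfg.populations[0].pore_rate == make_scenario("ffa", 1).populations[0].pore_rate

    def test_per_population_override(self):
        cfg = make_scenario("untreated", 1, {"syt9": {"diam_mean": 230.0}})
        by_label = {p.label: p for p in cfg.populations}
        assert by_label["syt9"].diam_mean == 230.0
        assert by_label["syt7"].diam_mean == 175.0

    @pytest.mark.parametrize(
        "name,override",
        [("nonsense", {}), ("ffa", {"not_a_field": 1}), ("ffa", {"syt9": {"k_half": 1}})],
    )
    def test_invalid_scenario_or_override_raises(self, name, override):
        with pytest.raises(ValueError):
            make_scenario(name, 0, override)

    def test_single_population_scenarios_match_treatment_model(self):
        # palmitate leaves syt7 granules, cytokines leave syt9 granules
        assert make_scenario("ffa", 0).populations[0].label == "syt7"
        assert make_scenario("cytokine", 0).populations[0].label == "syt9"

    def test_fast_mode_has_larger_collapse_gain(self):
        pops = {p.label: p for p in make_scenario("untreated", 0).populations}
        assert pops["syt9"].collapse_gain > pops["syt7"].collapse_gain


class TestFusionOutcomes:
    def test_half_activation_gives_half_maximal_fusion(self):
        cfg = make_scenario("syt7_only", 0, {"max_fuse_prob": 1.0})
        out = simulate_fusion_outcomes(cfg, [10.0], 4000, seed=3)
        frac = out["fused"].mean()
        # binomial 99% CI around 0.5 at n=4000
        assert abs(frac - 0.5) < 2.6 * np.sqrt(0.25 / 4000)

    def test_vanishing_calcium_gives_no_fusion(self, untreated):
        out = simulate_fusion_outcomes(untreated, [1e-4], 500, seed=1)
        assert out["fused"].sum() == 0

    def test_untreated_fraction_at_100um_matches_calibration(self, untreated):
        closed_form = float(synthetic.expected_fraction_fused(untreated, 100.0))
        fracs = [
            simulate_fusion_outcomes(untreated, [100.0], 500, seed=s)["fused"].mean()
            for s in range(10)
        ]
        assert closed_form == pytest.approx(0.60, abs=0.01)
        assert np.mean(fracs) == pytest.approx(closed_form, abs=0.02)

    def test_rejects_bad_inputs(self, untreated):
        with pytest.raises(ValueError):
            simulate_fusion_outcomes(untreated, [-1.0], 10)
        with pytest.raises(ValueError):
            simulate_fusion_outcomes(untreated, [10.0], 0)

    def test_bit_reproducible(self, untreated):
        a = simulate_fusion_outcomes(untreated, [10, 50], 100, seed=9)
        b = simulate_fusion_outcomes(untreated, [10, 50], 100, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestTraces:
    def test_no_collapse_step_is_monotone_nonincreasing_after_onset(self):
        ev = EventParams(1000, 1.0, 0.5, 0.0, 0.5, 2.0)
        vals, _ = simulate_trace(ev, 0.05, 200, noise_sd=0.0)
        post = vals[21:]  # frames after onset
        assert np.all(np.diff(post) <= 1e-9)

    def test_step_height_is_delta_ic_by_construction(self):
        ev = EventParams(1000, 1.0, 0.5, 0.8, 0.5, 2.0)
        _, truth = simulate_trace(ev, 0.05, 200, noise_sd=0.0)
        eps = 1e-9
        lo, hi = two_step_profile(np.array([ev.collapse_s - eps, ev.collapse_s]), ev)
        assert hi - lo == pytest.approx(truth["delta_ic"], rel=1e-6)

    def test_collapse_gain_applies_to_pre_collapse_intensity(self):
        # i_dock 100 decayed to 80 at collapse, gain 0.5 -> step of 40 counts
        ev = EventParams(
            i_dock=100.0, onset_s=1.0, pore_rate=-np.log(0.8), collapse_gain=0.5,
            post_rate=1.0, pore_duration=1.0,
        )
        assert ev.i_pre_collapse == pytest.approx(80.0)
        assert ev.delta_ic == pytest.approx(40.0)
        t = np.array([1.999, 2.0])
        lo, hi = two_step_profile(t, ev)
        assert hi - lo == pytest.approx(40.0, abs=0.1)

    def test_onset_outside_window_raises(self):
        ev = EventParams(1000, 50.0, 0.5, 0.3, 0.5, 2.0)
        with pytest.raises(ValueError):
            simulate_trace(ev, 0.05, 100, 0.0)


class TestStacks:
    def test_background_only_stack_is_poisson(self):
        cfg = make_scenario("untreated", 0)
        stack, truth = simulate_stack(cfg, 100.0, (64, 64), n_granules=0,
                                      background=100.0, n_frames=50, seed=1)
        assert len(truth) == 0
        assert stack.mean() == pytest.approx(100.0, rel=0.01)
        assert stack.var() == pytest.approx(100.0, rel=0.05)

    def test_unfused_spots_show_up_as_local_maxima(self):
        from granulekit import tirf

        cfg = make_scenario("untreated", 0, {"max_fuse_prob": 0.0})
        stack, truth = simulate_stack(cfg, 100.0, (64, 64), n_granules=3, seed=2)
        det = tirf.detect(stack.astype(float))
        assert len(det.centers) == 3

    def test_roi_trace_tracks_simulated_amplitude(self):
        # noiseless render: the 5x5 ROI sum is the amplitude profile times
        # the PSF integration factor
        cfg = make_scenario("syt9_only", 0, {"max_fuse_prob": 1.0, "delay_mean": 0.5})
        rng_stack, truth = simulate_stack(
            cfg, 300.0, (64, 64), n_granules=1, background=0.0, seed=5,
            n_frames=100,
        )
        g = truth.iloc[0]
        assert g["fused"]
        # rebuild noiseless profile and compare shape to the Poisson stack ROI
        pop = cfg.populations[0]
        ev = synthetic.event_params(pop, onset_s=g["onset_s"])
        t = np.arange(100) * 0.05
        profile = two_step_profile(t, ev)
        ix, iy = int(round(g["x_px"])), int(round(g["y_px"]))
        roi = rng_stack[:, iy - 2 : iy + 3, ix - 2 : ix + 3].sum(axis=(1, 2)).astype(float)
        factor = roi[:10].mean() / profile[:10].mean()
        assert np.corrcoef(roi, profile)[0, 1] > 0.99
        assert roi / factor == pytest.approx(profile, abs=6 * np.sqrt(roi.max()) / factor)

    def test_too_many_granules_raises(self):
        cfg = make_scenario("untreated", 0)
        with pytest.raises(RuntimeError):
            simulate_stack(cfg, 100.0, (32, 32), n_granules=200, seed=1)


class TestFcsGenerator:
    def test_diffusion_only_curve_strictly_decreasing_to_one(self):
        c = simulate_fcs(rh=97e-9, t_b=0.0, noise=0.0, noise_floor=0.0,
                         n_runs=1, temperature_jitter=0.0, seed=0)[0]
        assert np.all(np.diff(c.g) < 0)
        assert c.g[-1] == pytest.approx(1.0, abs=1e-3)

    def test_rh_maps_to_expected_diffusion_coefficient(self):
        d = fcs.diffusion_coefficient(97e-9, 298.15)
        assert d == pytest.approx(2.53e-12, rel=0.01)

    def test_diffusion_time_closed_form(self):
        tau_d = (0.2e-6) ** 2 / (4 * 2.53e-12)
        assert tau_d == pytest.approx(3.95e-3, rel=0.01)

    def test_nonphysical_inputs_raise(self):
        with pytest.raises(ValueError):
            simulate_fcs(rh=97e-9, structure=0.8)
        with pytest.raises(ValueError):
            simulate_fcs(rh=97e-9, t_b=1.0)
        with pytest.raises(ValueError):
            simulate_fcs(rh=97e-9, d=1e-12)


class TestDiameters:
    def test_single_population_mean_converges(self):
        cfg = make_scenario("syt9_only", 0)
        d = sample_diameters(cfg, 200_000, seed=4)
        assert d.mean() == pytest.approx(215.0, abs=0.5)

    def test_untreated_mixture_mean_near_195(self, untreated):
        d = sample_diameters(untreated, 100_000, seed=4)
        assert d.mean() == pytest.approx(195.0, abs=1.0)

    def test_mixture_moments_match_closed_form(self, untreated):
        # mixture mean and SD from component parameters
        w = untreated.weights()
        mu = np.array([p.diam_mean for p in untreated.populations])
        sd = np.array([p.diam_sd for p in untreated.populations])
        mix_mean = float(w @ mu)
        mix_sd = float(np.sqrt(w @ (sd**2 + mu**2) - mix_mean**2))
        d = sample_diameters(untreated, 200_000, seed=11)
        assert d.mean() == pytest.approx(mix_mean, abs=3 * mix_sd / np.sqrt(d.size))
        assert d.std(ddof=1) == pytest.approx(mix_sd, rel=0.01)

    def test_single_draw_is_positive(self, untreated):
        assert sample_diameters(untreated, 1, seed=0)[0] > 0


class TestLipidTable:
    def test_null_table_has_nominal_false_positive_rate(self):
        from granulekit import biochem

        hits = []
        for seed in range(8):
            t = simulate_lipid_table(n_species=250, enriched={}, seed=seed)
            vol = biochem.volcano(biochem.normalize_lipids(t))
            hits.append(vol["significant"].mean())
        assert np.mean(hits) == pytest.approx(0.05, abs=0.02)

    def test_enriched_species_true_ratio(self):
        t = simulate_lipid_table(cv=1e-6, seed=0)
        from granulekit import biochem

        norm = biochem.normalize_lipids(t)
        g7 = norm.groups[norm.groups == "syt7"].index
        g9 = norm.groups[norm.groups == "syt9"].index
        ratio = norm.areas.loc["SM 42:1", g7].mean() / norm.areas.loc["SM 42:1", g9].mean()
        assert ratio == pytest.approx(3.0, rel=1e-3)

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError):
            synthetic.LipidTable(
                areas=pd.DataFrame(np.ones((2, 2)), index=["a", "a"], columns=["s1", "s2"]),
                species_class=pd.Series(["PC", "PC"], index=["a", "a"]),
                groups=pd.Series(["syt7", "syt9"], index=["s1", "s2"]),
                internal_standard=pd.Series(1.0, index=["s1", "s2"]),
                protein=pd.Series(1.0, index=["s1", "s2"]),
            )


class TestDepletionAndSecretion:
    def test_depletion_worked_example(self):
        blot = simulate_depletion_blot({"MIF": 0.8}, noise=0.0)
        row = blot.iloc[0]
        assert row["dep9"] == pytest.approx(8.0)  # syt9-depleted keeps syt7 pool
        assert row["dep7"] == pytest.approx(2.0)

    @pytest.mark.parametrize("f7,dep7,dep9", [(1.0, 0.0, 10.0), (0.5, 5.0, 5.0)])
    def test_depletion_limits(self, f7, dep7, dep9):
        row = simulate_depletion_blot({"p": f7}, noise=0.0).iloc[0]
        assert row["dep7"] == pytest.approx(dep7)
        assert row["dep9"] == pytest.approx(dep9)

    def test_secretion_increases_with_stimulus_for_untreated(self, untreated):
        s25 = np.mean([m.secreted for m in simulate_secretion(untreated, 25.0, seed=1)])
        s90 = np.mean([m.secreted for m in simulate_secretion(untreated, 90.0, seed=2)])
        assert s90 > s25

    def test_ffa_response_saturates_at_mild_stimulus(self):
        # the high-affinity syt7 population is near-saturated already at the
        # mild-depolarisation calcium surrogate, unlike the untreated mixture
        ffa = make_scenario("ffa", 0)
        unt = make_scenario("untreated", 0)
        ratio = {
            c.name: float(
                synthetic.expected_fraction_fused(c, synthetic.KCL_TO_CALCIUM_UM[90.0])
                / synthetic.expected_fraction_fused(c, synthetic.KCL_TO_CALCIUM_UM[25.0])
            )
            for c in (ffa, unt)
        }
        assert ratio["ffa"] < 2.0
        assert ratio["ffa"] < ratio["untreated"]

    def test_zero_stimulus_yields_leak_only(self, untreated):
        ms = simulate_secretion(untreated, 0.0, seed=3, cv=1e-9)
        frac = np.mean([m.secreted / (m.secreted + m.lysate) for m in ms])
        assert frac == pytest.approx(0.02, abs=0.002)
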