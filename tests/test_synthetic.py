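"""Physical and statistical consistency of the trial/cohort generators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinegen.errors import ConfigError
from kinegen.events import net_vertical_impulse
from kinegen.genetics import hwe_chi_square
from kinegen.synthetic import (
    CohortSimConfig,
    JumpSimConfig,
    SprintSimConfig,
    simulate_cohort,
    simulate_jump_trial,
    simulate_quiet_standing,
    simulate_sprint_trial,
)

G = 9.81


class TestJumpTrial:
    def test_same_seed_bit_identical(self):
        cfg = JumpSimConfig(jump_type="CMJ", noise_sd=0.002, seed=11)
        m1, f1, t1 = simulate_jump_trial(cfg)
        m2, f2, t2 = simulate_jump_trial(JumpSimConfig(jump_type="CMJ", noise_sd=0.002, seed=11))
        assert np.array_equal(m1.positions, m2.positions)
        assert np.array_equal(f1.fz, f2.fz)
        assert t1.phase_times == t2.phase_times

    def test_flight_force_exactly_zero(self, cmj_trial):
        _, fp, truth = cmj_trial
        t0, t1 = truth.phase_times["F2"]
        sel = (fp.time > t0 + 1e-9) & (fp.time < t1 - 1e-9)
        assert (fp.fz[sel] == 0.0).all()

    def test_apex_equals_target_flight_height(self):
        for jt, box in (("CMJ", 0.0), ("DJ", 0.20)):
            cfg = JumpSimConfig(jump_type=jt, target_flight_height=0.25)
            markers, _, truth = simulate_jump_trial(cfg)
            z = markers.get("F_sacrum")[:, 2]
            s, e = truth.phase_frames("F2")
            ref = "L1" if jt == "CMJ" else "D"
            standing = z[truth.phase_frames(ref)[0]] - box
            assert abs(z[s:e].max() - standing - 0.25) < 1e-3

    def test_flight_height_consistent_with_takeoff_velocity(self, dj_trial):
        truth = dj_trial[2]
        assert abs(truth.flight_height - truth.v_takeoff**2 / (2 * G)) < 1e-9

    def test_propulsion_impulse_matches_momentum(self, cmj_trial):
        # trapezoid-rule impulse oracle against m * sqrt(2 g h)
        _, fp, truth = cmj_trial
        cfg = JumpSimConfig(jump_type="CMJ")
        t_on = truth.phase_times["E"][0]
        t_off = truth.phase_times["F2"][0]
        impulse = net_vertical_impulse(fp, t_on, t_off, cfg.body_mass, G)
        expected = cfg.body_mass * truth.v_takeoff
        assert abs(impulse - expected) / expected < 0.01

    def test_dj_contact_time_honoured(self):
        cfg = JumpSimConfig(jump_type="DJ", contact_time=0.18)
        _, _, truth = simulate_jump_trial(cfg)
        e0 = truth.phase_times["E"][0]
        c1 = truth.phase_times["C"][1]
        assert abs((c1 - e0) - 0.18) < 1e-9
        assert truth.contact_time == 0.18

    def test_impossible_depth_is_config_error(self):
        cfg = JumpSimConfig(jump_type="CMJ", countermovement_depth=0.70)
        with pytest.raises(ConfigError):
            simulate_jump_trial(cfg)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        jt=st.sampled_from(["SJ", "CMJ", "DJ"]),
        h=st.floats(0.12, 0.35),
        seed=st.integers(0, 10_000),
    )
    def test_phase_ordering_property(self, jt, h, seed):
        cfg = JumpSimConfig(jump_type=jt, target_flight_height=h, seed=seed,
                            noise_sd=0.001)
        _, _, truth = simulate_jump_trial(cfg)
        order = [p for p in ("D", "F1", "L1", "E", "C", "F2", "L2")
                 if p in truth.phase_times]
        times = [truth.phase_times[p] for p in order]
        for (a0, a1), (b0, b1) in zip(times, times[1:]):
            assert a0 <= a1 <= b0 <= b1
        if jt == "SJ":
            assert "E" not in truth.phase_times

    def test_standing_trial_force_balances_weight(self):
        mass, dur = 62.0, 2.0
        _, fp = simulate_quiet_standing(body_mass=mass, duration=dur)
        total = np.trapezoid(fp.fz, fp.time)
        expected = mass * G * fp.time[-1]
        assert abs(total - expected) / expected < 0.005


class TestSprintTrial:
    def test_constant_velocity_gate_interval(self):
        cfg = SprintSimConfig(v0=5.0, acceleration=0.0)
        _, truth = simulate_sprint_trial(cfg)
        assert abs((truth.gate_times[1] - truth.gate_times[0]) - 1.0) < 1e-12

    def test_constant_acceleration_closed_form(self):
        cfg = SprintSimConfig(v0=0.0, acceleration=2.0)
        _, truth = simulate_sprint_trial(cfg)
        assert abs(truth.gate_times[1] - np.sqrt(2 * 5 / 2)) < 1e-12

    def test_too_short_trial_is_config_error(self):
        cfg = SprintSimConfig(v0=1.0, acceleration=0.0, duration=2.0)
        with pytest.raises(ConfigError):
            simulate_sprint_trial(cfg)


class TestCohort:
    def test_realised_allele_frequency_within_binomial_bound(self):
        n = 10_000
        cfg = CohortSimConfig(n=n, allele_freq={"actn3": 0.5, "ace": 0.5}, seed=3)
        _, _, truth = simulate_cohort(cfg)
        se = np.sqrt(0.5 * 0.5 / (2 * n))
        for locus in ("actn3", "ace"):
            assert abs(truth["realized_allele_freq"][locus] - 0.5) < 3 * se

    def test_zero_effect_group_means_overlap(self):
        cfg = CohortSimConfig(n=3000, effect_size=0.0, seed=4)
        geno, out, _ = simulate_cohort(cfg)
        y = out["torque_peak"].to_numpy()
        g = geno["ace"].to_numpy()
        means = {lab: y[g == lab].mean() for lab in ("II", "ID", "DD")}
        ns = {lab: (g == lab).sum() for lab in means}
        for lab in means:
            ci = 1.96 * cfg.outcome_sd / np.sqrt(ns[lab])
            assert abs(means[lab] - cfg.baseline_mean) < ci * 1.5

    def test_additive_effect_recovered_by_ols_oracle(self):
        # regression of outcome on the additive code recovers the
        # homozygote difference (the code spans 0..1)
        effect = 0.8
        cfg = CohortSimConfig(n=1000, model="additive", effect_size=effect, seed=5)
        geno, out, truth = simulate_cohort(cfg)
        code = geno["ace"].map({"II": 0.0, "ID": 0.5, "DD": 1.0}).to_numpy()
        y = out["torque_peak"].to_numpy()
        slope = np.polyfit(code, y, 1)[0]
        se = cfg.outcome_sd / (np.std(code) * np.sqrt(cfg.n))
        assert abs(slope - effect) < 3 * se
        assert truth["shifts"]["DD"] == pytest.approx(effect)

    def test_cohens_f_parameterisation(self):
        # with f given, the implied between-group sd over within sd equals f
        cfg = CohortSimConfig(n=100, cohens_f=0.25, seed=6)
        _, _, truth = simulate_cohort(cfg)
        q = 0.5
        w = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        codes = np.array([0.0, 0.5, 1.0])
        shifts = truth["effect_size"] * codes
        mu = w @ shifts
        f = np.sqrt(w @ (shifts - mu) ** 2) / cfg.outcome_sd
        assert f == pytest.approx(0.25, rel=1e-9)

    def test_hwe_holds_across_seeds(self):
        # genotype draws should pass the HWE chi-square at alpha=0.01 in
        # at least 98 of 100 seeds
        ok = 0
        for seed in range(100):
            cfg = CohortSimConfig(n=300, seed=seed)
            geno, _, _ = simulate_cohort(cfg)
            counts = [(geno["ace"] == lab).sum() for lab in ("II", "ID", "DD")]
            _, _, p = hwe_chi_square(counts)
            ok += p > 0.01
        assert ok >= 98

    def test_bad_allele_frequency_rejected(self):
        with pytest.raises(ConfigError):
            simulate_cohort(CohortSimConfig(allele_freq={"actn3": 1.2, "ace": 0.5}))
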