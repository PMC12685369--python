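"""Synthetic cohort generator: determinism, structure, and calibration."""

import numpy as np
import pandas as pd
import pytest

import frailmsm as fm
from frailmsm.index import build_assessments
from frailmsm.model import TRANSITIONS
from frailmsm.simulate import SyntheticCohortConfig, panel_observe


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_subjects": 0},
        {"baseline_state_probs": (0.5, 0.5, 0.5)},
        {"item_missing_rate": 1.5},
        {"death_convention": "sometimes"},
        {"wave_offsets": (0.0,)},
        {"missingness_mechanism": "mnar"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(**kwargs)


class TestTrajectory:
    def test_frozen_chain_stays_put(self):
        model = fm.IntensityModel(log_q0=np.full(7, -30.0))
        rng = np.random.default_rng(0)
        times, states = fm.simulate_trajectory(model, {}, 2, 7.0, rng)
        assert states == [2] and times == [0.0]

    def test_holding_time_mean_matches_exit_rate(self, baseline_model):
        rng = np.random.default_rng(1)
        holds = []
        for _ in range(20_000):
            times, states = fm.simulate_trajectory(baseline_model, {}, 2,
                                                   1e9, rng,
                                                   age_timevarying=False)
            if len(times) > 1:
                holds.append(times[1])
        q = baseline_model.q0
        expected = 1.0 / (q[2] + q[3] + q[4])   # exits from pre-frail
        assert np.mean(holds) == pytest.approx(expected, rel=0.02)

    def test_next_state_split_matches_competing_risks(self, baseline_model):
        rng = np.random.default_rng(2)
        dest = []
        for _ in range(20_000):
            _, states = fm.simulate_trajectory(baseline_model, {}, 2, 1e9,
                                               rng, age_timevarying=False)
            if len(states) > 1:
                dest.append(states[1])
        dest = np.array(dest)
        q = baseline_model.q0
        total = q[2] + q[3] + q[4]
        for state, rate in ((1, q[2]), (3, q[3]), (4, q[4])):
            frac = (dest == state).mean()
            se = np.sqrt(frac * (1 - frac) / len(dest))
            assert abs(frac - rate / total) < 4 * se + 1e-3

    def test_no_disallowed_jumps(self, baseline_model):
        rng = np.random.default_rng(3)
        for _ in range(500):
            _, states = fm.simulate_trajectory(baseline_model, {},
                                               int(rng.integers(1, 4)),
                                               20.0, rng)
            for a, b in zip(states, states[1:]):
                assert (a, b) in TRANSITIONS


class TestPanelObserve:
    def test_alive_throughout_gives_all_waves(self):
        rows = panel_observe([0.0], [2], np.array([0.0, 2.0, 4.0, 7.0]))
        assert rows == [(0.0, 2), (2.0, 2), (4.0, 2), (7.0, 2)]

    def test_interval_death_midpoint(self):
        rows = panel_observe([0.0, 3.1], [2, 4], np.array([0.0, 2.0, 4.0]),
                             death_convention="interval")
        assert rows[-1] == (3.0, 4)

    def test_exact_death_time_kept(self):
        rows = panel_observe([0.0, 3.1], [2, 4], np.array([0.0, 2.0, 4.0]),
                             death_convention="exact")
        assert rows[-1] == (3.1, 4)
        assert rows[:2] == [(0.0, 2), (2.0, 2)]

    def test_no_observation_after_death(self):
        rows = panel_observe([0.0, 1.5], [3, 4], np.array([0.0, 2.0, 4.0]))
        times = [t for t, s in rows]
        assert all(t <= 1.5 for t in times)


class TestGenerateCohort:
    def test_seed_determinism(self):
        cfg = SyntheticCohortConfig(n_subjects=200, seed=99)
        a = fm.generate_cohort(cfg)
        b = fm.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_different_seeds_differ(self):
        a = fm.generate_cohort(SyntheticCohortConfig(n_subjects=200, seed=1))
        b = fm.generate_cohort(SyntheticCohortConfig(n_subjects=200, seed=2))
        assert not a.observations.equals(b.observations)

    def test_baseline_shares_match_config(self):
        cfg = SyntheticCohortConfig(n_subjects=8000, seed=5)
        panel = fm.generate_cohort(cfg)
        first = panel.observations.groupby("subject_id").first()
        shares = first["state"].value_counts(normalize=True).sort_index()
        tol = 2 / np.sqrt(cfg.n_subjects)
        for s, p in zip((1, 2, 3), cfg.baseline_state_probs):
            assert abs(shares[s] - p) < tol + 0.01

    def test_death_fraction_monotone_across_waves(self):
        cfg = SyntheticCohortConfig(n_subjects=3000, seed=6)
        panel = fm.generate_cohort(cfg)
        obs = panel.observations
        dead = obs[obs.state == 4]
        fracs = [(dead.time <= t).mean() for t in (2.0, 4.0, 7.0)]
        assert fracs == sorted(fracs)

    def test_item_emission_recovers_states_without_missingness(self):
        cfg = SyntheticCohortConfig(n_subjects=150, seed=8,
                                    item_missing_rate=0.0)
        panel, items = fm.generate_cohort(cfg, items=True)
        scored = build_assessments(items)
        merged = scored.merge(
            panel.observations, on=["subject_id", "time"],
            suffixes=("_scored", "_latent"))
        assert (merged["state_scored"] == merged["state_latent"]).all()

    def test_zero_item_missing_rate_no_missing_fi(self):
        cfg = SyntheticCohortConfig(n_subjects=100, seed=9,
                                    item_missing_rate=0.0)
        _, items = fm.generate_cohort(cfg, items=True)
        scored = build_assessments(items)
        assert not scored["fi_value"].isna().any()

    def test_covariate_missingness_rate(self):
        cfg = SyntheticCohortConfig(n_subjects=4000, seed=10,
                                    covariate_missing_rate=0.1)
        panel = fm.generate_cohort(cfg)
        frac = panel.covariates["married"].isna().mean()
        assert frac == pytest.approx(0.1, abs=0.02)
        # age anchors the MAR mechanism and is never removed
        assert not panel.covariates["age"].isna().any()

    def test_structure_compliance_in_panel(self):
        cfg = SyntheticCohortConfig(n_subjects=1000, seed=11)
        panel = fm.generate_cohort(cfg)
        panel.validate()
        obs = panel.observations
        assert obs.state.isin([1, 2, 3, 4]).all()


def test_round_trip_identifiability(baseline_model):
    """End-to-end: generate under known intensities, refit, recover."""
    cfg = SyntheticCohortConfig(n_subjects=2000, seed=13,
                                true_model=baseline_model)
    panel = fm.generate_cohort(cfg)
    fit = fm.fit_mle(panel, compute_covariance=False)
    rel = fit.model.q0 / baseline_model.q0 - 1
    well_populated = [TRANSITIONS.index(p)
                      for p in ((1, 2), (2, 1), (2, 3), (3, 2), (3, 4))]
    assert np.median(np.abs(rel[well_populated])) <= 0.10
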