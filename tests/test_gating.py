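"""Gated-emergence scheduling model: arithmetic oracles and invariants."""

import dataclasses

import numpy as np
import pytest

from eclopy import gating
from eclopy.gating import FlySchedule, GatingParams


def _det_params(model: str, commit_mean: float) -> GatingParams:
    # deterministic clock geometry used by the worked examples:
    # tau 24 h, gate [CT0, CT10), 12-h roughening, no stochasticity
    return GatingParams(
        model=model, tau_h=24.0, gate_open_ct=0.0, gate_width_h=10.0,
        commit_mean_h=commit_mean, commit_sd_h=0.0,
        rough_mean_h=12.0, rough_sd_h=0.0, ct0_offset_h=0.0,
    )


def _one(params: GatingParams, seed: int = 1) -> FlySchedule:
    return gating.simulate_cohort(params, [0.0], 1, seed)[0]


class TestScheduleArithmetic:
    @pytest.mark.parametrize(
        "model, commit, exp_onset, exp_emergence",
        [
            ("developmental", 20.0, 20.0, 32.0),  # completion CT8, inside gate
            ("developmental", 23.0, 36.0, 48.0),  # CT11 closed -> deferred onset
            ("permissive", 20.0, 20.0, 32.0),
            ("permissive", 23.0, 23.0, 48.0),     # waits, onset unchanged
        ],
    )
    def test_worked_examples(self, model, commit, exp_onset, exp_emergence):
        s = _one(_det_params(model, commit))
        assert s.onset_t_h == pytest.approx(exp_onset)
        assert s.emergence_t_h == pytest.approx(exp_emergence)

    def test_gated_models_same_emergence_different_onsets(self):
        dev = _one(_det_params("developmental", 23.0))
        perm = _one(_det_params("permissive", 23.0))
        assert dev.emergence_t_h == perm.emergence_t_h == 48.0
        assert dev.onset_t_h - perm.onset_t_h == pytest.approx(13.0)

    def test_arrhythmic_bypasses_gate(self):
        for commit in (20.0, 23.0, 31.5):
            s = _one(_det_params("arrhythmic", commit))
            assert s.emergence_t_h == pytest.approx(s.onset_t_h + 12.0)

    def test_completion_at_gate_close_is_deferred(self):
        # completion lands exactly at CT10 = gate close; half-open gate defers
        s = _one(_det_params("permissive", 22.0))
        assert s.completion_t_h == pytest.approx(34.0)
        assert s.emergence_t_h == pytest.approx(48.0)


class TestBruteForceOracle:
    """Minute-resolution exhaustive scan over candidate onset times."""

    @staticmethod
    def _oracle(params: GatingParams, commitment: float, duration: float):
        step = 1.0 / 60.0
        if params.model == "developmental":
            o = commitment
            while not params.in_gate(o + duration):
                o += step
            return o, o + duration
        if params.model == "permissive":
            e = commitment + duration
            while not params.in_gate(e):
                e += step
            return commitment, e
        return commitment, commitment + duration

    @pytest.mark.parametrize("model", ["developmental", "permissive", "arrhythmic"])
    def test_matches_scan(self, model):
        params = GatingParams(
            model=model, tau_h=24.0, gate_open_ct=3.0, gate_width_h=8.0,
            commit_mean_h=50.0, commit_sd_h=4.0, rough_mean_h=11.0,
            rough_sd_h=1.5, ct0_offset_h=5.0,
        )
        schedules = gating.simulate_cohort(params, [0.0, 6.0], 10, seed=9)
        for s in schedules:
            o, e = self._oracle(params, s.commitment_t_h, s.rough_duration_h)
            assert s.onset_t_h == pytest.approx(o, abs=1.0 / 60.0 + 1e-9)
            assert s.emergence_t_h == pytest.approx(e, abs=1.0 / 60.0 + 1e-9)


class TestCohortProperties:
    def test_deterministic_and_stable_under_growth(self):
        p = gating.wild_type_preset()
        a = gating.simulate_cohort(p, [0.0, 6.0], 5, seed=3)
        b = gating.simulate_cohort(p, [0.0, 6.0], 5, seed=3)
        assert [s.emergence_t_h for s in a] == [s.emergence_t_h for s in b]
        # enlarging the cohort must not reshuffle earlier flies
        big = gating.simulate_cohort(p, [0.0, 6.0], 9, seed=3)
        assert [s.emergence_t_h for s in big[:5]] == [s.emergence_t_h for s in a[:5]]

    def test_permissive_waiting_time_bounded(self):
        p = gating.wild_type_preset(model="permissive")
        for s in gating.simulate_cohort(p, [0.0, 6.0, 12.0], 50, seed=5):
            assert s.onset_t_h == pytest.approx(s.commitment_t_h)
            wait = s.emergence_t_h - s.completion_t_h
            assert -1e-9 <= wait < p.tau_h - p.gate_width_h + 1e-9

    def test_developmental_emergence_is_completion(self):
        p = gating.wild_type_preset()
        for s in gating.simulate_cohort(p, [0.0, 8.0], 50, seed=5):
            assert s.completion_t_h == s.emergence_t_h

    def test_gate_membership_of_emergence(self):
        p = gating.wild_type_preset(rough_sd_h=0.2)
        hits = []
        for seed in range(10):
            sch = gating.simulate_cohort(p, [0.0], 300, seed)
            hits.append(np.mean([p.in_gate(s.emergence_t_h) for s in sch]))
        assert all(h >= 0.95 for h in hits)

    def test_exact_gate_membership_at_zero_sd(self):
        p = gating.wild_type_preset(commit_sd_h=0.7, rough_sd_h=0.0)
        for s in gating.simulate_cohort(p, [0.0, 5.0, 11.0], 30, seed=2):
            assert p.in_gate(s.emergence_t_h)


class TestReadyFraction:
    def test_permissive_waiter_is_responder(self):
        s = _one(_det_params("permissive", 23.0))  # completion 35, E 48
        assert gating.ready_fraction([s], 40.0) == 1.0

    def test_developmental_never_ready_early(self):
        s = _one(_det_params("developmental", 23.0))  # completion = E = 48
        assert gating.ready_fraction([s], 40.0) == 0.0

    def test_probe_before_any_commitment(self):
        sch = gating.simulate_cohort(_det_params("permissive", 23.0), [0.0], 5, 1)
        assert gating.ready_fraction(sch, 0.0) == 0.0

    def test_empty_denominator_raises(self):
        s = _one(_det_params("arrhythmic", 20.0))  # E = 32
        with pytest.raises(ValueError, match="unemerged"):
            gating.ready_fraction([s], 100.0)


class TestCompareModels:
    def test_discriminators(self):
        dev = GatingParams(model="developmental", commit_sd_h=0.0, rough_sd_h=0.0)
        perm = dataclasses.replace(dev, model="permissive")
        out = gating.compare_models(dev, perm, [0.0, 6.0, 12.0], 40, seed=3)
        d = out["discriminators"]
        assert d["onset_discriminates"]
        assert d["max_pre_emergence_ready_fraction"]["permissive"] > 0.5
        assert d["max_pre_emergence_ready_fraction"]["developmental"] == 0.0
        # sd = 0: emergence distributions identical, onsets not
        dev_e = out["models"]["developmental"]["emergence"]
        perm_e = out["models"]["permissive"]["emergence"]
        assert dev_e == pytest.approx(perm_e)

    def test_mismatched_cohort_spec_rejected(self):
        dev = GatingParams(model="developmental")
        perm = GatingParams(model="permissive", tau_h=20.0)
        with pytest.raises(ValueError, match="cohort spec"):
            gating.compare_models(dev, perm, [0.0], 5, seed=1)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"model": "magic"},
            {"tau_h": -1.0},
            {"gate_open_ct": 25.0},
            {"gate_width_h": 30.0},
            {"rough_mean_h": 0.0},
            {"commit_sd_h": -2.0},
        ],
    )
    def test_bad_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GatingParams(**kwargs)

    def test_nonpositive_cohort_rejected(self):
        with pytest.raises(ValueError):
            gating.simulate_cohort(GatingParams(), [0.0], 0, seed=1)

    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            FlySchedule("f", 0.0, 10.0, 9.0, 20.0, 21.0, 1.0)  # onset < commit
        with pytest.raises(ValueError):
            FlySchedule("f", 0.0, 10.0, 10.0, 22.0, 21.0, 1.0)  # E < completion


def test_schedule_csv_round_trip(tmp_path):
    sch = gating.simulate_cohort(gating.wild_type_preset(), [0.0, 6.0], 4, seed=11)
    path = tmp_path / "sched.csv"
    gating.write_schedules_csv(sch, path)
    back = gating.read_schedules_csv(path)
    assert [s.fly_id for s in back] == [s.fly_id for s in sch]
    np.testing.assert_allclose(
        [s.emergence_t_h for s in back], [s.emergence_t_h for s in sch]
    )
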