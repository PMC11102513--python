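import numpy as np
import pandas as pd
import pytest

import nettdcs as nt
from nettdcs.sst import RaceAgentParams, SstSession, make_schedule, simulate_session


class TestMakeSchedule:
    def test_default_counts(self):
        sch = make_schedule(seed=1)
        assert sch.n_test_trials == 320
        assert sch.n_stop_trials == 80
        assert sch.n_trials == 336  # + 16 practice

    def test_stop_count_exact_per_block(self):
        sch = make_schedule(seed=2)
        stops = sch.is_stop[~sch.is_practice].reshape(5, 64)
        assert np.all(stops.sum(axis=1) == 16)

    def test_directions_balanced_within_one_per_block(self):
        sch = make_schedule(seed=3)
        dirs = sch.direction[~sch.is_practice].reshape(5, 64)
        assert np.all(np.abs(dirs.sum(axis=1) - 32) <= 1)

    def test_zero_stop_fraction_all_go(self):
        sch = make_schedule(stop_fraction=0.0, seed=4)
        assert sch.n_stop_trials == 0

    def test_same_seed_reproducible(self):
        a, b = make_schedule(seed=5), make_schedule(seed=5)
        assert np.array_equal(a.is_stop, b.is_stop)
        assert np.array_equal(a.direction, b.direction)

    def test_practice_trials_never_stop(self):
        sch = make_schedule(seed=6)
        assert not np.any(sch.is_stop[sch.is_practice])

    def test_non_representable_fraction_warns(self):
        with pytest.warns(UserWarning, match="rounding"):
            make_schedule(trials_per_block=10, stop_fraction=0.25, seed=7)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(stop_fraction=1.5)


class TestSimulateSession:
    def test_unstoppable_agent_drives_ssd_to_ceiling(self):
        # enormous go RT: the stop always wins, SSD climbs to the ceiling
        agent = RaceAgentParams(go_mu_ms=1e7, go_sigma_ms=0.0, go_tau_ms=0.0,
                                stop_mu_ms=0.0, stop_sigma_ms=0.0, omission_rate=0.0)
        sess = simulate_session(make_schedule(seed=8), agent, seed=8)
        assert sess.staircase[-1] == 1150.0
        assert np.all(np.diff(sess.staircase) >= 0)

    def test_never_stopping_agent_drives_ssd_to_floor(self):
        agent = RaceAgentParams(go_mu_ms=100.0, go_sigma_ms=0.0, go_tau_ms=0.0,
                                stop_mu_ms=1e6, stop_sigma_ms=0.0, omission_rate=0.0)
        sess = simulate_session(make_schedule(seed=9), agent, seed=9)
        assert sess.staircase[-1] == 50.0

    def test_staircase_tracks_fifty_percent_inhibition(self):
        # long-run equilibrium of the one-up/one-down staircase
        sch = make_schedule(n_blocks=1, trials_per_block=40000, practice_trials=0, seed=10)
        sess = simulate_session(sch, seed=10)
        assert sess.stop_success_rate() == pytest.approx(0.5, abs=0.02)

    def test_successful_stops_carry_no_rt(self):
        sess = simulate_session(make_schedule(seed=11), seed=11)
        stops = sess.stop_trials()
        assert stops.loc[stops["outcome"] == "successful_stop", "rt_ms"].isna().all()
        assert stops.loc[stops["outcome"] == "failed_stop", "rt_ms"].notna().all()

    def test_ssd_stays_within_bounds(self):
        sess = simulate_session(make_schedule(seed=12), seed=12)
        assert np.all(sess.staircase >= 50.0) and np.all(sess.staircase <= 1150.0)

    def test_deterministic_given_seed(self):
        a = simulate_session(make_schedule(seed=13), seed=14)
        b = simulate_session(make_schedule(seed=13), seed=14)
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_invalid_staircase_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_session(make_schedule(seed=1), staircase_step_ms=0.0)
        with pytest.raises(ValueError):
            simulate_session(make_schedule(seed=1), initial_ssd_ms=20.0)


def _manual_session(go_rts, ssds, outcomes):
    rows = []
    for i, rt in enumerate(go_rts):
        rows.append(dict(trial=i, practice=False, type="go", ssd_ms=np.nan,
                         rt_ms=rt, outcome="correct_go" if np.isfinite(rt) else "omission"))
    for j, (ssd, out) in enumerate(zip(ssds, outcomes)):
        rows.append(dict(trial=len(go_rts) + j, practice=False, type="stop", ssd_ms=ssd,
                         rt_ms=np.nan if out == "successful_stop" else 600.0, outcome=out))
    return SstSession(trials=pd.DataFrame(rows))


class TestSsrtMean:
    def test_constant_session_arithmetic(self):
        sess = _manual_session([500.0] * 10, [300.0] * 10,
                               ["successful_stop", "failed_stop"] * 5)
        assert nt.ssrt_mean(sess, burn_in=0) == pytest.approx(200.0)

    def test_burn_in_shift_equals_ssd_mean_shift(self):
        ssds = list(np.linspace(100, 400, 20))
        sess = _manual_session([500.0] * 10, ssds, ["successful_stop", "failed_stop"] * 10)
        d = nt.ssrt_mean(sess, burn_in=0) - nt.ssrt_mean(sess, burn_in=5)
        expected = np.mean(ssds[5:]) - np.mean(ssds)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_parameter_recovery_within_15ms(self):
        ests = []
        for s in range(100):
            sess = simulate_session(make_schedule(seed=300 + s), seed=700 + s)
            ests.append(nt.ssrt_mean(sess))
        assert np.mean(ests) == pytest.approx(200.0, abs=15.0)

    def test_no_stop_trials_rejected(self):
        sess = _manual_session([500.0], [], [])
        with pytest.raises(ValueError, match="no stop trials"):
            nt.ssrt_mean(sess, burn_in=0)

    def test_nonconverged_staircase_warns(self):
        sess = _manual_session([500.0] * 5, [300.0] * 10, ["failed_stop"] * 10)
        with pytest.warns(UserWarning, match="converge"):
            nt.ssrt_mean(sess, burn_in=0)


class TestSsrtIntegration:
    def test_symmetric_half_failures_arithmetic(self):
        # p = 0.5 with symmetric go RTs: median 500 minus mean SSD 300
        go = [400.0, 450.0, 500.0, 550.0, 600.0]
        sess = _manual_session(go, [300.0] * 10, ["successful_stop", "failed_stop"] * 5)
        assert nt.ssrt_integration(sess, burn_in=0) == pytest.approx(200.0)

    def test_quantile_matches_hand_computed_oracle(self):
        go = [350.0, 380.0, 400.0, 420.0, 450.0, 480.0, 520.0, 580.0, 650.0, 800.0]
        outcomes = ["failed_stop"] * 3 + ["successful_stop"] * 7  # p = 0.3
        sess = _manual_session(go, [250.0] * 10, outcomes)
        with pytest.warns(UserWarning, match="converge"):
            est = nt.ssrt_integration(sess, burn_in=0)
        oracle_q = np.quantile(np.array(go), 0.3, method="linear")
        assert est == pytest.approx(oracle_q - 250.0, abs=1e-12)

    def test_omissions_replaced_by_max_rt(self):
        go = [400.0, np.nan, 500.0, 600.0]
        sess = _manual_session(go, [300.0] * 4,
                               ["failed_stop", "failed_stop", "successful_stop", "successful_stop"])
        est = nt.ssrt_integration(sess, burn_in=0)
        filled = np.array([400.0, 600.0, 500.0, 600.0])
        assert est == pytest.approx(np.quantile(filled, 0.5) - 300.0)

    def test_all_stops_failed_still_finite(self):
        go = [400.0, 500.0, 600.0]
        sess = _manual_session(go, [100.0] * 10, ["failed_stop"] * 10)
        with pytest.warns(UserWarning, match="converge"):
            est = nt.ssrt_integration(sess, burn_in=0)
        assert np.isfinite(est) and est == pytest.approx(600.0 - 100.0)

    def test_no_failed_stops_flagged_undefined(self):
        go = [400.0, 500.0]
        sess = _manual_session(go, [900.0] * 10, ["successful_stop"] * 10)
        with pytest.warns(UserWarning):
            est = nt.ssrt_integration(sess, burn_in=0)
        assert np.isnan(est)

    def test_estimators_agree_on_large_stationary_sessions(self):
        # On a large stationary session the two estimators differ by the go
        # distribution's mean-median gap, so agreement is assessed with a
        # low-skew go process (tau small); no omissions.
        agent = RaceAgentParams(go_tau_ms=20.0, omission_rate=0.0)
        sch = make_schedule(n_blocks=1, trials_per_block=20000, practice_trials=0, seed=21)
        sess = simulate_session(sch, agent, seed=22)
        assert abs(nt.ssrt_mean(sess) - nt.ssrt_integration(sess)) < 10.0

    def test_estimator_gap_tracks_go_skew_on_large_sessions(self):
        # with the default skewed go process the gap approaches mean-median
        agent = RaceAgentParams(omission_rate=0.0)
        sch = make_schedule(n_blocks=1, trials_per_block=20000, practice_trials=0, seed=23)
        sess = simulate_session(sch, agent, seed=24)
        go = sess.go_rts()
        gap = nt.ssrt_mean(sess) - nt.ssrt_integration(sess)
        assert gap == pytest.approx(np.mean(go) - np.median(go), abs=6.0)
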