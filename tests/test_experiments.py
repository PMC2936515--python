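"""Session loops, experiment runners, Clopper-Pearson intervals, outputs."""

import json

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

import tdobserve as td
from tdobserve.engagement import EngagementParams
from tdobserve.experiments import (
    dopamine_probe,
    events_to_frame,
    run_session,
    summarize_session,
    trials_to_frame,
    write_outputs,
)
from tdobserve.td_engine import DISENGAGED_STATE


class TestRunTrial:
    def test_fixed_seed_gives_identical_trial_streams(self, task, eng, policy):
        def stream(seed):
            rng = np.random.default_rng(seed)
            V = td.initial_values(task, eng)
            return [td.run_trial(V, task, eng, policy, rng, trial_index=i)
                    for i in range(300)]
        a, b = stream(5), stream(5)
        assert a == b
        assert stream(5) != stream(6)

    def test_forced_informative_converges_to_certain_reward(self, policy, rng):
        task = td.build_observing_task(
            q=1.0, trial_types={"forced_informative": 1.0, "forced_random": 0.0,
                                "free_choice": 0.0})
        V = td.ValueTable.from_task(task, v0=0.0)
        for i in range(600):
            td.run_trial(V, task, td.EngagementParams.off(), policy, rng,
                         trial_index=i, record_errors=False)
        assert V.get("TGT_INFO") == pytest.approx(task.r_large, abs=0.01)
        assert V.get("CUE_LARGE") == pytest.approx(task.r_large, abs=1e-6)

    def test_disengaged_trial_records_reengagement_at_reward(self, task, policy, rng):
        always = EngagementParams(hazard_fn=lambda v, p: 1.0)
        V = td.initial_values(task, always)
        rec = td.run_trial(V, task, always, policy, rng,
                           trial_type=task.trial_type("forced_random"))
        assert rec.disengaged_at == "TGT_RAND"
        reward_events = [e for e in rec.errors if e.event_label == "reward"]
        assert len(reward_events) == 1
        e = reward_events[0]
        assert not e.engaged and e.state_id == DISENGAGED_STATE
        assert e.delta == pytest.approx(rec.reward - always.v_disengaged)
        # the re-engagement response exceeds the engaged 50/50 surprise when large
        if rec.reward == task.r_large:
            assert e.delta > task.r_large - td.expected_terminal_reward(task)

    def test_forced_trials_record_no_choice(self, task, eng, policy, rng):
        V = td.initial_values(task, eng)
        rec = td.run_trial(V, task, eng, policy, rng,
                           trial_type=task.trial_type("forced_informative"))
        assert rec.chosen_option == "none"
        assert rec.trial_type == "forced_informative"
        assert rec.cue_shown in ("CUE_LARGE", "CUE_SMALL")
        assert rec.reward in (task.r_large, task.r_small)


class TestRunSession:
    def test_default_mixture_yields_about_160_choice_trials(self, task, eng, policy):
        rng = np.random.default_rng(0)
        _, summary = run_session(task, eng, policy, rng)
        se = np.sqrt(480 * (1 / 3) * (2 / 3))
        assert abs(summary.n_choice - 160) <= 3 * se

    def test_single_forced_trial_session_has_undefined_bias(self, eng, policy):
        task = td.build_observing_task(trial_types={
            "forced_informative": 1.0, "forced_random": 0.0, "free_choice": 0.0})
        rng = np.random.default_rng(0)
        _, summary = run_session(task, eng, policy, rng, n_trials=1)
        assert summary.n_choice == 0 and not summary.bias_defined
        assert np.isnan(summary.bias)

    def test_indifferent_policy_bias_covered_by_interval(self, task, eng):
        """Nominal 95% session CIs cover 0.5 in at least 93 of 100 sessions at beta=0."""
        policy = td.PolicyParams(beta=0.0)
        covered = 0
        for s in range(100):
            rng = np.random.default_rng(10_000 + s)
            _, summary = run_session(task, eng, policy, rng, n_trials=480,
                                     record_errors=False)
            covered += summary.ci_low <= 0.5 <= summary.ci_high
        assert covered >= 93

    def test_invalid_trial_count(self, task, eng, policy, rng):
        with pytest.raises(ValueError):
            run_session(task, eng, policy, rng, n_trials=0)


class TestClopperPearson:
    def test_boundary_conventions_are_exact(self):
        assert td.clopper_pearson(0, 10)[0] == 0.0
        assert td.clopper_pearson(10, 10)[1] == 1.0

    def test_half_of_ten(self):
        low, high = td.clopper_pearson(5, 10)
        assert low == pytest.approx(0.187, abs=0.001)
        assert high == pytest.approx(0.813, abs=0.001)

    @pytest.mark.parametrize("k,n", [(0, 7), (3, 7), (7, 7), (42, 160), (159, 160)])
    def test_agrees_with_independent_implementation(self, k, n):
        low, high = td.clopper_pearson(k, n)
        ref_low, ref_high = proportion_confint(k, n, alpha=0.05, method="beta")
        assert low == pytest.approx(ref_low, abs=1e-10)
        assert high == pytest.approx(ref_high, abs=1e-10)

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0), (1.5, 10)])
    def test_invalid_counts_rejected(self, k, n):
        with pytest.raises(ValueError):
            td.clopper_pearson(k, n)

    def test_summary_interval_brackets_bias(self, task, eng, policy, rng):
        recs, summary = run_session(task, eng, policy, rng, record_errors=False)
        assert 0 <= summary.ci_low <= summary.bias <= summary.ci_high <= 1
        assert summary.bias == summary.n_info / summary.n_choice


class TestRunners:
    def test_acquisition_is_deterministic_per_seed(self):
        a = td.run_acquisition(n_sessions=3, n_trials=120, seed=9)
        b = td.run_acquisition(n_sessions=3, n_trials=120, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = td.run_acquisition(n_sessions=3, n_trials=120, seed=10)
        assert not a.equals(c)

    def test_acquisition_reports_one_row_per_session(self):
        df = td.run_acquisition(n_sessions=4, n_trials=120, seed=0)
        assert list(df["session"]) == [1, 2, 3, 4]
        assert {"n_choice", "n_info", "bias", "ci_low", "ci_high"} <= set(df.columns)

    def test_reversal_from_session_one_equals_acquisition_on_reversed_task(self):
        base = td.build_delayed_task()
        rev = td.apply_reversal(base)
        a = td.run_reversal(n_sessions=3, switch_session=1, seed=4, task=base,
                            n_trials=120)
        b = td.run_acquisition(n_sessions=3, seed=4, task=rev, n_trials=120)
        pd.testing.assert_frame_equal(a.drop(columns="reversed"), b)

    def test_pre_switch_segment_matches_acquisition(self):
        base = td.build_delayed_task()
        a = td.run_reversal(n_sessions=4, switch_session=4, seed=4, task=base,
                            n_trials=120)
        b = td.run_acquisition(n_sessions=4, seed=4, task=base, n_trials=120)
        pd.testing.assert_frame_equal(
            a[a.session < 4].drop(columns="reversed"), b[b.session < 4])

    def test_symmetric_punishment_task_is_unbiased_under_salience(self):
        # outcomes +r / -r with q=0.5: the salience hazard sees both cues alike
        task = td.build_observing_task(q=0.5, r_large=0.5, r_small=-0.5,
                                       variant_tag="aversive")
        eng = EngagementParams(hazard_family="salience")
        biases = [td.pooled_bias(td.run_acquisition(
            n_sessions=6, seed=s, task=task, eng=eng), last=3).bias
            for s in range(6)]
        pooled = np.mean(biases)
        se = np.std(biases, ddof=1) / np.sqrt(len(biases))
        assert abs(pooled - 0.5) < max(3 * se, 0.02)

    def test_dopamine_probe_reports_all_trial_events(self):
        df = dopamine_probe(seeds=[0], n_train=1, n_anneal=0, n_probe=1, n_trials=120)
        got = set(map(tuple, df[["trial_type", "event"]].itertuples(index=False)))
        assert ("forced_informative", "target") in got
        assert ("forced_random", "target") in got
        assert ("free_choice", "choice") in got


class TestOutputs:
    def test_end_to_end_determinism_of_written_tables(self, task, eng, policy, tmp_path):
        def write(dirname, seed):
            rng = np.random.default_rng(seed)
            recs, summary = run_session(task, eng, policy, rng, n_trials=90)
            out = write_outputs(tmp_path / dirname,
                                sessions=pd.DataFrame([summary.__dict__]),
                                trials=recs, events=recs,
                                config={"beta": policy.beta}, seed=seed)
            return {p.name: p.read_bytes() for p in sorted(out.iterdir())}
        assert write("a", 3) == write("b", 3)

    def test_manifest_and_tables_written(self, task, eng, policy, tmp_path):
        rng = np.random.default_rng(1)
        recs, summary = run_session(task, eng, policy, rng, n_trials=60)
        out = write_outputs(tmp_path / "run", sessions=pd.DataFrame([summary.__dict__]),
                            trials=recs, events=recs, config={}, seed=1)
        names = {p.name for p in out.iterdir()}
        assert {"sessions.csv", "trials.csv", "td_events.csv", "run_manifest.json"} <= names
        manifest = json.loads((out / "run_manifest.json").read_text())
        assert manifest["seed"] == 1 and "config_sha256" in manifest
        events = pd.read_csv(out / "td_events.csv")
        assert list(events.columns) == ["trial", "event", "state", "delta", "engaged"]
        # deterministic row order: trial-major, event time within trial
        assert (events["trial"].diff().fillna(0) >= 0).all()

    def test_frames_expose_trial_fields(self, task, eng, policy, rng):
        recs, _ = run_session(task, eng, policy, rng, n_trials=30)
        tf = trials_to_frame(recs)
        assert {"trial", "trial_type", "chosen_option", "reward"} <= set(tf.columns)
        ef = events_to_frame(recs)
        assert len(ef) >= len(tf)  # at least one event per trial
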