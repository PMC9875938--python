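"""Trial-table balancing, behavioural generator and EEG ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ridemvpa as rm
from ridemvpa.task_sim import CONGRUENT, GO, INCONGRUENT, NOGO


class TestTrialTable:
    def test_default_design_counts(self):
        t = rm.generate_trial_table(rm.TaskDesign(), seed=0)
        assert len(t) == 720
        assert (t.trial_type == GO).sum() == 504
        assert (t.trial_type == NOGO).sum() == 216
        assert t.block.nunique() == 6
        assert (t.groupby("block").size() == 120).all()

    def test_per_block_balance(self):
        t = rm.generate_trial_table(rm.TaskDesign(), seed=5)
        cell = t.groupby(["block", "trial_type", "congruency"]).size().unstack(0)
        # every cell count identical across blocks
        assert (cell.nunique(axis=1) == 1).all()

    def test_minimal_design_one_per_cell(self):
        t = rm.generate_trial_table(
            rm.TaskDesign(n_trials=4, go_proportion=0.5,
                          congruent_proportion=0.5, n_blocks=1), seed=0)
        assert len(t.groupby(["trial_type", "congruency"]).size()) == 4

    def test_congruency_consistent_with_letter_side(self):
        t = rm.generate_trial_table(rm.TaskDesign(), seed=1)
        hand = t.letter.map({"A": "left", "B": "right"})
        expect = np.where(t.side == hand, CONGRUENT, INCONGRUENT)
        assert (t.congruency == expect).all()

    def test_non_integral_counts_rejected(self):
        with pytest.raises(ValueError, match="integral|divisible"):
            rm.generate_trial_table(
                rm.TaskDesign(n_trials=10, go_proportion=0.7, n_blocks=1), seed=0)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_balance_holds_for_every_seed(self, seed):
        t = rm.generate_trial_table(
            rm.TaskDesign(n_trials=120, n_blocks=2), seed=seed)
        counts = t.groupby(["block", "trial_type", "congruency"]).size()
        assert set(counts.loc[0]) == set(counts.loc[1])
        assert (t.trial_type == GO).sum() == 84


class TestBehaviour:
    def test_zero_false_alarm_rates_all_omissions(self):
        t = rm.generate_trial_table(rm.TaskDesign(), seed=0)
        behav = rm.BehaviourParams(
            nogo_false_alarm_rate={CONGRUENT: 0.0, INCONGRUENT: 0.0})
        out = rm.simulate_behaviour(t, behav, seed=0)
        nogo = out[out.trial_type == NOGO]
        assert (nogo.outcome == "correct_omission").all()

    def test_zero_sd_rt_is_deterministic(self):
        t = rm.generate_trial_table(rm.TaskDesign(), seed=0)
        behav = rm.BehaviourParams(rt_sd_ms=0.0, go_error_rate=0.0)
        out = rm.simulate_behaviour(t, behav, seed=0)
        con = out[(out.trial_type == GO) & (out.congruency == CONGRUENT)]
        assert np.allclose(con.rt_ms, 539.18)

    def test_nogo_accuracy_matches_configured_rates_in_expectation(self):
        # 93.9 % / 95.3 % expected accuracies from FA rates 0.061 / 0.047
        t = rm.generate_trial_table(
            rm.TaskDesign(n_trials=216, go_proportion=0.0,
                          congruent_proportion=0.5, n_blocks=6), seed=0)
        acc = {CONGRUENT: [], INCONGRUENT: []}
        for rep in range(300):
            out = rm.simulate_behaviour(t, seed=rep)
            s = rm.summarize_behaviour(out)
            for cond in acc:
                acc[cond].append(float(
                    s[(s.trial_type == NOGO) & (s.congruency == cond)]
                    .accuracy_pct.iloc[0]))
        assert abs(np.mean(acc[CONGRUENT]) - 93.9) < 0.3
        assert abs(np.mean(acc[INCONGRUENT]) - 95.3) < 0.3

    def test_rts_respect_deadline(self):
        t = rm.generate_trial_table(rm.TaskDesign(), seed=0)
        out = rm.simulate_behaviour(t, rm.BehaviourParams(rt_sd_ms=400.0),
                                    seed=3, deadline_ms=1700.0)
        responded = out.rt_ms.dropna()
        assert (responded <= 1700.0).all()
        assert (out[out.outcome == "miss"].rt_ms.isna()).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            rm.BehaviourParams(go_error_rate=1.5).validate()


class TestMontage:
    @pytest.mark.parametrize("scheme", ["fibonacci-sphere", "ten-ten-subset"])
    def test_unit_norm_and_unique(self, scheme):
        m = rm.make_montage(60, scheme)
        assert m.n_channels == 60
        assert np.allclose(np.linalg.norm(m.positions, axis=1), 1.0)
        assert len(set(m.labels)) == 60
        assert len(np.unique(np.round(m.positions, 6), axis=0)) == 60

    def test_deterministic(self):
        a = rm.make_montage(60)
        b = rm.make_montage(60)
        assert a.labels == b.labels
        assert np.array_equal(a.positions, b.positions)

    def test_ten_ten_labels_standard(self):
        m = rm.make_montage(60, "ten-ten-subset")
        assert {"Fp1", "Cz"} & set(m.labels)

    def test_unsupported_scheme(self):
        with pytest.raises(ValueError):
            rm.make_montage(60, "grid")


class TestEpochSim:
    def test_noiseless_single_source_rank_one(self, montage60):
        t = rm.generate_trial_table(
            rm.TaskDesign(n_trials=8, go_proportion=0.5, n_blocks=1), seed=0)
        t = rm.simulate_behaviour(t, seed=0)
        tp = rm.TruthParams(srate_hz=250.0, epoch_window_ms=(-500.0, 1200.0),
                            c_amp=0.0, pink_sd=0.0, white_sd=0.0,
                            amplitude_by_condition={CONGRUENT: (1.0, 0.0),
                                                    INCONGRUENT: (1.0, 0.0)})
        ep, _ = rm.simulate_epochs(t, tp, montage60, seed=0)
        assert np.allclose(ep.data[0], ep.data[1])
        u = ep.data[0]
        assert np.linalg.matrix_rank(u, tol=1e-8 * np.abs(u).max()) == 1

    def test_null_deltas_identical_condition_averages(self, montage60):
        t = rm.generate_trial_table(
            rm.TaskDesign(n_trials=8, go_proportion=0.5, n_blocks=1), seed=0)
        t = rm.simulate_behaviour(t, rm.BehaviourParams(rt_sd_ms=0.0), seed=0)
        tp = rm.null_truth_params(srate_hz=250.0,
                                  epoch_window_ms=(-500.0, 1200.0),
                                  pink_sd=0.0, white_sd=0.0,
                                  c_jitter_sd_ms=0.0, c_rt_slope=0.0,
                                  pseudo_rt_sd_ms=0.0,
                                  pseudo_rt_mean_ms={CONGRUENT: 520.0,
                                                     INCONGRUENT: 520.0})
        ep, _ = rm.simulate_epochs(t, tp, montage60, seed=0)
        con = ep.data[(t.congruency == CONGRUENT).to_numpy()].mean(axis=0)
        inc = ep.data[(t.congruency == INCONGRUENT).to_numpy()].mean(axis=0)
        assert np.allclose(con, inc, atol=1e-10)

    def test_latency_rt_coupling(self, nogo_session):
        ep, truth = nogo_session
        # Nogo latencies come from pseudo-RTs; check the configured coupling
        # on a Go session where true RTs exist
        design = rm.TaskDesign(n_trials=504, go_proportion=1.0, n_blocks=6)
        t = rm.generate_trial_table(design, seed=0)
        t = rm.simulate_behaviour(t, seed=1)
        tp = rm.TruthParams(srate_hz=250.0, epoch_window_ms=(-500.0, 1200.0))
        _, tr = rm.simulate_epochs(t, tp, seed=2)
        ok = t.rt_ms.notna().to_numpy()
        r = np.corrcoef(tr.c_latency_ms[ok], t.rt_ms.to_numpy()[ok])[0, 1]
        b, srt = tp.c_rt_slope, 80.0
        expected = b * srt / np.hypot(b * srt, tp.c_jitter_sd_ms)
        assert r >= expected - 0.05

    def test_truth_records_unit_norm_topographies(self, nogo_session):
        _, truth = nogo_session
        assert np.isclose(np.linalg.norm(truth.s_topography), 1.0)
        assert np.isclose(np.linalg.norm(truth.c_topography), 1.0)
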