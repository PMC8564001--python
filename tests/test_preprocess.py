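"""Tests for gaze preprocessing: proportions, exclusions, salience, RTs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from lookmix.preprocess import (
    action_salience,
    apply_exclusions,
    attach_salience,
    bin_proportions,
    lwl_trial_rt,
    participant_rt,
    session_rts,
    standardize_covariate,
    summarize_windows,
    sv_transform,
    window_proportion,
)
from lookmix.preprocess.lwl import RtRecord
from lookmix.simulate import (
    GazeSimConfig,
    ParticipantTruth,
    design_frame,
    design_lookup,
    generate_gaze_stream,
    generate_lwl_session,
)
from tests.conftest import make_window_frame


def _stream(aoi_list, pid=1, seq=1, trial=1, window=1, dt=1000.0 / 60.0):
    n = len(aoi_list)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "task": "impl",
            "sequence_id": seq,
            "trial": trial,
            "window": window,
            "time_ms": np.round(np.arange(n) * dt).astype(int),
            "aoi": aoi_list,
        }
    )


class TestWindowProportion:
    def test_arithmetic(self):
        aoi = ["target"] * 240 + ["distracter"] * 120 + ["missing"] * 120
        ws = window_proportion(_stream(aoi), trial=1, window=1)
        assert ws.prop_target == pytest.approx(240 / 360)
        assert ws.frac_missing == pytest.approx(0.25)
        assert ws.n_valid == 360
        assert not ws.excluded

    def test_zero_target_boundary(self):
        ws = window_proportion(_stream(["distracter"] * 480), trial=1, window=1)
        assert ws.prop_target == 0.0

    def test_empty_window_excluded(self):
        ws = window_proportion(_stream(["target"] * 10), trial=1, window=2)
        assert ws.excluded
        assert ws.n_valid == 0

    def test_simulation_round_trip(self):
        truth = ParticipantTruth(
            participant_id=1, regime="graded", mu_i=0.6,
            rt_ms=500.0, n_verbs=5, total_vocab=50,
        )
        sim = GazeSimConfig(missing_run_prob=0.0, impl_trials=5, windows_per_trial=2)
        rows = [design_lookup()[((i % 8) + 1, (i % 2) + 1)] for i in range(5)]
        stream = generate_gaze_stream(truth, rows, sim, np.random.default_rng(8))
        win = summarize_windows(stream)
        assert len(win) == 10
        d = sim.mean_dwell_ms * sim.sample_rate_hz / 1000.0
        se = np.sqrt(0.24 * (2 * d - 1) / (10 * 480))
        assert abs(win["prop_target"].mean() - 0.6) < 3 * se

    def test_counts_account_for_every_sample(self):
        aoi = ["target"] * 100 + ["distracter"] * 200 + ["missing"] * 180
        ws = window_proportion(_stream(aoi), trial=1, window=1)
        total = ws.n_valid + round(ws.frac_missing * 480)
        assert total == 480

    def test_time_origin_invariance(self):
        aoi = ["target"] * 300 + ["distracter"] * 180
        s1 = _stream(aoi)
        s2 = s1.copy()
        s2["time_ms"] = s2["time_ms"] + 123_456
        w1 = window_proportion(s1, 1, 1)
        w2 = window_proportion(s2, 1, 1)
        assert w1.prop_target == w2.prop_target
        assert w1.frac_missing == w2.frac_missing


class TestExclusionCascade:
    def test_one_bad_window_participant_retained(self):
        win = make_window_frame(
            [(1, 1, 1, 0.5, 0.70, 100), (1, 1, 2, 0.5, 0.10, 400),
             (1, 2, 1, 0.5, 0.10, 400), (1, 2, 2, 0.5, 0.10, 400)]
        )
        included, excluded, audit = apply_exclusions(win)
        assert excluded == []
        assert len(included) == 3

    def test_two_bad_windows_participant_excluded(self):
        win = make_window_frame(
            [(1, 1, 1, 0.5, 0.70, 100), (1, 1, 2, 0.5, 0.70, 100),
             (1, 2, 1, 0.5, 0.10, 400), (1, 2, 2, 0.5, 0.10, 400)]
        )
        included, excluded, audit = apply_exclusions(win)
        assert excluded == [1]
        assert len(included) == 0

    def test_clean_data_nothing_excluded(self):
        win = make_window_frame(
            [(1, t, w, 0.5, 0.0, 480) for t in (1, 2) for w in (1, 2)]
        )
        included, excluded, _ = apply_exclusions(win)
        assert excluded == []
        assert len(included) == 4

    def test_threshold_is_inclusive(self):
        win = make_window_frame(
            [(1, 1, 1, 0.5, 0.66, 163), (1, 1, 2, 0.5, 0.0, 480),
             (1, 2, 1, 0.5, 0.0, 480), (1, 2, 2, 0.5, 0.0, 480)]
        )
        included, _, _ = apply_exclusions(win)
        assert len(included) == 3  # 0.66 exactly is dropped

    def test_absent_windows_count_against_participant(self):
        win = make_window_frame(
            [(1, 1, 1, 0.5, 0.0, 480), (1, 1, 2, 0.5, 0.0, 480),
             (1, 2, 1, 0.5, 0.70, 100)]
        )  # fourth window absent entirely
        _, excluded, _ = apply_exclusions(win)
        assert excluded == [1]

    def test_idempotent(self):
        win = make_window_frame(
            [(1, 1, 1, 0.5, 0.70, 100), (1, 1, 2, 0.5, 0.10, 400),
             (1, 2, 1, 0.5, 0.10, 400), (1, 2, 2, 0.5, 0.10, 400),
             (2, 1, 1, 0.5, 0.0, 480), (2, 1, 2, 0.5, 0.0, 480),
             (2, 2, 1, 0.5, 0.0, 480), (2, 2, 2, 0.5, 0.0, 480)]
        )
        once, exc1, _ = apply_exclusions(win)
        twice, exc2, _ = apply_exclusions(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )
        assert exc2 == []

    def test_duplicate_keys_raise(self):
        win = make_window_frame(
            [(1, 1, 1, 0.5, 0.0, 480), (1, 1, 1, 0.6, 0.0, 480)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            apply_exclusions(win)

    def test_audit_log_covers_every_participant(self):
        win = make_window_frame(
            [(pid, t, w, 0.5, 0.0, 480) for pid in (1, 2) for t in (1, 2) for w in (1, 2)]
        )
        _, _, audit = apply_exclusions(win)
        assert sum("participant 1" in line for line in audit) == 1
        assert sum("participant 2" in line for line in audit) == 1


class TestSvTransform:
    def test_midpoint_fixed(self):
        for n in (1, 10, 92, 1000):
            assert sv_transform(0.5, n) == 0.5

    def test_zero_at_n92(self):
        assert sv_transform(0.0, 92) == pytest.approx(0.5 / 92)
        assert sv_transform(0.0, 92) == pytest.approx(0.005435, abs=1e-6)

    def test_one_at_n92(self):
        assert sv_transform(1.0, 92) == pytest.approx(91.5 / 92)
        assert sv_transform(1.0, 92) == pytest.approx(0.994565, abs=1e-6)

    def test_n_zero_raises(self):
        with pytest.raises(ValueError):
            sv_transform(0.5, 0)

    @given(
        y=st.floats(0.0, 1.0),
        y2=st.floats(0.0, 1.0),
        n=st.integers(1, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_interior_and_monotone(self, y, y2, n):
        a, b = sv_transform(y, n), sv_transform(y2, n)
        assert 0.0 < a < 1.0
        if y < y2:
            assert a <= b


class TestBinProportions:
    def test_four_bins_per_window(self):
        stream = _stream(["target"] * 480)
        bins = bin_proportions(stream)
        assert len(bins) == 4
        assert sorted(bins["bin"]) == [1, 2, 3, 4]

    def test_all_target_bin_transformed_below_one(self):
        stream = _stream(["target"] * 480)
        bins = bin_proportions(stream)
        assert (bins["prop_target"] == 1.0).all()
        assert (bins["prop_target_transformed"] < 1.0).all()
        assert (bins["prop_target_transformed"] > 0.0).all()

    def test_constant_stream_equal_bins(self):
        stream = _stream(["target"] * 240 + ["distracter"] * 240)
        # interleave so all bins identical
        aoi = np.array(["target", "distracter"] * 240, dtype=object)
        stream["aoi"] = aoi
        bins = bin_proportions(stream)
        assert bins["prop_target"].nunique() == 1

    def test_empty_bin_flagged(self):
        aoi = ["missing"] * 120 + ["target"] * 360
        bins = bin_proportions(_stream(aoi))
        assert bool(bins.loc[bins["bin"] == 1, "excluded"].iloc[0])
        assert np.isnan(bins.loc[bins["bin"] == 1, "prop_target_transformed"]).all()

    def test_indivisible_window_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            bin_proportions(_stream(["target"] * 480), bin_ms=3000.0)


class TestActionSalience:
    def _windows_for(self, design, prop_by_distracter):
        rows = []
        for _, d in design.iterrows():
            prop_dist = prop_by_distracter[d["distracter_action"]]
            rows.append(
                {
                    "participant_id": d["sequence_id"],
                    "sequence_id": d["sequence_id"],
                    "trial": d["trial"],
                    "window": 1,
                    "prop_target": 1.0 - prop_dist,
                    "frac_missing": 0.0,
                    "n_valid": 480,
                    "excluded": False,
                }
            )
        return pd.DataFrame(rows)

    def test_half_gives_zero_logit(self):
        design = design_frame()
        win = self._windows_for(design, {a: 0.5 for a in "ABCD"})
        sal = action_salience(win, design)
        assert np.allclose(sal["salience_logit"], 0.0)

    def test_planted_salience_recovered(self):
        design = design_frame()
        win = self._windows_for(design, {"A": 0.6, "B": 0.5, "C": 0.5, "D": 0.5})
        sal = action_salience(win, design)
        row = sal[sal["action"] == "A"].iloc[0]
        assert row["prop_as_distracter"] == pytest.approx(0.6)
        assert row["salience_logit"] == pytest.approx(float(logit(0.6)))

    def test_equal_salience_sampling_bound(self):
        rng = np.random.default_rng(11)
        design = design_frame()
        rows = []
        for rep in range(625):  # 625 reps x 16 windows x 1000 samples = 10^4/action
            for _, d in design.iterrows():
                n = 1000
                k = rng.binomial(n, 0.5)
                rows.append(
                    {
                        "participant_id": rep * 8 + d["sequence_id"],
                        "sequence_id": d["sequence_id"],
                        "trial": d["trial"],
                        "window": 1,
                        "prop_target": 1 - k / n,
                        "frac_missing": 0.0,
                        "n_valid": n,
                        "excluded": False,
                    }
                )
        sal = action_salience(pd.DataFrame(rows), design)
        assert np.abs(sal["salience_logit"]).max() < 0.1

    def test_attach_maps_target_action(self):
        design = design_frame()
        win = self._windows_for(design, {"A": 0.6, "B": 0.5, "C": 0.5, "D": 0.5})
        obs = attach_salience(win, design)
        a_rows = obs[obs["target_action"] == "A"]
        assert np.allclose(a_rows["salience_logit"], float(logit(0.6)))


class TestLwlRt:
    def _trial(self, segments, onset_idx=150, n=420):
        """segments: list of (aoi, n_samples) after onset; pre-onset distracter."""
        aoi = ["distracter"] * onset_idx
        for label, cnt in segments:
            aoi += [label] * cnt
        aoi += ["distracter"] * (n - len(aoi))
        return _stream(aoi)

    def test_clean_shift_650(self):
        # 39 samples = 650 ms after onset, then a 30-sample (500 ms) fixation
        t = self._trial([("distracter", 39), ("target", 30), ("distracter", 100)])
        rec = lwl_trial_rt(t, 2500.0)
        assert rec.eligible and rec.rt_ms == 650.0

    def test_shift_at_250_ineligible(self):
        t = self._trial([("distracter", 15), ("target", 30), ("distracter", 100)])
        rec = lwl_trial_rt(t, 2500.0)
        assert not rec.eligible
        assert rec.exclusion_reason == "no_shift_in_window"

    def test_short_fixation_does_not_count(self):
        # 80 ms fixation (5 samples < 6 needed) at 400 ms, real shift at 1000 ms
        t = self._trial(
            [("distracter", 24), ("target", 5), ("distracter", 31),
             ("target", 30), ("distracter", 50)]
        )
        rec = lwl_trial_rt(t, 2500.0)
        assert rec.eligible
        assert rec.rt_ms == pytest.approx(1000.0)

    def test_target_at_onset_ineligible(self):
        aoi = ["distracter"] * 149 + ["target"] * 271
        rec = lwl_trial_rt(_stream(aoi), 2500.0)
        assert rec.exclusion_reason == "target_initial"

    def test_low_screen_time(self):
        aoi = ["distracter"] * 151 + ["missing"] * 269
        rec = lwl_trial_rt(_stream(aoi), 2500.0)
        assert rec.exclusion_reason == "low_screen_time"

    def test_onset_outside_stream_raises(self):
        with pytest.raises(ValueError, match="onset"):
            lwl_trial_rt(_stream(["distracter"] * 60), 5000.0)

    def test_planted_session_exact_recovery(self, truth, sim_config):
        planted = [450.0, 650.0, 900.0, 1200.0, "target_initial", "missing", 250.0]
        stream = generate_lwl_session(truth, sim_config, planted)
        recs = session_rts(stream, sim_config.lwl_target_onset_ms)
        extracted = [r.rt_ms for r in recs if r.eligible]
        assert extracted == [450.0, 650.0, 900.0, 1200.0]
        reasons = [r.exclusion_reason for r in recs if not r.eligible]
        assert "target_initial" in reasons
        assert "low_screen_time" in reasons
        assert "no_shift_in_window" in reasons
        assert participant_rt(recs) == pytest.approx(np.mean([450, 650, 900, 1200]))


class TestParticipantRt:
    def test_mean(self):
        recs = [
            RtRecord(1, 1, True, 400.0, "none"),
            RtRecord(1, 2, True, 600.0, "none"),
        ]
        assert participant_rt(recs) == 500.0

    def test_singleton(self):
        recs = [RtRecord(1, 1, True, 700.0, "none")]
        assert participant_rt(recs) == 700.0

    def test_no_eligible_gives_nan(self):
        recs = [RtRecord(1, 1, False, None, "target_initial")]
        assert np.isnan(participant_rt(recs))

    def test_record_consistency_enforced(self):
        with pytest.raises(ValueError):
            RtRecord(1, 1, True, None, "none")
        with pytest.raises(ValueError):
            RtRecord(1, 1, True, 250.0, "none")  # outside 300-1800


class TestStandardize:
    def test_basic(self):
        out = standardize_covariate([1.0, 2.0, 3.0])
        assert np.allclose(out, [-1.0, 0.0, 1.0])  # ddof=1 denominator

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="variance"):
            standardize_covariate([2.0, 2.0, 2.0])

    def test_round_trip_identity(self, rng):
        x = rng.normal(500, 100, size=50)
        z = standardize_covariate(x)
        back = z * np.std(x, ddof=1) + np.mean(x)
        assert np.allclose(back, x, atol=1e-12)

    def test_nan_propagates(self):
        out = standardize_covariate([1.0, np.nan, 3.0, 5.0])
        assert np.isnan(out[1])
        assert np.isfinite(out[[0, 2, 3]]).all()
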