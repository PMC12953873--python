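import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from choirsync import accuracy as acc
from choirsync import simulate as sim


def make_events(onsets, devs, singer="soprano_1", **meta):
    """Build a minimal linked event frame (deviation already attached)."""
    base = dict(piece="p", voice="soprano", condition="m", block=0, repeat=0, unit="u")
    base.update(meta)
    n = len(onsets)
    return pd.DataFrame(
        {
            "singer": singer,
            "event_index": np.arange(n),
            "onset_s": np.asarray(onsets, dtype=float),
            "deviation": np.asarray(devs, dtype=float),
            **{k: v for k, v in base.items()},
        }
    )


class TestConversions:
    @pytest.mark.parametrize(
        "hz,midi", [(440.0, 69.0), (880.0, 81.0), (261.6256, 60.0)]
    )
    def test_hz_to_midi_reference_points(self, hz, midi):
        assert acc.hz_to_midi(hz) == pytest.approx(midi, abs=1e-3)

    def test_hz_midi_roundtrip_and_errors(self):
        assert acc.midi_to_hz(acc.hz_to_midi(123.4)) == pytest.approx(123.4)
        with pytest.raises(ValueError):
            acc.hz_to_midi(0.0)

    def test_cents_scaling(self):
        assert acc.cents_between(69.5, 69.0) == pytest.approx(50.0)
        assert acc.cents_between(60.0, 60.0) == 0.0

    def test_pythagorean_comma(self):
        assert acc.pythagorean_comma() == pytest.approx(23.46, abs=0.005)


class TestGrossErrors:
    def test_semitone_off_score_removed(self):
        a = make_events([0, 1, 2], [0.0, 1.0, -1.2], singer="soprano_1")
        b = make_events([0, 1, 2], [0.0, 0.0, 0.0], singer="soprano_2")
        kept, report = acc.remove_gross_errors(pd.concat([a, b], ignore_index=True))
        assert report.n_gross_pitch == 2
        assert len(kept) == 4

    def test_onset_screen_boundary_301_removed_299_kept(self):
        # partner anchors the reference onset; the pair filter threshold is
        # strictly "more than 300 ms"
        for gap, removed in ((0.301, True), (0.299, False)):
            a = make_events([0.0, 2.0, 4.0], [0, 0, 0], singer="soprano_1")
            b = make_events([0.0, 2.0 + gap, 4.0], [0, 0, 0], singer="soprano_2")
            kept, report = acc.remove_gross_errors(pd.concat([a, b], ignore_index=True))
            assert (report.n_gross_onset > 0) is removed

    def test_clean_stream_untouched(self, clean_perf_cfg):
        score = sim.make_score("soprano", "p", 30, seed=0)
        a, b = sim.generate_unison_performance(
            score, clean_perf_cfg, rng=np.random.default_rng(0)
        )
        from conftest import tag_streams

        notes = tag_streams(a, b)
        score = score.rename(columns={"piece": "piece"})
        linked = acc.link_to_score(notes.assign(piece="p"), score)
        kept, report = acc.remove_gross_errors(linked)
        assert report.n_gross_pitch == report.n_gross_onset == 0
        assert len(kept) == len(linked)

    def test_unlinked_event_rejected(self):
        score = sim.make_score("soprano", "p", 5, seed=0)
        ev = pd.DataFrame(
            {
                "voice": ["soprano"], "piece": ["p"], "event_index": [99],
                "f0_hz": [440.0], "onset_s": [0.0],
                "singer": ["soprano_1"], "condition": ["m"], "block": [0],
                "repeat": [0], "unit": ["u"],
            }
        )
        with pytest.raises(ValueError, match="not present in score"):
            acc.link_to_score(ev, score)


class TestDetrend:
    def test_linear_trend_gives_zero_residuals(self):
        ev = make_events([0, 1, 2, 3], [0.0, 0.1, 0.2, 0.3])
        out = acc.detrend_pitch(ev)
        assert np.allclose(out["residual_deviation"], 0.0, atol=1e-12)

    def test_constant_deviation_absorbed_by_intercept(self):
        ev = make_events([0, 1, 2], [0.4, 0.4, 0.4])
        out = acc.detrend_pitch(ev)
        assert np.allclose(out["residual_deviation"], 0.0, atol=1e-12)

    def test_three_point_toy_matches_hand_ols(self):
        # OLS of (0, 0.1, 0.26) on t=(0,1,2): slope 0.13, intercept -0.01
        # -> residuals (+0.01, -0.02, +0.01)
        ev = make_events([0, 1, 2], [0.0, 0.1, 0.26])
        out = acc.detrend_pitch(ev)
        assert np.allclose(
            out["residual_deviation"], [0.01, -0.02, 0.01], atol=1e-12
        )

    def test_added_trend_leaves_residuals_unchanged(self, rng):
        t = np.sort(rng.uniform(0, 60, 50))
        base = rng.normal(0, 0.1, 50)
        r1 = acc.detrend_pitch(make_events(t, base))["residual_deviation"]
        r2 = acc.detrend_pitch(make_events(t, base + 0.7 + 0.02 * t))["residual_deviation"]
        assert np.allclose(r1, r2, atol=1e-9)

    def test_double_detrend_rejected(self):
        out = acc.detrend_pitch(make_events([0, 1, 2], [0, 0.1, 0.2]))
        with pytest.raises(RuntimeError, match="twice"):
            acc.detrend_pitch(out)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            acc.detrend_pitch(make_events([1.0, 1.0], [0.0, 0.1]))


class TestMatchingAndFiltering:
    def _stream(self, idx, onsets, residuals):
        return pd.DataFrame(
            {"event_index": idx, "onset_s": onsets, "residual_deviation": residuals}
        )

    def test_identical_streams_full_match(self):
        s = self._stream([0, 1, 2], [0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        pairs = acc.match_pairs(s, s.copy())
        assert len(pairs) == 3
        assert np.allclose(pairs["onset_gap"], 0)

    def test_missing_event_yields_no_pair(self):
        a = self._stream([0, 1, 2], [0, 1, 2], [0, 0, 0])
        b = self._stream([0, 2], [0, 2], [0, 0])
        pairs = acc.match_pairs(a, b)
        assert list(pairs["event_index"]) == [0, 2]

    def test_duplicate_event_index_rejected(self):
        a = self._stream([0, 0], [0, 1], [0, 0])
        with pytest.raises(ValueError, match="duplicate"):
            acc.match_pairs(a, a)

    def test_five_pair_toy_filter_cascade(self):
        # gaps: (0.1 st, 10 ms), (2.6 st, 20 ms), (0.2 st, 310 ms),
        #        (3 st, 400 ms), (0 st, 0 ms)
        pairs = pd.DataFrame(
            {
                "event_index": range(5),
                "onset_a": [0.0, 0.0, 0.0, 0.0, 0.0],
                "onset_b": [0.010, 0.020, 0.310, 0.400, 0.0],
                "residual_a": [0.1, 2.6, 0.2, 3.0, 0.0],
                "residual_b": [0.0, 0.0, 0.0, 0.0, 0.0],
            }
        )
        pairs["pitch_gap"] = (pairs["residual_a"] - pairs["residual_b"]).abs()
        pairs["onset_gap"] = (pairs["onset_a"] - pairs["onset_b"]).abs()
        kept_int, kept_tim, report = acc.filter_pairs(pairs)
        assert len(kept_int) == 3 and len(kept_tim) == 3
        assert set(kept_int["event_index"]) == {0, 2, 4}
        assert set(kept_tim["event_index"]) == {0, 1, 4}
        assert report.n_pair_pitch_removed == 2
        assert report.n_pair_onset_removed == 2

    def test_filters_are_independent(self):
        pairs = pd.DataFrame(
            {
                "event_index": [0], "onset_a": [0.0], "onset_b": [0.35],
                "residual_a": [0.0], "residual_b": [0.0],
            }
        )
        pairs["pitch_gap"] = 0.0
        pairs["onset_gap"] = 0.35
        kept_int, kept_tim, _ = acc.filter_pairs(pairs)
        assert len(kept_int) == 1 and len(kept_tim) == 0


class TestAccuracyRecord:
    def test_two_pair_arithmetic(self):
        intonation = pd.DataFrame({"residual_a": [0.10, 0.20], "residual_b": [0.0, 0.0]})
        timing = pd.DataFrame({"onset_gap": [0.02, 0.04]})
        rec = acc.accuracy_record(intonation, timing)
        assert rec["MAPE"] == pytest.approx(15.0)  # mean of 10 and 20 cents
        assert rec["MOE"] == pytest.approx(0.03)
        assert rec["LMAPE"] == pytest.approx(-np.log(0.15))
        assert rec["LMOE"] == pytest.approx(-np.log(0.03))

    def test_zero_error_flags_l_values(self):
        intonation = pd.DataFrame({"residual_a": [0.0], "residual_b": [0.0]})
        timing = pd.DataFrame({"onset_gap": [0.0]})
        rec = acc.accuracy_record(intonation, timing)
        assert rec["MAPE"] == 0.0 and rec["MOE"] == 0.0
        assert np.isnan(rec["LMAPE"]) and np.isnan(rec["LMOE"])

    def test_brute_force_oracle_mape_moe(self, unison_pair):
        """Pipeline MAPE/MOE equal an explicit per-pair loop, bit-exactly."""
        score, notes = unison_pair
        table, _ = acc.accuracy_table(notes, score, level="piece")
        linked = acc.link_to_score(notes, score)
        kept, _ = acc.remove_gross_errors(linked)
        det = acc.detrend_pitch(kept)
        a = det[det["singer"] == "soprano_1"].set_index("event_index")
        b = det[det["singer"] == "soprano_2"].set_index("event_index")
        common = sorted(set(a.index) & set(b.index))
        pitch_gaps, onset_gaps = [], []
        for i in common:
            pg = abs(a.loc[i, "residual_deviation"] - b.loc[i, "residual_deviation"])
            og = abs(a.loc[i, "onset_s"] - b.loc[i, "onset_s"])
            if pg <= 2.5:
                pitch_gaps.append(pg * 100.0)
            if og <= 0.300:
                onset_gaps.append(og)
        assert table.iloc[0]["MAPE"] == np.mean(pitch_gaps)
        assert table.iloc[0]["MOE"] == np.mean(onset_gaps)

    @given(st.floats(-0.5, 0.5), st.floats(-2, 2))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_translation_invariance(self, dt, dp):
        """Shifting both singers' onsets or pitches equally changes nothing."""
        intonation = pd.DataFrame(
            {"residual_a": [0.10 + dp, 0.20 + dp], "residual_b": [dp, dp]}
        )
        timing = pd.DataFrame({"onset_gap": [0.02, 0.04]})  # gap unchanged by dt
        rec = acc.accuracy_record(intonation, timing)
        assert rec["MAPE"] == pytest.approx(15.0)
        assert rec["MOE"] == pytest.approx(0.03)


class TestAccuracyTable:
    def test_moment_recovery_closed_forms(self):
        from choirsync.experiments import accuracy_moment_recovery

        r = accuracy_moment_recovery(n_notes=4000, seed=11)
        assert abs(r["MOE"] - r["MOE_expected"]) < 3 * r["MOE_se"]
        assert abs(r["MAPE"] - r["MAPE_expected"]) < 3 * r["MAPE_se"]

    def test_gross_saturation_empties_record(self, clean_perf_cfg):
        from dataclasses import replace

        score = sim.make_score("soprano", "p", 30, seed=1)
        cfg = replace(clean_perf_cfg, gross_pitch_error_rate=1.0)
        a, b = sim.generate_unison_performance(score, cfg, rng=np.random.default_rng(1))
        from conftest import tag_streams

        notes = tag_streams(a, b)
        linked = acc.link_to_score(notes, score)
        kept, report = acc.remove_gross_errors(linked)
        assert len(kept) == 0
        assert report.fraction_gross_removed == 1.0

    def test_table_row_count_validated_against_design(self, small_design):
        from choirsync.experiments import _tiny_perf_cfg, generate_perf_only_study

        study = generate_perf_only_study(small_design, _tiny_perf_cfg(), seed=0, events_per_piece=8)
        table, _ = acc.accuracy_table(
            study.notes, study.score, level="piece", design=small_design
        )
        assert len(table) == 72  # 4 voices x 6 repeats x 3 conditions
        unit, _ = acc.accuracy_table(
            study.notes, study.score, level="recording_unit", design=small_design
        )
        assert len(unit) == 24  # 4 voices x 2 blocks x 3 conditions
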