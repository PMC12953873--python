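"""Intonation and timing accuracy of unison singer pairs.

Each voice of the ensemble is sung by two singers in unison, so singing
quality is measured *between* the two singers of a voice rather than
against the score: micro-timing deviations from the notation are artistic
interpretation, but two singers rendering the same line should agree with
each other.  The cascade is:

1. link note events to the score and convert Hz to fractional MIDI
   (equal temperament, a' = 440 Hz = MIDI 69);
2. remove gross singing errors (pitch >= 1 semitone off the score, or
   onset > 300 ms away from the ensemble's reference onset for that event);
3. remove per-singer linear pitch drift by OLS residualization within each
   recording;
4. match the two singers' events by score position;
5. filter matched pairs (> 2.5 semitone pitch gaps out of the intonation
   set, > 300 ms onset gaps out of the timing set — deemed singing or
   reading errors, not inaccuracy);
6. aggregate: MAPE (mean absolute pitch error, cents), MOE (mean onset
   error, seconds), and their negative logs LMAPE/LMOE where higher means
   more accurate.

The cascade order is fixed; ``detrend_pitch`` is applied exactly once per
stream (tracked by a processing flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ObservationLevel, StudyDesign

__all__ = [
    "hz_to_midi",
    "midi_to_hz",
    "cents_between",
    "pythagorean_comma",
    "link_to_score",
    "remove_gross_errors",
    "detrend_pitch",
    "match_pairs",
    "filter_pairs",
    "accuracy_record",
    "accuracy_table",
    "AccuracyThresholds",
    "RemovalReport",
]

#: identity of one audio recording: one singer performing one piece once
STREAM_KEY = ["piece", "voice", "singer", "condition", "block", "repeat"]
#: identity of one unison recording instance (the pair of streams)
RECORDING_KEY = ["piece", "voice", "condition", "block", "repeat"]


@dataclass(frozen=True)
class AccuracyThresholds:
    """Filter constants of the cascade (units: fractional MIDI and seconds)."""

    gross_pitch_semitones: float = 1.0  # >= 1 semitone off the score
    gross_onset_s: float = 0.300  # > 300 ms off the reference onset
    pair_pitch_semitones: float = 2.5  # > 2.5 semitones between the pair
    pair_onset_s: float = 0.300  # > 300 ms between the pair

    def __post_init__(self) -> None:
        if min(vars(self).values()) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class RemovalReport:
    """Counts and fractions removed at each cascade stage."""

    n_events: int = 0
    n_gross_pitch: int = 0
    n_gross_onset: int = 0
    n_pairs: int = 0
    n_pair_pitch_removed: int = 0
    n_pair_onset_removed: int = 0
    iqr_onset_criterion_s: float = float("nan")  # 1.5*IQR diagnostic, logged only

    @property
    def fraction_gross_removed(self) -> float:
        return (self.n_gross_pitch + self.n_gross_onset) / max(self.n_events, 1)

    def as_dict(self) -> dict:
        d = dict(vars(self))
        d["fraction_gross_removed"] = self.fraction_gross_removed
        return d


# ---------------------------------------------------------------------------
# music-theory conversions


def hz_to_midi(f0):
    """Fractional MIDI pitch at concert tuning: 69 + 12*log2(f0/440)."""
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise ValueError("fundamental frequency must be positive")
    out = 69.0 + 12.0 * np.log2(f0 / 440.0)
    return float(out) if out.ndim == 0 else out


def midi_to_hz(midi):
    midi = np.asarray(midi, dtype=float)
    out = 440.0 * 2.0 ** ((midi - 69.0) / 12.0)
    return float(out) if out.ndim == 0 else out


def cents_between(midi_a, midi_b):
    """Signed interval in cents: 100 * (midi_a - midi_b); 0.5 MIDI = 50 cents."""
    out = 100.0 * (np.asarray(midi_a, dtype=float) - np.asarray(midi_b, dtype=float))
    return float(out) if out.ndim == 0 else out


def pythagorean_comma() -> float:
    """Gap between twelve pure fifths and seven octaves, in cents (~23.46).

    Bounds the discrepancy between equal-tempered and just tuning targets,
    which justifies assuming equal temperament when the measured pitch
    errors are well below it.
    """
    return float(1200.0 * np.log2(3.0**12 / 2.0**19))


# ---------------------------------------------------------------------------
# cascade stages


def link_to_score(events: pd.DataFrame, score: pd.DataFrame) -> pd.DataFrame:
    """Attach score pitch/onset and derive fractional MIDI and score deviation.

    Every event must reference an existing (voice, piece, event_index) in
    the score; an unlinked event is an annotation error, not data.
    """
    ev = events.copy()
    sc = score.rename(columns={"midi_pitch": "score_midi"})[
        ["voice", "piece", "event_index", "score_midi", "onset_beats"]
    ]
    merged = ev.merge(sc, on=["voice", "piece", "event_index"], how="left", validate="m:1")
    if merged["score_midi"].isna().any():
        bad = merged.loc[merged["score_midi"].isna(), ["voice", "piece", "event_index"]]
        raise ValueError(f"events not present in score:\n{bad.drop_duplicates().head()}")
    merged["midi_pitch"] = hz_to_midi(merged["f0_hz"].to_numpy())
    merged["deviation"] = merged["midi_pitch"] - merged["score_midi"]
    return merged


def _reference_onsets(events: pd.DataFrame) -> pd.Series:
    """Leave-one-out median onset per (recording instance, event_index).

    The ensemble itself anchors performance time: an event's reference is
    the median onset of the *other* singers at the same score position in
    the same recording.  With a unison pair this is the partner's onset.
    Events with no co-performer get no reference (NaN) and pass the screen.
    """
    keys = RECORDING_KEY + ["event_index"]
    grp = events.groupby(keys)["onset_s"]
    total = grp.transform("sum")
    count = grp.transform("count")
    med = grp.transform("median")
    loo_mean = (total - events["onset_s"]) / (count - 1).replace(0, np.nan)
    # with two singers the leave-one-out median equals the partner's onset
    # (= leave-one-out mean); for larger groups fall back to the plain
    # median, which is robust to the left-out value for n >= 3
    ref = loo_mean.where(count == 2, med.where(count >= 3))
    return ref


def remove_gross_errors(
    events: pd.DataFrame,
    score: pd.DataFrame | None = None,
    thresholds: AccuracyThresholds = AccuracyThresholds(),
    report: RemovalReport | None = None,
) -> tuple[pd.DataFrame, RemovalReport]:
    """Drop gross singing errors; returns (kept events, removal report).

    Pitch screen: |deviation from score| >= 1 semitone (1.0 fractional
    MIDI).  Onset screen: |onset - reference onset| > 300 ms, the reference
    being the leave-one-out ensemble onset for that score event.
    """
    if "deviation" not in events.columns:
        if score is None:
            raise ValueError("events lack a 'deviation' column and no score was given")
        events = link_to_score(events, score)
    report = report or RemovalReport()
    report.n_events += len(events)
    bad_pitch = events["deviation"].abs() >= thresholds.gross_pitch_semitones
    ref = _reference_onsets(events)
    onset_err = (events["onset_s"] - ref).abs()
    bad_onset = (onset_err > thresholds.gross_onset_s) & ~bad_pitch
    report.n_gross_pitch += int(bad_pitch.sum())
    report.n_gross_onset += int(bad_onset.sum())
    kept = events[~(bad_pitch | bad_onset)].copy()
    return kept, report


def detrend_pitch(events: pd.DataFrame) -> pd.DataFrame:
    """OLS-residualize score deviation on onset time, per singer per recording.

    Removes each singer's linear pitch drift within a recording; the
    residuals (``residual_deviation``) are what intonation accuracy is
    computed from.  Constant between-singer offsets are absorbed by the
    per-singer intercepts, so MAPE measures dispersion, not bias.  Groups
    with fewer than 3 events keep their demeaned deviation.
    """
    if events.attrs.get("detrended"):
        raise RuntimeError("detrend_pitch applied twice to the same stream")
    out = events.copy()
    resid = np.full(len(out), np.nan)
    for _, idx in out.groupby(STREAM_KEY, sort=False).indices.items():
        t = out["onset_s"].to_numpy()[idx]
        y = out["deviation"].to_numpy()[idx]
        if len(idx) >= 3 and np.ptp(t) > 0:
            coef = np.polyfit(t, y, 1)
            resid[idx] = y - np.polyval(coef, t)
        elif len(idx) >= 1:
            if len(idx) >= 2 and np.ptp(t) == 0:
                raise ValueError("degenerate drift group: all onsets identical")
            resid[idx] = y - y.mean()
    out["residual_deviation"] = resid
    out.attrs["detrended"] = True
    return out


def match_pairs(stream_a: pd.DataFrame, stream_b: pd.DataFrame) -> pd.DataFrame:
    """Pair the two singers' surviving events by score position.

    Events present in only one stream (omissions, gross-error removals)
    yield no pair.  Duplicate score positions within a stream are an
    annotation error.
    """
    for s in (stream_a, stream_b):
        if s["event_index"].duplicated().any():
            raise ValueError("duplicate event_index within a stream")
    cols = ["event_index", "onset_s", "residual_deviation"]
    a = stream_a[cols].rename(columns={"onset_s": "onset_a", "residual_deviation": "residual_a"})
    b = stream_b[cols].rename(columns={"onset_s": "onset_b", "residual_deviation": "residual_b"})
    pairs = a.merge(b, on="event_index", how="inner")
    pairs["pitch_gap"] = (pairs["residual_a"] - pairs["residual_b"]).abs()
    pairs["onset_gap"] = (pairs["onset_a"] - pairs["onset_b"]).abs()
    return pairs


def filter_pairs(
    pairs: pd.DataFrame,
    thresholds: AccuracyThresholds = AccuracyThresholds(),
    report: RemovalReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, RemovalReport]:
    """Split pairs into the intonation and timing analysis sets.

    The two screens are independent: a pair with a 3-semitone pitch gap but
    tight onsets stays in the timing set, and vice versa.
    """
    report = report or RemovalReport()
    report.n_pairs += len(pairs)
    keep_int = pairs["pitch_gap"] <= thresholds.pair_pitch_semitones
    keep_tim = pairs["onset_gap"] <= thresholds.pair_onset_s
    report.n_pair_pitch_removed += int((~keep_int).sum())
    report.n_pair_onset_removed += int((~keep_tim).sum())
    if len(pairs):
        q1, q3 = np.percentile(pairs["onset_gap"], [25, 75])
        report.iqr_onset_criterion_s = float(q3 + 1.5 * (q3 - q1))
    return pairs[keep_int].copy(), pairs[keep_tim].copy(), report


def accuracy_record(
    intonation: pd.DataFrame, timing: pd.DataFrame, keys: dict | None = None
) -> dict:
    """MAPE/MOE and their negative logs for one group of matched pairs.

    MAPE is reported in cents, but the logarithm is taken of the value in
    fractional-MIDI units (cents/100); MOE and its log are in seconds.  The
    unit choice inside the log shifts L-values by an additive constant only,
    which model intercepts absorb.  Empty or zero-error groups yield NaN
    L-values and are flagged for downstream exclusion.
    """
    rec = dict(keys or {})
    n_int, n_tim = len(intonation), len(timing)
    mape = float(cents_between(intonation["residual_a"], intonation["residual_b"]).__abs__().mean()) if n_int else np.nan
    moe = float(timing["onset_gap"].mean()) if n_tim else np.nan
    rec.update(
        MAPE=mape,
        MOE=moe,
        LMAPE=-np.log(mape / 100.0) if n_int and mape > 0 else np.nan,
        LMOE=-np.log(moe) if n_tim and moe > 0 else np.nan,
        n_pairs_intonation=n_int,
        n_pairs_timing=n_tim,
    )
    return rec


# ---------------------------------------------------------------------------
# full cascade over a study's note table


def _prepare(notes, score, thresholds, report):
    linked = link_to_score(notes, score)
    kept, report = remove_gross_errors(linked, thresholds=thresholds, report=report)
    detrended = detrend_pitch(kept)
    return detrended, report


def accuracy_table(
    notes: pd.DataFrame,
    score: pd.DataFrame,
    level: ObservationLevel | str = ObservationLevel.PIECE,
    thresholds: AccuracyThresholds = AccuracyThresholds(),
    design: StudyDesign | None = None,
) -> tuple[pd.DataFrame, RemovalReport]:
    """Run the whole cascade and aggregate accuracy records.

    ``level='piece'`` yields one row per (piece repeat x voice x condition)
    — the study's piece-level table (336 rows at full scale).
    ``level='recording_unit'`` pools matched pairs over the pieces of a
    block before averaging — the unit-level table (96 rows).
    """
    level = ObservationLevel(level)
    if level not in (ObservationLevel.PIECE, ObservationLevel.RECORDING_UNIT):
        raise ValueError(f"unsupported aggregation level {level}")
    report = RemovalReport()
    detrended, report = _prepare(notes, score, thresholds, report)

    all_int, all_tim = [], []
    for rec_key, grp in detrended.groupby(RECORDING_KEY, sort=False):
        singers = sorted(grp["singer"].unique())
        if len(singers) != 2:
            raise ValueError(f"recording {rec_key} has {len(singers)} singers, expected 2")
        a = grp[grp["singer"] == singers[0]]
        b = grp[grp["singer"] == singers[1]]
        pairs = match_pairs(a, b)
        kept_int, kept_tim, report = filter_pairs(pairs, thresholds, report)
        meta = dict(zip(RECORDING_KEY, rec_key))
        meta["unit"] = grp["unit"].iloc[0] if "unit" in grp else ""
        for name, df, coll in (("i", kept_int, all_int), ("t", kept_tim, all_tim)):
            tagged = df.copy()
            for k, v in meta.items():
                tagged[k] = v
            coll.append(tagged)
    int_pairs = pd.concat(all_int, ignore_index=True) if all_int else pd.DataFrame()
    tim_pairs = pd.concat(all_tim, ignore_index=True) if all_tim else pd.DataFrame()

    if level is ObservationLevel.PIECE:
        group_cols = RECORDING_KEY + ["unit"]
    else:
        group_cols = ["voice", "condition", "block", "unit"]

    keys = pd.concat(
        [int_pairs[group_cols], tim_pairs[group_cols]], ignore_index=True
    ).drop_duplicates()
    records = []
    gi = dict(tuple(int_pairs.groupby(group_cols, sort=False))) if len(int_pairs) else {}
    gt = dict(tuple(tim_pairs.groupby(group_cols, sort=False))) if len(tim_pairs) else {}
    empty = int_pairs.iloc[0:0]
    for key_row in keys.itertuples(index=False):
        k = tuple(key_row)
        kk = k if len(group_cols) > 1 else k[0]
        records.append(
            accuracy_record(
                gi.get(kk, empty), gt.get(kk, empty), keys=dict(zip(group_cols, k))
            )
        )
    table = pd.DataFrame(records)
    if design is not None:
        from .design import observation_count

        expected = observation_count(design, level)
        if len(table) != expected:
            raise ValueError(
                f"{level.value} table has {len(table)} rows, design expects {expected}"
            )
    return table, report
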