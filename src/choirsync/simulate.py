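"""Synthetic study generator: coupled respiration and unison note streams.

The real study measured eight professional singers (two per voice) breathing
and singing Renaissance polyphony under three spatial arrangements.  No raw
recordings ship with this package, so every analysis stage is exercised
against a generator that emulates the study's statistical structure:

* **Respiration** — noisy Kuramoto phase oscillators.  Each singer's belt
  signal is ``sin(phi_i) + measurement noise`` with
  ``dphi_i/dt = omega_i(t) + sum_j kappa_ij sin(phi_j - phi_i) + noise``,
  integrated by fixed-step Euler-Maruyama.  The pairwise coupling strength
  ``kappa`` is the tunable knob the coupling indices must recover; breathing
  frequencies sit around 0.25 Hz (15 breaths/min) inside the analysis band
  0.025-0.40 Hz, with a slow frequency wander.
* **Performance** — both singers of a voice render the same score line with
  a *shared* expressive-timing random walk (artistic interpretation, common
  to the pair and therefore invisible to between-singer measures) plus
  independent Gaussian onset jitter, cents-scale pitch jitter, a linear
  pitch drift, constant pitch offsets, and rare gross errors (>= 1 semitone
  pitch substitutions, > 300 ms onset displacements, omitted notes).

Every generator is deterministic under a fixed seed; child streams are
spawned per trial/stream so stages can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupling import RespirationTrace
from .design import StudyDesign, enumerate_recordings

__all__ = [
    "RespirationSimConfig",
    "PerformanceSimConfig",
    "SyntheticStudy",
    "generate_respiration_ensemble",
    "generate_unison_performance",
    "generate_study_dataset",
    "make_score",
    "default_score",
    "load_example_score",
    "read_score",
    "write_score",
]

# vocal ranges (MIDI) used for synthetic score lines
_VOICE_RANGES = {
    "soprano": (60, 79),
    "altus": (55, 74),
    "tenor": (50, 69),
    "bassus": (43, 62),
}


@dataclass(frozen=True)
class RespirationSimConfig:
    """Parameters of the coupled-oscillator respiration ensemble.

    ``coupling_strength`` (rad/s) applies per ordered pair; pass a square
    matrix for heterogeneous coupling.  ``phase_noise_sd`` is the diffusion
    scale in rad/sqrt(s); ``slow_modulation`` is (amplitude in Hz, frequency
    in Hz) of a sinusoidal wander of each oscillator's base frequency.
    """

    n_singers: int = 8
    duration: float = 400.0  # s; >= 360 s so full-pipeline clips succeed
    sampling_rate: float = 10.0  # Hz; far above 2 * 0.40 Hz Nyquist
    base_frequency_mean: float = 0.25  # Hz
    base_frequency_sd: float = 0.03  # Hz
    coupling_strength: float | np.ndarray = 0.1  # rad/s per pair
    phase_noise_sd: float = 0.2  # rad/sqrt(s)
    amplitude_noise_sd: float = 0.1
    slow_modulation: tuple[float, float] = (0.02, 0.005)  # (Hz amplitude, Hz)
    seed: int | None = None

    def kappa_matrix(self) -> np.ndarray:
        k = self.coupling_strength
        if np.isscalar(k):
            m = np.full((self.n_singers, self.n_singers), float(k))
        else:
            m = np.asarray(k, dtype=float)
            if m.shape != (self.n_singers, self.n_singers):
                raise ValueError("coupling matrix must be n_singers x n_singers")
        np.fill_diagonal(m, 0.0)
        if (m < 0).any():
            raise ValueError("coupling strengths must be >= 0")
        return m


@dataclass(frozen=True)
class PerformanceSimConfig:
    """Parameters of the unison-performance generator.

    Defaults emulate the accuracy scale of a professional early-music
    ensemble: independent onset jitter of 46 ms per singer puts the expected
    mean absolute onset difference ``2*sigma_t/sqrt(pi)`` near 52 ms, and
    independent pitch jitter of 14.5 cents puts the expected mean absolute
    pitch difference near 16.4 cents.
    """

    onset_jitter_sd: float = 0.0461  # s, independent per singer
    shared_timing_sd: float = 0.010  # s, random-walk step shared by the pair
    pitch_jitter_sd: float = 14.5  # cents, independent per singer
    drift_slope: float = 0.1  # cents/s, per singer
    pitch_offset: float = 0.0  # cents, per singer
    gross_pitch_error_rate: float = 0.012  # prob. of a >= 1 semitone substitution
    gross_onset_error_rate: float = 0.004  # prob. of a > 300 ms displacement
    omission_rate: float = 0.005  # prob. a note is not sung
    tempo: float = 2.0  # beats per second
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("onset_jitter_sd", "shared_timing_sd", "pitch_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gross_pitch_error_rate", "gross_onset_error_rate", "omission_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.tempo <= 0:
            raise ValueError("tempo must be positive")


def _rng(seed: int | None, *context: object) -> np.random.Generator:
    """Deterministic child generator from a seed plus a context tag."""
    if not context:
        return np.random.default_rng(seed)
    tag = int.from_bytes(hashlib.sha256(repr(context).encode()).digest()[:4], "big")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed or 0) & 0x7FFFFFFF, tag & 0x7FFFFFFF])
    )


# ---------------------------------------------------------------------------
# respiration


def generate_respiration_ensemble(
    config: RespirationSimConfig,
    rng: np.random.Generator | None = None,
    singers: list[str] | None = None,
    block: int = 0,
    condition: str = "",
) -> list[RespirationTrace]:
    """Integrate the noisy Kuramoto ensemble and return one trace per singer."""
    if config.duration <= 0 or config.sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    if rng is None:
        rng = _rng(config.seed)
    n = config.n_singers
    fs = config.sampling_rate
    dt = 1.0 / fs
    n_steps = int(round(config.duration * fs))
    kappa = config.kappa_matrix()

    base_f = rng.normal(config.base_frequency_mean, config.base_frequency_sd, size=n)
    base_f = np.clip(base_f, 0.03, None)  # keep every oscillator in-band
    mod_amp, mod_f = config.slow_modulation
    mod_phase = rng.uniform(0, 2 * np.pi, size=n)
    phi = rng.uniform(0, 2 * np.pi, size=n)
    noise = rng.normal(0.0, config.phase_noise_sd * np.sqrt(dt), size=(n_steps, n))

    phases = np.empty((n_steps, n))
    t = 0.0
    for k in range(n_steps):
        phases[k] = phi
        f_inst = base_f + mod_amp * np.sin(2 * np.pi * mod_f * t + mod_phase)
        pull = (kappa * np.sin(phi[None, :] - phi[:, None])).sum(axis=1)
        phi = phi + (2 * np.pi * f_inst + pull) * dt + noise[k]
        t += dt
    signals = np.sin(phases)
    if config.amplitude_noise_sd > 0:
        signals = signals + rng.normal(0.0, config.amplitude_noise_sd, size=signals.shape)
    if singers is None:
        singers = [f"singer_{i + 1}" for i in range(n)]
    return [
        RespirationTrace(
            singer=singers[i],
            samples=signals[:, i].copy(),
            sampling_rate=fs,
            block=block,
            condition=condition,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# scores


def make_score(
    voice: str,
    piece: str,
    n_events: int,
    seed: int = 0,
    midi_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """A synthetic score line: a bounded random-walk melody with mixed note values."""
    rng = _rng(seed, "score", voice, piece)
    lo, hi = midi_range or _VOICE_RANGES.get(voice, (48, 72))
    pitch = rng.integers(lo + 4, hi - 4)
    pitches, durations = [], []
    for _ in range(n_events):
        step = rng.choice([-4, -2, -1, 0, 1, 2, 4], p=[0.05, 0.2, 0.22, 0.06, 0.22, 0.2, 0.05])
        pitch = int(np.clip(pitch + step, lo, hi))
        pitches.append(pitch)
        durations.append(float(rng.choice([0.5, 1.0, 1.0, 2.0])))
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return pd.DataFrame(
        {
            "voice": voice,
            "piece": piece,
            "event_index": np.arange(n_events),
            "midi_pitch": np.asarray(pitches, dtype=float),
            "onset_beats": onsets,
            "duration_beats": np.asarray(durations),
        }
    )


# default piece lengths (score events per voice) chosen so a full study at
# the default design carries on the order of 65k tone events in total
_DEFAULT_PIECE_EVENTS = {
    "Agnus Dei I": 100,
    "Agnus Dei II": 90,
    "Agnus Dei III": 95,
    "Kyrie I": 100,
    "Kyrie II": 100,
    "Gloria": 110,
    "Virgo prudentissima": 95,
    "D'ung aultre amer": 90,
}


def default_score(
    design: StudyDesign, events_per_piece: dict[str, int] | int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic score for every (voice, piece) the design performs."""
    frames = []
    for piece in design.pieces:
        for voice in design.voices:
            if piece.repeats_per_voice.get(voice, 0) == 0:
                continue
            if isinstance(events_per_piece, int):
                n = events_per_piece
            elif events_per_piece is not None:
                n = events_per_piece[piece.name]
            else:
                n = _DEFAULT_PIECE_EVENTS.get(piece.name, 60)
            frames.append(make_score(voice, piece.name, n, seed=seed))
    return pd.concat(frames, ignore_index=True)


SCORE_COLUMNS = ["voice", "piece", "event_index", "midi_pitch", "onset_beats", "duration_beats"]


def load_example_score() -> pd.DataFrame:
    """The bundled synthetic example score: 4 voices x 60 events of one piece."""
    from importlib import resources

    with resources.files("choirsync.data").joinpath("example_score.csv").open() as fh:
        return read_score(fh)


def read_score(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"score file lacks columns {sorted(missing)}")
    return df[SCORE_COLUMNS]


def write_score(df: pd.DataFrame, path) -> None:
    df[SCORE_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# unison performance


def _render_stream(
    score: pd.DataFrame,
    config: PerformanceSimConfig,
    shared_walk: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(score)
    onset_nominal = score["onset_beats"].to_numpy() / config.tempo
    duration = score["duration_beats"].to_numpy() / config.tempo
    onset = onset_nominal + shared_walk + rng.normal(0.0, config.onset_jitter_sd, n)
    cents = (
        config.pitch_offset
        + config.drift_slope * onset_nominal
        + rng.normal(0.0, config.pitch_jitter_sd, n)
    )
    midi = score["midi_pitch"].to_numpy() + cents / 100.0

    gross_pitch = rng.random(n) < config.gross_pitch_error_rate
    if gross_pitch.any():
        # substitution of at least one semitone, either direction
        shift = (1.0 + np.abs(rng.normal(0.0, 0.5, gross_pitch.sum()))) * rng.choice(
            [-1.0, 1.0], gross_pitch.sum()
        )
        midi[gross_pitch] += shift
    gross_onset = rng.random(n) < config.gross_onset_error_rate
    if gross_onset.any():
        disp = (0.301 + rng.exponential(0.15, gross_onset.sum())) * rng.choice(
            [-1.0, 1.0], gross_onset.sum()
        )
        onset[gross_onset] += disp

    keep = rng.random(n) >= config.omission_rate
    f0 = 440.0 * 2.0 ** ((midi - 69.0) / 12.0)
    out = pd.DataFrame(
        {
            "voice": score["voice"].to_numpy(),
            "piece": score["piece"].to_numpy(),
            "event_index": score["event_index"].to_numpy(),
            "onset_s": onset,
            "duration_s": duration,
            "f0_hz": f0,
        }
    )
    return out[keep].reset_index(drop=True)


def generate_unison_performance(
    score: pd.DataFrame,
    config: PerformanceSimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render one score line twice: the two unison singers of a voice.

    Returns two note-event DataFrames (columns ``voice, piece, event_index,
    onset_s, duration_s, f0_hz``).  The expressive-timing random walk is
    drawn once and applied to both singers, so it cancels from every
    between-singer measure; all jitters, drifts and gross errors are
    independent per singer.
    """
    if score.empty:
        raise ValueError("score must be non-empty")
    if not score["event_index"].is_monotonic_increasing:
        raise ValueError("score event_index must be increasing")
    if rng is None:
        rng = _rng(config.seed)
    n = len(score)
    shared = np.cumsum(rng.normal(0.0, config.shared_timing_sd, n))
    return (
        _render_stream(score, config, shared, rng),
        _render_stream(score, config, shared, rng),
    )


# ---------------------------------------------------------------------------
# full study


@dataclass
class SyntheticStudy:
    """All raw material of one synthetic study run."""

    design: StudyDesign
    score: pd.DataFrame
    notes: pd.DataFrame  # one row per sung tone, all singers/conditions
    respiration: dict[tuple[int, str], list[RespirationTrace]] = field(repr=False)

    @property
    def n_streams(self) -> int:
        cols = ["piece", "voice", "singer", "condition", "repeat"]
        return len(self.notes[cols].drop_duplicates())


def _condition_adjusted(
    cfg, condition: str, condition_effects: dict | None, fields: tuple[str, ...]
):
    """Apply additive per-condition offsets to selected config fields."""
    if not condition_effects or condition not in condition_effects:
        return cfg
    eff = condition_effects[condition]
    updates = {}
    for name in fields:
        if name in eff:
            base = getattr(cfg, name)
            updates[name] = max(0.0, float(base) + float(eff[name]))
    if not updates:
        return cfg
    from dataclasses import replace

    return replace(cfg, **updates)


def generate_study_dataset(
    design: StudyDesign,
    resp_cfg: RespirationSimConfig | None = None,
    perf_cfg: PerformanceSimConfig | None = None,
    condition_effects: dict[str, dict[str, float]] | None = None,
    seed: int | None = None,
    score: pd.DataFrame | None = None,
    events_per_piece: dict[str, int] | int | None = None,
) -> SyntheticStudy:
    """One full synthetic study mirroring the design lattice.

    Produces one respiration trace per singer per (block x condition) trial
    and one note-event stream per (piece repeat x voice x singer x
    condition).  ``condition_effects`` maps a condition label to additive
    offsets on ``coupling_strength`` and/or the accuracy SDs
    (``onset_jitter_sd``, ``pitch_jitter_sd``), so tests can build worlds in
    which, e.g., touch increases respiration coupling.
    """
    design.validate()
    resp_cfg = resp_cfg or RespirationSimConfig(n_singers=design.n_singers)
    perf_cfg = perf_cfg or PerformanceSimConfig()
    if resp_cfg.n_singers != design.n_singers:
        raise ValueError("resp_cfg.n_singers must match the design's singer count")
    if score is None:
        score = default_score(design, events_per_piece=events_per_piece, seed=seed or 0)

    respiration: dict[tuple[int, str], list[RespirationTrace]] = {}
    for block in range(len(design.blocks)):
        for cond in design.conditions:
            cfg = _condition_adjusted(
                resp_cfg, cond, condition_effects, ("coupling_strength",)
            )
            rng = _rng(seed, "resp", block, cond)
            respiration[(block, cond)] = generate_respiration_ensemble(
                cfg, rng=rng, singers=list(design.singers), block=block, condition=cond
            )

    recs = enumerate_recordings(design)
    voice_recs = recs[recs["singer"].str.endswith("_1")]  # one row per voice-recording
    note_frames = []
    score_by = dict(tuple(score.groupby(["voice", "piece"], sort=False)))
    for row in voice_recs.itertuples(index=False):
        cfg = _condition_adjusted(
            perf_cfg,
            row.condition,
            condition_effects,
            ("onset_jitter_sd", "pitch_jitter_sd"),
        )
        rng = _rng(seed, "perf", row.piece, row.voice, row.condition, row.repeat)
        line = score_by[(row.voice, row.piece)]
        a, b = generate_unison_performance(line, cfg, rng=rng)
        for s_idx, stream in ((1, a), (2, b)):
            stream = stream.copy()
            stream["singer"] = f"{row.voice}_{s_idx}"
            stream["condition"] = row.condition
            stream["block"] = row.block
            stream["unit"] = row.unit
            stream["repeat"] = row.repeat
            note_frames.append(stream)
    notes = pd.concat(note_frames, ignore_index=True)
    return SyntheticStudy(design=design, score=score, notes=notes, respiration=respiration)
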