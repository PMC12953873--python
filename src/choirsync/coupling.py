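"""Respiration phase-coupling: Morlet wavelet phases and pairwise indices.

Breathing of ensemble singers is treated as a band-limited oscillatory
signal (0.025-0.40 Hz, i.e. breath cycles from 2.5 s up to 40 s).  A
complex Morlet continuous wavelet transform yields an instantaneous phase
per time point and frequency component; pairwise phase differences feed
three coupling indices:

* **ACI** (absolute coupling index): fraction of time-frequency points with
  ``|dphi| <= pi/4`` — phase locking in a symmetric quarter-cycle window.
* **PSI** (phase synchronization index): circular mean resultant length
  ``R = |mean(exp(i*dphi))|`` — sensitive to concentration anywhere on the
  circle, also counting points with larger phase differences.
* **ICI** (integrative coupling index): directional variant of the ACI
  counting only ``dphi in (0, +pi/4]`` — a leads b.

All indices live in [0, 1].  Under independent (uniform) phase differences
the analytic chance levels are ACI -> 1/4, ICI -> 1/8, PSI -> O(n^-1/2).

Edge samples inside the cone of influence (where the wavelet support spills
over the ends of the series) are masked and excluded from every index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt
from scipy import stats as sps

from .design import StudyDesign

__all__ = [
    "RespirationTrace",
    "WaveletSpec",
    "WaveletPhases",
    "PhaseDifferenceSeries",
    "CouplingResult",
    "clip_trace",
    "morlet_phases",
    "phase_differences",
    "wrap_phase",
    "aci",
    "psi",
    "ici",
    "pairwise_coupling",
    "aggregate_coupling",
    "band_of_frequency",
    "index_correlations",
    "BANDS",
]

#: frequency-band partition (Hz), following the HRV convention of very-low /
#: low (sympathetic) vs high (parasympathetic) bands; membership of a wavelet
#: component is decided by its center frequency.
BANDS: dict[str, tuple[float, float]] = {
    "very_low": (0.0, 0.04),
    "low": (0.04, 0.15),
    "high": (0.15, np.inf),
}


@dataclass(frozen=True)
class RespirationTrace:
    """One singer's evenly-sampled respiration-belt signal for one trial."""

    singer: str
    samples: np.ndarray
    sampling_rate: float
    block: int = 0
    condition: str = ""
    start_time: float = 0.0

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class WaveletSpec:
    """Morlet transform layout: band edges, number of components, mother parameter."""

    f_min: float = 0.025
    f_max: float = 0.40
    n_components: int = 10
    omega0: float = 6.0
    spacing: str = "logarithmic"  # or "linear"

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.spacing not in ("logarithmic", "linear"):
            raise ValueError("spacing must be 'logarithmic' or 'linear'")

    @property
    def frequencies(self) -> np.ndarray:
        if self.n_components == 1:
            return np.array([np.sqrt(self.f_min * self.f_max)])
        if self.spacing == "logarithmic":
            return np.geomspace(self.f_min, self.f_max, self.n_components)
        return np.linspace(self.f_min, self.f_max, self.n_components)

    @property
    def center_frequency(self) -> float:
        """pywt 'cmor' center frequency equivalent to mother parameter omega0."""
        return self.omega0 / (2 * np.pi)

    @property
    def wavelet_name(self) -> str:
        # cmorB-C: envelope exp(-t^2/B) with B=2 reproduces the standard
        # Morlet envelope exp(-t^2/2); C = omega0 / 2pi.
        return f"cmor2.0-{self.center_frequency:.10f}"


@dataclass(frozen=True)
class WaveletPhases:
    singer: str
    frequencies: np.ndarray  # (n_f,)
    phases: np.ndarray  # (n_t, n_f), radians in (-pi, pi]
    valid: np.ndarray  # (n_t, n_f) bool, False inside the cone of influence
    sampling_rate: float


@dataclass(frozen=True)
class PhaseDifferenceSeries:
    """Wrapped pairwise phase differences dphi = wrap(phi_a - phi_b), per frequency."""

    pair: tuple[str, str]
    frequencies: np.ndarray  # (n_f,)
    dphi: np.ndarray  # (n_t, n_f) in (-pi, pi]
    valid: np.ndarray  # (n_t, n_f) bool

    def at(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(dphi, valid) of frequency component ``k``."""
        return self.dphi[:, k], self.valid[:, k]

    def swapped(self) -> "PhaseDifferenceSeries":
        return PhaseDifferenceSeries(
            pair=(self.pair[1], self.pair[0]),
            frequencies=self.frequencies,
            dphi=wrap_phase(-self.dphi),
            valid=self.valid,
        )


# ---------------------------------------------------------------------------
# preprocessing and transform


def clip_trace(trace: RespirationTrace, max_duration: float = 360.0) -> RespirationTrace:
    """Clip a trace to exactly ``floor(max_duration * fs)`` samples from the start.

    Raises ``ValueError`` (naming the trial) when the trace is shorter than
    the requested duration — coupling estimates on different window lengths
    would not be comparable.
    """
    n_keep = int(np.floor(max_duration * trace.sampling_rate))
    if len(trace.samples) < n_keep:
        raise ValueError(
            f"trace {trace.singer} (block {trace.block}, condition {trace.condition!r}) "
            f"is {trace.duration:.1f} s, shorter than the {max_duration:.0f} s analysis window"
        )
    if len(trace.samples) == n_keep:
        return trace
    return replace(trace, samples=trace.samples[:n_keep])


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    out = np.mod(-np.asarray(x) + np.pi, 2 * np.pi)
    return -(out - np.pi)


def morlet_phases(trace: RespirationTrace, spec: WaveletSpec = WaveletSpec()) -> WaveletPhases:
    """Instantaneous phase per (time, frequency component) via complex Morlet CWT.

    The trace is linearly detrended and z-scored first (belt signals carry
    arbitrary offset and gain; the indices are purely phase-based so this is
    safe).  The cone of influence masks, per component, the edge samples
    closer to either end than the wavelet's e-folding time.
    """
    fs = trace.sampling_rate
    if fs < 2 * spec.f_max:
        raise ValueError(
            f"sampling rate {fs} Hz below Nyquist for f_max={spec.f_max} Hz"
        )
    x = np.asarray(trace.samples, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("trace must be a 1-D series with >= 2 samples")
    x = sps.zscore(_detrend(x))
    dt = 1.0 / fs
    freqs = spec.frequencies
    wavelet = pywt.ContinuousWavelet(spec.wavelet_name)
    scales = pywt.frequency2scale(wavelet, freqs * dt)
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=dt)
    phases = np.angle(coef).T  # (n_t, n_f)

    # cone of influence: e-folding time of the cmor envelope exp(-t^2/B) at
    # scale a is sqrt(B)*a samples; with B=2 this matches the sqrt(2)*s
    # Morlet convention.
    n_t = len(x)
    idx = np.arange(n_t)
    valid = np.empty((n_t, len(freqs)), dtype=bool)
    for k, a in enumerate(scales):
        e_fold = np.sqrt(2.0) * a  # samples
        valid[:, k] = (idx >= e_fold) & (idx <= n_t - 1 - e_fold)
    return WaveletPhases(
        singer=trace.singer, frequencies=freqs, phases=phases, valid=valid, sampling_rate=fs
    )


def _detrend(x: np.ndarray) -> np.ndarray:
    from scipy.signal import detrend

    return detrend(x, type="linear")


def phase_differences(a: WaveletPhases, b: WaveletPhases) -> PhaseDifferenceSeries:
    """dphi = wrap(phi_a - phi_b); a point is valid only where both inputs are."""
    if a.phases.shape != b.phases.shape or not np.allclose(a.frequencies, b.frequencies):
        raise ValueError("phase arrays must share time base and wavelet spec")
    return PhaseDifferenceSeries(
        pair=(a.singer, b.singer),
        frequencies=a.frequencies,
        dphi=wrap_phase(a.phases - b.phases),
        valid=a.valid & b.valid,
    )


# ---------------------------------------------------------------------------
# indices


def _valid_values(dphi: np.ndarray, valid: np.ndarray | None) -> np.ndarray:
    dphi = np.asarray(dphi, dtype=float).ravel()
    if valid is not None:
        dphi = dphi[np.asarray(valid, dtype=bool).ravel()]
    if dphi.size == 0:
        raise ValueError("no valid phase-difference points")
    return dphi

# phase-locking window: |dphi| <= pi/4 counts as coupled (closed interval);
# the directional ICI uses the half-open positive window (0, +pi/4].
LOCK_WINDOW = np.pi / 4


def aci(dphi: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Fraction of valid points with ``|dphi| <= pi/4``.  Chance level 1/4."""
    d = _valid_values(dphi, valid)
    return float(np.mean(np.abs(d) <= LOCK_WINDOW))


def psi(dphi: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Circular mean resultant length ``|mean(exp(i*dphi))|``.  Chance ~ n^-1/2."""
    d = _valid_values(dphi, valid)
    return float(min(1.0, np.abs(np.mean(np.exp(1j * d)))))


def ici(dphi: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Fraction of valid points with ``dphi in (0, +pi/4]`` (a leads b).  Chance 1/8."""
    d = _valid_values(dphi, valid)
    return float(np.mean((d > 0) & (d <= LOCK_WINDOW)))


INDEX_FUNCS = {"ACI": aci, "PSI": psi, "ICI": ici}


def pairwise_coupling(
    traces: list[RespirationTrace],
    spec: WaveletSpec = WaveletSpec(),
    clip: float | None = 360.0,
) -> pd.DataFrame:
    """All unordered singer pairs x frequency components -> ACI/PSI/ICI.

    Returns a long DataFrame with columns ``singer_a, singer_b, frequency_hz,
    ACI, PSI, ICI`` (ICI is directional a->b; the b->a value of a pair is
    obtained from the swapped series and reported as ``ICI_ba``).
    """
    if clip is not None:
        traces = [clip_trace(t, clip) for t in traces]
    phases = [morlet_phases(t, spec) for t in traces]
    rows = []
    for pa, pb in itertools.combinations(phases, 2):
        series = phase_differences(pa, pb)
        rev = series.swapped()
        for k, f in enumerate(series.frequencies):
            d, v = series.at(k)
            rows.append(
                {
                    "singer_a": pa.singer,
                    "singer_b": pb.singer,
                    "frequency_hz": f,
                    "ACI": aci(d, v),
                    "PSI": psi(d, v),
                    "ICI": ici(d, v),
                    "ICI_ba": ici(*rev.at(k)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation


def band_of_frequency(f: float) -> str:
    for name, (lo, hi) in BANDS.items():
        if lo <= f < hi:
            return name
    raise ValueError(f"frequency {f} not in any band")  # pragma: no cover


@dataclass
class CouplingResult:
    """Singer- and voice-level means of one coupling index over a band."""

    index_name: str
    band: str
    singer_means: dict[str, float]
    voice_means: dict[str, float]
    values: pd.DataFrame = field(repr=False)


def aggregate_coupling(
    pairwise: pd.DataFrame,
    design: StudyDesign,
    index_name: str = "ACI",
    band: str = "all",
) -> CouplingResult:
    """Average an index to singer level (each singer vs all others) and voice level.

    A singer's mean couples that singer to *all* other singers — during
    ensemble singing every singer relates to the whole group, not only to
    the unison partner — averaged over the band's frequency components.  A
    voice mean is the arithmetic mean of its two singers' means.
    """
    singers = design.singers
    expected = set(frozenset(p) for p in itertools.combinations(singers, 2))
    present = set(
        frozenset((a, b)) for a, b in zip(pairwise["singer_a"], pairwise["singer_b"])
    )
    missing = expected - present
    if missing:
        names = sorted(tuple(sorted(m)) for m in missing)
        raise ValueError(f"missing singer pairs: {names}")
    df = pairwise
    if band != "all":
        if band not in BANDS:
            raise ValueError(f"unknown band {band!r}")
        lo, hi = BANDS[band]
        df = df[(df["frequency_hz"] >= lo) & (df["frequency_hz"] < hi)]
        if df.empty:
            raise ValueError(f"no frequency components fall in band {band!r}")
    singer_means: dict[str, float] = {}
    for s in singers:
        if index_name == "ICI":
            # directional: use the s -> other orientation for every pair of s
            fwd = df.loc[df["singer_a"] == s, "ICI"]
            bwd = df.loc[df["singer_b"] == s, "ICI_ba"]
            vals = pd.concat([fwd, bwd])
        else:
            sel = (df["singer_a"] == s) | (df["singer_b"] == s)
            vals = df.loc[sel, index_name]
        singer_means[s] = float(vals.mean())
    voice_means = {
        v: float(
            np.mean([singer_means[s] for s in singers if design.voice_of(s) == v])
        )
        for v in design.voices
    }
    return CouplingResult(
        index_name=index_name,
        band=band,
        singer_means=singer_means,
        voice_means=voice_means,
        values=df,
    )


def index_correlations(table: pd.DataFrame, columns=("ACI", "PSI", "ICI")) -> pd.DataFrame:
    """Pearson correlations between coupling indices on matched observations.

    ``table`` holds one row per matched unit with one column per index.
    Returns rows (index_a, index_b, r, p, n).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 matched observations")
    rows = []
    for a, b in itertools.combinations(columns, 2):
        r, p = sps.pearsonr(table[a], table[b])
        rows.append({"index_a": a, "index_b": b, "r": float(r), "p": float(p), "n": len(table)})
    return pd.DataFrame(rows)
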