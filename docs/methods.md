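# Methods

This note documents the models, parameter choices and numerical decisions
behind `choirsync`, and what the synthetic test bed does and does not show
about real ensemble recordings.

## Study-design model

The design is a lattice: 4 voices × 2 singers per voice, 8 pieces grouped
into 3 recording units ("Agnus", "Kyrie", "Josquin"), 8 blocks (3 + 2 + 3
performances of the units), and 3 spatial conditions. Per-voice repeat
counts are stored per piece; the two-voice piece (Agnus Dei II) simply
carries zero repeats for altus and tenor, and no counting rule
special-cases it. The Latin-square ordering of conditions within blocks is
not modelled — it affects no computed quantity. Repeats of a piece within
one condition are assigned round-robin to the blocks of the piece's unit
(uneven counts, e.g. 4 repeats over 3 blocks, put the extra in earlier
blocks); the true per-block distribution is not derivable from the repeat
table, and only block-level aggregates depend on it. All observation
counts (672 audio files; 336/224/112 piece-level rows; 96 unit-level rows;
32 block × voice cells; 640 respiration grid points per condition) are
derived both by closed form and by brute-force enumeration of the recording
descriptors, and the two must agree. The default design ships as an
editable JSON file, so synthetic studies of other shapes are possible.

## Respiration generator

Real respiration is only available as belt recordings, so the generator is
a *stand-in* whose single contract is controllable pairwise phase coupling
in the analysis band: noisy Kuramoto oscillators

  dφᵢ/dt = ωᵢ(t) + Σⱼ κᵢⱼ sin(φⱼ − φᵢ) + σ_φ dW,   sᵢ(t) = sin φᵢ + ε,

integrated by Euler–Maruyama with dt = 1/f_s. Defaults: 10 Hz sampling
(well above the 0.8 Hz Nyquist requirement, cheap for wavelet runs), 400 s
duration (≥ 360 s so trial clipping succeeds), base breathing frequency
0.25 Hz ± 0.03 Hz between singers (≈ 15 breaths/min), slow sinusoidal
frequency wander (±0.02 Hz at 0.005 Hz), phase noise 0.2 rad/√s, amplitude
noise 0.1, and pairwise coupling κ = 0.1 rad/s — a moderate coupling level
at which the indices vary meaningfully across trials without locking. The
original study's belt sampling rate is not derivable from its report;
10 Hz is a free, configurable choice. κ = 0 reproduces the chance levels
(mean ACI ≈ 0.25), κ ≈ 1 locks pairs (ACI ≈ 1 at the breathing frequency).

What this emulates: band-limited quasi-periodic signals with tunable phase
coupling. What it does not: respiratory waveform shape (inhale/exhale
asymmetry), singing-induced apnea and phrase-locked breathing, amplitude
coupling, or nonstationary coupling regimes. Passing tests therefore show
that the *estimators* behave correctly, not that real choir breathing is a
Kuramoto system.

## Performance generator

Both singers of a voice render the same score line. Onsets get a *shared*
expressive-timing random walk (step SD 10 ms per note) plus independent
N(0, σ_t²) jitter; the walk models artistic interpretation common to the
pair and cancels exactly from between-singer measures — the reason the
accuracy measures are defined between singers rather than against the
score. Pitches get independent N(0, σ_c²) cents jitter, a linear drift
(0.1 cents/s), an optional constant offset, and rare gross errors: pitch
substitutions of ≥ 1 semitone (probability 0.012/note), onset displacements
of > 300 ms (0.004/note), and omissions (0.005/note). Defaults σ_t = 46.1 ms
and σ_c = 14.5 cents place the expected mean absolute gaps 2σ/√π at
≈ 52 ms and ≈ 16.4 cents — the accuracy level of a professional early-music
ensemble — and the default piece lengths (~90–110 events) put a full study
near 65k tone events. Tempo is 2 beats/s. Scores are bounded random-walk
melodies within each voice's range; a real score can be supplied as CSV.
Vibrato is deliberately absent (the repertoire is performed without it).

## Wavelet phases and coupling indices

The transform is a complex Morlet (`cmor` with envelope e^{−t²/2},
center frequency ω₀/2π, ω₀ = 6 — the common balance of time and frequency
resolution) over ten components log-spaced on [0.025, 0.40] Hz. Log
spacing is the standard choice for a band spanning more than a decade;
linear spacing is available. Traces are linearly detrended and z-scored
per trial first (belt offset and gain are arbitrary; the indices are
phase-based, so this is safe). Each component masks samples closer to
either edge than the wavelet's e-folding time (√2 · scale); at 0.025 Hz
this cone of influence eats ≈ 54 s per edge, which is why trials must be
long (the 360-s clip leaves ≈ 250 s of valid data at the lowest component)
and why short test fixtures must restrict the band.

Conventions: Δφ = wrap(φ_a − φ_b) into (−π, π]; a quarter-period delayed
copy of a signal yields Δφ = +π/2. ACI counts |Δφ| ≤ π/4 (closed
interval); ICI counts the half-open positive window (0, +π/4], making
ici(a,b) + ici(b,a) ≤ aci(a,b) with equality up to points at exactly 0;
PSI is the circular mean resultant length. PSI and ICI definitions vary in
the literature; each index is one small swappable function, so alternative
definitions can be dropped in without touching the pipeline. Singer-level
means couple each singer to all seven others (during ensemble singing every
singer relates to the whole group); voice means average the two singers.
The band split (very-low < 0.04 Hz, low 0.04–0.15 Hz, high ≥ 0.15 Hz)
follows the HRV sympathetic/parasympathetic convention, with component
membership by center frequency.

## Accuracy cascade

Fixed order: link to score → gross-error removal → per-singer drift removal
→ pair matching → pair filters → aggregation. Decisions:

- **Gross onset screen reference.** The screen removes onsets > 300 ms away
  from a reference in performance time. No score timeline exists for a
  freely-interpreted performance, so the reference is the *leave-one-out*
  ensemble onset for that score event (with a unison pair: the partner's
  onset; with ≥ 3 singers: the median of the others). A plain pair median
  would let a 301-ms displacement hide at ±150 ms; the leave-one-out anchor
  removes both members of a badly split pair, which is conservative. A
  side effect at default settings is that the later 300-ms *pair* filter
  rarely removes anything extra — the gross screen already caught those
  pairs — but the pair filter is kept as an independent guarantee and for
  data ingested without the gross screen.
- **Drift removal** is OLS of score deviation on onset time per singer ×
  recording (per-voice or per-take alternatives would change only how much
  constant offset is absorbed). Consequence, stated prominently: constant
  between-singer pitch offsets are absorbed, so MAPE measures dispersion
  around each singer's own drift line, not bias. Groups with < 3 events
  are demeaned; a group with all-identical onsets is an error. Detrending
  is applied exactly once, enforced by a processing flag.
- **L-transforms.** LMAPE = −ln(MAPE in fractional-MIDI units), LMOE =
  −ln(MOE in seconds); natural log. The unit inside the log only shifts
  L-values additively, which model intercepts absorb; the choice is
  recorded here and configurable in the record layer.
- The 1.5·IQR onset-gap diagnostic is computed and reported per run but is
  *not* used as a filter; the 300-ms musical criterion is.
- Equal temperament (a′ = 440) defines score targets; just-intonation
  targets are out of scope. The 23.46-cent Pythagorean comma bounds the
  tuning-system discrepancy and is exposed as a constant.

## Statistical models

- **Paired t-test** on block × voice condition means (df = n_pairs − 1),
  with paired Cohen's d = mean(diff)/sd(diff) and a noncentral-t 95% CI.
- **Mixed models** use crossed random effects implemented as independent
  variance components over a single spanning group (statsmodels MixedLM):
  one component per random intercept, one per random slope;
  intercept–slope correlations are not modelled. REML for reported fits,
  ML for likelihood-ratio comparisons.
- **Model reduction** is greedy backward selection from the stated start
  structures (timing: `(1|voice) + (1+idx|block) + (1+idx|condition)`;
  intonation: `(1+idx|voice) + (1+idx|block) + (1|condition)`): at each
  step the removal (slopes before intercepts) with the largest LRT
  p ≥ 0.05 is accepted; a singular or non-convergent current fit forces a
  removal regardless. The full trace (term, χ², df, p, reason) is kept.
- **Inference on fixed effects** uses the Wald statistic against a t
  reference with residual-style degrees of freedom (observations minus
  fixed-effect and variance parameters) — a coarse Satterthwaite-type
  correction that is indistinguishable from the normal reference at
  hundreds of observations but less anticonservative on small tables. The
  |t| > 2 significance convention is reported alongside the p-value.
  Condition contrasts are coded ±0.5, so betas are condition differences.
- **Singularity** is flagged when a variance component collapses below 1%
  of the residual variance; singular and non-convergent fits are recorded
  and reduced further rather than reported as best models.

## Calibration and recovery (what the tests establish)

- Analytic nulls: uniform phase differences give ACI → 1/4, ICI → 1/8,
  PSI → O(n^{−1/2}), each verified at n = 10⁵ within 3 Monte-Carlo SEs.
- Closed-form accuracy recovery: with only independent jitters on,
  E[MAPE] = 2σ_c/√π and E[MOE] = 2σ_t/√π, verified within 3 SEs at 2×10⁴
  notes.
- Coupling recovery: mean ACI is monotone in κ over (0, 0.1, 0.2, 0.4,
  0.8) rad/s with 30 seeds per point (Spearman ρ > 0.9; two-singer
  ensembles at 180 s keep this fast).
- Slope recovery: on simulated 96-row unit tables with a known coupling →
  accuracy slope, the 95% CI covers the truth in ≥ 90% of 100 replicates,
  and a shuffled-coupling null rejects in ≤ 10%.
- Type-I calibration: 200 full-cascade null replicates on a small design
  (4 voices, 2 blocks, 2 conditions, 4 pieces of 25 events — chosen so the
  suite completes in minutes) put both the paired t-test and the contrast
  model inside the binomial 95% band around 5%. Long-run rates estimated
  at 600 replicates sit near 5–6%: mixed-model Wald tests carry a known
  small-sample inflation of well under one percentage point after the t
  correction.

These checks validate the estimators and the inference machinery under the
generator's assumptions (stationary coupling, Gaussian jitters,
independence across recordings). They cannot validate annotation quality,
belt artifacts, or non-Gaussian expressive behavior in real recordings.

## Known limitations

- The Kuramoto stand-in has no physiological realism beyond band-limited
  coupled phases; condition effects enter only as parameter offsets.
- Crossed random effects omit intercept–slope correlations, so a reduction
  path involving correlated structures cannot be expressed.
- p-values for mixed models are approximate (no Kenward–Roger or full
  Satterthwaite degrees of freedom).
- The per-block assignment of piece repeats is a modelling convention;
  block-level aggregates would shift slightly under a different assignment.
- MAPE is dispersion-only by construction (drift removal absorbs constant
  offsets); studies of systematic pitch bias need a different estimator.
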