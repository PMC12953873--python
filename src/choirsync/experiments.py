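"""Monte-Carlo validation experiments for the analysis pipeline.

These are the package's own calibration and recovery studies: each one
generates synthetic data with known ground truth, runs the relevant
analysis stages, and summarizes how well the truth is recovered.  They are
used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import accuracy as acc
from . import coupling as cpl
from . import simulate as sim
from . import stats as st
from .design import StudyDesign, tiny_design

__all__ = [
    "mean_abs_diff_expected",
    "accuracy_moment_recovery",
    "aci_vs_kappa",
    "null_condition_calibration",
    "slope_recovery",
    "simulate_unit_table",
]


def mean_abs_diff_expected(sigma: float) -> float:
    """E|X_a - X_b| for independent N(0, sigma^2) errors: 2*sigma/sqrt(pi)."""
    return 2.0 * sigma / np.sqrt(np.pi)


# ---------------------------------------------------------------------------
# accuracy-moment recovery


def accuracy_moment_recovery(
    sigma_t: float = 0.0461,
    sigma_c: float = 14.5,
    n_notes: int = 20000,
    seed: int = 0,
) -> dict:
    """Run clean unison streams through the full cascade; report MAPE/MOE.

    Only independent jitters are switched on, so the closed forms
    E[MOE] = 2*sigma_t/sqrt(pi) and E[MAPE] = 2*sigma_c/sqrt(pi) hold; the
    returned dict carries observed values, expectations, and Monte-Carlo
    standard errors of the observed means.
    """
    rng = np.random.default_rng(seed)
    score = sim.make_score("soprano", "long", n_notes, seed=seed)
    cfg = sim.PerformanceSimConfig(
        onset_jitter_sd=sigma_t,
        shared_timing_sd=0.0,
        pitch_jitter_sd=sigma_c,
        drift_slope=0.0,
        pitch_offset=0.0,
        gross_pitch_error_rate=0.0,
        gross_onset_error_rate=0.0,
        omission_rate=0.0,
    )
    a, b = sim.generate_unison_performance(score, cfg, rng=rng)
    for s_idx, stream in ((1, a), (2, b)):
        stream["singer"] = f"soprano_{s_idx}"
        stream["condition"] = "modern"
        stream["block"] = 0
        stream["repeat"] = 0
        stream["unit"] = "u"
    notes = pd.concat([a, b], ignore_index=True)
    table, _ = acc.accuracy_table(notes, score, level="piece")
    rec = table.iloc[0]
    # SE of the mean of |D| with D ~ N(0, 2 sigma^2):
    # Var|D| = 2 sigma^2 (1 - 2/pi)
    def se_absdiff(sigma, n):
        var = 2 * sigma**2 * (1 - 2 / np.pi)
        return np.sqrt(var / n)

    return {
        "MOE": float(rec["MOE"]),
        "MOE_expected": mean_abs_diff_expected(sigma_t),
        "MOE_se": se_absdiff(sigma_t, n_notes),
        "MAPE": float(rec["MAPE"]),
        "MAPE_expected": mean_abs_diff_expected(sigma_c),
        "MAPE_se": se_absdiff(sigma_c, n_notes),
        "n_notes": int(rec["n_pairs_timing"]),
    }


# ---------------------------------------------------------------------------
# coupling recovery


def aci_vs_kappa(
    kappas: np.ndarray | list[float] = (0.0, 0.1, 0.2, 0.4, 0.8),
    n_seeds: int = 30,
    duration: float = 180.0,
    n_singers: int = 2,
    seed: int = 0,
    spec: cpl.WaveletSpec = cpl.WaveletSpec(),
) -> pd.DataFrame:
    """Mean pairwise ACI as a function of Kuramoto coupling strength.

    Oscillators share the same base-frequency distribution; increasing the
    pairwise coupling must monotonically raise the mean ACI.  Returns one
    row per kappa with the mean over seeds, plus the Spearman correlation
    between kappa and the per-seed ACI means in ``DataFrame.attrs``.
    """
    rows = []
    for kap in kappas:
        vals = []
        for s in range(n_seeds):
            cfg = sim.RespirationSimConfig(
                n_singers=n_singers,
                duration=duration,
                coupling_strength=float(kap),
                base_frequency_sd=0.02,
            )
            traces = sim.generate_respiration_ensemble(
                cfg, rng=np.random.default_rng((seed * 100003 + s * 97 + int(kap * 1000)) % (2**31))
            )
            pw = cpl.pairwise_coupling(traces, spec, clip=None)
            vals.append(float(pw["ACI"].mean()))
        rows.append({"kappa": float(kap), "mean_ACI": float(np.mean(vals)), "sd_ACI": float(np.std(vals))})
    out = pd.DataFrame(rows)
    rho, p = sps.spearmanr(out["kappa"], out["mean_ACI"])
    out.attrs["spearman_rho"] = float(rho)
    out.attrs["spearman_p"] = float(p)
    return out


# ---------------------------------------------------------------------------
# null calibration of the condition contrast


def _tiny_perf_cfg() -> sim.PerformanceSimConfig:
    return sim.PerformanceSimConfig(
        gross_pitch_error_rate=0.0, gross_onset_error_rate=0.0, omission_rate=0.0
    )


def null_condition_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    design: StudyDesign | None = None,
    events_per_piece: int = 25,
    response: str = "LMOE",
) -> dict:
    """Type-I error of the condition tests under a null world.

    Each replicate simulates a small study with *no* condition effect, runs
    the accuracy cascade, and applies both the paired t-test (block x voice
    means) and the mixed-effects condition contrast.  Returns rejection
    rates, which should sit inside the binomial band around ``alpha``.
    """
    design = design or tiny_design(conditions=("touch", "no_touch"), blocks_per_unit=1)
    perf = _tiny_perf_cfg()
    reject_t = 0
    reject_lmm = 0
    for r in range(n_replicates):
        study = generate_perf_only_study(
            design, perf, seed=(seed * 1000003 + r) % (2**31), events_per_piece=events_per_piece
        )
        table, _ = acc.accuracy_table(study.notes, study.score, level="piece", design=design)
        tt = st.paired_ttest(table, response, conditions=design.conditions[:2])
        if tt.p < alpha:
            reject_t += 1
        lmm = st.fit_contrast_model(table, response, conditions=design.conditions[:2])
        if lmm.term("cond_c")["p"] < alpha:
            reject_lmm += 1
    return {
        "n_replicates": n_replicates,
        "paired_t_rejection_rate": reject_t / n_replicates,
        "contrast_rejection_rate": reject_lmm / n_replicates,
        "alpha": alpha,
    }


def generate_perf_only_study(
    design: StudyDesign,
    perf_cfg: sim.PerformanceSimConfig,
    seed: int,
    events_per_piece: int = 25,
    condition_effects: dict | None = None,
) -> sim.SyntheticStudy:
    """A study with note streams only (no respiration), for fast replicates."""
    from .design import enumerate_recordings

    score = sim.default_score(design, events_per_piece=events_per_piece, seed=seed)
    recs = enumerate_recordings(design)
    voice_recs = recs[recs["singer"].str.endswith("_1")]
    score_by = dict(tuple(score.groupby(["voice", "piece"], sort=False)))
    frames = []
    for row in voice_recs.itertuples(index=False):
        cfg = sim._condition_adjusted(
            perf_cfg, row.condition, condition_effects, ("onset_jitter_sd", "pitch_jitter_sd")
        )
        rng = sim._rng(seed, "perf", row.piece, row.voice, row.condition, row.repeat)
        a, b = sim.generate_unison_performance(score_by[(row.voice, row.piece)], cfg, rng=rng)
        for s_idx, stream in ((1, a), (2, b)):
            stream["singer"] = f"{row.voice}_{s_idx}"
            stream["condition"] = row.condition
            stream["block"] = row.block
            stream["unit"] = row.unit
            stream["repeat"] = row.repeat
            frames.append(stream)
    notes = pd.concat(frames, ignore_index=True)
    return sim.SyntheticStudy(design=design, score=score, notes=notes, respiration={})


# ---------------------------------------------------------------------------
# slope recovery in the prediction models


def simulate_unit_table(
    beta: float,
    rng: np.random.Generator,
    n_voices: int = 4,
    n_blocks: int = 8,
    conditions: tuple[str, ...] = ("modern", "touch", "no_touch"),
    index: str = "ACI",
    response: str = "LMOE",
    sd_voice: float = 0.25,
    sd_block: float = 0.15,
    sd_resid: float = 0.2,
    intercept: float = 2.9,
) -> pd.DataFrame:
    """A recording-unit-level analysis table with a known coupling slope.

    Coupling values are drawn per (voice x block x condition) cell; the
    response is ``intercept + beta * index + voice and block intercepts +
    noise`` — the generative counterpart of the prediction models.
    """
    voices = [f"v{i}" for i in range(n_voices)]
    u_voice = dict(zip(voices, rng.normal(0, sd_voice, n_voices)))
    u_block = dict(zip(range(n_blocks), rng.normal(0, sd_block, n_blocks)))
    rows = []
    for v in voices:
        for b in range(n_blocks):
            for c in conditions:
                x = float(np.clip(rng.normal(0.35, 0.08), 0.02, 0.98))
                y = intercept + beta * x + u_voice[v] + u_block[b] + rng.normal(0, sd_resid)
                rows.append({"voice": v, "block": b, "condition": c, index: x, response: y})
    return pd.DataFrame(rows)


def slope_recovery(
    beta: float = 1.5,
    n_replicates: int = 100,
    seed: int = 0,
    index: str = "ACI",
    response: str = "LMOE",
) -> dict:
    """Coverage of the true coupling slope and the size of the shuffled null.

    For each replicate a unit-level table with true slope ``beta`` is fitted
    with random intercepts for voice and block; coverage counts replicates
    whose 95% CI contains ``beta``.  A second fit on the same table with the
    coupling column permuted estimates the null rejection rate.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    null_sig = 0
    terms = (st.RandomTerm("voice"), st.RandomTerm("block"))
    for _ in range(n_replicates):
        tab = simulate_unit_table(beta, rng, index=index, response=response)
        fit = st.fit_mixed_model(tab, response, [index], terms, reml=True)
        s = fit.term(index)
        if s["ci_lo"] <= beta <= s["ci_hi"]:
            covered += 1
        shuffled = tab.copy()
        shuffled[index] = rng.permutation(shuffled[index].to_numpy())
        nfit = st.fit_mixed_model(shuffled, response, [index], terms, reml=True)
        if nfit.term(index)["p"] < 0.05:
            null_sig += 1
    return {
        "n_replicates": n_replicates,
        "beta_true": beta,
        "coverage": covered / n_replicates,
        "null_rejection_rate": null_sig / n_replicates,
    }
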