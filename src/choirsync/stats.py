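"""Statistical inference: condition contrasts and coupling -> accuracy models.

Two complementary routes test whether respiration coupling relates to
singing accuracy:

1. **Condition contrasts** — touch vs no-touch is known to shift
   respiration coupling, so an accuracy difference between those conditions
   is an indirect test.  A paired t-test (with Cohen's d) runs on block x
   voice means; a linear mixed model with a +/-0.5 contrast-coded condition
   and crossed random intercepts for voice and piece runs on the piece-level
   table.
2. **Direct prediction** — accuracy (LMOE or LMAPE) regressed on a coupling
   index (ACI/PSI/ICI) at the recording-unit level, with random intercepts
   (and optionally slopes) for voice, block and condition.  Starting from a
   rich random structure, terms are removed one at a time via
   likelihood-ratio tests until every remaining term earns its keep; the
   best model with the fewest parameters is reported with the full
   reduction trace.

Mixed models are fitted with crossed random effects expressed as
independent variance components (one component per grouping factor, plus
one per random slope; intercept-slope correlations are not modelled).
Fixed-effect p-values use the large-sample normal (Wald) reference, and the
``|t| > 2`` significance rule is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "PairedTTestResult",
    "RandomTerm",
    "FitResult",
    "ReductionStep",
    "paired_ttest",
    "fit_mixed_model",
    "fit_contrast_model",
    "fit_prediction_model",
    "report_tables",
    "LRT_ALPHA",
]

#: retention threshold for likelihood-ratio model reduction
LRT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# paired t-test with Cohen's d


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    df: int
    p: float
    d: float
    ci_d: tuple[float, float]
    n_pairs: int
    mean_diff: float


def paired_ttest(
    table: pd.DataFrame,
    value: str,
    conditions: tuple[str, str] = ("touch", "no_touch"),
    condition_col: str = "condition",
    unit_cols: tuple[str, ...] = ("block", "voice"),
) -> PairedTTestResult:
    """Two-sided paired t-test on per-(block x voice) condition means.

    ``table`` is a piece- or unit-level accuracy table; rows are averaged
    within each (block, voice, condition) cell first, then cells are paired
    across the two conditions.  Cohen's d for paired data is
    ``mean(diff)/sd(diff)`` with a noncentral-t 95% CI.
    """
    sub = table[table[condition_col].isin(conditions)]
    cells = (
        sub.groupby(list(unit_cols) + [condition_col], sort=False)[value]
        .mean()
        .unstack(condition_col)
    )
    missing = cells[cells[list(conditions)].isna().any(axis=1)]
    if len(missing):
        raise ValueError(f"unpaired cells:\n{missing.index.tolist()}")
    diff = (cells[conditions[0]] - cells[conditions[1]]).to_numpy()
    n = len(diff)
    sd = diff.std(ddof=1)
    if n < 2 or sd == 0:
        raise ValueError("degenerate paired sample: zero variance or fewer than 2 pairs")
    t, p = sps.ttest_rel(cells[conditions[0]], cells[conditions[1]])
    d = float(diff.mean() / sd)
    ci = _cohens_d_ci(d, n)
    return PairedTTestResult(
        t=float(t), df=n - 1, p=float(p), d=d, ci_d=ci, n_pairs=n, mean_diff=float(diff.mean())
    )


def _cohens_d_ci(d: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Noncentral-t confidence interval for a paired-samples Cohen's d."""
    import pingouin as pg

    lo, hi = pg.compute_esci(
        stat=d, nx=n, ny=n, paired=True, eftype="cohen", confidence=confidence, decimals=6
    )
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# mixed models with crossed random effects


@dataclass(frozen=True)
class RandomTerm:
    """One random-effects term: intercept and/or slope for a grouping factor."""

    group: str
    intercept: bool = True
    slope: str | None = None

    def label(self) -> str:
        inner = "1" if self.intercept else "0"
        if self.slope:
            inner += f" + {self.slope}"
        return f"({inner}|{self.group})"

    def vc_entries(self) -> dict[str, str]:
        out = {}
        if self.intercept:
            out[self.group] = f"0 + C({self.group})"
        if self.slope:
            out[f"{self.group}_x_{self.slope}"] = f"0 + C({self.group}):{self.slope}"
        return out

    def n_params(self) -> int:
        return int(self.intercept) + int(self.slope is not None)


@dataclass
class ReductionStep:
    removed: str
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    reason: str  # "lrt" | "singular" | "nonconvergent"


@dataclass
class FitResult:
    formula: str
    fixed: pd.DataFrame  # index: term; columns beta, se, ci_lo, ci_hi, t, p, significant_t2
    converged: bool
    singular: bool
    llf: float
    n_obs: int
    n_random_params: int
    random_terms: tuple[RandomTerm, ...] = ()
    reduction_trace: list[ReductionStep] = field(default_factory=list)
    variance_components: dict[str, float] = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        return self.fixed.loc[name]


def _formula_string(response: str, fixed: list[str], terms: tuple[RandomTerm, ...]) -> str:
    rhs = " + ".join(fixed + [t.label() for t in terms]) or "1"
    return f"{response} ~ {rhs}"


def fit_mixed_model(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    random_terms: tuple[RandomTerm, ...],
    reml: bool = True,
) -> FitResult:
    """Fit a linear mixed model with crossed random effects.

    Each ``RandomTerm`` becomes one (or two, with a slope) independent
    variance components over a single all-encompassing group, which
    implements crossed random intercepts/slopes without intercept-slope
    correlations.  Non-convergence and singularity (a variance component
    estimated at ~0) are recorded as flags, never raised.
    """
    df = data.dropna(subset=[response] + [f for f in fixed if f in data.columns]).copy()
    if df[response].std(ddof=0) == 0:
        raise ValueError(f"response {response!r} has zero variance")
    fixed_rhs = " + ".join(fixed) if fixed else "1"
    vc: dict[str, str] = {}
    for t in random_terms:
        vc.update(t.vc_entries())
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if vc:
                model = smf.mixedlm(
                    f"{response} ~ {fixed_rhs}",
                    df,
                    groups=np.ones(len(df)),
                    vc_formula=vc,
                )
                fit = model.fit(reml=reml, method=["lbfgs", "powell"])
                converged = bool(fit.converged)
                vcomp = dict(zip(model.exog_vc.names, np.asarray(fit.vcomp, dtype=float)))
            else:  # pure fixed-effects fallback: OLS
                fit = smf.ols(f"{response} ~ {fixed_rhs}", df).fit()
                vcomp = {}
        except (np.linalg.LinAlgError, ValueError) as err:
            empty = pd.DataFrame(
                np.nan,
                index=["Intercept"] + fixed,
                columns=["beta", "se", "ci_lo", "ci_hi", "t", "p", "significant_t2"],
            )
            return FitResult(
                formula=_formula_string(response, fixed, random_terms),
                fixed=empty,
                converged=False,
                singular=True,
                llf=-np.inf,
                n_obs=len(df),
                n_random_params=sum(t.n_params() for t in random_terms),
                random_terms=random_terms,
            )
    names = ["Intercept"] + fixed
    params = fit.params
    bse = fit.bse
    # t reference with residual-style degrees of freedom (observations minus
    # fixed-effect and variance parameters) — a coarse stand-in for a
    # Satterthwaite approximation; indistinguishable from the normal
    # reference at hundreds of observations but meaningfully less
    # anticonservative on small tables
    ddf = max(len(df) - len(names) - len(vc), 1)
    tcrit = float(sps.t.ppf(0.975, ddf))
    rows = {}
    for name in names:
        beta = float(params[name])
        se = float(bse[name])
        z = beta / se if se > 0 else np.nan
        rows[name] = {
            "beta": beta,
            "se": se,
            "ci_lo": beta - tcrit * se,
            "ci_hi": beta + tcrit * se,
            "t": z,
            "p": float(2 * sps.t.sf(abs(z), ddf)) if np.isfinite(z) else np.nan,
            "significant_t2": bool(abs(z) > 2) if np.isfinite(z) else False,
        }
    tab = pd.DataFrame(rows).T[["beta", "se", "ci_lo", "ci_hi", "t", "p", "significant_t2"]]
    # a variance component that collapses to a sliver of the residual
    # variance marks a singular (boundary) fit, as lme4's isSingular does
    resid_var = float(getattr(fit, "scale", np.nan))
    singular = any(
        v <= 1e-2 * max(resid_var, 1e-12) for v in (vcomp.values() if vcomp else [])
    )
    return FitResult(
        formula=_formula_string(response, fixed, random_terms),
        fixed=tab,
        converged=converged,
        singular=bool(singular),
        llf=float(fit.llf),
        n_obs=len(df),
        n_random_params=sum(t.n_params() for t in random_terms),
        random_terms=random_terms,
        variance_components=vcomp,
    )


# ---------------------------------------------------------------------------
# condition-contrast model


def fit_contrast_model(
    table: pd.DataFrame,
    response: str,
    conditions: tuple[str, str] = ("touch", "no_touch"),
    condition_col: str = "condition",
) -> FitResult:
    """Accuracy ~ condition contrast + (1|voice) + (1|piece) on piece-level rows.

    The two conditions are coded +0.5 (first) and -0.5 (second), so the
    reported beta is the first-minus-second difference.
    """
    sub = table[table[condition_col].isin(conditions)].copy()
    code = {conditions[0]: 0.5, conditions[1]: -0.5}
    sub["cond_c"] = sub[condition_col].map(code)
    terms = (RandomTerm("voice"), RandomTerm("piece"))
    res = fit_mixed_model(sub, response, ["cond_c"], terms, reml=True)
    return res


# ---------------------------------------------------------------------------
# prediction models with likelihood-ratio reduction


def _start_terms(response: str, index: str) -> tuple[RandomTerm, ...]:
    """Starting random structures for the coupling -> accuracy models.

    Timing starts from ``(1|voice) + (1+idx|block) + (1+idx|condition)``,
    intonation from ``(1+idx|voice) + (1+idx|block) + (1|condition)`` —
    the richest structures that fit at all on 96 observations.
    """
    if response == "LMOE":
        return (
            RandomTerm("voice"),
            RandomTerm("block", slope=index),
            RandomTerm("condition", slope=index),
        )
    return (
        RandomTerm("voice", slope=index),
        RandomTerm("block", slope=index),
        RandomTerm("condition"),
    )


def _reductions(terms: tuple[RandomTerm, ...]) -> list[tuple[RandomTerm, ...]]:
    """All structures with exactly one component removed (slopes before intercepts)."""
    out = []
    for i, t in enumerate(terms):
        if t.slope is not None:
            reduced = terms[:i] + (RandomTerm(t.group, t.intercept, None),) + terms[i + 1 :]
            out.append((f"slope {t.slope}|{t.group}", reduced))
    for i, t in enumerate(terms):
        if t.slope is None and t.intercept:
            reduced = terms[:i] + terms[i + 1 :]
            out.append((f"intercept 1|{t.group}", reduced))
    return out


def fit_prediction_model(
    table: pd.DataFrame,
    response: str,
    index: str,
    start_terms: tuple[RandomTerm, ...] | None = None,
    alpha: float = LRT_ALPHA,
) -> FitResult:
    """Predict accuracy from a coupling index, reducing the random structure.

    Greedy backward selection: at each step, each candidate with one
    variance component removed is compared to the current model by a
    likelihood-ratio test (ML fits).  The removal with the largest p >= alpha
    is accepted; singular or non-convergent current fits force a removal
    regardless.  The final structure is refit by REML for reporting.
    """
    terms = start_terms if start_terms is not None else _start_terms(response, index)
    current = fit_mixed_model(table, response, [index], terms, reml=False)
    trace: list[ReductionStep] = []
    while terms:
        candidates = _reductions(terms)
        if not candidates:
            break
        best: tuple[float, str, tuple[RandomTerm, ...], FitResult] | None = None
        for label, reduced_terms in candidates:
            red = fit_mixed_model(table, response, [index], reduced_terms, reml=False)
            if not np.isfinite(red.llf):
                continue
            stat = max(0.0, 2.0 * (current.llf - red.llf))
            ddf = current.n_random_params - red.n_random_params
            p = float(sps.chi2.sf(stat, ddf)) if np.isfinite(current.llf) else 1.0
            if best is None or p > best[0]:
                best = (p, label, reduced_terms, red)
        if best is None:
            break
        p, label, reduced_terms, red = best
        degenerate = current.singular or not current.converged
        if p >= alpha or degenerate:
            reason = "lrt" if p >= alpha else ("singular" if current.singular else "nonconvergent")
            stat = max(0.0, 2.0 * (current.llf - red.llf))
            trace.append(
                ReductionStep(
                    removed=label,
                    lrt_stat=stat,
                    lrt_df=current.n_random_params - red.n_random_params,
                    lrt_p=p,
                    reason=reason,
                )
            )
            terms, current = reduced_terms, red
        else:
            break
    final = fit_mixed_model(table, response, [index], terms, reml=True)
    final.reduction_trace = trace
    return final


# ---------------------------------------------------------------------------
# reporting


def report_tables(fits: dict[str, FitResult], term_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Flatten fit results into one row per model for CSV/JSON export.

    ``term_of`` maps a fit label to the fixed term to report (default: the
    first non-intercept term, or the intercept if none).
    """
    rows = []
    for label, fit in fits.items():
        terms = [t for t in fit.fixed.index if t != "Intercept"]
        term = (term_of or {}).get(label, terms[0] if terms else "Intercept")
        s = fit.fixed.loc[term]
        rows.append(
            {
                "model": label,
                "formula": fit.formula,
                "term": term,
                "beta": s["beta"],
                "se": s["se"],
                "ci_lo": s["ci_lo"],
                "ci_hi": s["ci_hi"],
                "t": s["t"],
                "p": s["p"],
                "significant_t2": s["significant_t2"],
                "converged": fit.converged,
                "singular": fit.singular,
                "n_obs": fit.n_obs,
            }
        )
    return pd.DataFrame(rows)
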