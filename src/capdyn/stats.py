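"""Inferential layer: within-subject ANOVA, Bonferroni-corrected paired
tests, the anticorrelation mixed model, and Steiger's test for dependent
overlapping correlations."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

log = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_sq_partial: float


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    p_corrected: float
    cohen_d: float
    n: int
    n_dropped: int = 0


@dataclass
class LmmResult:
    fixed_effects: pd.Series
    pvalues: pd.Series
    var_subject: float
    var_residual: float
    r2_marginal: float
    r2_conditional: float
    converged: bool


@dataclass
class CorrelationComparison:
    r1: float
    r2: float
    r_y1y2: float
    n: int
    z: float
    p: float
    sided: str


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (balanced within-subject partitioning)
# ---------------------------------------------------------------------------

def _cell_means(df: pd.DataFrame, dv: str, by: list[str]) -> pd.Series:
    return df.groupby(by, observed=True)[dv].mean()


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject",
    covariates: list[str] | None = None,
) -> list[AnovaResult]:
    """Classical repeated-measures ANOVA with one or two within-subject factors.

    Requires a complete balanced design (each subject observed exactly once
    per factor cell); missing cells raise with the offending (subject, cell)
    pairs listed.  Each within effect is tested against its effect × subject
    interaction, the standard univariate partitioning; for a 2-level factor
    this F equals the squared paired t on the same data.  Partial eta squared
    is SS_effect / (SS_effect + SS_error), which satisfies
    η² = F·df1 / (F·df1 + df2).

    Between-subject covariates (age, sex) only adjust the between-subject
    stratum, which does not enter any within-subject F on balanced data; they
    are accepted for interface completeness and recorded in the log.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("rm_anova supports 1 or 2 within-subject factors")
    df = table.copy()
    levels = {f: sorted(df[f].unique()) for f in within}
    subjects = sorted(df[subject].unique())

    counts = df.groupby([subject, *within], observed=True).size()
    expected = len(subjects) * int(np.prod([len(v) for v in levels.values()]))
    if (counts != 1).any() or len(counts) != expected:
        missing = []
        full = pd.MultiIndex.from_product(
            [subjects, *levels.values()], names=[subject, *within]
        )
        for key in full.difference(counts[counts == 1].index):
            missing.append(key)
        raise ValueError(f"incomplete within-subject design; missing/duplicated cells: {missing[:10]}")
    if covariates:
        log.info("covariates %s adjust the between-subject stratum only", covariates)

    y = df[dv].astype(float)
    grand = y.mean()
    n = len(subjects)
    m_s = _cell_means(df, dv, [subject])

    results: list[AnovaResult] = []

    if len(within) == 1:
        a_f = within[0]
        a = len(levels[a_f])
        m_a = _cell_means(df, dv, [a_f])
        ss_a = n * ((m_a - grand) ** 2).sum()
        resid = (
            y
            - df[a_f].map(m_a).astype(float)
            - df[subject].map(m_s).astype(float)
            + grand
        )
        ss_err = (resid ** 2).sum()
        results.append(_f_test(a_f, ss_a, a - 1, ss_err, (a - 1) * (n - 1)))
        return results

    a_f, b_f = within
    a, b = len(levels[a_f]), len(levels[b_f])
    m_a = _cell_means(df, dv, [a_f])
    m_b = _cell_means(df, dv, [b_f])
    m_ab = _cell_means(df, dv, [a_f, b_f])
    m_as = _cell_means(df, dv, [a_f, subject])
    m_bs = _cell_means(df, dv, [b_f, subject])

    c_a = df.groupby(a_f, observed=True)[dv].transform("mean")
    c_b = df.groupby(b_f, observed=True)[dv].transform("mean")
    c_s = df.groupby(subject, observed=True)[dv].transform("mean")
    c_ab = df.groupby([a_f, b_f], observed=True)[dv].transform("mean")
    c_as = df.groupby([a_f, subject], observed=True)[dv].transform("mean")
    c_bs = df.groupby([b_f, subject], observed=True)[dv].transform("mean")

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_ab.groupby(level=0).transform("mean")
                  - m_ab.groupby(level=1).transform("mean") + grand) ** 2).sum()
    ss_as = b * (((m_as.to_frame("m").reset_index()
                   .assign(e=lambda d: d["m"]
                           - d[a_f].map(m_a)
                           - d[subject].map(m_s) + grand))["e"] ** 2).sum())
    ss_bs = a * (((m_bs.to_frame("m").reset_index()
                   .assign(e=lambda d: d["m"]
                           - d[b_f].map(m_b)
                           - d[subject].map(m_s) + grand))["e"] ** 2).sum())
    resid = y - c_ab - c_as - c_bs + c_a + c_b + c_s - grand
    ss_abs = (resid ** 2).sum()

    specs = [
        (a_f, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (b_f, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{a_f}:{b_f}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]
    for name, ss_e, df1, ss_err, df2 in specs:
        results.append(_f_test(name, ss_e, df1, ss_err, df2))
    return results


def _f_test(name: str, ss_e: float, df1: int, ss_err: float, df2: int) -> AnovaResult:
    # an effect whose SS and error SS both vanish (a dv constrained to a
    # constant within the stratum, e.g. total time summed over states) is
    # reported as a null effect rather than 0/0
    if ss_err <= 1e-12 * max(1.0, abs(ss_e)):
        if ss_e <= 1e-12:
            log.info("effect %s has no variance in its stratum; F set to 0", name)
            return AnovaResult(name, 0.0, df1, df2, 1.0, 0.0)
        return AnovaResult(name, float("inf"), df1, df2, 0.0, 1.0)
    f = (ss_e / df1) / (ss_err / df2)
    return AnovaResult(
        name, float(f), df1, df2, float(sstats.f.sf(f, df1, df2)),
        float(ss_e / (ss_e + ss_err)),
    )


# ---------------------------------------------------------------------------
# paired contrasts
# ---------------------------------------------------------------------------

def paired_t(
    a: np.ndarray, b: np.ndarray, m_comparisons: int = 1
) -> TTestResult:
    """Paired t with Bonferroni correction and the d_z effect size.

    NaN pairs (e.g. a state never visited for one subject) are dropped
    pairwise and the dropped count reported.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("paired_t: dropped %d incomplete pair(s)", n_dropped)
    d = a[ok] - b[ok]
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: zero variance of differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sstats.t.sf(abs(t), df=n - 1)
    return TTestResult(
        t=float(t), df=n - 1, p=float(p),
        p_corrected=float(min(1.0, p * m_comparisons)),
        cohen_d=float(d.mean() / sd), n=n, n_dropped=n_dropped,
    )


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison alpha under Bonferroni: family_alpha / m."""
    if not 0 < family_alpha <= 1:
        raise ValueError("family_alpha must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


# ---------------------------------------------------------------------------
# mixed model for the anticorrelation analysis
# ---------------------------------------------------------------------------

def lmm_anticorr(
    table: pd.DataFrame,
    dv: str = "anticorr_z",
    time: str = "time_in_state_s",
    subject: str = "subject",
    drug: str = "condition",
    age: str = "age",
    sex: str = "sex",
) -> LmmResult:
    """Random-intercept model of anticorrelation on combined time-in-state.

    Fixed effects: centered time in state, centered age, sex, drug, and the
    drug × time interaction; random intercept per subject.  Marginal R² is
    the fixed-effect variance share, conditional R² adds the subject
    intercept variance (Nakagawa-style decomposition).
    """
    import statsmodels.formula.api as smf

    df = table.copy()
    counts = df.groupby(subject).size()
    if (counts < 2).any():
        raise ValueError("need >= 2 observations per subject")
    df["_time_c"] = df[time] - df[time].mean()
    df["_age_c"] = df[age] - df[age].mean()
    formula = f"{dv} ~ _time_c + _age_c + C({sex}) + C({drug}) + C({drug}):_time_c"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(formula, df, groups=df[subject]).fit(reml=True)
    var_subject = float(max(0.0, np.asarray(fit.cov_re)[0, 0]))
    var_resid = float(fit.scale)
    if not fit.converged or np.asarray(fit.cov_re)[0, 0] <= 0:
        log.warning("mixed model near-singular fit; subject variance pinned at %.3g",
                    var_subject)
    fe = fit.fe_params
    design = fit.model.exog
    var_fixed = float(np.var(design @ fe.to_numpy()))
    total = var_fixed + var_subject + var_resid
    return LmmResult(
        fixed_effects=fe,
        pvalues=fit.pvalues.reindex(fe.index),
        var_subject=var_subject,
        var_residual=var_resid,
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + var_subject) / total,
        converged=bool(fit.converged),
    )


# ---------------------------------------------------------------------------
# dependent overlapping correlations
# ---------------------------------------------------------------------------

def steiger_z(
    r1: float, r2: float, r_y1y2: float, n: int, sided: str = "one"
) -> CorrelationComparison:
    """Steiger's z for two dependent correlations sharing one variable.

    r1 = cor(x, y1) and r2 = cor(x, y2) are compared given r_y1y2 = cor(y1, y2),
    using the pooled-correlation covariance term:

        r̄ = (r1 + r2)/2
        s  = [r_y1y2(1 − 2r̄²) − ½·r̄²(1 − 2r̄² − r_y1y2²)] / (1 − r̄²)²
        z  = (atanh r1 − atanh r2) · √((n − 3) / (2(1 − s)))

    One-sided p tests r1 > r2; the statistic is antisymmetric in (r1, r2).
    """
    for name, r in (("r1", r1), ("r2", r2)):
        if not abs(r) < 1:
            raise ValueError(f"|{name}| must be < 1")
    if not abs(r_y1y2) <= 1:
        raise ValueError("|r_y1y2| must be <= 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    rbar = (r1 + r2) / 2.0
    s = (r_y1y2 * (1 - 2 * rbar ** 2)
         - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r_y1y2 ** 2)) / (1 - rbar ** 2) ** 2
    dz = np.arctanh(r1) - np.arctanh(r2)
    if dz == 0 or s >= 1:
        # y1 ≡ y2 (or perfectly coupled): no information to separate the
        # correlations beyond their point difference
        z = 0.0 if dz == 0 else np.sign(dz) * np.inf
    else:
        z = dz * np.sqrt((n - 3) / (2.0 * (1.0 - s)))
    if sided == "one":
        p = float(sstats.norm.sf(z))
    elif sided == "two":
        p = float(2 * sstats.norm.sf(abs(z)))
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return CorrelationComparison(r1, r2, r_y1y2, n, float(z), p, sided)
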