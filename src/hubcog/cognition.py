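"""Neuropsychological scores: normative w-scores, domains, impairment.

Raw test scores are transformed into w-scores — z-like scores adjusted for
age and education by an ordinary-least-squares normative model fitted on the
healthy controls: ``w = (observed - predicted) / SD(control residuals)``.
w-scores of time-critical tests are then multiplied by -1 so that a higher
w-score always means better performance.  Test-level w-scores are averaged
into six cognitive domains, and a subject is classified as cognitively
impaired (ICCTF rule) when at least two tests fall at or below w = -1.5 or at
least one test at or below w = -2.0.

Education enters the normative model as a single ordinal numeric covariate
(Verhage 1-7) by default; categorical dummy coding is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DOMAINS = (
    "memory",
    "executive",
    "attention_processing_speed",
    "motor",
    "proxy_IQ",
    "language",
)

HIGHER_BETTER = "higher_better"
TIME_LOWER_BETTER = "time_lower_better"


@dataclass(frozen=True)
class TestSpec:
    test_id: str
    name: str
    domain: str
    direction: str = HIGHER_BETTER

    @property
    def inverted(self) -> bool:
        return self.direction == TIME_LOWER_BETTER


#: the default 17-outcome battery: HVLT-R, TMT, SCWT, WAIS-IV subtests,
#: COWAT and Grooved Pegboard, grouped into six domains.
DEFAULT_BATTERY: tuple[TestSpec, ...] = (
    TestSpec("hvlt_immediate", "HVLT-R immediate recall", "memory"),
    TestSpec("hvlt_delayed", "HVLT-R delayed recall", "memory"),
    TestSpec("hvlt_recognition", "HVLT-R recognition", "memory"),
    TestSpec("tmt_b", "TMT B", "executive", TIME_LOWER_BETTER),
    TestSpec("scwt_interference", "SCWT interference", "executive"),
    TestSpec("digit_span_backwards", "WAIS IV digit span backwards", "executive"),
    TestSpec("wais_sequencing", "WAIS IV sequencing", "executive"),
    TestSpec("symbol_substitution", "WAIS IV symbol substitution",
             "attention_processing_speed"),
    TestSpec("tmt_a", "TMT A", "attention_processing_speed", TIME_LOWER_BETTER),
    TestSpec("scwt_colors", "SCWT colors", "attention_processing_speed",
             TIME_LOWER_BETTER),
    TestSpec("scwt_words", "SCWT words", "attention_processing_speed",
             TIME_LOWER_BETTER),
    TestSpec("digit_span_forward", "WAIS IV digit span forward",
             "attention_processing_speed"),
    TestSpec("pegboard_dominant", "Grooved pegboard dominant hand", "motor",
             TIME_LOWER_BETTER),
    TestSpec("pegboard_nondominant", "Grooved pegboard non-dominant hand",
             "motor", TIME_LOWER_BETTER),
    TestSpec("matrix_reasoning", "WAIS IV matrix reasoning", "proxy_IQ"),
    TestSpec("cowat_semantic", "COWAT semantic", "language"),
    TestSpec("cowat_phonemic", "COWAT phonemic", "language"),
)


def battery_by_id(battery=DEFAULT_BATTERY) -> dict[str, TestSpec]:
    return {t.test_id: t for t in battery}


@dataclass
class NormativeModel:
    """Per-test OLS fit (intercept, age, education) on healthy controls."""

    coefficients: dict[str, np.ndarray]  # test_id -> [intercept, b_age, b_edu...]
    residual_sd: dict[str, float]
    n_controls: int
    education_coding: str = "ordinal"  # or "categorical"
    education_levels: tuple[int, ...] = ()

    def design(self, meta: pd.DataFrame) -> np.ndarray:
        age = meta["age"].to_numpy(float)
        edu = meta["education"].to_numpy(float)
        if self.education_coding == "ordinal":
            return np.column_stack([np.ones(len(meta)), age, edu])
        cols = [np.ones(len(meta)), age]
        for lev in self.education_levels[1:]:
            cols.append((edu == lev).astype(float))
        return np.column_stack(cols)

    def predict(self, test_id: str, meta: pd.DataFrame) -> np.ndarray:
        return self.design(meta) @ self.coefficients[test_id]


def fit_normative_model(
    controls: pd.DataFrame,
    battery=DEFAULT_BATTERY,
    education_coding: str = "ordinal",
) -> NormativeModel:
    """Fit the per-test normative regressions on control data.

    ``controls`` must carry one row per control with ``age``, ``education``
    and one column per test id.  Residual SD uses denominator n - p.
    """
    test_ids = [t.test_id for t in battery]
    missing = [t for t in test_ids if t not in controls.columns]
    if missing:
        raise KeyError(f"control table lacks test columns {missing}")
    meta = controls[["age", "education"]].astype(float)
    if meta.isna().any().any():
        raise ValueError("controls with missing age/education")
    levels = tuple(sorted(controls["education"].unique().astype(int)))
    model = NormativeModel(
        {}, {}, n_controls=len(controls),
        education_coding=education_coding, education_levels=levels,
    )
    X = model.design(controls)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} controls, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient normative design (constant covariate?)")
    import statsmodels.api as sm

    for tid in test_ids:
        y = controls[tid].to_numpy(float)
        fit = sm.OLS(y, X).fit()
        beta = fit.params
        resid = fit.resid
        sd = float(np.sqrt((resid @ resid) / (n - p)))
        if sd <= 1e-10 * max(1.0, float(np.abs(y).mean())):
            raise ValueError(f"degenerate residual scale for test {tid!r}")
        model.coefficients[tid] = beta
        model.residual_sd[tid] = sd
    return model


def compute_wscores(
    raw: pd.DataFrame, model: NormativeModel, battery=DEFAULT_BATTERY
) -> pd.DataFrame:
    """Per-test w-scores: (observed - predicted) / residual SD, then sign-
    inverted for time-critical tests.  Missing covariates give missing w."""
    have_cov = raw[["age", "education"]].notna().all(axis=1)
    if not have_cov.all():
        log.warning("%d subject(s) lack covariates; w set missing",
                    int((~have_cov).sum()))
    out = pd.DataFrame(index=raw.index)
    for t in battery:
        pred = model.predict(t.test_id, raw.fillna({"age": 0, "education": 0}))
        w = (raw[t.test_id].to_numpy(float) - pred) / model.residual_sd[t.test_id]
        if t.inverted:
            w = -w
        w[~have_cov.to_numpy()] = np.nan
        out[t.test_id] = w
    return out


def domain_scores(w: pd.DataFrame, battery=DEFAULT_BATTERY) -> pd.DataFrame:
    """Unweighted mean of available test w-scores per domain."""
    out = pd.DataFrame(index=w.index)
    for dom in DOMAINS:
        tests = [t.test_id for t in battery if t.domain == dom]
        block = w[tests]
        n_miss = int(block.isna().any(axis=1).sum())
        if n_miss:
            log.info("domain %s: averaging over available tests for %d subject(s)",
                     dom, n_miss)
        out[dom] = block.mean(axis=1, skipna=True)
    return out


def classify_impairment(w_tests: np.ndarray | pd.Series) -> bool:
    """ICCTF criterion: >= 2 tests at w <= -1.5, or >= 1 test at w <= -2.0."""
    w = np.asarray(w_tests, dtype=float)
    w = w[np.isfinite(w)]
    if w.size == 0:
        raise ValueError("no test-level w-scores available")
    return bool((w <= -1.5).sum() >= 2 or (w <= -2.0).sum() >= 1)


def impairment_table(w: pd.DataFrame, battery=DEFAULT_BATTERY) -> pd.Series:
    test_ids = [t.test_id for t in battery]
    return w[test_ids].apply(classify_impairment, axis=1)


def group_domain_comparison(
    patients: pd.DataFrame, controls: pd.DataFrame, bonferroni: int = len(DOMAINS)
) -> pd.DataFrame:
    """Per-domain two-sided Mann-Whitney U (patients vs controls).

    U is reported for the patient sample (number of (patient, control) pairs
    with patient > control, ties counting 1/2).  Exact enumeration when both
    group sizes are <= 10, tie-corrected normal approximation otherwise.
    Bonferroni divisor: the six domains.
    """
    rows = []
    for dom in patients.columns:
        x = patients[dom].dropna().to_numpy()
        y = controls[dom].dropna().to_numpy()
        method = "exact" if (len(x) <= 10 and len(y) <= 10
                             and not _has_ties(x, y)) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(dict(domain=dom, U=float(res.statistic), p=float(res.pvalue),
                         p_bonf=min(float(res.pvalue) * bonferroni, 1.0),
                         n_patients=len(x), n_controls=len(y), method=method))
    return pd.DataFrame(rows)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    z = np.concatenate([x, y])
    return len(np.unique(z)) < len(z)
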