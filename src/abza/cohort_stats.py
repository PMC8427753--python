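"""Prognostic statistics for ABZA-graded stroke cohorts.

Implements the analysis pipeline applied to the 108-patient endovascular
treatment cohort: univariate comparisons between favorable (90-day mRS ≤ 2)
and unfavorable outcome groups, enter-method logistic regression with the
collateral score as a dichotomized covariate, ROC analysis with the Youden
optimal cutoff, 2×2 diagnostic metrics, r×c contingency analyses, and
inter-rater reliability of the angle and grade.

Standard tests are delegated to scipy/statsmodels/sklearn/pingouin; the
DeLong AUC variance is computed here because no installed package exposes
it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from .errors import ConstantScoreWarning, DegenerateTestError, SeparationError
from .grading import GradingScheme

__all__ = [
    "TwoByTwo",
    "ConfusionMetrics",
    "confusion_metrics",
    "UnivariateResult",
    "univariate_compare",
    "TermResult",
    "LogisticModelResult",
    "fit_logistic",
    "ROCResult",
    "roc_analysis",
    "delong_auc_variance",
    "ContingencyResult",
    "contingency_analysis",
    "interrater_reliability",
    "ReproCheck",
    "reproduce_printed_tables",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching hand-rounded percentages
    (e.g. 9/72 = 12.5% printed as 13%)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# 2x2 diagnostic metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwo:
    """2×2 diagnostic table.

    Positive test = good collaterals (grade > 2); positive state =
    favorable outcome (mRS ≤ 2).  ``tp`` are good-collateral patients with
    a favorable outcome, ``tn`` poor-collateral patients with an
    unfavorable one.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fn, self.fp, self.tn)
        if any(c < 0 for c in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Sensitivity/specificity/Youden/odds-ratio with explicit undefined flags."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    youden: Optional[float]
    odds_ratio: Optional[float]
    undefined: Tuple[str, ...] = ()


def confusion_metrics(table: TwoByTwo) -> ConfusionMetrics:
    """Diagnostic accuracy of the dichotomized score.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), Youden = sens +
    spec − 1, odds ratio = (tp·tn)/(fp·fn).  A metric whose denominator is
    zero is reported as None and named in ``undefined`` rather than as a
    silent NaN.
    """
    undefined: List[str] = []
    sens = spec = youden = oratio = None
    if table.tp + table.fn > 0:
        sens = table.tp / (table.tp + table.fn)
    else:
        undefined.append("sensitivity")
    if table.tn + table.fp > 0:
        spec = table.tn / (table.tn + table.fp)
    else:
        undefined.append("specificity")
    if sens is not None and spec is not None:
        youden = sens + spec - 1.0
    else:
        undefined.append("youden")
    if table.fp > 0 and table.fn > 0:
        oratio = (table.tp * table.tn) / (table.fp * table.fn)
    else:
        undefined.append("odds_ratio")
    return ConfusionMetrics(sens, spec, youden, oratio, tuple(undefined))


# ---------------------------------------------------------------------------
# univariate comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    test_name: str
    statistic: float
    p: float
    n_excluded: int = 0


def _expected_counts(table: np.ndarray) -> np.ndarray:
    total = table.sum()
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / total


def univariate_compare(
    cohort: pd.DataFrame,
    variable: str,
    outcome: str = "mrs_90",
    favorable_cutoff: int = 2,
    kind: str = "auto",
) -> UnivariateResult:
    """Compare one baseline variable between outcome groups.

    Continuous variables are screened for normality (Shapiro–Wilk at 0.05
    in each group) and routed to the two-sample t-test or the Mann–Whitney
    U; categorical variables get a Pearson chi-square, switching to
    Fisher's exact when any expected count of a 2×2 table is below 5.
    Missing values are dropped complete-case, with the exclusion count
    reported.
    """
    df = cohort[[variable, outcome]].dropna()
    n_excluded = len(cohort) - len(df)
    fav = df[outcome] <= favorable_cutoff
    x = df[variable]

    if kind == "auto":
        if x.dtype == bool or x.dtype == object or str(x.dtype) == "category":
            kind = "categorical"
        elif x.nunique() <= 2:
            kind = "categorical"
        else:
            kind = "continuous"

    groups = [x[fav], x[~fav]]
    if any(len(g) < 2 for g in groups):
        raise DegenerateTestError(
            f"{variable}: fewer than 2 observations in an outcome group"
        )

    if kind == "continuous":
        if x.nunique() == 1:
            raise DegenerateTestError(f"{variable}: constant variable")
        normal = all(
            st.shapiro(np.asarray(g, dtype=float)).pvalue > 0.05 for g in groups
        )
        if normal:
            res = st.ttest_ind(groups[0], groups[1])
            return UnivariateResult(variable, "t_test", float(res.statistic),
                                    float(res.pvalue), n_excluded)
        res = st.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return UnivariateResult(variable, "mann_whitney_u", float(res.statistic),
                                float(res.pvalue), n_excluded)

    table = pd.crosstab(fav, x).to_numpy(dtype=float)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTestError(f"{variable}: constant variable")
    if table.shape == (2, 2) and (_expected_counts(table) < 5).any():
        res = st.fisher_exact(table)
        return UnivariateResult(variable, "fisher_exact", float(res[0]),
                                float(res[1]), n_excluded)
    chi2, p, _, _ = st.chi2_contingency(table, correction=False)
    return UnivariateResult(variable, "chi_square", float(chi2), float(p),
                            n_excluded)


# ---------------------------------------------------------------------------
# logistic regression (enter method)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermResult:
    name: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class LogisticModelResult:
    label: str
    terms: Tuple[TermResult, ...]
    auc: float
    auc_ci: Tuple[float, float]
    n: int
    factor_pvalues: Dict[str, float] = field(default_factory=dict)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


_FACTOR_REFERENCE = {"toast": "LAA"}


def _design_matrix(
    cohort: pd.DataFrame, covariates: Sequence[str]
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Numeric design matrix; multi-level factors become reference-coded
    dummies (TOAST reference level LAA)."""
    cols: Dict[str, np.ndarray] = {}
    factors: Dict[str, List[str]] = {}
    for cov in covariates:
        x = cohort[cov]
        if x.dtype == object or str(x.dtype) == "category":
            levels = sorted(x.dropna().unique().tolist())
            ref = _FACTOR_REFERENCE.get(cov, levels[0])
            dummy_names = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{cov}[{lev}]"
                cols[name] = (x == lev).to_numpy(dtype=float)
                dummy_names.append(name)
            factors[cov] = dummy_names
        else:
            cols[cov] = x.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cohort.index), factors


def fit_logistic(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    outcome: str = "mrs_90",
    favorable_cutoff: int = 2,
    model_label: str = "Model 1",
) -> LogisticModelResult:
    """Enter-method maximum-likelihood logistic fit of the favorable-outcome
    indicator on all listed covariates simultaneously.

    Reports exp(coef) per covariate with Wald 95% CIs and Wald p-values, a
    pooled likelihood-ratio p for each multi-level factor, and the model
    AUC (with DeLong CI) computed from the fitted probabilities.

    Raises :class:`SeparationError` on a single-class outcome, detected
    complete/quasi-separation, or non-convergence.
    """
    cols = list(dict.fromkeys(list(covariates) + [outcome]))
    df = cohort[cols].dropna()
    if outcome == "mrs_90":
        y = (df[outcome] <= favorable_cutoff).to_numpy(dtype=float)
    else:
        y = df[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome has a single class; model is degenerate")

    X, factors = _design_matrix(df, covariates)
    for name in X.columns:
        if X[name].nunique() <= 1:
            raise SeparationError(f"covariate {name} is constant")
    Xc = sm.add_constant(X, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, RuntimeWarning, Exception) as exc:  # noqa: BLE001
            if isinstance(exc, SeparationError):
                raise
            raise SeparationError(
                f"logistic fit failed ({type(exc).__name__}: {exc}); "
                "complete/quasi-separation is likely — use a larger cohort"
            ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError(
            f"logistic fit did not converge after "
            f"{fit.mle_retvals.get('iterations', '?')} iterations"
        )
    if np.any(np.abs(fit.params.drop("const")) > 15) or np.any(fit.bse > 50):
        raise SeparationError(
            "divergent coefficients indicate complete/quasi-separation; "
            "a larger synthetic cohort is needed"
        )

    ci = fit.conf_int()
    terms = tuple(
        TermResult(
            name=name,
            odds_ratio=float(np.exp(fit.params[name])),
            ci_low=float(np.exp(ci.loc[name, 0])),
            ci_high=float(np.exp(ci.loc[name, 1])),
            p=float(fit.pvalues[name]),
        )
        for name in X.columns
    )

    factor_ps: Dict[str, float] = {}
    for fac, dummies in factors.items():
        if not dummies:
            continue
        reduced_cols = [c for c in X.columns if c not in dummies]
        Xr = sm.add_constant(X[reduced_cols], has_constant="add")
        fit_r = sm.Logit(y, Xr).fit(disp=0, maxiter=200)
        lr = 2.0 * (fit.llf - fit_r.llf)
        factor_ps[fac] = float(st.chi2.sf(max(lr, 0.0), df=len(dummies)))

    proba = np.asarray(fit.predict(Xc))
    roc = roc_analysis(proba, y.astype(int))
    return LogisticModelResult(
        label=model_label,
        terms=terms,
        auc=roc.auc,
        auc_ci=roc.auc_ci,
        n=len(df),
        factor_pvalues=factor_ps,
    )


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    auc: float
    auc_ci: Tuple[float, float]
    youden: float
    cutoff: float
    sensitivity: float
    specificity: float


def delong_auc_variance(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """DeLong variance of the empirical AUC (single-curve case).

    Uses the placement-value formulation: V10[i] is the proportion of
    controls with a score below case i (ties count 1/2), V01[j] the
    proportion of cases above control j; var(AUC) = var(V10)/m +
    var(V01)/n for m cases and n controls.
    """
    pos = np.asarray(scores)[np.asarray(outcomes) == 1]
    neg = np.asarray(scores)[np.asarray(outcomes) == 0]
    m, n = len(pos), len(neg)
    cmp_ = (pos[:, None] > neg[None, :]).astype(float)
    cmp_ += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_.mean(axis=1)
    v01 = cmp_.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_analysis(scores: Sequence[float], outcomes: Sequence[int]) -> ROCResult:
    """Empirical ROC with the Youden-optimal cutoff.

    Candidate cutoffs sit at midpoints between consecutive sorted unique
    scores (plus one below the minimum and one above the maximum); a
    patient is predicted favorable when score > cutoff.  The optimal
    cutoff maximizes the Youden index with ties broken toward higher
    specificity.  The AUC is the area under the empirical curve (equal to
    the concordance probability with ties counting 1/2) with a DeLong 95%
    CI.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    if len(np.unique(y)) < 2:
        raise DegenerateTestError("ROC needs both outcome classes present")

    uniq = np.unique(s)
    if len(uniq) == 1:
        warnings.warn(
            "all scores identical; AUC is 0.5 by convention",
            ConstantScoreWarning,
            stacklevel=2,
        )
        cut = float(uniq[0] - 1.0)
        return ROCResult(auc=0.5, auc_ci=(0.5, 0.5), youden=0.0, cutoff=cut,
                         sensitivity=1.0, specificity=0.0)

    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cutoffs = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    npos = int((y == 1).sum())
    nneg = int((y == 0).sum())
    best = None
    for cut in cutoffs:
        pred = s > cut
        sens = float((pred & (y == 1)).sum()) / npos
        spec = float((~pred & (y == 0)).sum()) / nneg
        youd = sens + spec - 1.0
        key = (youd, spec, cut)
        if best is None or key > best[0]:
            best = (key, float(cut), sens, spec)
    (youd, _, _), cut, sens, spec = best

    auc = float(roc_auc_score(y, s))
    var = delong_auc_variance(s, y)
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return ROCResult(auc=auc, auc_ci=ci, youden=youd, cutoff=cut,
                     sensitivity=sens, specificity=spec)


# ---------------------------------------------------------------------------
# contingency analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyResult:
    test_name: str
    statistic: float
    p: float


def contingency_analysis(table: Sequence[Sequence[float]]) -> ContingencyResult:
    """Pearson chi-square on an r×c count table (no continuity correction),
    with a Fisher-exact fallback for 2×2 tables with small expected counts.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or (arr < 0).any():
        raise ValueError("table must be a 2D array of non-negative counts")
    if arr.sum() <= 0:
        raise DegenerateTestError("empty table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTestError("empty margin in contingency table")
    if arr.shape == (2, 2) and (_expected_counts(arr) < 5).any():
        oratio, p = st.fisher_exact(arr)
        return ContingencyResult("fisher_exact", float(oratio), float(p))
    chi2, p, _, _ = st.chi2_contingency(arr, correction=False)
    return ContingencyResult("chi_square", float(chi2), float(p))


# ---------------------------------------------------------------------------
# inter-rater reliability
# ---------------------------------------------------------------------------

def interrater_reliability(
    rater_a: Sequence[float],
    rater_b: Sequence[float],
    mode: str = "continuous_angle",
) -> float:
    """Agreement between two raters scoring the same patients.

    ``continuous_angle`` mode returns the two-way random-effects,
    absolute-agreement, single-measure ICC (ICC(2,1)), the natural
    statistic for the raw angle.  ``ordinal_grade`` mode returns the
    linearly weighted Cohen kappa for the 0–4 grade.  The original report
    does not name which statistic its reliability coefficient is, so both
    modes are exposed.
    """
    a = np.asarray(rater_a, dtype=float)
    b = np.asarray(rater_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length rating vectors of >= 2 patients")
    if a.var() == 0 and b.var() == 0:
        raise DegenerateTestError(
            "zero variance in both raters; reliability undefined"
        )
    if mode == "continuous_angle":
        import pingouin as pg  # deferred: slow import

        long = pd.DataFrame(
            {
                "target": np.tile(np.arange(len(a)), 2),
                "rater": np.repeat(["A", "B"], len(a)),
                "score": np.concatenate([a, b]),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # zero MSE edge
            icc = pg.intraclass_corr(
                data=long, targets="target", raters="rater", ratings="score"
            ).set_index("Type")
        # two-way random, absolute agreement, single measures; label differs
        # across pingouin versions
        key = "ICC(A,1)" if "ICC(A,1)" in icc.index else "ICC2"
        return float(icc.loc[key, "ICC"])
    if mode == "ordinal_grade":
        labels = np.unique(np.concatenate([a, b])).astype(int)
        return float(
            cohen_kappa_score(a.astype(int), b.astype(int), labels=labels,
                              weights="linear")
        )
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# reproduction of the published summary numbers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReproCheck:
    name: str
    computed: float
    reference: float
    ok: bool


def _load_reference_counts() -> dict:
    with resources.files("abza.data").joinpath("reference_counts.json").open() as fh:
        return json.load(fh)


def reproduce_printed_tables(
    fixtures: Optional[dict] = None,
    scheme: GradingScheme = GradingScheme(),
) -> List[ReproCheck]:
    """Recompute every summary statistic derivable from the published
    contingency counts and compare it with the published value.

    Uses the packaged reference counts by default; percentages are rounded
    half-up to the printed precision before comparison.
    """
    fx = fixtures if fixtures is not None else _load_reference_counts()
    try:
        oc = fx["outcome_by_collateral"]
        tc = fx["toast_by_collateral"]
        co = fx["cohort"]
        ref = fx["reported"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"fixture schema mismatch: missing {exc}") from exc

    table = TwoByTwo(
        tp=oc["good_collateral_favorable"],
        fn=oc["poor_collateral_favorable"],
        fp=oc["good_collateral_unfavorable"],
        tn=oc["poor_collateral_unfavorable"],
    )
    cm = confusion_metrics(table)

    checks: List[ReproCheck] = []

    def add(name: str, computed: float, reference: float) -> None:
        checks.append(ReproCheck(name, computed, reference,
                                 bool(np.isclose(computed, reference))))

    add("sensitivity_pct", round_half_up(100 * cm.sensitivity, 1),
        ref["sensitivity_pct"])
    add("specificity_pct", round_half_up(100 * cm.specificity, 1),
        ref["specificity_pct"])
    add("youden", round_half_up(cm.youden, 3), ref["youden"])
    add("prevalence_pct", round_half_up(100 * co["favorable"] / co["n"], 1),
        ref["prevalence_pct"])

    n_good = table.tp + table.fp
    n_poor = table.fn + table.tn
    add("favorable_in_good_pct", round_half_up(100 * table.tp / n_good, 0),
        ref["favorable_in_good_pct"])
    add("favorable_in_poor_pct", round_half_up(100 * table.fn / n_poor, 0),
        ref["favorable_in_poor_pct"])
    add("good_in_laa_pct", round_half_up(100 * tc["laa_good"] / tc["laa_total"], 0),
        ref["good_in_laa_pct"])
    add("good_in_ce_pct", round_half_up(100 * tc["ce_good"] / tc["ce_total"], 0),
        ref["good_in_ce_pct"])
    add("grade3_boundary_deg", scheme.dashed_edges_deg[1],
        ref["grade3_boundary_deg"])
    return checks
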