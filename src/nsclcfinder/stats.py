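"""Validation statistics for dichotomous case-finding algorithms.

Covers the full diagnostic-accuracy battery against a gold standard —
sensitivity, specificity, PPV, NPV, accuracy, the diagnostic odds ratio and
the binary-test AUC — plus the DeLong comparison of correlated ROC curves
and a hierarchical logistic-regression robustness analysis.

Conventions
-----------
* Proportion confidence intervals are Wilson score intervals (95% default).
* The DOR interval uses the Woolf log method, ``log DOR ± z·sqrt(Σ 1/cell)``,
  with an optional Haldane–Anscombe 0.5 correction when a cell is zero.
* For a dichotomous test the ROC polygon has a single interior vertex at
  (1−Sp, Se), so AUC = (Se + Sp)/2; its CI here uses a normal approximation
  with var(AUC) = (var(Se) + var(Sp))/4.
* The pseudo-R² is McFadden's: 1 − logLik(model)/logLik(intercept-only).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import Logit
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools import add_constant
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import ContractError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion table & accuracy measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionTable:
    """2×2 cross-tabulation of predicted vs. gold-standard subtype.

    ``tp``: predicted positive, labelled positive; ``fp``: predicted
    positive, labelled negative; ``fn``/``tn`` accordingly.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion-table cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total

    def transpose_classes(self) -> "ConfusionTable":
        """The table with the positive class swapped (tp<->tn, fp<->fn)."""
        return ConfusionTable(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


def confusion_table(
    predictions: Mapping[str, str] | pd.Series,
    labels: Mapping[str, str] | pd.Series,
    positive_class: str = "NSCLC",
) -> ConfusionTable:
    """Cross-tabulate per-patient predictions against gold-standard labels.

    Both collections must cover exactly the same patients; both must be
    binary on {positive_class, other}.
    """
    pred = pd.Series(predictions)
    lab = pd.Series(labels)
    if set(pred.index) != set(lab.index):
        raise ContractError("predictions and labels must cover the same patient set")
    lab = lab.reindex(pred.index)
    p_pos = pred == positive_class
    l_pos = lab == positive_class
    return ConfusionTable(
        tp=int((p_pos & l_pos).sum()),
        fp=int((p_pos & ~l_pos).sum()),
        fn=int((~p_pos & l_pos).sum()),
        tn=int((~p_pos & ~l_pos).sum()),
    )


@dataclass
class Measure:
    """A point estimate with a 95% CI; ``defined`` is False (with a reason)
    when a margin of the table is zero and no correction applies."""

    estimate: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    defined: bool = True
    reason: str | None = None


def _proportion_measure(k: int, n: int, name: str, alpha: float) -> Measure:
    if n == 0:
        return Measure(None, defined=False, reason=f"{name}: zero denominator")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return Measure(k / n, float(lo), float(hi))


@dataclass
class DorResult:
    dor: float | None
    ci_low: float | None
    ci_high: float | None
    correction_applied: bool
    defined: bool = True
    reason: str | None = None


def diagnostic_odds_ratio(
    ct: ConfusionTable, zero_cell_correction: str = "none", alpha: float = 0.05
) -> DorResult:
    """Diagnostic odds ratio (tp·tn)/(fp·fn) with a Woolf log-method CI.

    ``zero_cell_correction='haldane'`` adds 0.5 to every cell when any cell
    is zero; with ``'none'`` a zero cell leaves the DOR undefined.
    """
    if zero_cell_correction not in ("none", "haldane"):
        raise ValueError("zero_cell_correction must be 'none' or 'haldane'")
    cells = np.array([ct.tp, ct.fp, ct.fn, ct.tn], dtype=float)
    corrected = False
    if (cells == 0).any():
        if zero_cell_correction == "haldane":
            cells = cells + 0.5
            corrected = True
        else:
            return DorResult(
                None, None, None, False, defined=False,
                reason="zero cell and no correction enabled",
            )
    tp, fp, fn, tn = cells
    dor = (tp * tn) / (fp * fn)
    se_log = float(np.sqrt((1 / cells).sum()))
    z = float(sps.norm.ppf(1 - alpha / 2))
    log_dor = float(np.log(dor))
    return DorResult(
        float(dor),
        float(np.exp(log_dor - z * se_log)),
        float(np.exp(log_dor + z * se_log)),
        corrected,
    )


@dataclass
class DiagnosticAccuracy:
    """The full diagnostic-accuracy measure set for one 2×2 table."""

    table: ConfusionTable
    sensitivity: Measure
    specificity: Measure
    ppv: Measure
    npv: Measure
    accuracy: Measure
    dor: DorResult
    auc: Measure
    correction_applied: bool = False

    def summary(self, percent: bool = True) -> pd.DataFrame:
        """One row per measure: estimate and 95% CI.

        Proportions are shown as percentages (one decimal, matching the
        usual presentation) when ``percent`` is True; DOR and AUC stay on
        their natural scales.  Full precision is retained on the objects.
        """
        def fmt(m, scale):
            if not m.defined or m.estimate is None:
                return (np.nan, np.nan, np.nan)
            lo = np.nan if m.ci_low is None else m.ci_low * scale
            hi = np.nan if m.ci_high is None else m.ci_high * scale
            return (m.estimate * scale, lo, hi)

        s = 100.0 if percent else 1.0
        rows = {
            "sensitivity": fmt(self.sensitivity, s),
            "specificity": fmt(self.specificity, s),
            "ppv": fmt(self.ppv, s),
            "npv": fmt(self.npv, s),
            "accuracy": fmt(self.accuracy, s),
            "dor": (
                (self.dor.dor, self.dor.ci_low, self.dor.ci_high)
                if self.dor.defined
                else (np.nan, np.nan, np.nan)
            ),
            "auc": fmt(self.auc, 1.0),
        }
        return pd.DataFrame(rows, index=["estimate", "ci_low", "ci_high"]).T

    def to_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "auc"):
            m = getattr(self, name)
            out[name] = {
                "estimate": m.estimate, "ci_low": m.ci_low, "ci_high": m.ci_high,
                "defined": m.defined, "reason": m.reason,
            }
        out["dor"] = {
            "estimate": self.dor.dor, "ci_low": self.dor.ci_low,
            "ci_high": self.dor.ci_high, "defined": self.dor.defined,
            "correction_applied": self.dor.correction_applied, "reason": self.dor.reason,
        }
        out["table"] = {
            "tp": self.table.tp, "fp": self.table.fp,
            "fn": self.table.fn, "tn": self.table.tn,
        }
        return out


def accuracy_measures(
    ct: ConfusionTable,
    zero_cell_correction: str = "none",
    alpha: float = 0.05,
) -> DiagnosticAccuracy:
    """Compute Se, Sp, PPV, NPV, accuracy, DOR and binary-test AUC with CIs.

    AUC is the single-operating-point trapezoid (Se + Sp)/2, the area under
    the two-segment ROC polygon of a dichotomous test.  Any measure whose
    denominator is zero is returned undefined with a reason rather than
    raising.
    """
    if ct.total == 0:
        raise ValidationError("cannot compute measures on an empty table")
    se = _proportion_measure(ct.tp, ct.tp + ct.fn, "sensitivity", alpha)
    sp = _proportion_measure(ct.tn, ct.tn + ct.fp, "specificity", alpha)
    ppv = _proportion_measure(ct.tp, ct.tp + ct.fp, "ppv", alpha)
    npv = _proportion_measure(ct.tn, ct.tn + ct.fn, "npv", alpha)
    acc = _proportion_measure(ct.tp + ct.tn, ct.total, "accuracy", alpha)
    dor = diagnostic_odds_ratio(ct, zero_cell_correction, alpha)

    if se.defined and sp.defined:
        auc_est = (se.estimate + sp.estimate) / 2
        n1, n0 = ct.tp + ct.fn, ct.tn + ct.fp
        var = (
            se.estimate * (1 - se.estimate) / n1
            + sp.estimate * (1 - sp.estimate) / n0
        ) / 4
        z = float(sps.norm.ppf(1 - alpha / 2))
        half = z * float(np.sqrt(var))
        auc = Measure(auc_est, max(0.0, auc_est - half), min(1.0, auc_est + half))
    else:
        auc = Measure(None, defined=False, reason="sensitivity or specificity undefined")

    return DiagnosticAccuracy(
        table=ct, sensitivity=se, specificity=sp, ppv=ppv, npv=npv,
        accuracy=acc, dor=dor, auc=auc,
        correction_applied=dor.correction_applied,
    )


# ---------------------------------------------------------------------------
# DeLong correlated-ROC comparison
# ---------------------------------------------------------------------------

@dataclass
class RocComparison:
    auc_a: float
    auc_b: float
    auc_difference: float
    var_a: float
    var_b: float
    covariance: float
    variance_of_difference: float
    chi_square: float | None
    degrees_of_freedom: int
    p_value: float | None
    degenerate: bool = False


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the DeLong structural components (placement values).

    Uses midranks, so ties count one half, matching the Mann–Whitney kernel
    ψ(x, y) = 1[x > y] + ½·1[x = y].
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tz = sps.rankdata(all_scores, method="average")
    tx = sps.rankdata(pos, method="average")
    ty = sps.rankdata(neg, method="average")
    v10 = (tz[:m] - tx) / n           # per-positive placement
    v01 = 1.0 - (tz[m:] - ty) / m     # per-negative placement
    auc = float((tz[:m].sum() - m * (m + 1) / 2) / (m * n))
    return auc, v10, v01


def delong_auc(scores, labels, positive_label=1) -> tuple[float, float]:
    """AUC of one score vector and its DeLong variance."""
    comparison = delong_compare(scores, scores, labels, positive_label)
    return comparison.auc_a, comparison.var_a


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence,
    positive_label=1,
) -> RocComparison:
    """Compare the AUCs of two scores measured on the same subjects.

    Variances and the covariance of the empirical AUCs come from the DeLong
    placement values; the test statistic is (AUC_a − AUC_b)² / var(diff),
    referred to a χ² distribution with 1 degree of freedom.

    Identical score vectors give difference 0, χ² = 0, p = 1.  A zero
    variance of the difference with unequal AUCs is flagged ``degenerate``
    (no p-value).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray([1 if v == positive_label else 0 for v in labels])
    if len(scores_a) != len(y) or len(scores_b) != len(y):
        raise ContractError("scores and labels must be paired on the same subjects")
    m = int(y.sum())
    n = len(y) - m
    if m == 0 or n == 0:
        raise ValidationError("AUC undefined: both classes must be present")

    auc_a, v10_a, v01_a = _placements(scores_a, y)
    auc_b, v10_b, v01_b = _placements(scores_b, y)

    def cov(u, v, size):
        if size < 2:
            return 0.0
        return float(np.cov(u, v, ddof=1)[0, 1])

    s10_aa = cov(v10_a, v10_a, m)
    s10_bb = cov(v10_b, v10_b, m)
    s10_ab = cov(v10_a, v10_b, m)
    s01_aa = cov(v01_a, v01_a, n)
    s01_bb = cov(v01_b, v01_b, n)
    s01_ab = cov(v01_a, v01_b, n)

    var_a = s10_aa / m + s01_aa / n
    var_b = s10_bb / m + s01_bb / n
    cov_ab = s10_ab / m + s01_ab / n
    diff = auc_a - auc_b
    var_diff = var_a + var_b - 2 * cov_ab

    tiny = 1e-12
    if var_diff <= tiny:
        if abs(diff) <= tiny:
            return RocComparison(auc_a, auc_b, 0.0, var_a, var_b, cov_ab,
                                 max(var_diff, 0.0), 0.0, 1, 1.0)
        return RocComparison(auc_a, auc_b, diff, var_a, var_b, cov_ab,
                             max(var_diff, 0.0), None, 1, None, degenerate=True)
    chi2 = diff**2 / var_diff
    p = float(sps.chi2.sf(chi2, df=1))
    return RocComparison(auc_a, auc_b, diff, var_a, var_b, cov_ab, var_diff, chi2, 1, p)


# ---------------------------------------------------------------------------
# hierarchical logistic robustness analysis
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalLogisticResult:
    """Two-step logistic analysis of the gold-standard subtype.

    Step 1 enters the covariates alone; step 2 adds the algorithm's
    prediction.  ``delta_pseudo_r2`` is the McFadden pseudo-R² increment
    attributable to the algorithm after the covariates have claimed their
    variance.  ``interaction_p_values`` holds, per covariate, the
    likelihood-ratio p-value of adding covariate×algorithm interaction
    terms to the step-2 model (fitted one covariate at a time).
    """

    model1_pseudo_r2: float
    model2_pseudo_r2: float
    delta_pseudo_r2: float
    model1_params: pd.Series
    model1_p_values: pd.Series
    model2_params: pd.Series
    model2_p_values: pd.Series
    algorithm_p_value: float
    interaction_p_values: dict = field(default_factory=dict)
    n_obs: int = 0
    n_dropped: int = 0
    separation_flag: bool = False


def _full_rank(X: pd.DataFrame) -> pd.DataFrame:
    """Drop linearly dependent columns (QR with pivoting), keeping order."""
    arr = X.to_numpy(dtype=float)
    if arr.shape[1] == 0:
        return X
    from scipy.linalg import qr

    _, r, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = (diag[0] if diag.size else 0.0) * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    return X.iloc[:, keep]


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """ML logistic fit; falls back to an L2 penalty under (quasi-)separation."""
    X = _full_rank(X)
    model = Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            if not np.isfinite(res.llf) or np.isnan(res.params).any():
                raise PerfectSeparationError("non-finite fit")
            return res, False
        except (PerfectSeparationError, np.linalg.LinAlgError):
            for alpha in (1e-4, 1e-1, 1.0):
                try:
                    res = model.fit_regularized(
                        alpha=alpha, L1_wt=0.0, disp=0, maxiter=500
                    )
                    if np.isfinite(res.llf):
                        return res, True
                except np.linalg.LinAlgError:
                    continue
            raise


def _mcfadden(res, ll_null: float) -> float:
    return float(1.0 - res.llf / ll_null) if ll_null != 0 else 0.0


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categorical covariates (first level as reference)."""
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    return X.astype(float)


def hierarchical_logistic(
    labels: Sequence,
    covariates: pd.DataFrame,
    algorithm_predictions: Sequence,
    positive_label="NSCLC",
    fit_interactions: bool = True,
) -> HierarchicalLogisticResult:
    """Assess whether patient covariates affect the algorithm's functioning.

    Complete-case analysis: rows with any missing covariate are dropped and
    counted.  Constant covariates are rejected.  ``labels`` is the gold
    standard; ``algorithm_predictions`` the dichotomous algorithm output.
    """
    lab = pd.Series(list(labels)).reset_index(drop=True)
    alg = pd.Series(list(algorithm_predictions)).reset_index(drop=True)
    cov = covariates.reset_index(drop=True)
    if not (len(lab) == len(alg) == len(cov)):
        raise ContractError("labels, covariates and predictions must align")

    keep = ~cov.isna().any(axis=1) & ~lab.isna() & ~alg.isna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("hierarchical_logistic: dropping %d incomplete cases", n_dropped)
    lab, alg, cov = lab[keep], alg[keep], cov[keep]

    for col in cov.columns:
        if cov[col].nunique() < 2:
            raise ValidationError(f"covariate {col!r} is constant")

    y = (lab == positive_label).to_numpy(dtype=float)
    X_cov = _design(cov)
    X1 = add_constant(X_cov, has_constant="add")
    algo = (alg == positive_label).to_numpy(dtype=float)
    X2 = X1.copy()
    X2["algorithm"] = algo

    null_res, _ = _fit_logit(y, add_constant(pd.DataFrame(index=X1.index), has_constant="add"))
    ll_null = float(null_res.llf)

    res1, sep1 = _fit_logit(y, X1)
    res2, sep2 = _fit_logit(y, X2)
    r2_1 = _mcfadden(res1, ll_null)
    r2_2 = _mcfadden(res2, ll_null)

    interactions: dict[str, float] = {}
    if fit_interactions:
        # one covariate's interaction block at a time, LR test vs. step 2
        for col in cov.columns:
            block = [c for c in X_cov.columns if c == col or c.startswith(f"{col}_")]
            X_int = X2.copy()
            n_added = 0
            for b in block:
                term = X2[b].to_numpy() * algo
                if np.ptp(term) == 0:  # degenerate: constant interaction column
                    continue
                X_int[f"{b}_x_algorithm"] = term
                n_added += 1
            if n_added == 0:
                interactions[col] = float("nan")
                continue
            try:
                res_int, _ = _fit_logit(y, X_int)
            except np.linalg.LinAlgError:
                interactions[col] = float("nan")
                continue
            lr = 2 * (res_int.llf - res2.llf)
            interactions[col] = float(sps.chi2.sf(max(lr, 0.0), df=n_added))

    return HierarchicalLogisticResult(
        model1_pseudo_r2=r2_1,
        model2_pseudo_r2=r2_2,
        delta_pseudo_r2=r2_2 - r2_1,
        model1_params=res1.params,
        model1_p_values=res1.pvalues,
        model2_params=res2.params,
        model2_p_values=res2.pvalues,
        algorithm_p_value=float(res2.pvalues.get("algorithm", np.nan)),
        interaction_p_values=interactions,
        n_obs=int(len(y)),
        n_dropped=n_dropped,
        separation_flag=sep1 or sep2,
    )


# ---------------------------------------------------------------------------
# cohort description
# ---------------------------------------------------------------------------

def describe_cohort(patients: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Per-subtype demographic and clinical summary.

    Returns a tidy frame with columns (variable, level, statistic, SCLC,
    NSCLC): n (%) for the cohort split, mean/sd/median for age, BMI and
    comorbidity score, and n (%) for gender, insurance, region and stage.
    """
    df = patients.merge(labels, on="patient_id", how="inner")
    total = len(df)
    rows = []

    def add(variable, level, statistic, values: dict):
        rows.append({"variable": variable, "level": level, "statistic": statistic, **values})

    counts = df["subtype"].value_counts()
    add("patients", "", "n", {s: int(counts.get(s, 0)) for s in ("SCLC", "NSCLC")})
    add("patients", "", "pct_of_total",
        {s: 100.0 * counts.get(s, 0) / total for s in ("SCLC", "NSCLC")})

    for var, col in (("age", "age_at_index"), ("dci", "dci_score"), ("bmi", "bmi")):
        g = df.groupby("subtype")[col]
        for stat, series in (("mean", g.mean()), ("sd", g.std()), ("median", g.median())):
            add(var, "", stat, {s: float(series.get(s, np.nan)) for s in ("SCLC", "NSCLC")})

    for var in ("gender", "insurance", "region", "cancer_stage"):
        sub = df[df[var].astype(str).str.len() > 0]
        tab = sub.groupby(["subtype", var]).size().unstack(fill_value=0)
        denom = tab.sum(axis=1)
        for level in tab.columns:
            add(var, str(level), "n", {s: int(tab.loc[s, level]) if s in tab.index else 0
                                       for s in ("SCLC", "NSCLC")})
            add(var, str(level), "pct",
                {s: 100.0 * tab.loc[s, level] / denom[s] if s in tab.index and denom[s] else 0.0
                 for s in ("SCLC", "NSCLC")})
    return pd.DataFrame(rows, columns=["variable", "level", "statistic", "SCLC", "NSCLC"])
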