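"""Clinical evaluation statistics for phenotype classifiers.

Covers the evaluation arithmetic used to judge the spatial-phenotype
classifier against staining-derived truth and clinical outcome:

* 3x3 confusion matrices (staining rows, classifier columns) with
  per-class sensitivity, the column-precision convention that clinical
  reports often label "specificity" (correct assignments divided by all
  samples assigned to the class), the textbook one-vs-rest specificity,
  and overall accuracy;
* NPV/PPV of the inflamed-vs-rest dichotomy for anti-PD1 response;
* ROC curves and AUC, computed both as trapezoidal area over all
  score-midpoint thresholds and as the Mann–Whitney pair statistic with
  half credit for ties — the two are asserted identical;
* univariate logistic regression odds ratios (own IRLS fit with Wald
  confidence intervals);
* gene-set scores (unweighted mean expression of a gene list);
* Benjamini–Hochberg multiple-testing adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .phenotypes import PHENOTYPES, UNASSIGNED

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 confusion counts; rows = staining truth, columns = classifier.

    Row and column order is fixed to (excluded, ignored, inflamed).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (c < 0).any():
            raise ValueError("confusion counts must be >= 0")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(PHENOTYPES), columns=list(PHENOTYPES)
        )


@dataclass(frozen=True)
class TwoByTwoTable:
    """(phenotype group) x (response) counts for clinical validation.

    Rows: (nonresponder, responder); columns: (excluded+ignored,
    inflamed). The inflamed phenotype is the test-positive group.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2):
            raise ValueError("table must be 2x2")
        if (c < 0).any():
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def cross_product_odds_ratio(self) -> float:
        """OR of response for inflamed vs excluded+ignored: (a*d)/(b*c)."""
        c = self.counts
        num = c[0, 0] * c[1, 1]
        den = c[0, 1] * c[1, 0]
        return math.inf if den == 0 else num / den


def confusion_matrix(true_labels, assigned_labels) -> ConfusionMatrix3:
    """Cross-tabulate staining-derived vs classifier-assigned phenotypes.

    Samples with an ``unassigned`` classifier label are dropped with a
    logged count; any other label outside the three phenotypes raises.
    """
    true_labels = list(true_labels)
    assigned_labels = list(assigned_labels)
    if len(true_labels) != len(assigned_labels):
        raise ValueError("label vectors must have equal length")
    if not true_labels:
        raise ValueError("empty label vectors")
    idx = {p: i for i, p in enumerate(PHENOTYPES)}
    counts = np.zeros((3, 3), dtype=int)
    n_dropped = 0
    for t, a in zip(true_labels, assigned_labels):
        if a == UNASSIGNED:
            n_dropped += 1
            continue
        if t not in idx:
            raise ValueError(f"unknown true label {t!r}")
        if a not in idx:
            raise ValueError(f"unknown assigned label {a!r}")
        counts[idx[t], idx[a]] += 1
    if n_dropped:
        logger.info("dropped %d unassigned samples", n_dropped)
    if counts.sum() == 0:
        raise ValueError("no assigned samples to tabulate")
    return ConfusionMatrix3(counts)


def confusion_metrics(cm: ConfusionMatrix3) -> dict:
    """Sensitivity, precision ("specificity" in the clinical-table
    convention), true specificity and accuracy from a 3x3 matrix.

    ``sensitivity[k]`` = diagonal / row total; ``specificity_paper[k]``
    = diagonal / column total (a precision); ``specificity_true[k]`` =
    true negatives / all negatives of class k. Division by a zero
    margin yields NaN rather than 0.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, diag / row, np.nan)
        prec = np.where(col > 0, diag / col, np.nan)
    spec_true = np.empty(3)
    for k in range(3):
        tn = total - row[k] - col[k] + diag[k]
        fp = col[k] - diag[k]
        denom = tn + fp
        spec_true[k] = tn / denom if denom > 0 else np.nan
    return {
        "sensitivity": dict(zip(PHENOTYPES, sens)),
        "specificity_paper": dict(zip(PHENOTYPES, prec)),
        "specificity_true": dict(zip(PHENOTYPES, spec_true)),
        "accuracy": float(diag.sum() / total),
    }


def npv_ppv(table: TwoByTwoTable) -> tuple[float, float]:
    """Predictive values of the inflamed phenotype for anti-PD1 response.

    PPV = responders among inflamed / all inflamed; NPV = nonresponders
    among excluded+ignored / all excluded+ignored. Values are returned
    unrounded (round only at presentation). A zero group total yields
    NaN.
    """
    c = table.counts.astype(float)
    col_other, col_infl = c.sum(axis=0)
    npv = c[0, 0] / col_other if col_other > 0 else math.nan
    ppv = c[1, 1] / col_infl if col_infl > 0 else math.nan
    return npv, ppv


@dataclass(frozen=True)
class RocResult:
    """ROC curve with AUC; ``higher_is_positive`` records orientation."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    higher_is_positive: bool


def roc_auc(scores, positives, higher_is_positive: bool = True) -> RocResult:
    """ROC curve and AUC for a score against a binary outcome.

    The threshold set is every midpoint between adjacent distinct scores
    plus +/- infinity, which makes the trapezoidal area identical to the
    Mann–Whitney statistic with 0.5 credit for tied scores; both are
    computed and required to agree to 1e-12. For a score where *lower*
    values indicate the positive class, pass
    ``higher_is_positive=False`` (the score is negated internally and
    the orientation recorded).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(positives).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and positives must be equal-length vectors")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    if not higher_is_positive:
        s = -s

    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    # predict positive when score > threshold; descending thresholds give
    # the conventional (0,0) -> (1,1) sweep
    thresholds = thresholds[::-1]
    tpr = np.array([(s[y] > t).sum() / n_pos for t in thresholds])
    fpr = np.array([(s[~y] > t).sum() / n_neg for t in thresholds])
    auc_trap = float(np.trapezoid(tpr, fpr))

    # Mann–Whitney pair statistic with half credit for ties
    ranks = pd.Series(s).rank(method="average").to_numpy()
    auc_mw = float(
        (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )
    if abs(auc_trap - auc_mw) > 1e-12:
        raise AssertionError(
            f"trapezoid ({auc_trap}) and Mann-Whitney ({auc_mw}) AUC differ"
        )
    return RocResult(thresholds, fpr, tpr, auc_trap, higher_is_positive)


@dataclass(frozen=True)
class LogisticOrResult:
    """Univariate logistic regression summary on the odds-ratio scale."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    slope: float
    intercept: float
    slope_se: float
    converged: bool
    n_iter: int


def logistic_or(
    score,
    outcome,
    standardize: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100,
    slope_bound: float = 30.0,
) -> LogisticOrResult:
    """Odds ratio from a univariate logistic fit (IRLS, Wald 95% CI).

    OR = exp(slope) per unit of the score (or per standard deviation
    when ``standardize=True``). Perfect separation is detected as a
    slope diverging beyond ``slope_bound`` and reported as
    non-converged.
    """
    x = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("score and outcome must be equal-length vectors")
    if not np.isfinite(x).all():
        raise ValueError("score must be finite")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcomes must be present")
    if standardize:
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("score has zero variance")
        x = x / sd

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        step = np.abs(beta_new - beta).max()
        beta = beta_new
        if abs(beta[1]) > slope_bound:
            logger.warning(
                "logistic fit diverging (|slope| > %g): separation?",
                slope_bound,
            )
            break
        if step < tol:
            converged = True
            break

    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = math.sqrt(cov[1, 1])
    with np.errstate(over="ignore"):
        or_, lo, hi = np.exp(
            [beta[1], beta[1] - 1.96 * se, beta[1] + 1.96 * se]
        )
    return LogisticOrResult(
        odds_ratio=float(or_),
        ci_low=float(lo),
        ci_high=float(hi),
        slope=float(beta[1]),
        intercept=float(beta[0]),
        slope_se=se,
        converged=converged,
        n_iter=it,
    )


def gene_set_score(expr: ExpressionMatrix, genes) -> pd.Series:
    """Per-sample unweighted mean expression over a gene set.

    Genes missing from the matrix are dropped with a log message; an
    empty intersection raises.
    """
    genes = list(genes)
    present = [g for g in genes if g in expr.values.index]
    absent = sorted(set(genes) - set(present))
    if absent:
        logger.info("gene-set genes absent from matrix: %s", absent[:10])
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    return expr.values.loc[present].mean(axis=0)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Standard FDR step-up with monotonicity enforcement; the result is
    stable under permutation of the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
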