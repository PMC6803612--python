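"""Nonparametric statistical battery for feature screening and ROC evaluation.

Group differences use the two-sided Wilcoxon rank-sum test (exact enumeration
for small untied samples, midrank normal approximation otherwise), corrected
across features by the Benjamini-Hochberg step-up procedure at a 10% false
discovery rate.  Feature-metric associations use Spearman rank correlation.
Discrimination is summarized by the Mann-Whitney AUC with half credit for
ties; significance against the chance value AUC = 0.5 uses Noether's z-test
with a DeLong structural-components variance estimate (one-sided, since the
question is whether the feature does better than guessing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "spearman_matrix",
    "roc_auc",
    "noether_auc_test",
    "compare_features",
    "per_feature_roc",
]

FDR_Q = 0.10


def _two_groups(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    return x, y


def wilcoxon_rank_sum(x, y, exact_max_n: int = 10):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when the pooled sample has at most ``exact_max_n``
    untied observations, otherwise the tie-corrected normal approximation
    with continuity correction.  Returns ``(statistic, p)`` where the
    statistic is the Mann-Whitney U of the first sample.
    """
    x, y = _two_groups(x, y)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= exact_max_n and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values, q: float = FDR_Q):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(q_values, reject)`` with monotonicity enforced; a hypothesis
    is rejected when its adjusted value is at most ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


def spearman_matrix(
    radiomic: pd.DataFrame, conventional: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlation between every (feature, metric) column pair.

    Returns ``(r, p)`` DataFrames indexed by radiomic feature with one column
    per conventional metric.  A constant column yields r = 0 with p = 1 and a
    logged warning.
    """
    if len(radiomic) != len(conventional):
        raise ValueError("tables must have the same number of rows")
    if len(radiomic) < 3:
        raise ValueError("need at least 3 paired observations")
    r = pd.DataFrame(index=radiomic.columns, columns=conventional.columns, dtype=float)
    p = pd.DataFrame(index=radiomic.columns, columns=conventional.columns, dtype=float)
    for fc in radiomic.columns:
        fx = radiomic[fc].to_numpy(dtype=float)
        for mc in conventional.columns:
            my = conventional[mc].to_numpy(dtype=float)
            if np.ptp(fx) == 0 or np.ptp(my) == 0:
                logger.warning("constant column in pair (%s, %s); r set to 0", fc, mc)
                r.loc[fc, mc], p.loc[fc, mc] = 0.0, 1.0
                continue
            res = sps.spearmanr(fx, my)
            r.loc[fc, mc] = float(res.statistic)
            p.loc[fc, mc] = float(res.pvalue)
    return r, p


def _binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OU":
        labels = (labels == "mutant").astype(int)
    labels = labels.astype(int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1 or 'mutant'/'wild')")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


@dataclass(frozen=True)
class RocResult:
    auc: float
    p_value: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the pairwise concordance probability with 0.5 credit for ties."""
    labels = _binary_labels(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = sps.rankdata(scores)
    m = int(labels.sum())
    n = len(labels) - m
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def _youden_operating_point(scores, labels):
    """Threshold maximizing sensitivity + specificity - 1 (rule: score >= t)."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    thresholds = np.unique(scores)[::-1]
    sens = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] < thresholds[:, None]).mean(axis=1)
    best = int(np.argmax(sens + spec - 1.0))
    acc = (sens[best] * len(pos) + spec[best] * len(neg)) / len(scores)
    return float(thresholds[best]), float(sens[best]), float(spec[best]), float(acc)


def roc_auc(scores, labels, orient: bool = False) -> RocResult:
    """ROC summary: AUC, Noether p-value and the Youden-optimal operating point.

    With ``orient=True`` the score sign is flipped when AUC < 0.5 so the
    reported AUC lies in [0.5, 1]; useful for per-feature screening where the
    direction of association is not fixed a priori.
    """
    labels = _binary_labels(labels)
    scores = np.asarray(scores, dtype=float)
    if orient and mann_whitney_auc(scores, labels) < 0.5:
        scores = -scores
    auc = mann_whitney_auc(scores, labels)
    _, p_value = noether_auc_test(scores, labels)
    threshold, sens, spec, acc = _youden_operating_point(scores, labels)
    return RocResult(
        auc=auc,
        p_value=p_value,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        threshold=threshold,
    )


def noether_auc_test(scores, labels):
    """One-sided z-test of AUC > 0.5 with the DeLong variance estimate.

    The variance uses the structural components V10 (per positive: fraction
    of negatives it out-scores, ties half) and V01 (per negative), giving
    var(AUC) = S10/m + S01/n.  A degenerate variance (perfect or perfectly
    wrong separation) falls back to the null variance (m+n+1)/(12 m n), the
    tightest bound still defined, with a logged note.
    """
    labels = _binary_labels(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 observations per class")
    gt = (pos[:, None] > neg[None, :]).astype(float)
    eq = (pos[:, None] == neg[None, :]).astype(float)
    conc = gt + 0.5 * eq
    auc = float(conc.mean())
    v10 = conc.mean(axis=1)
    v01 = conc.mean(axis=0)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    if var <= 0:
        logger.info("degenerate AUC variance (AUC=%.3g); using null variance bound", auc)
        var = (m + n + 1) / (12.0 * m * n)
    z = (auc - 0.5) / np.sqrt(var)
    p = float(sps.norm.sf(z))
    return float(z), p


def compare_features(features: pd.DataFrame, labels, q: float = FDR_Q) -> pd.DataFrame:
    """Per-feature Wilcoxon screening with BH-FDR flags.

    Returns a tidy table (feature, statistic, p, q, reject) sorted by the
    original column order.
    """
    labels = _binary_labels(labels)
    rows = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        stat, p = wilcoxon_rank_sum(vals[labels == 1], vals[labels == 0])
        rows.append({"feature": col, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    out["q"], out["reject"] = bh_fdr(out["p"].to_numpy(), q=q)
    return out


def per_feature_roc(features: pd.DataFrame, labels) -> pd.DataFrame:
    """Whole-cohort oriented AUC with the Noether test, one row per feature."""
    labels = _binary_labels(labels)
    rows = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            rows.append(
                {"feature": col, "auc": 0.5, "p_auc": 0.5, "sensitivity": np.nan,
                 "specificity": np.nan, "accuracy": np.nan}
            )
            continue
        res = roc_auc(vals, labels, orient=True)
        rows.append(
            {"feature": col, "auc": res.auc, "p_auc": res.p_value,
             "sensitivity": res.sensitivity, "specificity": res.specificity,
             "accuracy": res.accuracy}
        )
    return pd.DataFrame(rows)
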