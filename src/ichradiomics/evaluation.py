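"""Outcome definitions, matched train/test splitting, and ROC/threshold metrics.

Outcomes: haematoma expansion (follow-up growth > 6 mL absolute or > 33%
relative to baseline) and poor functional outcome (modified Rankin scale 4-6
at day 90). The classification threshold is chosen on training scores by
maximising Youden's index (sensitivity + specificity - 1); proportions carry
Wald 95% confidence intervals, AUCs carry DeLong intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

Z95 = 1.959963984540054


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# outcome labels and clinical derived variables


def label_haematoma_expansion(v0_ml: float, v24_ml: float) -> bool:
    """Growth > 6 mL or > 33% of baseline (strict inequalities)."""
    if v0_ml < 0 or v24_ml < 0:
        raise EvaluationError("volumes must be non-negative")
    if v0_ml == 0:
        raise EvaluationError("zero baseline volume: relative growth undefined")
    growth = v24_ml - v0_ml
    return bool(growth > 6.0 or growth / v0_ml > 0.33)


def label_poor_outcome(mrs: int) -> bool:
    """Modified Rankin scale 4-6 at day 90."""
    if not (0 <= int(mrs) <= 6) or int(mrs) != mrs:
        raise EvaluationError(f"mRS must be an integer in 0..6, got {mrs}")
    return int(mrs) >= 4


def ultra_early_growth(v0_ml: float, onset_to_scan_h: float) -> float:
    """Baseline haematoma volume over onset-to-scan time, in mL/h."""
    if onset_to_scan_h <= 0:
        raise EvaluationError("onset-to-scan time must be positive")
    return v0_ml / onset_to_scan_h


# ---------------------------------------------------------------------------
# matched split


def matched_split(
    cohort: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    outcome_col: str | None = None,
    age_col: str = "age",
    gender_col: str = "gender",
    max_attempts: int = 100,
    p_threshold: float = 0.05,
):
    """Age/gender-matched stratified train/test split.

    Subjects are drawn within (gender x age-quintile x outcome) cells; a draw
    is accepted when a rank-sum test on age and a chi-square test on gender
    between the two sets both give two-sided p > 0.05. Returns
    ``(train_index, test_index)``.
    """
    if len(cohort) < 20:
        raise EvaluationError("cohort too small for a matched split")
    if not 0 < train_fraction < 1:
        raise EvaluationError("train_fraction must be in (0, 1)")
    age = cohort[age_col].to_numpy(dtype=np.float64)
    gender = cohort[gender_col].to_numpy()
    quint = pd.qcut(age, 5, labels=False, duplicates="drop")
    strata = pd.Series(
        [f"{g}|{q}" for g, q in zip(gender, quint)], index=cohort.index
    )
    if outcome_col is not None:
        strata = strata + "|" + cohort[outcome_col].astype(str)
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        train_mask = pd.Series(False, index=cohort.index)
        for _, idx in strata.groupby(strata).groups.items():
            idx = list(idx)
            perm = rng.permutation(len(idx))
            n_tr_f = train_fraction * len(idx)
            n_tr = int(np.floor(n_tr_f))
            if rng.random() < (n_tr_f - n_tr):
                n_tr += 1
            train_mask.loc[[idx[i] for i in perm[:n_tr]]] = True
        tr, te = cohort.index[train_mask], cohort.index[~train_mask]
        if len(tr) == 0 or len(te) == 0:
            continue
        p_age = stats.ranksums(age[train_mask.to_numpy()], age[~train_mask.to_numpy()]).pvalue
        tab = pd.crosstab(train_mask, pd.Series(gender, index=cohort.index))
        if tab.shape == (2, 2):
            p_gender = stats.chi2_contingency(tab, correction=False).pvalue
        else:
            p_gender = 1.0
        if p_age > p_threshold and p_gender > p_threshold:
            return list(tr), list(te)
    raise EvaluationError(f"matched split not attained in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# ROC / AUC


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC estimate (single classifier)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)

    def midrank(x):
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x))
        xs = x[order]
        i = 0
        while i < len(x):
            j = i
            while j < len(x) and xs[j] == xs[i]:
                j += 1
            ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
            i = j
        return ranks

    allv = np.concatenate([pos, neg])
    tx = midrank(pos)
    ty = midrank(neg)
    tz = midrank(allv)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels):
    """AUC via the rank (Mann-Whitney) statistic with tie correction, plus a
    DeLong 95% CI. Returns ``(roc_points, auc, (lo, hi))`` where roc_points is
    a DataFrame with fpr/tpr/threshold columns."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    var = _delong_variance(scores, labels)
    half = Z95 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, auc, ci


def _confusion(scores, labels, threshold):
    pred = np.asarray(scores) >= threshold
    labels = np.asarray(labels).astype(bool)
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return tp, fp, fn, tn


def youden_threshold(scores, labels) -> float:
    """Threshold maximising sensitivity + specificity - 1 under the rule
    score >= threshold => positive; ties resolved to the lowest threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("both classes must be present")
    cands = np.unique(scores)
    best_t, best_j = cands[0], -np.inf
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    for t in cands:
        tp, fp, fn, tn = _confusion(scores, labels, t)
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def wald_ci(p: float, n: int) -> tuple[float, float]:
    """Wald 95% interval p +/- 1.96 sqrt(p(1-p)/n), clipped to [0, 1]."""
    if n <= 0:
        return (float("nan"), float("nan"))
    half = Z95 * np.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


@dataclass
class MetricReport:
    """Threshold metrics with 95% CIs; undefined metrics are NaN."""

    threshold: float
    auc: float
    auc_ci: tuple
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    ppv: float
    ppv_ci: tuple
    npv: float
    npv_ci: tuple
    prevalence: float
    prevalence_ci: tuple
    counts: dict

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity, "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity, "specificity_ci": list(self.specificity_ci),
            "ppv": self.ppv, "ppv_ci": list(self.ppv_ci),
            "npv": self.npv, "npv_ci": list(self.npv_ci),
            "prevalence": self.prevalence, "prevalence_ci": list(self.prevalence_ci),
            "counts": self.counts,
        }


def metric_report(scores, labels, threshold: float) -> MetricReport:
    """Confusion metrics at ``score >= threshold`` with Wald 95% CIs.

    Each CI uses the metric's own denominator. Empty PPV/NPV denominators
    yield NaN (undefined), never 0.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("both classes must be present")
    tp, fp, fn, tn = _confusion(scores, labels, threshold)
    n = tp + fp + fn + tn
    npos, nneg = tp + fn, fp + tn
    sens = tp / npos
    spec = tn / nneg
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npvv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    prev = npos / n
    _, auc, auc_ci = roc_auc(scores, labels)
    return MetricReport(
        threshold=float(threshold),
        auc=auc, auc_ci=auc_ci,
        sensitivity=sens, sensitivity_ci=wald_ci(sens, npos),
        specificity=spec, specificity_ci=wald_ci(spec, nneg),
        ppv=ppv, ppv_ci=wald_ci(ppv, tp + fp) if (tp + fp) > 0 else (float("nan"),) * 2,
        npv=npvv, npv_ci=wald_ci(npvv, tn + fn) if (tn + fn) > 0 else (float("nan"),) * 2,
        prevalence=prev, prevalence_ci=wald_ci(prev, n),
        counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


def fbeta(ppv: float, sens: float, beta: float) -> float:
    if np.isnan(ppv) or np.isnan(sens) or (ppv == 0 and sens == 0):
        return float("nan")
    b2 = beta**2
    denom = b2 * ppv + sens
    return (1.0 + b2) * ppv * sens / denom if denom > 0 else float("nan")


def threshold_analysis(scores, labels) -> pd.DataFrame:
    """Sensitivity, specificity, Youden J, and F-scores over all candidate
    thresholds (the unique score values)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("both classes must be present")
    rows = []
    npos = labels.sum()
    nneg = len(labels) - npos
    for t in np.unique(scores):
        tp, fp, fn, tn = _confusion(scores, labels, t)
        sens = tp / npos
        spec = tn / nneg
        ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
        rows.append({
            "threshold": float(t), "sensitivity": sens, "specificity": spec,
            "youden_j": sens + spec - 1.0,
            "f1": fbeta(ppv, sens, 1.0),
            "f0.5": fbeta(ppv, sens, 0.5),
            "f2": fbeta(ppv, sens, 2.0),
        })
    return pd.DataFrame(rows)
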