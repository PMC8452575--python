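import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ichradiomics.evaluation import (
    EvaluationError,
    fbeta,
    label_haematoma_expansion,
    label_poor_outcome,
    matched_split,
    metric_report,
    roc_auc,
    threshold_analysis,
    ultra_early_growth,
    wald_ci,
    youden_threshold,
)

from .oracles import exhaustive_youden, pair_counting_auc


# ---------------------------------------------------------------- labels

def test_expansion_rule_examples():
    assert label_haematoma_expansion(10.0, 17.0)      # +7 mL > 6 mL
    assert label_haematoma_expansion(9.0, 12.1)       # +34.4% > 33%
    assert not label_haematoma_expansion(10.0, 13.0)  # +3 mL, +30%
    assert not label_haematoma_expansion(20.0, 26.0)  # exactly 6 mL: strict


def test_expansion_rule_zero_baseline():
    with pytest.raises(EvaluationError, match="zero baseline"):
        label_haematoma_expansion(0.0, 7.0)


def test_expansion_rejects_negative():
    with pytest.raises(EvaluationError):
        label_haematoma_expansion(-1.0, 5.0)


def test_poor_outcome_rule():
    assert not label_poor_outcome(3)
    assert label_poor_outcome(4)
    assert label_poor_outcome(6)
    with pytest.raises(EvaluationError):
        label_poor_outcome(7)
    with pytest.raises(EvaluationError):
        label_poor_outcome(-1)


def test_ultra_early_growth():
    assert ultra_early_growth(12.0, 2.0) == pytest.approx(6.0)
    assert ultra_early_growth(0.0, 1.5) == 0.0
    with pytest.raises(EvaluationError):
        ultra_early_growth(5.0, 0.0)


# ---------------------------------------------------------------- split

def make_cohort(n=1000, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(69, 13, n), 18, 100),
            "gender": rng.integers(0, 2, n),
            "y": rng.integers(0, 2, n),
        },
        index=[f"s{i:04d}" for i in range(n)],
    )


def test_matched_split_fraction_and_balance():
    cohort = make_cohort()
    tr, te = matched_split(cohort, train_fraction=0.7, seed=3, outcome_col="y")
    assert len(tr) + len(te) == len(cohort)
    assert len(set(tr) & set(te)) == 0
    assert len(tr) / len(cohort) == pytest.approx(0.70, abs=0.02)
    p_age = stats.ranksums(cohort.loc[tr, "age"], cohort.loc[te, "age"]).pvalue
    assert p_age > 0.05
    tab = pd.crosstab(cohort.index.isin(tr), cohort["gender"])
    assert stats.chi2_contingency(tab, correction=False).pvalue > 0.05


def test_matched_split_deterministic():
    cohort = make_cohort(seed=1)
    s1 = matched_split(cohort, seed=7, outcome_col="y")
    s2 = matched_split(cohort, seed=7, outcome_col="y")
    assert s1 == s2


def test_matched_split_too_small():
    with pytest.raises(EvaluationError):
        matched_split(make_cohort(5))


# ---------------------------------------------------------------- ROC/AUC

def test_auc_worked_example():
    _, auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert auc == pytest.approx(0.75)


def test_auc_perfect_and_ties():
    _, auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert auc == 1.0
    _, auc, _ = roc_auc([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1])
    assert auc == 0.5


def test_auc_matches_pair_counting():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(4, 13))
        scores = rng.choice(np.linspace(0, 1, 6), n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        _, auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)


def test_youden_matches_exhaustive():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(6, 30))
        scores = rng.choice(np.linspace(0, 1, 8), n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        assert youden_threshold(scores, labels) == exhaustive_youden(scores, labels)


# ---------------------------------------------------------------- intervals

def test_wald_ci_reference_values():
    lo, hi = wald_ci(137 / 521, 521)
    assert round(lo, 3) == 0.225
    assert round(hi, 3) == 0.301
    lo, hi = wald_ci(0.635, 137)
    assert round(lo, 3) == 0.554
    assert round(hi, 3) == 0.716


def test_wald_ci_clipping():
    lo, hi = wald_ci(1.0, 50)
    assert (lo, hi) == (1.0, 1.0)
    lo, hi = wald_ci(0.0, 50)
    assert (lo, hi) == (0.0, 0.0)


# ---------------------------------------------------------------- reports

def test_metric_report_consistency():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 2, 200)
    scores = np.clip(labels * 0.3 + rng.random(200) * 0.7, 0, 1)
    rep = metric_report(scores, labels, 0.5)
    # PPV * (TP + FP) == sensitivity * P
    pred_pos = np.sum(scores >= 0.5)
    assert rep.ppv * pred_pos == pytest.approx(rep.sensitivity * labels.sum())
    assert 0 <= rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1] <= 1


def test_metric_report_perfect_classifier():
    labels = np.array([0, 0, 0, 1, 1, 1])
    scores = labels.astype(float)
    rep = metric_report(scores, labels, 0.5)
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    assert rep.sensitivity_ci[1] <= 1.0 and rep.ppv_ci[1] <= 1.0


def test_fbeta_values():
    assert fbeta(0.5, 1.0, 1.0) == pytest.approx(2 / 3)
    assert fbeta(0.5, 1.0, 2.0) == pytest.approx(5 / 6)
    assert np.isnan(fbeta(np.nan, 1.0, 1.0))
    assert np.isnan(fbeta(0.0, 0.0, 1.0))


def test_threshold_analysis_perfect():
    labels = np.array([0, 0, 1, 1])
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    ta = threshold_analysis(scores, labels)
    best = ta.loc[ta["youden_j"].idxmax()]
    assert best["youden_j"] == pytest.approx(1.0)
    assert best["f1"] == pytest.approx(1.0)
    assert best["f2"] == pytest.approx(1.0)
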