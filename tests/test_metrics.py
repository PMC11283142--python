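"""Evaluation metrics: AUC against the pairwise oracle, bootstrap CI
behaviour and coverage, confusion-matrix arithmetic, report invariants."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundex.metrics import (bootstrap_ci, confusion_and_rates, evaluate_scores,
                            roc_auc, youden_threshold)

from conftest import auc_pairwise_oracle, rank_auc


def test_perfect_separation_gives_auc_one():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0


def test_all_tied_scores_give_auc_half():
    assert roc_auc([0.5] * 10, [1, 0] * 5) == 0.5


@pytest.mark.parametrize("seed", range(8))
def test_auc_matches_pairwise_oracle_exactly(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 200))
    # quantised scores force ties; labels guaranteed both classes
    scores = np.round(rng.uniform(size=n), 2)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    expected = auc_pairwise_oracle(scores, labels)
    assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)
    assert rank_auc(scores, labels) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_auc_invariances(seed):
    rng = np.random.default_rng(seed)
    n = 30
    scores = rng.normal(size=n)
    labels = np.r_[np.ones(10, dtype=int), np.zeros(20, dtype=int)]
    auc = roc_auc(scores, labels)
    # strictly monotone transform leaves AUC unchanged
    assert roc_auc(np.exp(2 * scores) + 1, labels) == pytest.approx(auc)
    # flipping labels maps AUC -> 1 - AUC
    assert roc_auc(scores, 1 - labels) == pytest.approx(1 - auc)
    # flipping labels and negating scores leaves AUC unchanged
    assert roc_auc(-scores, 1 - labels) == pytest.approx(auc)


def test_single_class_rejected():
    with pytest.raises(ValueError, match="single class"):
        roc_auc([0.1, 0.2], [1, 1])


def test_confusion_arithmetic_matches_hand_counts():
    # 14 cases (13 above threshold), 10 controls (6 below)
    scores = np.r_[np.full(13, 0.9), [0.1], np.full(6, 0.1), np.full(4, 0.9)]
    labels = np.r_[np.ones(14, dtype=int), np.zeros(10, dtype=int)]
    cm, sens, spec = confusion_and_rates(scores, labels, threshold=0.5)
    tn, fp, fn, tp = cm.ravel()
    assert (tp, fn, tn, fp) == (13, 1, 6, 4)
    assert sens == pytest.approx(13 / 14)
    assert spec == pytest.approx(6 / 10)


def test_threshold_extremes():
    scores = np.random.default_rng(0).uniform(size=50)
    labels = np.r_[np.ones(25, dtype=int), np.zeros(25, dtype=int)]
    _, sens, _ = confusion_and_rates(scores, labels, threshold=0.0)
    assert sens == 1.0  # everything called positive
    _, _, spec = confusion_and_rates(scores, labels, threshold=1.0 + 1e-9)
    assert spec == 1.0  # nothing called positive


def test_bootstrap_ci_contains_point_and_saturates_when_separated():
    rng = np.random.default_rng(1)
    scores = np.r_[rng.uniform(0.6, 1.0, 100), rng.uniform(0.0, 0.4, 100)]
    labels = np.r_[np.ones(100, dtype=int), np.zeros(100, dtype=int)]
    lo, hi = bootstrap_ci(scores, labels, rank_auc, n_boot=200, seed=0)
    assert hi == 1.0
    assert lo <= roc_auc(scores, labels) <= hi


def test_bootstrap_is_deterministic_given_seed():
    rng = np.random.default_rng(2)
    scores = rng.uniform(size=60)
    labels = np.r_[np.ones(30, dtype=int), np.zeros(30, dtype=int)]
    a = bootstrap_ci(scores, labels, rank_auc, n_boot=100, seed=5)
    assert a == bootstrap_ci(scores, labels, rank_auc, n_boot=100, seed=5)
    assert a != bootstrap_ci(scores, labels, rank_auc, n_boot=100, seed=6)


def test_bootstrap_coverage_near_nominal():
    """Binormal scores with known AUC = Phi(1/sqrt(2)) ~ 0.760: the 95%
    stratified percentile bootstrap CI should cover it ~95% +/- 3% of the
    time over 200 simulated datasets."""
    from scipy.stats import norm

    true_auc = norm.cdf(1 / np.sqrt(2))
    hits = 0
    for i in range(200):
        rng = np.random.default_rng(i)
        scores = np.concatenate([rng.normal(0, 1, 75), rng.normal(1, 1, 75)])
        labels = np.r_[np.zeros(75, dtype=int), np.ones(75, dtype=int)]
        lo, hi = bootstrap_ci(scores, labels, rank_auc, n_boot=400, seed=1000 + i)
        hits += lo <= true_auc <= hi
    assert 0.92 <= hits / 200 <= 0.98


def test_evaluate_scores_report_invariants(tmp_path):
    rng = np.random.default_rng(3)
    scores = np.clip(np.r_[rng.normal(0.7, 0.2, 40), rng.normal(0.3, 0.2, 60)], 0, 1)
    labels = np.r_[np.ones(40, dtype=int), np.zeros(60, dtype=int)]
    rep = evaluate_scores(scores, labels, n_boot=200, seed=0)
    assert rep.confusion.sum() == rep.n_pos + rep.n_neg == 100
    for point, (lo, hi) in [(rep.auc, rep.auc_ci),
                            (rep.sensitivity, rep.sensitivity_ci),
                            (rep.specificity, rep.specificity_ci)]:
        assert 0.0 <= lo <= point <= hi <= 1.0
    rep.save_json(tmp_path / "report.json")
    d = json.loads((tmp_path / "report.json").read_text())
    assert d["auc"] == rep.auc
    rep.save_roc_csv(tmp_path / "roc.csv")
    lines = (tmp_path / "roc.csv").read_text().strip().splitlines()
    assert lines[0] == "fpr,tpr,threshold" and len(lines) > 2


def test_youden_threshold_optimises_j():
    scores = np.array([0.1, 0.2, 0.35, 0.4, 0.6, 0.7, 0.8, 0.9])
    labels = np.array([0, 0, 0, 1, 1, 1, 1, 1])
    thr = youden_threshold(scores, labels)
    _, sens, spec = confusion_and_rates(scores, labels, thr)
    assert sens + spec - 1 == pytest.approx(1.0)  # perfectly separable here
    rep = evaluate_scores(scores, labels, threshold_policy="youden", n_boot=50)
    assert rep.threshold_policy == "youden"
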