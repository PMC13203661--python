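"""Confusion metrics, overlap scores, ANOVA, classifier harness."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dermopt.simulate import gen_feature_matrix
from dermopt.stats import (
    ConfusionCounts,
    anova_from_sums,
    anova_oneway,
    confusion_metrics,
    counts_from_masks,
    f_critical,
    train_eval_classifier,
)


def test_perfect_prediction():
    rep = confusion_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=10))
    assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
    assert rep.fnr == rep.fpr == 0.0
    assert rep.f1 == rep.jaccard == rep.dice == 1.0


def test_hand_computed_metrics():
    rep = confusion_metrics(ConfusionCounts(tp=8, fp=1, fn=2, tn=9))
    assert rep.sensitivity == pytest.approx(0.8)
    assert rep.specificity == pytest.approx(0.9)
    assert rep.accuracy == pytest.approx(0.85)
    assert rep.f1 == pytest.approx(16 / 19)
    rep2 = confusion_metrics(ConfusionCounts(tp=8, fp=1, fn=1, tn=0))
    assert rep2.jaccard == pytest.approx(0.8)
    assert rep2.dice == pytest.approx(16 / 18)


def test_undefined_metrics_are_nan():
    rep = confusion_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
    assert math.isnan(rep.sensitivity) and math.isnan(rep.fnr)
    rep = confusion_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=0))
    assert math.isnan(rep.accuracy)
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


@given(
    st.integers(1, 500), st.integers(0, 500), st.integers(0, 500),
    st.integers(0, 500),
)
def test_metric_identities(tp, fp, fn, tn):
    rep = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
    assert rep.dice == pytest.approx(2 * rep.jaccard / (1 + rep.jaccard))
    assert rep.fnr == pytest.approx(1 - rep.sensitivity)
    if tn + fp > 0:
        assert rep.fpr == pytest.approx(1 - rep.specificity)


def test_counts_from_masks():
    pred = np.array([[1, 1], [0, 0]], dtype=bool)
    truth = np.array([[1, 0], [1, 0]], dtype=bool)
    c = counts_from_masks(pred, truth)
    assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
    with pytest.raises(ValueError):
        counts_from_masks(pred, truth[:1])


def test_anova_from_sums_and_degenerate_cases():
    t = anova_from_sums(9.6274, 2, 2.5001, 12)
    assert t.ms_between == pytest.approx(4.8137)
    assert t.f_stat == pytest.approx(23.1046, abs=0.01)
    assert t.ss_total == pytest.approx(12.1275)
    assert anova_from_sums(0.0, 2, 5.0, 12).f_stat == 0.0
    inf_table = anova_from_sums(3.0, 2, 0.0, 12)
    assert math.isinf(inf_table.f_stat) and inf_table.p_value == 0.0
    with pytest.raises(ValueError):
        anova_from_sums(1.0, 0, 1.0, 12)


def test_anova_oneway_hand_example():
    t = anova_oneway([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
    assert t.ss_between == pytest.approx(13.5)
    assert t.ss_within == pytest.approx(4.0)
    assert (t.df_between, t.df_within) == (1, 4)
    assert t.f_stat == pytest.approx(13.5)


def test_anova_oneway_invariances(rng):
    groups = [rng.normal(size=6) for _ in range(3)]
    base = anova_oneway(groups)
    # identical groups -> F = 0
    same = anova_oneway([groups[0], groups[0].copy()])
    assert same.f_stat == pytest.approx(0.0, abs=1e-20)
    # permuting values within groups changes nothing
    permuted = [rng.permutation(g) for g in groups]
    assert anova_oneway(permuted).f_stat == pytest.approx(base.f_stat)
    # self-consistency with anova_from_sums
    again = anova_from_sums(base.ss_between, base.df_between,
                            base.ss_within, base.df_within)
    assert again.f_stat == base.f_stat


def _anova_two_pass_oracle(groups):
    """Naive two-pass SS decomposition."""
    means = [g.mean() for g in groups]
    grand = np.concatenate(groups).mean()
    ss_b = sum(g.size * (m - grand) ** 2 for g, m in zip(groups, means))
    ss_w = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    df_b = len(groups) - 1
    df_w = sum(g.size for g in groups) - len(groups)
    return (ss_b / df_b) / (ss_w / df_w)


def test_anova_matches_two_pass_oracle():
    rng = np.random.default_rng(77)
    for _ in range(100):
        k = int(rng.integers(2, 6))
        groups = [rng.normal(rng.uniform(-1, 1), 1.0, size=int(rng.integers(2, 12)))
                  for _ in range(k)]
        t = anova_oneway(groups)
        assert abs(t.f_stat - _anova_two_pass_oracle(groups)) < 1e-9
        # scipy agreement on the same groups
        from scipy.stats import f_oneway

        f_ref, p_ref = f_oneway(*groups)
        assert t.f_stat == pytest.approx(f_ref)
        assert t.p_value == pytest.approx(p_ref)


def test_f_critical_values():
    assert round(f_critical(2, 12, 0.05), 2) == 3.89
    assert f_critical(1, 10**6, 0.05) == pytest.approx(3.8415, abs=2e-4)
    assert f_critical(3, 9, 0.999) < 0.05  # quantile -> 0 as alpha -> 1
    with pytest.raises(ValueError):
        f_critical(2, 12, 1.5)


def test_classifiers_separate_well_separated_classes():
    fx = gen_feature_matrix(n_samples=120, n_noise=10, separation=4.0, seed=42)
    for family in ("quadratic-svm", "weighted-knn",
                   "ensemble-subspace-discriminant"):
        rep = train_eval_classifier(fx.matrix.values, fx.matrix.labels,
                                    family, seed=42)
        assert rep.accuracy >= 0.95, family


def test_classifier_chance_level_on_permuted_labels():
    fx = gen_feature_matrix(n_samples=120, n_noise=10, separation=4.0, seed=42)
    rng = np.random.default_rng(42)
    shuffled = rng.permutation(fx.matrix.labels)
    rep = train_eval_classifier(fx.matrix.values, shuffled, "weighted-knn",
                                seed=42)
    majority = max(np.mean(shuffled == 0), np.mean(shuffled == 1))
    assert abs(rep.accuracy - majority) <= 0.15


def test_classifier_determinism_and_validation():
    fx = gen_feature_matrix(n_samples=60, n_noise=5, seed=9)
    a = train_eval_classifier(fx.matrix.values, fx.matrix.labels,
                              "medium-nn", seed=9)
    b = train_eval_classifier(fx.matrix.values, fx.matrix.labels,
                              "medium-nn", seed=9)
    assert a == b
    with pytest.raises(ValueError, match="two classes"):
        train_eval_classifier(fx.matrix.values, np.zeros(60), "medium-nn")
    with pytest.raises(ValueError, match="unknown family"):
        train_eval_classifier(fx.matrix.values, fx.matrix.labels, "bogus")


def test_kfold_evaluation_runs():
    fx = gen_feature_matrix(n_samples=80, n_noise=5, separation=4.0, seed=3)
    rep = train_eval_classifier(fx.matrix.values, fx.matrix.labels,
                                "weighted-knn", k_folds=5, seed=3)
    assert rep.accuracy >= 0.9


def test_multiclass_micro_and_macro():
    rng = np.random.default_rng(5)
    n = 150
    y = np.repeat([0, 1, 2], n // 3)
    x = rng.normal(size=(n, 4)) + 4.0 * y[:, None]
    micro = train_eval_classifier(x, y, "weighted-knn", seed=5)
    macro = train_eval_classifier(x, y, "weighted-knn", averaging="macro",
                                  seed=5)
    assert micro.accuracy >= 0.9
    assert macro.sensitivity >= 0.9
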