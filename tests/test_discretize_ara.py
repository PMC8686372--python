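"""Class-guided discretization and the forward-stepwise rule miner."""

import numpy as np
import pytest

from ctg_interpret import discretize_ara as da
from ctg_interpret.discretize_ara import (
    AssociationRule, BinningScheme, Condition, exhaustive_best_rule,
    fit_all_bins, fit_class_distribution_bins, forward_stepwise_rule,
    rule_support_confidence, rule_to_text,
)

from conftest import make_dataset, random_dataset


# -- binning ------------------------------------------------------------------

def test_binning_scheme_validates_edges():
    with pytest.raises(ValueError):
        BinningScheme("ASTV", (1.0,))
    with pytest.raises(ValueError):
        BinningScheme("ASTV", (1.0, 1.0, 2.0))
    assert BinningScheme("ASTV", (0.0, 1.0, 2.0)).n_bins == 2


def test_bin_index_half_open_with_closed_last():
    scheme = BinningScheme("ASTV", (0.0, 10.0, 20.0))
    idx = scheme.bin_index(np.array([0.0, 9.99, 10.0, 19.9, 20.0, 25.0]))
    np.testing.assert_array_equal(idx, [0, 0, 1, 1, 1, 1])


def test_fit_bins_places_cut_at_class_change():
    # classes change exactly at value 5/6: expect one interior cut at 5.5
    ds = make_dataset(ASTV=list(range(1, 11)),
                      NSP=[1, 1, 1, 1, 1, 3, 3, 3, 3, 3])
    scheme = fit_class_distribution_bins(ds, "ASTV", max_bins=4, min_frac=0.05)
    assert scheme.n_bins == 2
    assert scheme.edges[1] == pytest.approx(5.5)


def test_fit_bins_respects_max_bins_and_min_frac(rng):
    v = rng.uniform(0, 100, size=400)
    nsp = np.where(v < 30, 1, np.where(v < 60, 2, 3))
    flip = rng.uniform(size=400) < 0.2
    nsp = np.where(flip, rng.integers(1, 4, size=400), nsp)
    ds = make_dataset(ASTV=v, NSP=nsp)
    scheme = fit_class_distribution_bins(ds, "ASTV", max_bins=5, min_frac=0.05)
    assert 2 <= scheme.n_bins <= 5
    counts = np.bincount(scheme.bin_index(v), minlength=scheme.n_bins)
    assert counts.min() >= 0.05 * len(v)


def test_fit_bins_constant_feature():
    ds = make_dataset(ASTV=[7.0] * 5, NSP=[1, 1, 2, 3, 1])
    scheme = fit_class_distribution_bins(ds, "ASTV")
    assert scheme.n_bins == 1
    assert scheme.bin_index(np.array([7.0]))[0] == 0


def test_fit_bins_parameter_domain(small_dataset):
    with pytest.raises(ValueError):
        fit_class_distribution_bins(small_dataset, "ASTV", max_bins=1)
    with pytest.raises(ValueError):
        fit_class_distribution_bins(small_dataset, "ASTV", min_frac=0.7)


def test_fit_all_bins_covers_every_feature(small_dataset):
    bins = fit_all_bins(small_dataset)
    assert set(bins) == set(small_dataset.feature_names)


# -- rule statistics ----------------------------------------------------------

def test_support_confidence_hand_computed():
    ds = make_dataset(ASTV=[10, 20, 30, 40, 50, 60],
                      NSP=[3, 3, 3, 1, 1, 1])
    cond = Condition("ASTV", 0.0, 35.0)
    rule = rule_support_confidence([cond], 3, ds)
    assert rule.match_count == 3
    assert rule.support == pytest.approx(0.5)
    assert rule.confidence == pytest.approx(1.0)
    rule2 = rule_support_confidence([cond], 1, ds)
    assert rule2.confidence == pytest.approx(0.0)


def test_empty_antecedent_confidence_is_prior():
    ds = make_dataset(NSP=[1] * 8 + [3] * 2)
    rule = rule_support_confidence([], 3, ds)
    assert rule.support == 1.0
    assert rule.confidence == pytest.approx(0.2)


def test_zero_match_confidence_is_none():
    ds = make_dataset(ASTV=[10.0, 20.0], NSP=[1, 3])
    rule = rule_support_confidence([Condition("ASTV", 90.0, 99.0)], 3, ds)
    assert rule.match_count == 0 and rule.confidence is None


def test_condition_interval_semantics():
    cond = Condition("ASTV", 10.0, 20.0)
    got = cond.matches(np.array([9.9, 10.0, 19.99, 20.0]))
    np.testing.assert_array_equal(got, [False, True, True, False])
    closed = Condition("ASTV", 10.0, 20.0, hi_closed=True)
    assert closed.matches(np.array([20.0]))[0]


# -- forward selection --------------------------------------------------------

def equal_width_bins(ds, features, k):
    out = {}
    for f in features:
        v = ds.frame[f].to_numpy(float)
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:
            hi = lo + 1.0
        out[f] = BinningScheme(f, tuple(np.linspace(lo, hi, k + 1)))
    return out


def test_forward_trace_confidence_strictly_increases(rng):
    ds = random_dataset(rng, 150, ["LB", "AC", "FM", "UC"], levels=8)
    bins = equal_width_bins(ds, ["LB", "AC", "FM", "UC"], 4)
    _, trace = forward_stepwise_rule(ds, bins, 1, min_support=5)
    confs = [c for _, _, c in trace.steps]
    assert all(b > a for a, b in zip(confs, confs[1:]))
    assert trace.stopping_reason in {"confidence_1", "no_improvement",
                                     "support_floor", "feature_exhausted"}


def test_forward_respects_support_floor(rng):
    ds = random_dataset(rng, 100, ["LB", "AC"], levels=5)
    bins = equal_width_bins(ds, ["LB", "AC"], 4)
    rule, _ = forward_stepwise_rule(ds, bins, 2, min_support=10)
    assert rule.match_count >= 10 or not rule.antecedent


def test_forward_each_feature_used_once(rng):
    ds = random_dataset(rng, 200, ["LB", "AC", "FM"], levels=6)
    bins = equal_width_bins(ds, ["LB", "AC", "FM"], 4)
    rule, _ = forward_stepwise_rule(ds, bins, 3, min_support=5)
    feats = [c.feature for c in rule.antecedent]
    assert len(feats) == len(set(feats))


def test_forward_deterministic(rng):
    ds = random_dataset(rng, 200, ["LB", "AC", "FM", "UC"], levels=6)
    bins = equal_width_bins(ds, ["LB", "AC", "FM", "UC"], 4)
    r1, t1 = forward_stepwise_rule(ds, bins, 3, min_support=5)
    r2, t2 = forward_stepwise_rule(ds, bins, 3, min_support=5)
    assert r1 == r2
    assert t1.steps == t2.steps


def test_forward_rejects_absent_class_and_bad_support(small_dataset):
    bins = equal_width_bins(small_dataset, ["ASTV"], 3)
    ds = make_dataset(ASTV=[1.0, 2.0], NSP=[1, 1])
    with pytest.raises(ValueError, match="absent"):
        forward_stepwise_rule(ds, equal_width_bins(ds, ["ASTV"], 2), 3)
    with pytest.raises(ValueError, match="min_support"):
        forward_stepwise_rule(small_dataset, bins, 1, min_support=0)


def test_forward_finds_pure_single_condition():
    # ASTV in [80, 100] is purely pathological by construction
    astv = np.array([10, 20, 30, 40, 85, 90, 95, 99, 88, 92], float)
    nsp = np.where(astv >= 80, 3, 1)
    ds = make_dataset(ASTV=astv, NSP=nsp)
    bins = {"ASTV": BinningScheme("ASTV", (0.0, 40.0, 80.0, 100.0))}
    rule, trace = forward_stepwise_rule(ds, bins, 3, min_support=5)
    assert trace.stopping_reason == "confidence_1"
    assert rule.confidence == 1.0
    assert rule.antecedent[0].feature == "ASTV"
    assert rule.antecedent[0].lo >= 80.0


def test_refinement_widens_to_purity_boundary():
    # greedy enters via the [60, 80) bin; the pure region is [40, 100]
    astv = np.concatenate([np.linspace(0, 39, 30),
                           np.linspace(41, 99, 30)])
    nsp = np.where(astv > 40, 3, 1)
    ds = make_dataset(ASTV=astv, NSP=nsp)
    bins = {"ASTV": BinningScheme("ASTV", (0.0, 20.0, 40.0, 60.0, 80.0, 100.0))}
    rule, _ = forward_stepwise_rule(ds, bins, 3, min_support=5)
    assert rule.confidence == 1.0
    assert rule.match_count == 30      # the whole pure region, not one bin


def test_greedy_not_above_exhaustive(rng):
    for _ in range(10):
        ds = random_dataset(rng, 120, ["LB", "AC", "FM"], levels=5)
        bins = equal_width_bins(ds, ["LB", "AC", "FM"], 3)
        rule, trace = forward_stepwise_rule(ds, bins, 1, min_support=5)
        length = max(1, len(trace.steps))
        best = exhaustive_best_rule(ds, bins, 1, min_support=5, max_len=length)
        greedy_conf = trace.steps[-1][2] if trace.steps else \
            rule_support_confidence([], 1, ds).confidence
        assert greedy_conf <= best.confidence + 1e-12


def test_exhaustive_guard():
    ds = make_dataset(ASTV=[1.0, 2.0, 3.0], NSP=[1, 2, 3])
    bins = equal_width_bins(ds, ["ASTV", "LB"], 2)
    with pytest.raises(ValueError, match="guard"):
        exhaustive_best_rule(ds, bins, 1, max_len=2, guard=1)


def test_rule_to_text_renders():
    rule = AssociationRule(
        (Condition("ASTV", 80.0, 100.0, hi_closed=True),), 3, 0.1, 1.0, 12)
    text = rule_to_text(rule)
    assert "pathology" in text and "confidence 100.0%" in text
    empty = AssociationRule((), 1, 1.0, None, 0)
    assert "undefined" in rule_to_text(empty)
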