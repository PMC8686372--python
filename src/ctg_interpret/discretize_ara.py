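"""Class-guided discretization and forward-stepwise association-rule mining.

Classical frequent-itemset miners cannot surface rules for the rare
pathology class (8% of records), and re-weighting the minority class biases
the rule statistics.  The miner here instead maximises rule *confidence*
directly: starting from an empty antecedent it greedily adds, one feature at
a time, the discretized interval condition that most increases the
confidence of ``antecedent -> target class``, subject to an absolute
match-count floor.  This reaches high-purity rules for rare classes without
any re-weighting.

Features are first discretized by the fetal-status distribution: candidate
cut points sit where the majority class changes along the sorted feature,
then adjacent bins with the most similar class-proportion vectors are merged
until the bin count and minimum bin mass constraints hold.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np

from ctg_interpret.ctg_data import CTG_FEATURES, CTGDataset

#: Default absolute support floor: keeps rare-class rules reachable while
#: barring singleton "rules".
DEFAULT_MIN_SUPPORT = 5

_FEATURE_ORDER = {f: i for i, f in enumerate(CTG_FEATURES)}


@dataclasses.dataclass(frozen=True)
class BinningScheme:
    """Ordered interval partition of one feature, [lo, hi) with closed last bin."""

    feature: str
    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValueError("need at least two edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            if not (len(self.edges) == 2 and self.edges[0] == self.edges[1]):
                raise ValueError("edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_index(self, values: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.edges, values, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


@dataclasses.dataclass(frozen=True)
class Condition:
    """Interval condition on one feature: lo <= value < hi (or <= hi if closed)."""

    feature: str
    lo: float
    hi: float
    hi_closed: bool = False
    bin_start: int = 0
    bin_span: int = 1

    def matches(self, values: np.ndarray) -> np.ndarray:
        upper = values <= self.hi if self.hi_closed else values < self.hi
        return (values >= self.lo) & upper

    def __str__(self) -> str:
        if self.hi_closed and np.isfinite(self.hi):
            return f"{self.feature} > {self.lo:g}" if self.bin_start > 0 and self.bin_span > 1 \
                else f"{self.feature}: [{self.lo:g}, {self.hi:g}]"
        return f"{self.feature}: [{self.lo:g}, {self.hi:g})"


@dataclasses.dataclass
class AssociationRule:
    """Conjunction of interval conditions implying an NSP class."""

    antecedent: tuple[Condition, ...]
    consequent: int
    support: float
    confidence: float | None
    match_count: int


@dataclasses.dataclass
class RuleTrace:
    """Greedy path of the forward selection: one step per added condition."""

    steps: list[tuple[Condition, float, float]]  # (condition, support, confidence)
    stopping_reason: str  # confidence_1 | no_improvement | support_floor | feature_exhausted


def fit_class_distribution_bins(dataset: CTGDataset, feature: str,
                                max_bins: int = 8,
                                min_frac: float = 0.05) -> BinningScheme:
    """Discretize one feature by the fetal-status distribution.

    Candidate cuts sit at midpoints between consecutive distinct values whose
    majority class differs; adjacent bins are then merged greedily (smallest
    L1 distance between class-proportion vectors first, lowest index on ties)
    until at most ``max_bins`` remain and each holds at least ``min_frac`` of
    the records.
    """
    if max_bins < 2:
        raise ValueError("max_bins must be >= 2")
    if not 0.0 < min_frac < 0.5:
        raise ValueError("min_frac must lie in (0, 0.5)")
    v = dataset.frame[feature].to_numpy(float)
    y = dataset.nsp
    order = np.argsort(v, kind="stable")
    v_sorted, y_sorted = v[order], y[order]
    uniq, starts = np.unique(v_sorted, return_index=True)
    if len(uniq) == 1:
        return BinningScheme(feature, (float(uniq[0]), float(uniq[0] + 1.0)))

    # group sorted records into blocks of roughly equal mass (never splitting
    # tied values) and take the majority class per block; for small samples
    # each distinct value is its own block
    bounds = list(starts) + [len(v_sorted)]
    target = max(1, len(v_sorted) // 200)
    blocks: list[tuple[int, int]] = []
    s = 0
    for i in range(len(uniq)):
        if bounds[i + 1] - s >= target or i == len(uniq) - 1:
            blocks.append((s, bounds[i + 1]))
            s = bounds[i + 1]
    majors = []
    for s, e in blocks:
        counts = np.bincount(y_sorted[s:e], minlength=4)[1:]
        majors.append(int(np.argmax(counts)) + 1)  # argmax ties -> lower class
    cuts = []
    for i in range(len(blocks) - 1):
        if majors[i] == majors[i + 1]:
            continue
        # refine the cut to the best split inside the two adjacent blocks:
        # minimise records on the wrong side of their block's majority
        s, e = blocks[i][0], blocks[i + 1][1]
        seg_v, seg_y = v_sorted[s:e], y_sorted[s:e]
        left_wrong = np.cumsum(seg_y != majors[i])
        right_wrong = np.cumsum((seg_y != majors[i + 1])[::-1])[::-1]
        # split after position j (1..len-1), only between distinct values
        valid = seg_v[:-1] < seg_v[1:]
        cost = left_wrong[:-1] + right_wrong[1:]
        cost = np.where(valid, cost, np.iinfo(np.int64).max)
        j = int(np.argmin(cost))
        cuts.append(float((seg_v[j] + seg_v[j + 1]) / 2.0))
    cuts = sorted(set(cuts))
    edges = [float(v_sorted[0])] + cuts + [float(v_sorted[-1])]
    if len(edges) == 2:
        if edges[0] == edges[1]:
            edges[1] += 1.0
        return BinningScheme(feature, tuple(edges))

    # per-bin class counts for the merge criterion
    scheme = BinningScheme(feature, tuple(edges))
    idx = scheme.bin_index(v)
    counts = np.zeros((scheme.n_bins, 3))
    np.add.at(counts, (idx, y - 1), 1.0)

    n = len(v)
    edges_arr = np.asarray(edges)

    def merge(i: int) -> None:
        nonlocal counts, edges_arr
        counts[i] += counts[i + 1]
        counts = np.delete(counts, i + 1, axis=0)
        edges_arr = np.delete(edges_arr, i + 1)

    # phase 1: repair undersized bins, merging each into its most similar
    # neighbour so well-populated informative bins survive
    while counts.shape[0] > 1:
        sizes = counts.sum(axis=1)
        small = sizes < min_frac * n
        if not small.any():
            break
        props = counts / np.maximum(sizes, 1.0)[:, None]
        dists = np.abs(props[1:] - props[:-1]).sum(axis=1)
        involved = small[:-1] | small[1:]
        dists = np.where(involved, dists, np.inf)
        merge(int(np.argmin(dists)))  # argmin ties -> lowest index
    # phase 2: reduce to max_bins by globally most similar adjacent pairs
    while counts.shape[0] > max_bins:
        sizes = counts.sum(axis=1)
        props = counts / np.maximum(sizes, 1.0)[:, None]
        dists = np.abs(props[1:] - props[:-1]).sum(axis=1)
        merge(int(np.argmin(dists)))
    return BinningScheme(feature, tuple(float(e) for e in edges_arr))


def fit_all_bins(dataset: CTGDataset, max_bins: int = 8,
                 min_frac: float = 0.05) -> dict[str, BinningScheme]:
    return {f: fit_class_distribution_bins(dataset, f, max_bins, min_frac)
            for f in CTG_FEATURES}


def rule_support_confidence(antecedent: Sequence[Condition], consequent: int,
                            dataset: CTGDataset) -> AssociationRule:
    """Support, confidence and match count of ``antecedent -> consequent``.

    The empty antecedent matches everything, so its confidence is the class
    prior.  Zero matches give confidence ``None`` (undefined), never NaN.
    """
    mask = np.ones(dataset.n, bool)
    for cond in antecedent:
        mask &= cond.matches(dataset.frame[cond.feature].to_numpy(float))
    m = int(mask.sum())
    support = m / dataset.n
    conf = float(np.mean(dataset.nsp[mask] == consequent)) if m else None
    return AssociationRule(tuple(antecedent), consequent, support, conf, m)


def _candidate_conditions(scheme: BinningScheme) -> list[Condition]:
    """All single bins and unions of adjacent bins spanning <= half the bins."""
    k = scheme.n_bins
    max_span = max(1, k // 2)
    out = []
    for span in range(1, max_span + 1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            out.append(Condition(
                feature=scheme.feature,
                lo=float(scheme.edges[i]), hi=float(scheme.edges[j + 1]),
                hi_closed=(j == k - 1), bin_start=i, bin_span=span))
    return out


def forward_stepwise_rule(dataset: CTGDataset, bins: Mapping[str, BinningScheme],
                          target_class: int,
                          min_support: int = DEFAULT_MIN_SUPPORT
                          ) -> tuple[AssociationRule, RuleTrace]:
    """Greedy confidence-maximising forward selection of interval conditions.

    At each step every unused feature contributes its candidate bin (and
    adjacent-bin-union) conditions; the condition giving the highest
    confidence of ``antecedent ∪ {condition} -> target_class`` with at least
    ``min_support`` matching records is added.  Ties break by higher support,
    then canonical feature order, then lower bin start, then shorter span.
    Stops at confidence 1, when no candidate strictly improves confidence,
    or when the support floor blocks every candidate.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    nsp = dataset.nsp
    if not np.any(nsp == target_class):
        raise ValueError(f"target class {target_class} absent from dataset")

    feat_values = {f: dataset.frame[f].to_numpy(float) for f in bins}
    cond_masks = {f: [(c, c.matches(feat_values[f])) for c in _candidate_conditions(s)]
                  for f, s in bins.items()}
    is_target = nsp == target_class

    mask = np.ones(dataset.n, bool)
    used: set[str] = set()
    antecedent: list[Condition] = []
    conf_cur = float(is_target.mean())
    steps: list[tuple[Condition, float, float]] = []
    reason = "feature_exhausted"

    while True:
        remaining = [f for f in bins if f not in used]
        if not remaining:
            reason = "feature_exhausted"
            break
        best = None  # (conf, m, -order, -start, -span) maximised lexicographically
        any_candidate = False
        for f in remaining:
            for cond, cmask in cond_masks[f]:
                new_mask = mask & cmask
                m = int(new_mask.sum())
                if m < min_support:
                    continue
                any_candidate = True
                conf = float(is_target[new_mask].sum()) / m
                key = (conf, m, -_FEATURE_ORDER[f], -cond.bin_start, -cond.bin_span)
                if best is None or key > best[0]:
                    best = (key, cond, new_mask, m, conf)
        if not any_candidate:
            reason = "support_floor"
            break
        _, cond, new_mask, m, conf = best
        if conf <= conf_cur + 1e-15:
            reason = "no_improvement"
            break
        mask = new_mask
        used.add(cond.feature)
        antecedent.append(cond)
        conf_cur = conf
        steps.append((cond, m / dataset.n, conf))
        if conf >= 1.0:
            reason = "confidence_1"
            break

    if antecedent:
        _refine_conditions(antecedent, bins, feat_values, is_target,
                           min_support, dataset.n)

    rule = rule_support_confidence(antecedent, target_class, dataset)
    return rule, RuleTrace(steps=steps, stopping_reason=reason)


def _refine_conditions(antecedent: list[Condition],
                       bins: Mapping[str, BinningScheme],
                       feat_values: Mapping[str, np.ndarray],
                       is_target: np.ndarray, min_support: int,
                       n: int) -> None:
    """Coordinate-descent polish of a mined antecedent.

    Each condition in turn is replaced by the interval (any union of
    adjacent bins of its feature, except the tautological full range) that
    maximises (confidence, match count) of the whole rule.  This widens a
    rule to the full extent its purity allows — the first pure sub-interval
    the greedy entered is grown out to the purity boundary — and narrows
    conditions the greedy overshot.  Strict lexicographic improvement
    guarantees termination.
    """
    def evaluate(conds: Sequence[Condition]) -> tuple[float, int]:
        mask = np.ones(n, bool)
        for c in conds:
            mask &= c.matches(feat_values[c.feature])
        m = int(mask.sum())
        if m < min_support:
            return (-1.0, 0)
        return (float(is_target[mask].sum()) / m, m)

    for _ in range(50):
        changed = False
        for pos, cond in enumerate(antecedent):
            scheme = bins[cond.feature]
            k = scheme.n_bins
            cur_key = evaluate(antecedent)
            best_key, best_c = cur_key, cond
            for span in range(1, k):  # span == k would drop the condition
                for start in range(0, k - span + 1):
                    cand = Condition(
                        feature=cond.feature,
                        lo=float(scheme.edges[start]),
                        hi=float(scheme.edges[start + span]),
                        hi_closed=(start + span == k), bin_start=start,
                        bin_span=span)
                    key = evaluate(antecedent[:pos] + [cand] + antecedent[pos + 1:])
                    if key > best_key:
                        best_key, best_c = key, cand
            if best_c is not cond:
                antecedent[pos] = best_c
                changed = True
        if not changed:
            break

    # fine pass: slide each interval boundary exactly, one side at a time.
    # Bin merging can delete the very cut a pure rule needs, so coarse bins
    # alone cannot always stop an interval at the purity boundary.  Given
    # the other conditions' mask, the best endpoint over the actual feature
    # values is found by a sorted cumulative scan; accepted boundaries sit
    # at midpoints between the last included and first excluded value.  A
    # slide that leaves (confidence, matches) unchanged but narrows the
    # interval is also taken: it trims overshoot across empty value bands,
    # which can block the widening of another condition.
    for _ in range(50):
        changed = False
        for pos in range(len(antecedent)):
            for side in ("hi", "lo"):
                cond = antecedent[pos]
                others = np.ones(n, bool)
                for c2 in antecedent[:pos] + antecedent[pos + 1:]:
                    others &= c2.matches(feat_values[c2.feature])
                cand = _slide_boundary(cond, side, feat_values[cond.feature],
                                       is_target, others, min_support)
                if cand is None or cand == cond:
                    continue
                new_key = evaluate(antecedent[:pos] + [cand]
                                   + antecedent[pos + 1:])
                cur_key = evaluate(antecedent)
                if new_key > cur_key or (new_key == cur_key
                                         and cand.hi - cand.lo
                                         < cond.hi - cond.lo):
                    antecedent[pos] = cand
                    changed = True
        if not changed:
            break


def _slide_boundary(cond: Condition, side: str, values: np.ndarray,
                    is_target: np.ndarray, others: np.ndarray,
                    min_support: int) -> Condition | None:
    """Best replacement for one endpoint of ``cond``, the other side fixed.

    Restricted to records matching the rest of the antecedent (``others``),
    sorts the feature values and scans cumulative target counts, so every
    achievable endpoint is evaluated exactly once.  Boundaries snap to the
    observed values themselves (interval closed at the last included value)
    rather than to gap midpoints, so a wide empty value band never inflates
    the stated interval.  Returns ``None`` when no candidate meets the
    support floor.
    """
    keep = others.copy()
    if side == "hi":
        keep &= values >= cond.lo
    else:
        keep &= (values <= cond.hi) if cond.hi_closed else (values < cond.hi)
    v = values[keep]
    t = is_target[keep]
    if len(v) < min_support:
        return None
    order = np.argsort(v, kind="stable")
    v, t = v[order], t[order]
    if side == "lo":  # scan suffixes as reversed prefixes
        v, t = -v[::-1], t[::-1]
    hits = np.cumsum(t)
    m = np.arange(1, len(v) + 1)
    # a cut after position j is realisable only between distinct values
    ok = np.empty(len(v), bool)
    ok[:-1] = v[:-1] < v[1:]
    ok[-1] = True
    ok &= m >= min_support
    if not ok.any():
        return None
    conf = np.where(ok, hits / m, -1.0)
    m_ok = np.where(ok, m, 0)
    best = int(np.lexsort((m_ok, conf))[-1])  # ties -> larger match count
    if side == "hi":
        return dataclasses.replace(cond, hi=float(v[best]), hi_closed=True,
                                   bin_start=0, bin_span=1)
    return dataclasses.replace(cond, lo=float(-v[best]),
                               bin_start=0, bin_span=1)


def exhaustive_best_rule(dataset: CTGDataset, bins: Mapping[str, BinningScheme],
                         target_class: int,
                         min_support: int = DEFAULT_MIN_SUPPORT,
                         max_len: int = 2,
                         guard: int = 1_000_000) -> AssociationRule:
    """Globally confidence-maximal rule over all antecedents of size <= max_len.

    Brute-force enumeration over the same candidate condition set as the
    greedy miner; ties break by higher support then the greedy miner's
    deterministic ordering.  Refuses when the candidate count would exceed
    ``guard``.
    """
    feats = [f for f in bins]
    conds = {f: _candidate_conditions(bins[f]) for f in feats}
    total = 0
    for size in range(1, max_len + 1):
        for combo in itertools.combinations(feats, size):
            prod = 1
            for f in combo:
                prod *= len(conds[f])
            total += prod
    if total > guard:
        raise ValueError(f"candidate count {total} exceeds enumeration guard {guard}")

    feat_values = {f: dataset.frame[f].to_numpy(float) for f in feats}
    masks = {f: [(c, c.matches(feat_values[f])) for c in conds[f]] for f in feats}
    is_target = dataset.nsp == target_class

    best_key = None
    best_rule = rule_support_confidence([], target_class, dataset)
    for size in range(1, max_len + 1):
        for combo in itertools.combinations(feats, size):
            for picks in itertools.product(*(masks[f] for f in combo)):
                mask = picks[0][1].copy()
                for _, cm in picks[1:]:
                    mask &= cm
                m = int(mask.sum())
                if m < min_support:
                    continue
                conf = float(is_target[mask].sum()) / m
                order_key = tuple((-_FEATURE_ORDER[c.feature], -c.bin_start, -c.bin_span)
                                  for c, _ in picks)
                key = (conf, m, order_key)
                if best_key is None or key > best_key:
                    best_key = key
                    best_rule = AssociationRule(
                        tuple(c for c, _ in picks), target_class,
                        m / dataset.n, conf, m)
    return best_rule


def rule_to_text(rule: AssociationRule, class_names={1: "normal", 2: "suspicious", 3: "pathology"}) -> str:
    ante = "; ".join(str(c) for c in rule.antecedent) or "(any record)"
    conf = "undefined" if rule.confidence is None else f"{100 * rule.confidence:.1f}%"
    return (f"IF {ante} THEN {class_names[rule.consequent]} "
            f"(support {100 * rule.support:.1f}%, confidence {conf}, "
            f"matches {rule.match_count})")
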