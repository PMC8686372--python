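"""Spearman screening, correlated-feature grouping and class-proportion profiles.

The fetal-state label NSP is an ordered grading (normal < suspicious <
pathology), so rank correlation is the natural association measure between
it and each CTG feature.  Ties receive mid-ranks; NSP, though heavily tied,
is ranked like any other variable.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ctg_interpret.ctg_data import CTG_FEATURES, CTGDataset

#: Default |rho| cutoff for grouping highly correlated features.
DEFAULT_GROUP_THRESHOLD = 0.7

#: Landmark cut points quoted in clinical discussion of the profiles:
#: ASTV below 18 is essentially always normal, above 80 mostly pathological;
#: normal baselines concentrate in 111-120 bpm.
LANDMARK_EDGES = {"ASTV": [0.0, 18.0, 80.0, 100.0], "LB": [100.0, 111.0, 120.0, 180.0]}


@dataclasses.dataclass
class CorrelationResult:
    """Spearman rho and p-value matrices over the 21 features plus NSP."""

    variables: list[str]
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    n: int
    flagged: list[str]  # constant columns with undefined correlation


@dataclasses.dataclass
class BinClassProportions:
    """Per-bin record counts and class-proportion triples for one feature."""

    feature: str
    edges: list[float]
    counts: list[int]
    proportions: list[tuple[float, float, float] | None]  # None for empty bins


def spearman_matrix(dataset: CTGDataset) -> CorrelationResult:
    """Spearman rank correlation of the 21 features and NSP.

    Mid-ranks for ties; two-sided p-values from the large-sample t
    approximation.  A constant column has no rank variance; its entries are
    flagged rather than silently zeroed.
    """
    if dataset.n < 3:
        raise ValueError("need at least 3 records")
    variables = list(CTG_FEATURES) + ["NSP"]
    X = dataset.frame[variables].to_numpy(float)
    flagged = [v for v, col in zip(variables, X.T) if np.ptp(col) == 0]
    ranks = stats.rankdata(X, axis=0)  # mid-ranks for ties
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        n = dataset.n
        r2 = np.clip(rho * rho, 0.0, 1.0)
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - r2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p[r2 >= 1.0] = 0.0
        p[~np.isfinite(rho)] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho_df = pd.DataFrame(rho, index=variables, columns=variables)
    p_df = pd.DataFrame(p, index=variables, columns=variables)
    return CorrelationResult(variables=variables, rho=rho_df, pvalues=p_df,
                             n=dataset.n, flagged=flagged)


def nsp_correlations(corr: CorrelationResult) -> pd.DataFrame:
    """Features ranked by |rho| with NSP, with p-values and a Bonferroni column."""
    rows = []
    m = len(CTG_FEATURES)
    for feat in CTG_FEATURES:
        r = corr.rho.loc[feat, "NSP"]
        p = corr.pvalues.loc[feat, "NSP"]
        rows.append({"feature": feat, "rho": r, "p": p,
                     "p_bonferroni": min(1.0, p * m)})
    df = pd.DataFrame(rows)
    return df.reindex(df["rho"].abs().sort_values(ascending=False).index).reset_index(drop=True)


def correlated_groups(corr: CorrelationResult,
                      threshold: float = DEFAULT_GROUP_THRESHOLD) -> list[list[str]]:
    """Disjoint groups of features linked by |rho| >= threshold.

    Groups are the non-singleton connected components of the thresholded
    correlation graph over the 21 features (NSP excluded), ordered by the
    canonical position of each group's first member.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    order = {f: i for i, f in enumerate(CTG_FEATURES)}
    g = nx.Graph()
    g.add_nodes_from(CTG_FEATURES)
    for i, a in enumerate(CTG_FEATURES):
        for b in CTG_FEATURES[i + 1:]:
            r = corr.rho.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                g.add_edge(a, b)
    groups = [sorted(c, key=order.get) for c in nx.connected_components(g) if len(c) > 1]
    return sorted(groups, key=lambda grp: order[grp[0]])


def stacked_proportions(dataset: CTGDataset, feature: str,
                        edges: list[float]) -> BinClassProportions:
    """Class-proportion triples per bin of one feature.

    Bins are half-open ``[lo, hi)`` except the last, which is closed.  Edges
    not covering the observed range are auto-extended with a warning so every
    record lands in a bin.
    """
    if feature not in CTG_FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    edges = [float(e) for e in edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    v = dataset.frame[feature].to_numpy(float)
    if v.min() < edges[0] or v.max() > edges[-1]:
        warnings.warn(f"extending {feature} bin edges to cover observed range")
        edges = [min(edges[0], float(v.min()))] + edges[1:-1] + [max(edges[-1], float(v.max()))]
    nsp = dataset.nsp
    idx = np.searchsorted(edges, v, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)  # closed last bin
    counts, props = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        c = int(mask.sum())
        counts.append(c)
        if c == 0:
            props.append(None)
        else:
            sub = nsp[mask]
            props.append(tuple(float(np.mean(sub == k)) for k in (1, 2, 3)))
    return BinClassProportions(feature=feature, edges=edges,
                               counts=counts, proportions=props)


def equal_width_edges(dataset: CTGDataset, feature: str, bins: int = 10) -> list[float]:
    v = dataset.frame[feature].to_numpy(float)
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        hi = lo + 1.0
    return list(np.linspace(lo, hi, bins + 1))


def proportions_table(bp: BinClassProportions) -> pd.DataFrame:
    rows = []
    for i, (c, p) in enumerate(zip(bp.counts, bp.proportions)):
        lo, hi = bp.edges[i], bp.edges[i + 1]
        row = {"bin": f"[{lo:g}, {hi:g}{']' if i == len(bp.counts) - 1 else ')'}",
               "count": c}
        if p is None:
            row.update({"normal": np.nan, "suspicious": np.nan, "pathology": np.nan})
        else:
            row.update({"normal": p[0], "suspicious": p[1], "pathology": p[2]})
        rows.append(row)
    return pd.DataFrame(rows)
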