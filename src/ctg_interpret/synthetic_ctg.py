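"""CTG-like synthetic data with known ground truth.

The generator emulates the structural properties of antepartum CTG summary
tables that the downstream stages rely on, without attempting to reproduce
any real dataset's joint distribution:

* the heavy fetal-state class imbalance (normal/suspicious/pathology
  defaulting to 78/14/8 percent);
* per-class feature shifts in the clinically reported directions
  (pathological traces run high in ASTV, ALTV, prolonged decelerations and
  baseline, and low in accelerations and short-term variability);
* deterministically planted association-rule regions with exact purity, for
  testing the rule miner end to end;
* samples drawn from an explicit latent-factor covariance structure, for
  testing the SEM engine against known parameters.

Continuous features use truncated normals; event counts use Poisson draws
over a nominal 1800 s trace converted to events/second; the histogram
tendency is categorical.  A single integer seed drives one root generator
from which stage-local substreams are derived.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ctg_interpret.ctg_data import CTG_FEATURES, CTGDataset
from ctg_interpret.sem_engine import SEMModel, structural_model

#: Nominal trace length (seconds) converting event counts to events/second.
TRACE_SECONDS = 1800.0

#: Features generated as Poisson event counts over the trace.
RATE_FEATURES = ("AC", "FM", "UC", "DL", "DS", "DP")

#: Per-class Poisson rates (events/second), order (normal, suspicious, pathology).
DEFAULT_RATES: dict[str, tuple[float, float, float]] = {
    "AC": (0.0040, 0.0010, 0.0004),
    "FM": (0.0050, 0.0050, 0.0020),
    "UC": (0.0050, 0.0030, 0.0020),
    "DL": (0.0020, 0.0020, 0.0040),
    "DS": (0.0000, 0.0000, 0.0005),
    "DP": (0.0001, 0.0004, 0.0030),
}

#: Per-class (mean, sd) for truncated-normal features, with domain bounds.
#: Class order (normal, suspicious, pathology).
DEFAULT_LOCATIONS: dict[str, dict] = {
    "LB":       {"mean": (120.0, 135.0, 145.0), "sd": (10.0, 10.0, 12.0), "lo": 100.0, "hi": 180.0},
    "ASTV":     {"mean": (40.0, 62.0, 75.0),   "sd": (12.0, 12.0, 12.0), "lo": 0.0,   "hi": 100.0},
    "MSTV":     {"mean": (1.6, 0.8, 0.7),      "sd": (0.5, 0.3, 0.3),    "lo": 0.2,   "hi": 7.0},
    "ALTV":     {"mean": (5.0, 20.0, 32.0),    "sd": (6.0, 10.0, 14.0),  "lo": 0.0,   "hi": 100.0},
    "MLTV":     {"mean": (9.0, 8.0, 6.0),      "sd": (4.0, 4.0, 4.0),    "lo": 0.0,   "hi": 50.0},
    "Min":      {"mean": (90.0, 100.0, 105.0), "sd": (20.0, 18.0, 18.0), "lo": 50.0,  "hi": 159.0},
    "Width":    {"mean": (75.0, 55.0, 50.0),   "sd": (25.0, 20.0, 25.0), "lo": 5.0,   "hi": 170.0},
    "Mode":     {"mean": (138.0, 146.0, 115.0), "sd": (12.0, 12.0, 20.0), "lo": 60.0, "hi": 190.0},
    "Mean":     {"mean": (135.0, 142.0, 110.0), "sd": (12.0, 12.0, 18.0), "lo": 60.0, "hi": 190.0},
    "Median":   {"mean": (138.0, 144.0, 114.0), "sd": (12.0, 12.0, 18.0), "lo": 60.0, "hi": 190.0},
    "Variance": {"mean": (22.0, 14.0, 90.0),   "sd": (16.0, 10.0, 60.0), "lo": 0.0,   "hi": 270.0},
}

#: Per-class probabilities over Tendency values (-1, 0, 1).
DEFAULT_TENDENCY = {
    1: (0.10, 0.60, 0.30),
    2: (0.20, 0.50, 0.30),
    3: (0.40, 0.40, 0.20),
}

COUNT_FEATURES = {"Nmax": (4.0, 3.0, 3.0), "Nzeros": (0.3, 0.3, 0.7)}


class ConfigError(ValueError):
    """Inconsistent synthetic-data configuration."""


def neutral_locations() -> dict[str, dict]:
    """Location table with no class signal (all classes share the normal-class
    distribution); useful for isolating planted-rule structure in tests."""
    out = {}
    for feat, spec in DEFAULT_LOCATIONS.items():
        out[feat] = {"mean": (spec["mean"][0],) * 3, "sd": (spec["sd"][0],) * 3,
                     "lo": spec["lo"], "hi": spec["hi"]}
    return out


def neutral_rates() -> dict[str, tuple]:
    """Event rates with no class signal."""
    return {f: (DEFAULT_RATES[f][0],) * 3 for f in DEFAULT_RATES}


@dataclasses.dataclass(frozen=True)
class PlantedRule:
    """A rectangular feature region whose records are forced to one class."""

    conditions: tuple[tuple[str, tuple[float, float]], ...]
    target_class: int
    purity: float = 1.0
    region_fraction: float = 0.05

    def __post_init__(self) -> None:
        for feat, (lo, hi) in self.conditions:
            if feat not in CTG_FEATURES:
                raise ConfigError(f"unknown feature {feat!r}")
            if not lo < hi:
                raise ConfigError(f"empty interval for {feat}: [{lo}, {hi})")
        if not 0.0 <= self.purity <= 1.0:
            raise ConfigError("purity must lie in [0, 1]")
        if not 0.0 < self.region_fraction < 1.0:
            raise ConfigError("region_fraction must lie in (0, 1)")
        if self.target_class not in (1, 2, 3):
            raise ConfigError("target_class must be an NSP value")


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic CTG dataset."""

    n: int = 2000
    class_proportions: tuple[float, float, float] = (0.78, 0.14, 0.08)
    seed: int = 0
    planted_rules: tuple[PlantedRule, ...] = ()
    locations: Mapping[str, dict] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LOCATIONS))
    rates: Mapping[str, tuple] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RATES))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        p = np.asarray(self.class_proportions, float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("class proportions must be >= 0 and sum to 1")
        for feat, spec in self.locations.items():
            if np.any(np.asarray(spec["sd"]) <= 0):
                raise ConfigError(f"non-positive scale for {feat}")


def plant_rule(config: SynthConfig, rule: PlantedRule) -> SynthConfig:
    """Return a new config whose datasets contain the planted region.

    Two rules over the same feature rectangle with different target classes
    are contradictory and rejected.
    """
    for other in config.planted_rules:
        if other.target_class != rule.target_class:
            if _regions_overlap(other, rule):
                raise ConfigError(
                    "contradictory planted rules: overlapping regions with "
                    f"classes {other.target_class} and {rule.target_class}")
    return dataclasses.replace(config,
                               planted_rules=config.planted_rules + (rule,))


def _regions_overlap(a: PlantedRule, b: PlantedRule) -> bool:
    fa = dict(a.conditions)
    fb = dict(b.conditions)
    shared = set(fa) & set(fb)
    if set(fa) != set(fb):
        # regions over different feature sets are unconstrained elsewhere and
        # only conflict when every shared interval overlaps
        if not shared:
            return True
    for feat in shared:
        lo_a, hi_a = fa[feat]
        lo_b, hi_b = fb[feat]
        if hi_a <= lo_b or hi_b <= lo_a:
            return False
    return True


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Rejection-free truncated normal via inverse-cdf sampling."""
    from scipy import stats
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    u = rng.uniform(size=size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_dataset(config: SynthConfig) -> CTGDataset:
    """Draw a CTG table with the configured class mix and feature shifts.

    Class labels are multinomial; features are drawn per class; planted
    regions are carved from existing records last, so their purity is
    exact (records outside the region are nudged out of it).
    """
    root = np.random.default_rng(config.seed)
    streams = root.spawn(4)
    rng_class, rng_feat, rng_rule, _ = streams

    p = np.asarray(config.class_proportions, float)
    labels = rng_class.choice([1, 2, 3], size=config.n, p=p)
    warning = ""
    if np.any(p * config.n < 1):
        warning = "degenerate proportions: some class has expected count < 1"

    n = config.n
    cols: dict[str, np.ndarray] = {}
    cls_idx = labels - 1
    for feat, spec in config.locations.items():
        mean = np.asarray(spec["mean"])[cls_idx]
        sd = np.asarray(spec["sd"])[cls_idx]
        cols[feat] = _trunc_normal(rng_feat, mean, sd, spec["lo"], spec["hi"], n)
    for feat in RATE_FEATURES:
        rate = np.asarray(config.rates[feat])[cls_idx]
        counts = rng_feat.poisson(rate * TRACE_SECONDS)
        cols[feat] = counts / TRACE_SECONDS
    for feat, means in COUNT_FEATURES.items():
        lam = np.asarray(means)[cls_idx]
        cols[feat] = rng_feat.poisson(lam).astype(float)
    tend_p = np.vstack([DEFAULT_TENDENCY[c] for c in (1, 2, 3)])
    u = rng_feat.uniform(size=n)
    cum = np.cumsum(tend_p[cls_idx], axis=1)
    cols["Tendency"] = np.array([-1, 0, 1])[(u[:, None] > cum).sum(axis=1)]

    # histogram consistency: Max derived, centre statistics clipped into range
    cols["Max"] = cols["Min"] + cols["Width"]
    for feat in ("Mode", "Mean", "Median"):
        cols[feat] = np.clip(cols[feat], cols["Min"], cols["Max"])

    frame = pd.DataFrame({f: cols[f] for f in CTG_FEATURES})
    frame["NSP"] = labels

    for rule in config.planted_rules:
        _inject_rule(frame, rule, rng_rule, config)

    prov = f"synthetic(seed={config.seed}, n={config.n})"
    if warning:
        prov += f" [{warning}]"
    return CTGDataset(frame, provenance=prov)


def _inject_rule(frame: pd.DataFrame, rule: PlantedRule,
                 rng: np.random.Generator, config: SynthConfig) -> None:
    n = len(frame)
    k = max(1, int(round(rule.region_fraction * n)))
    members = rng.choice(n, size=k, replace=False)
    member_mask = np.zeros(n, bool)
    member_mask[members] = True

    for feat, (lo, hi) in rule.conditions:
        vals = frame[feat].to_numpy(float)
        vals[members] = rng.uniform(lo, hi, size=k)
        frame[feat] = vals

    # evict accidental non-member residents of the full rectangle so the
    # region's purity is exactly as configured
    inside = ~member_mask
    for feat, (lo, hi) in rule.conditions:
        v = frame[feat].to_numpy(float)
        inside &= (v >= lo) & (v < hi)
    if inside.any():
        feat, (lo, hi) = rule.conditions[0]
        dom_lo, dom_hi = _feature_domain(feat, config)
        vals = frame[feat].to_numpy(float)
        vals[inside] = _sample_outside(rng, lo, hi, dom_lo, dom_hi,
                                       int(inside.sum()))
        frame[feat] = vals

    forced = rng.uniform(size=k) < rule.purity if rule.purity < 1.0 else np.ones(k, bool)
    nsp = frame["NSP"].to_numpy()
    nsp[members[forced]] = rule.target_class
    frame["NSP"] = nsp


def _feature_domain(feat: str, config: SynthConfig) -> tuple[float, float]:
    if feat in config.locations:
        spec = config.locations[feat]
        return float(spec["lo"]), float(spec["hi"])
    if feat in RATE_FEATURES:
        return 0.0, 0.05
    return 0.0, 20.0


def _sample_outside(rng, lo, hi, dom_lo, dom_hi, size) -> np.ndarray:
    """Uniform draws from the domain minus [lo, hi)."""
    left = max(lo - dom_lo, 0.0)
    right = max(dom_hi - hi, 0.0)
    if left + right <= 0:
        raise ConfigError("planted interval covers the whole feature domain")
    u = rng.uniform(0, left + right, size=size)
    out = np.where(u < left, dom_lo + u, hi + (u - left))
    return out


def generate_sem_sample(model: SEMModel, params: Mapping[str, float] | np.ndarray,
                        n: int, seed: int) -> pd.DataFrame:
    """Draw observed-variable data from a structural equation model.

    Exogenous latents come from Phi, endogenous latents from
    eta = (I - beta)^-1 (Gamma xi + zeta), and indicators add independent
    unique errors; the sample covariance converges to the model-implied
    covariance as n grows.
    """
    rng = np.random.default_rng(seed)
    Lam, B, G, Phi, Psi, Th = model.matrices(params)
    ne = len(model.latents_endo)
    M = np.linalg.inv(np.eye(ne) - B)

    w = np.linalg.eigvalsh((Phi + Phi.T) / 2)
    if np.any(w < -1e-10):
        raise ValueError("exogenous covariance is not positive semi-definite")

    xi = rng.multivariate_normal(np.zeros(Phi.shape[0]), Phi, size=n,
                                 method="cholesky" if np.all(w > 1e-12) else "svd")
    if ne:
        zeta = rng.multivariate_normal(np.zeros(ne), Psi, size=n, method="svd")
        eta = (M @ (G @ xi.T + zeta.T)).T
        lat = np.hstack([xi, eta])
    else:
        lat = xi
    err_sd = np.sqrt(np.maximum(np.diag(Th), 0.0))
    errs = rng.standard_normal((n, len(model.observed))) * err_sd
    obs = lat @ Lam.T + errs
    return pd.DataFrame(obs, columns=model.observed)


def structural_true_params(model: SEMModel | None = None) -> dict[str, float]:
    """Ground-truth parameters for the structural preset's topology.

    Built so every indicator has unit variance; the standardized path
    coefficients equal the clinically reported values (VCat->BCat 0.527,
    UCat->DCat 0.952, NSP<-ACat -0.665, NSP<-BCat -0.240, NSP<-DCat 0.173,
    UCat~~VCat correlation -0.925), which makes parameter-recovery tests
    directly interpretable on the standardized scale.
    """
    if model is None:
        model = structural_model()
    std_load = {
        "Variance<-VCat": -0.700, "MSTV<-VCat": -0.886, "ALTV<-VCat": 0.608,
        "ASTV<-VCat": 0.531, "Width<-VCat": -0.805,
        "LB<-BCat": 0.754, "Mean<-BCat": 0.975, "Median<-BCat": 0.992,
        "Mode<-BCat": 0.936,
        "DP<-DCat": 0.535, "DL<-DCat": 0.755, "Nzeros<-DCat": 0.345,
        "AC<-ACat": 0.734, "Nmax<-ACat": 0.427, "FM<-ACat": 0.166,
        "UC<-UCat": 1.0, "NSP<-Fetal": 1.0,
    }
    std_path = {
        ("BCat", "VCat"): 0.527, ("DCat", "UCat"): 0.952,
        ("Fetal", "ACat"): -0.665, ("Fetal", "BCat"): -0.240,
        ("Fetal", "DCat"): 0.173,
    }
    r_uv = -0.925

    # latent sd fixed by the reference indicator's standardized loading
    lat_sd = {lat: abs(std_load[f"{model.reference[lat]}<-{lat}"])
              for lat in model.latents}
    params: dict[str, float] = {}
    for name in model.param_names:
        kind, rest = name.split(":", 1)
        if kind == "lambda":
            obs, lat = rest.split("<-")
            params[name] = std_load[f"{obs}<-{lat}"] / lat_sd[lat]
        elif kind in ("beta", "gamma"):
            tgt, src = rest.split("<-")
            params[name] = std_path[(tgt, src)] * lat_sd[tgt] / lat_sd[src]
        elif kind == "theta":
            params[name] = 1.0 - std_load[_loading_key(model, rest)] ** 2
        elif kind == "phi":
            a, b = rest.split("~~")
            if a == b:
                params[name] = lat_sd[a] ** 2
            else:
                params[name] = r_uv * lat_sd[a] * lat_sd[b]
    # structural disturbances chosen so endogenous latents hit their target sd
    explained_B = std_path[("BCat", "VCat")] ** 2
    explained_D = std_path[("DCat", "UCat")] ** 2
    corr_BD = std_path[("BCat", "VCat")] * std_path[("DCat", "UCat")] * r_uv
    a_, b_, c_ = (std_path[("Fetal", "ACat")], std_path[("Fetal", "BCat")],
                  std_path[("Fetal", "DCat")])
    explained_F = a_ ** 2 + b_ ** 2 + c_ ** 2 + 2 * b_ * c_ * corr_BD
    psi_std = {"BCat": 1 - explained_B, "DCat": 1 - explained_D,
               "Fetal": 1 - explained_F}
    for name in model.param_names:
        if name.startswith("psi:"):
            lat = name.split(":", 1)[1].split("~~")[0]
            params[name] = psi_std[lat] * lat_sd[lat] ** 2
    return params


def _loading_key(model: SEMModel, obs: str) -> str:
    for (o, lat) in model.lam:
        if o == obs:
            return f"{o}<-{lat}"
    raise KeyError(obs)
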