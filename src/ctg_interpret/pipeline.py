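"""End-to-end orchestration: screening, rule mining and SEM fitting.

``run_pipeline`` executes the stages in their analysis order on either a
supplied CTG table or a synthetic configuration, collects every numeric
table into an :class:`AnalysisReport`, and ``export_report`` writes one CSV
per table plus a manifest with content hashes.  The report is a pure
function of the configuration, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ctg_interpret import ctg_data, discretize_ara, feature_screen, sem_engine
from ctg_interpret.ctg_data import CTGDataset
from ctg_interpret.synthetic_ctg import SynthConfig, generate_dataset

log = logging.getLogger("ctg_interpret")

CLASS_NAMES = {1: "normal", 2: "suspicious", 3: "pathology"}


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclasses.dataclass
class PipelineConfig:
    input_path: str | None = None
    synth: SynthConfig | None = None
    group_threshold: float = feature_screen.DEFAULT_GROUP_THRESHOLD
    profile_features: tuple[str, ...] = ("ASTV", "LB")
    target_classes: tuple[int, ...] = (1, 3)
    min_support: int = discretize_ara.DEFAULT_MIN_SUPPORT
    max_bins: int = 8
    min_frac: float = 0.05
    sem_presets: tuple[str, ...] = ("measurement", "structural")
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synth is None):
            raise PipelineConfigError(
                "exactly one of input_path / synth must be set")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclasses.dataclass
class AnalysisReport:
    config_hash: str
    seed: int
    class_summary: pd.DataFrame
    correlation: pd.DataFrame
    nsp_correlations: pd.DataFrame
    groups: list[list[str]]
    profiles: dict[str, pd.DataFrame]
    rules: pd.DataFrame
    rule_text: list[str]
    sem_tables: dict[str, pd.DataFrame]
    sem_fit_indices: dict[str, dict]
    effects: pd.DataFrame | None


def _load(config: PipelineConfig) -> CTGDataset:
    if config.input_path is not None:
        return ctg_data.read_ctg_table(config.input_path)
    return generate_dataset(config.synth)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute all stages; any stage failure aborts with its stage name."""
    chash = config.hash()

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise StageError(name, exc) from exc

    dataset = stage("load", lambda: _load(config))
    log.info("loaded %d records", dataset.n)

    def class_stage():
        cc = ctg_data.class_counts(dataset)
        rows = [{"class": CLASS_NAMES[c], "count": cc["counts"][c],
                 "proportion": cc["proportions"][c]} for c in (1, 2, 3)]
        return pd.DataFrame(rows)
    class_summary = stage("class_counts", class_stage)

    def screen_stage():
        corr = feature_screen.spearman_matrix(dataset)
        groups = feature_screen.correlated_groups(corr, config.group_threshold)
        ranked = feature_screen.nsp_correlations(corr)
        profiles = {}
        for feat in config.profile_features:
            edges = feature_screen.LANDMARK_EDGES.get(
                feat, feature_screen.equal_width_edges(dataset, feat))
            bp = feature_screen.stacked_proportions(dataset, feat, edges)
            profiles[feat] = feature_screen.proportions_table(bp)
        return corr, groups, ranked, profiles
    corr, groups, ranked, profiles = stage("feature_screen", screen_stage)

    def mine_stage():
        bins = discretize_ara.fit_all_bins(dataset, config.max_bins, config.min_frac)
        rows, texts = [], []
        for cls in config.target_classes:
            rule, trace = discretize_ara.forward_stepwise_rule(
                dataset, bins, cls, config.min_support)
            texts.append(discretize_ara.rule_to_text(rule))
            for step_i, (cond, supp, conf) in enumerate(trace.steps):
                standalone = discretize_ara.rule_support_confidence(
                    [cond], cls, dataset)
                rows.append({
                    "class": CLASS_NAMES[cls], "step": step_i + 1,
                    "condition": str(cond), "support": supp, "confidence": conf,
                    "standalone_confidence": standalone.confidence,
                    "stopping_reason": trace.stopping_reason,
                })
        return pd.DataFrame(rows), texts
    rules, rule_text = stage("mine_rules", mine_stage)

    def sem_stage():
        tables: dict[str, pd.DataFrame] = {}
        indices: dict[str, dict] = {}
        effects = None
        for preset in config.sem_presets:
            model = (sem_engine.measurement_model() if preset == "measurement"
                     else sem_engine.structural_model())
            frame = dataset.frame.copy()
            data = sem_engine.SEMData.from_frame(frame, model.observed)
            fit = sem_engine.fit_ml(model, data)
            wald = sem_engine.wald_statistics(fit)
            std = sem_engine.standardize_solution(fit)
            wald["standardized"] = [
                std.get(name.split(":", 1)[1], np.nan)
                for name in wald["parameter"]]
            wald["converged"] = fit.converged
            wald["heywood"] = ", ".join(fit.heywood)
            tables[preset] = wald
            indices[preset] = sem_engine.fit_indices(fit)
            if preset == "structural":
                effects = sem_engine.effect_decomposition(fit, "NSP")
        return tables, indices, effects
    sem_tables, sem_fit_indices, effects = stage("fit_sem", sem_stage)

    return AnalysisReport(
        config_hash=chash, seed=config.seed, class_summary=class_summary,
        correlation=corr.rho.round(12), nsp_correlations=ranked, groups=groups,
        profiles=profiles, rules=rules, rule_text=rule_text,
        sem_tables=sem_tables, sem_fit_indices=sem_fit_indices, effects=effects)


def export_report(report: AnalysisReport, outdir: str | Path) -> dict:
    """Write the report tables and a manifest of file hashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise IOError(f"{outdir} is not a writable directory")

    files: dict[str, str] = {}

    def write_csv(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        files[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    write_csv("class_summary.csv", report.class_summary)
    write_csv("correlation_matrix.csv",
              report.correlation.reset_index().rename(columns={"index": "variable"}))
    write_csv("nsp_correlations.csv", report.nsp_correlations)
    write_csv("rules.csv", report.rules)
    for feat, table in report.profiles.items():
        write_csv(f"profile_{feat}.csv", table)
    for preset, table in report.sem_tables.items():
        write_csv(f"sem_{preset}.csv", table)
    if report.effects is not None:
        write_csv("effects.csv", report.effects)

    summary_lines = [f"config hash: {report.config_hash}", ""]
    summary_lines += [f"group {i + 1}: {', '.join(g)}"
                      for i, g in enumerate(report.groups)] or ["no correlated groups"]
    summary_lines += [""] + report.rule_text
    for preset, ix in report.sem_fit_indices.items():
        summary_lines.append(
            f"{preset}: chi2={ix['chi2']:.3f} df={ix['df']} cfi={ix['cfi']:.4f} "
            f"rmsea={ix['rmsea']:.4f} srmr={ix['srmr']:.4f}")
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    files["summary.txt"] = hashlib.sha256(
        (outdir / "summary.txt").read_bytes()).hexdigest()

    manifest = {"config_hash": report.config_hash, "seed": report.seed,
                "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
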