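"""Pipeline orchestration: categorize -> preprocess -> cluster -> classify
-> evaluate, from a single configuration with one master seed."""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .classify import (ForestConfig, TreeConfig, forest_importance, fit_tree,
                       marginal_anova)
from .cluster import (ClusterConfig, ScreeningConfig, cluster_clinical,
                      screen_clinical)
from .datamodel import (DiagnosisLabels, FeatureCategories, FeatureTable,
                        RunReport, config_hash, read_category_map,
                        read_diagnosis_labels, read_feature_table,
                        write_report)
from .preprocess import PreprocessConfig, impute_knn, standardize, symmetrize
from .stability import (ProfileConfig, StabilityConfig,
                        _rank_clusters_by_severity, bootstrap_profile,
                        cross_validate, two_proportion_test)
from .synthetic import SyntheticSpec, generate_dataset

log = logging.getLogger("threec")

CLUSTER_NAMES = {0: "HiClus", 1: "LoClus"}


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one data source must be set."""

    table_path: str | None = None
    category_map_path: str | None = None
    diagnosis_path: str | None = None
    synthetic: SyntheticSpec | None = None
    seed: int = 0
    output_dir: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    stability: StabilityConfig | None = field(default_factory=StabilityConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    run_stability: bool = True
    profile_top: int = 10

    def validate(self) -> None:
        has_files = self.table_path is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError(
                "exactly one of table_path / synthetic must be configured")
        if has_files and self.category_map_path is None:
            raise ValueError("category_map_path is required with table_path")
        self.preprocess.validate()
        self.screening.validate()
        self.cluster.validate()
        self.forest.validate()
        self.tree.validate()
        if self.stability is not None:
            self.stability.validate()
        self.profile.validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def config_from_dict(raw: Mapping[str, Any]) -> PipelineConfig:
    """Build a validated PipelineConfig from a plain (YAML) mapping."""
    def build(cls, key):
        sub = raw.get(key)
        if sub is None:
            return cls()
        try:
            return cls(**sub)
        except TypeError as exc:
            raise ValueError(f"invalid {key} settings: {exc}") from None

    cfg = PipelineConfig(
        table_path=raw.get("table_path"),
        category_map_path=raw.get("category_map_path"),
        diagnosis_path=raw.get("diagnosis_path"),
        synthetic=(SyntheticSpec(**raw["synthetic"])
                   if raw.get("synthetic") is not None else None),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir"),
        preprocess=build(PreprocessConfig, "preprocess"),
        screening=build(ScreeningConfig, "screening"),
        cluster=build(ClusterConfig, "cluster"),
        forest=build(ForestConfig, "forest"),
        tree=build(TreeConfig, "tree"),
        stability=build(StabilityConfig, "stability"),
        profile=build(ProfileConfig, "profile"),
        run_stability=bool(raw.get("run_stability", True)),
        profile_top=int(raw.get("profile_top", 10)),
    )
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ("synthetic", "gap", "forest", "stability", "profile")
    children = ss.spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2**31 - 1))
            for name, child in zip(names, children)}


def load_inputs(config: PipelineConfig
                ) -> tuple[FeatureTable, FeatureCategories,
                           DiagnosisLabels | None]:
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic)
        table, categories, diagnosis, _ = generate_dataset(spec)
        return table, categories, diagnosis
    table = read_feature_table(config.table_path)
    categories = read_category_map(config.category_map_path,
                                   table.feature_ids)
    diagnosis = (read_diagnosis_labels(config.diagnosis_path)
                 if config.diagnosis_path else None)
    return table, categories, diagnosis


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full 3C pipeline and return the populated report.

    Every stochastic step (gap references, forest, stability draws,
    bootstrap) is seeded from the master seed; identical configuration and
    seed give an identical report.
    """
    config.validate()
    seeds = _stage_seeds(config.seed)
    report = RunReport(
        seed=config.seed,
        config_hash=config_hash(config.to_dict()),
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("categorize")
        if config.synthetic is not None and config.synthetic.seed == 0:
            config = dataclasses.replace(
                config, synthetic=dataclasses.replace(
                    config.synthetic, seed=seeds["synthetic"]))
        table, categories, diagnosis = load_inputs(config)
        categories.validate_against(table.feature_ids)
        log.info("loaded %d subjects x %d features", table.n_subjects,
                 table.n_features)
    except Exception as exc:
        raise PipelineError("categorize", exc) from exc

    try:
        stage("preprocess")
        complete = impute_knn(table, config.preprocess)
        transformed, tlog = symmetrize(complete, config.preprocess)
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc

    try:
        stage("cluster")
        screen = screen_clinical(transformed, categories, config.screening)
        selected = screen.loc[screen["selected"], "feature"].tolist()
        if not selected:
            raise ValueError("no clinical feature survived the FDR screen")
        clin = transformed.subset_features(selected)
        if config.preprocess.standardize_clinical and config.cluster.standardize:
            clin = standardize(clin)
        model = cluster_clinical(clin.values, config.cluster, seeds["gap"])
        labels = _rank_clusters_by_severity(
            model.labels,
            transformed.column(categories.assigned_diagnosis_feature))
        report.screening = {
            "q": config.screening.q_screen,
            "table": screen.to_dict(orient="records"),
            "selected": selected,
        }
        report.cluster = {
            "k": model.k,
            "metric": model.metric,
            "sizes": [int((labels == c).sum()) for c in range(model.k)],
            "mean_silhouette": model.mean_silhouette,
            "gap": {"ks": model.gap.ks.tolist(),
                    "gap": model.gap.gap.tolist(),
                    "s_k": model.gap.s_k.tolist(),
                    "k_hat": model.gap.k_hat} if model.gap else None,
            "rationale": model.rationale,
            "labels": labels.tolist(),
            "medoid_subjects": [table.subject_ids[i]
                                for i in model.medoid_indices],
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("cluster", exc) from exc

    try:
        stage("evaluate-association")
        if diagnosis is not None and model.k == 2:
            counts = np.array(
                [[int(((labels == c) & (diagnosis.values == 1)).sum()),
                  int(((labels == c) & (diagnosis.values == 0)).sum())]
                 for c in (0, 1)])
            assoc = two_proportion_test(counts)
            report.association = {
                "counts": assoc.counts.tolist(), "p1": assoc.p1,
                "p2": assoc.p2, "z": assoc.z, "p": assoc.p_value,
            }
    except Exception as exc:
        raise PipelineError("evaluate-association", exc) from exc

    try:
        stage("classify")
        biomarkers = categories.biomarker_features
        Xb = transformed.subset_features(biomarkers).values
        importance = forest_importance(
            Xb, labels, biomarkers,
            domains=categories.domain, config=config.forest,
            seed=seeds["forest"])
        fitted = fit_tree(Xb, labels, biomarkers, config.tree)
        anova = marginal_anova(Xb, labels, biomarkers, q=0.05)
        report.classifier = {
            "importance": importance.to_dict(orient="records"),
            "tree_text": fitted.render(CLUSTER_NAMES),
            "tree": fitted.root.to_dict(),
            "anova": anova.to_dict(orient="records"),
            "anova_summary": {
                "n_features": int(len(anova)),
                "n_significant": int(anova["significant"].sum()),
                "q": 0.05,
            },
        }
    except Exception as exc:
        raise PipelineError("classify", exc) from exc

    try:
        stage("profile")
        top = importance.head(config.profile_top)["feature"].tolist()
        Xt = transformed.subset_features(top).values
        prof = bootstrap_profile(Xt, labels, top, config.profile,
                                 seeds["profile"])
        report.profiles = prof.to_dict(orient="records")
    except Exception as exc:
        raise PipelineError("profile", exc) from exc

    if config.run_stability and config.stability is not None:
        try:
            stage("stability")
            stab_cfg = dataclasses.replace(config.stability,
                                           base_seed=seeds["stability"])
            stab = cross_validate(table, categories, labels, stab_cfg,
                                  config.screening, config.preprocess,
                                  config.cluster, config.tree)
            report.stability = stab.to_dict(orient="records")
        except Exception as exc:
            raise PipelineError("stability", exc) from exc

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
    return report


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
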