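"""End-to-end study pipeline: simulate/load -> extract -> select -> screen
-> classify -> stability, with a machine-readable JSON report."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import __version__
from .analysis import (
    MODELS,
    bootstrap_stability,
    cross_validate,
    roc_analysis,
    screen_features,
    tune_hyperparameters,
)
from .features import ExtractionConfig, extract_all, feature_names
from .io import FeatureTable, RoiImage
from .selection import retest_feature_frames, select_features
from .synthetic import (
    DEFAULT_COUNTS,
    DEFAULT_N_RETEST,
    DEFAULT_SPLIT,
    PhantomSpec,
    generate_cohort,
    generate_test_retest,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "extract_cohort", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    phantom: PhantomSpec = dataclasses.field(default_factory=PhantomSpec)
    extraction: ExtractionConfig = dataclasses.field(default_factory=ExtractionConfig)
    n_per_class: dict[str, int] = dataclasses.field(default_factory=lambda: dict(DEFAULT_COUNTS))
    split: tuple[int, int] | float = DEFAULT_SPLIT
    n_retest: int = DEFAULT_N_RETEST
    models: tuple[str, ...] = MODELS
    n_bootstrap: int = 100
    cv_folds: int = 10
    alpha: float = 0.05
    seed: int = 0


def extract_cohort(
    rois: list[RoiImage],
    cohorts: list[str] | None = None,
    config: ExtractionConfig | None = None,
) -> FeatureTable:
    """Extract the 233-feature vector for every ROI of a cohort.

    A ROI that fails at any stage is excluded with a logged reason naming
    the stage; it is never silently dropped.
    """
    vectors = []
    kept_cohorts = []
    cohorts = cohorts or ["training"] * len(rois)
    for roi, coh in zip(rois, cohorts, strict=True):
        try:
            vectors.append(extract_all(roi, config))
            kept_cohorts.append(coh)
        except Exception as exc:  # noqa: BLE001
            logger.error("subject %r excluded: extraction failed (%s)", roi.subject_id, exc)
    return FeatureTable.from_vectors(vectors, kept_cohorts)


def run_pipeline(config: PipelineConfig | None = None, seed: int | None = None) -> dict:
    """Run the whole synthetic study and return a JSON-serializable report."""
    config = config or PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(
            config, phantom=dataclasses.replace(config.phantom, seed=seed), seed=seed
        )

    logger.info("simulating cohort %s split %s", config.n_per_class, config.split)
    cohort = generate_cohort(config.phantom, config.n_per_class, config.split)
    pairs = generate_test_retest(config.phantom, config.n_retest)

    logger.info("extracting %d cohort + %d retest-pair feature vectors",
                len(cohort), len(pairs))
    table = extract_cohort(cohort.rois, cohort.cohorts, config.extraction)
    test_vecs = [extract_all(t, config.extraction) for t, _ in pairs]
    retest_vecs = [extract_all(r, config.extraction) for _, r in pairs]
    test_frame, retest_frame = retest_feature_frames(test_vecs, retest_vecs)

    selection = select_features(table, test_frame, retest_frame)
    features = selection.selected or table.feature_names
    if not selection.selected:
        logger.warning("empty selection; screening/classifying on all features")

    train = table.cohort("training")
    val = table.cohort("validation")
    screening = screen_features(train, features, alpha=config.alpha)

    tasks = {}
    for pair, scr in screening.items():
        task_key = f"{pair[0]}_vs_{pair[1]}"
        roc_rows = {}
        for f in scr.significant:
            sub = train.frame[train.frame["label"].isin(pair)]
            roc = roc_analysis(sub[f].to_numpy(), (sub["label"] == pair[1]).to_numpy())
            roc_rows[f] = dataclasses.asdict(roc)
        used = scr.significant or features
        models = {}
        for model in config.models:
            ev = cross_validate(
                model, train, val, pair, used, k=config.cv_folds, seed=config.seed
            )
            stab = bootstrap_stability(
                model, train, pair, used,
                n_resamples=config.n_bootstrap, seed=config.seed, hyper=ev.hyper,
            )
            models[model] = {**ev.to_dict(), **stab.to_dict()}
        tasks[task_key] = {
            "n_significant": len(scr.significant),
            "significant": scr.significant,
            "features_used": used,
            "roc": roc_rows,
            "models": models,
        }

    return {
        "version": __version__,
        "seed": int(config.seed),
        "n_features": table.n_features,
        "cohort": {
            "n_training": len(train),
            "n_validation": len(val),
            "n_per_class": dict(config.n_per_class),
            "n_retest_pairs": len(pairs),
        },
        "selection": selection.to_dict(),
        "tasks": tasks,
    }


def render_report(report: dict) -> str:
    """Render the pipeline report as readable Markdown summary tables."""
    lines = [
        f"# livertex report (seed {report['seed']})",
        "",
        f"Features extracted: {report['n_features']}; "
        f"reproducible: {report['selection']['n_reproducible']}; "
        f"selected after de-correlation: {report['selection']['n_selected']}",
        "",
    ]
    for task, data in report["tasks"].items():
        lines += [f"## {task.replace('_', ' ')}", ""]
        lines += [f"Significant features (raw p < 0.05): {data['n_significant']}", ""]
        if data["roc"]:
            lines += ["| feature | AUC | cut-off | sens | spec |", "|---|---|---|---|---|"]
            for f, r in list(data["roc"].items())[:10]:
                lines.append(
                    f"| {f} | {r['auc']:.3f} | {r['cutoff']:.3g} "
                    f"| {r['sensitivity']:.3f} | {r['specificity']:.3f} |"
                )
            lines.append("")
        lines += [
            "| model | Acc% | Sens% | Spec% | MCC | RSD% | AUC% |",
            "|---|---|---|---|---|---|---|",
        ]
        for model, m in data["models"].items():
            lines.append(
                f"| {model} | {100*m['accuracy']:.0f} | {100*m['sensitivity']:.0f} "
                f"| {100*m['specificity']:.0f} | {m['mcc']:.2f} "
                f"| {m['rsd_percent']:.1f} | {100*m['auc']:.0f} |"
            )
        lines.append("")
    return "\n".join(lines)
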