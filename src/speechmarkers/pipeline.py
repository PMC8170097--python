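"""End-to-end orchestration: extract -> screen -> select -> classify.

``run_all`` executes the three-step methodology on either a synthetic
cohort (the default: no clinical data access required) or a directory of
CHAT transcripts with a labels CSV, and writes five artifacts: the feature
table, the registry sidecar, the per-language screening table, the
selection JSON, and the experiment results JSON, plus a human-readable
report.  Every output embeds the seed and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features_text import extract_text_features, load_frequency_table
from .ingest import SubjectRecord, load_lexicon, parse_chat
from .ml import ExperimentResult, run_scenarios
from .synth import SynthParams, generate_cohort, generate_paralinguistic_table
from .tagging import get_tagger
from .vectors import registry_counts
from .xlingual import (build_stats_table, select_generalizable,
                       stats_to_frame)

log = logging.getLogger("speechmarkers")

__all__ = ["RunConfig", "RunReport", "extract_cohort_features", "run_all"]


@dataclass
class RunConfig:
    """Pipeline settings for one run."""

    out_dir: str | Path = "speechmarkers_run"
    seed: int = 0
    alpha: float = 0.05
    bonferroni_m: Optional[int] = None  # None -> runtime registry size
    models: tuple = ("LR", "SVM", "MLP")
    # "full-data-selection" screens features once on the whole cohort
    # before LOOCV; "nested-selection" re-screens inside each fold
    mode: str = "full-data-selection"
    synth: SynthParams = field(default_factory=SynthParams)
    transcripts_dir: Optional[str] = None
    labels_csv: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def hash(self) -> str:
        def _norm(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return _norm(dataclasses.asdict(o))
            if isinstance(o, dict):
                return sorted((str(k), _norm(v)) for k, v in o.items())
            if isinstance(o, (list, tuple, set, frozenset)):
                return [_norm(v) for v in o]
            return str(o)
        blob = json.dumps(_norm(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    features: pd.DataFrame
    registry: dict[str, str]
    stats: pd.DataFrame
    selection: set[str]
    results: list[ExperimentResult]
    paths: dict[str, Path] = field(default_factory=dict)


def extract_cohort_features(records: Sequence[SubjectRecord]
                            ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Text-feature table (rows = subjects) and the shared registry."""
    taggers = {}
    freqs = {}
    lexicons = {}
    rows = {}
    registry: dict[str, str] = {}
    for rec in records:
        lang = rec.language
        if lang not in taggers:
            taggers[lang] = get_tagger(lang)
            freqs[lang] = load_frequency_table(lang)
            lexicons[lang] = load_lexicon(language=lang)
        fv = extract_text_features(
            rec.transcript, lexicons[lang], duration_s=rec.duration_s,
            tagger=taggers[lang], freq=freqs[lang],
            subject_id=rec.subject_id)
        rows[rec.subject_id] = fv.values
        registry.update(fv.registry)
    return pd.DataFrame.from_dict(rows, orient="index"), registry


def _load_chat_cohort(config: RunConfig) -> list[SubjectRecord]:
    meta = pd.read_csv(config.labels_csv)
    records = []
    for _, row in meta.iterrows():
        path = Path(config.transcripts_dir) / f"{row['subject_id']}.cha"
        transcript = parse_chat(path.read_text(encoding="utf-8"))
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), language=row["language"],
            group=row["group"], transcript=transcript,
            age=row.get("age"), duration_s=row.get("duration_s")))
    return records


def run_all(config: RunConfig) -> RunReport:
    """Run the full pipeline and write all artifacts to ``out_dir``."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    meta = {"config_hash": chash, "seed": config.seed}

    # --- stage 1: cohort and feature extraction
    if config.transcripts_dir:
        records = _load_chat_cohort(config)
        ground_truth = None
    else:
        params = dataclasses.replace(config.synth, seed=config.seed)
        records, _, ground_truth = generate_cohort(params)
    features, registry = extract_cohort_features(records)
    if not config.transcripts_dir:
        para = generate_paralinguistic_table(params, records)
        features = features.join(para)
        from .features_audio import PARALINGUISTIC_FEATURES
        registry.update({n: "paralinguistic"
                         for n in PARALINGUISTIC_FEATURES})
    labels = pd.Series({r.subject_id: r.group for r in records})
    languages = pd.Series({r.subject_id: r.language for r in records})
    ages = pd.Series({r.subject_id: r.age for r in records})
    log.info("extracted %d features for %d subjects",
             features.shape[1], features.shape[0])

    # --- stage 2: per-language screening and selection
    m = config.bonferroni_m or features.shape[1]
    stats_rows = {}
    for lang in sorted(languages.unique()):
        sel = languages == lang
        stats_rows[lang] = build_stats_table(
            features.loc[sel], labels[sel], lang, registry=registry,
            bonferroni_m=m)
    stats_df = pd.concat([stats_to_frame(v) for v in stats_rows.values()],
                         ignore_index=True)
    selection = select_generalizable(stats_rows["en"], stats_rows["fr"],
                                     registry, alpha=config.alpha)

    # --- stage 3: classification experiments
    results = run_scenarios(features, labels.to_numpy(),
                            languages.to_numpy(), registry,
                            selection=selection.selected,
                            ages=ages.to_numpy(dtype=float),
                            models=config.models,
                            nested=(config.mode == "nested-selection"),
                            alpha=config.alpha, seed=config.seed)

    # --- artifacts
    paths = {
        "features": out / "features.csv",
        "registry": out / "registry.csv",
        "stats": out / "stats.csv",
        "selection": out / "selection.json",
        "results": out / "results.json",
        "report": out / "report.md",
    }
    features.to_csv(paths["features"], index_label="subject_id")
    pd.DataFrame(sorted(registry.items()),
                 columns=["feature_name", "subgroup"]
                 ).to_csv(paths["registry"], index=False)
    stats_df.assign(**meta).to_csv(paths["stats"], index=False)
    paths["selection"].write_text(json.dumps(
        {**meta, "alpha": selection.alpha,
         "excluded_task_count": selection.excluded_task_count,
         "selected": sorted(selection.selected)}, indent=2))
    paths["results"].write_text(json.dumps(
        {**meta, "results": [_result_dict(r) for r in results]}, indent=2,
        default=float))
    paths["report"].write_text(_render_report(
        meta, registry, stats_df, selection.selected, results,
        time.time() - t0))
    return RunReport(config_hash=chash, seed=config.seed, features=features,
                     registry=registry, stats=stats_df,
                     selection=selection.selected, results=results,
                     paths=paths)


def _result_dict(r: ExperimentResult) -> dict:
    return {"scenario": r.scenario_id, "model": r.model,
            "auc": None if np.isnan(r.auc) else round(float(r.auc), 4),
            "n_subjects": r.n_subjects, "n_features": r.n_features,
            "confusion": r.confusion, "note": r.note}


def _render_report(meta, registry, stats_df, selected, results,
                   elapsed) -> str:
    counts = registry_counts(registry)
    lines = ["# speechmarkers run report", "",
             f"config hash: {meta['config_hash']}  seed: {meta['seed']}",
             f"elapsed: {elapsed:.1f} s", "",
             "## Feature families", ""]
    for sub, n in counts.items():
        lines.append(f"- {sub}: {n} features")
    lines += ["", f"## Generalizable features ({len(selected)} selected)", ""]
    for name in sorted(selected):
        lines.append(f"- {name} ({registry.get(name, '?')})")
    sig = stats_df[stats_df["significant_uncorrected"]]
    lines += ["", "## Screening (significant uncorrected rows)", "",
              sig.to_string(index=False, float_format=lambda v: f"{v:.4g}")]
    # cross-language effect-size pairs for correlation-style inspection
    piv = stats_df.pivot_table(index="feature", columns="language",
                               values="r_pb")
    if {"en", "fr"} <= set(piv.columns):
        both = piv.dropna()
        lines += ["", "## Cross-language effect sizes (r_pb en vs fr)", "",
                  both.to_string(float_format=lambda v: f"{v:.3f}")]
    lines += ["", "## Experiments", ""]
    for r in results:
        if r.note:
            lines.append(f"- {r.scenario_id}/{r.model}: {r.note}")
            continue
        overall = r.confusion["overall"]
        lines.append(
            f"- {r.scenario_id}/{r.model}: AUC={r.auc:.3f} "
            f"error={overall['error_rate']}% "
            f"(TP={overall['TP']} FP={overall['FP']} TN={overall['TN']} "
            f"FN={overall['FN']}; {r.n_features} features)")
    return "\n".join(lines) + "\n"
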