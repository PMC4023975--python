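"""End-to-end orchestration: simulate/read -> classify -> discover -> enrich.

One :func:`run_pipeline` call executes every stage under a single seed and
writes all artifacts (study tables, per-sample classes, per-treatment and
per-platform tallies, per-platform marker tables in both rounded and
full-precision form, class profile, heatmap matrix, outlier report,
enrichment table, and a JSON run summary).  Every numeric threshold is
surfaced in the summary; two runs with the same configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import enrich as en
from . import markers as mk
from .preprocess import center_study
from .simulate import SimulationConfig, TruthTable, default_config, \
    generate_study, control_envelope, _stream
from .study import PLATFORMS, Study, read_study_dir, validate_study, write_study

logger = logging.getLogger("hepamark")

__all__ = ["PipelineConfig", "RunSummary", "run_pipeline", "load_config",
           "synthetic_term_sets"]


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults are the analysis' standard thresholds."""

    seed: int = 0
    study_dir: str | None = None      # read an existing study; else simulate
    out_dir: str = "hepamark_run"
    fdr: float = 0.05
    fc: float = 2.0
    alt_ast_fold: float = 2.0
    top_n: int = 500
    p_cut: float = 1e-7
    enrich_p: float = 1e-5
    k_outlier_markers: int = 3
    outlier_fold: float = 2.0
    outlier_top_per_platform: int = 2
    gmt: str | None = None            # term sets; None + simulated => synthetic
    write_study_tables: bool = True

    def settings_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "fdr": self.fdr,
            "fc": self.fc,
            "alt_ast_fold": self.alt_ast_fold,
            "top_n": self.top_n,
            "p_cut": self.p_cut,
            "enrich_p": self.enrich_p,
            "k_outlier_markers": self.k_outlier_markers,
            "outlier_fold": self.outlier_fold,
            "outlier_top_per_platform": self.outlier_top_per_platform,
            "control_matching_key": "(study_id, time_h)",
        }


def load_config(path: str | Path) -> PipelineConfig:
    """Read a key-value YAML config; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class RunSummary:
    """Machine-readable summary of one pipeline run."""

    settings: dict[str, Any]
    n_samples: int
    class_tally_by_treatment: dict[str, dict[str, int]]
    class_tally_by_platform: dict[str, dict[str, int]]
    confusion: dict[str, int]
    sensitivity: float | None
    specificity: float | None
    platform_counts: dict[str, dict[str, int]]
    outliers: list[dict[str, Any]]
    control_envelope: dict[str, float] | None
    n_enriched_terms: int | None
    validation_issues: int

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )


def synthetic_term_sets(
    transcript_ids: list[str], planted_ids: list[str], seed: int,
    n_random_terms: int = 20,
) -> list[en.TermSet]:
    """Annotation term sets for a simulated study.

    One "injury response" term collects the planted transcripts plus some
    bystanders (so its over-representation is real and discoverable); the
    remaining terms are random draws from the measured transcripts and act
    as the null background of the term test.
    """
    rng = _stream(seed, "terms")
    planted = [p for p in planted_ids if p in set(transcript_ids)]
    bystanders = [t for t in transcript_ids if t not in set(planted)]
    extra = rng.choice(len(bystanders), size=min(20, len(bystanders)),
                       replace=False)
    terms = [
        en.TermSet(
            "TERM:0000001", "response_to_hepatic_injury",
            frozenset(planted + [bystanders[i] for i in sorted(extra)]),
        )
    ]
    for i in range(n_random_terms):
        size = int(rng.integers(10, 80))
        idx = rng.choice(len(transcript_ids), size=size, replace=False)
        terms.append(
            en.TermSet(
                f"TERM:{i + 2:07d}", f"random_term_{i + 1:02d}",
                frozenset(transcript_ids[j] for j in sorted(idx)),
            )
        )
    return terms


def run_pipeline(
    config: PipelineConfig,
    sim_config: SimulationConfig | None = None,
) -> RunSummary:
    """Execute all stages and write artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: input ---------------------------------------------------
    truth: TruthTable | None = None
    if config.study_dir is not None:
        study = read_study_dir(config.study_dir)
        simulated = False
    else:
        sim = sim_config if sim_config is not None else default_config(config.seed)
        study, truth = generate_study(sim)
        simulated = True
        if config.write_study_tables:
            write_study(study, out / "study")
            truth.parameters.to_csv(out / "study" / "truth_parameters.tsv",
                                    sep="\t")
            truth.samples.to_csv(out / "study" / "truth_samples.tsv", sep="\t")
    issues = validate_study(study)
    if issues:
        logger.warning("validation reported %d issue(s)", len(issues))
    pd.DataFrame(
        [(i.kind, i.subject, i.message) for i in issues],
        columns=["kind", "subject", "message"],
    ).to_csv(out / "validation_issues.tsv", sep="\t", index=False)

    envelope = None
    if study.control_groups():
        envelope = control_envelope(study)

    # --- stage: preprocessing ------------------------------------------
    deltas = center_study(study)
    for platform, d in deltas.items():
        with open(out / f"delta_{platform}.tsv", "w") as fh:
            fh.write(f"#platform={platform} scale=log2_delta\n")
            d.values.to_csv(fh, sep="\t", index_label="parameter_id")
        d.provenance.to_csv(out / f"provenance_{platform}.tsv", sep="\t")

    # --- stage: classification -----------------------------------------
    threshold = math.log2(config.alt_ast_fold)
    classes = cl.classify_study(
        study, deltas.get("clinical_chemistry"), threshold
    )
    classes.to_csv(out / "classes.tsv", sep="\t")
    tally_treat = cl.class_tally_by_treatment(study, classes)
    tally_treat.to_csv(out / "class_tally_by_treatment.tsv", sep="\t")
    tally_plat = cl.class_tally_by_platform(study, classes)
    tally_plat.to_csv(out / "class_tally_by_platform.tsv", sep="\t")

    outcomes = cl.alt_ast_rule_outcomes(
        study, deltas.get("clinical_chemistry"), threshold
    )
    confusion = cl.rule_confusion(
        classes["class"].tolist(), outcomes.loc[classes.index].tolist()
    )
    sens, spec = cl.sens_spec(confusion)

    # --- stage: marker discovery ---------------------------------------
    all_results: dict[str, list[mk.MarkerResult]] = {}
    selected: dict[str, list[str]] = {}
    platform_counts: dict[str, dict[str, int]] = {}
    for platform in PLATFORMS:
        if platform not in deltas:
            continue
        res = mk.discover_markers(deltas[platform], classes,
                                  fdr_threshold=config.fdr,
                                  fc_threshold=config.fc)
        ranked = mk.rank_markers(res)
        all_results[platform] = ranked
        sel = [r.parameter_id for r in ranked if r.significant]
        selected[platform] = sel
        platform_counts[platform] = {
            "parameters": len(deltas[platform].values.index),
            "tested": len(res),
            "significant": len(sel),
        }
        mk.markers_to_frame(ranked, rounded=True).to_csv(
            out / f"markers_{platform}.tsv", sep="\t", index=False
        )
        mk.markers_to_frame(ranked, rounded=False).to_csv(
            out / f"markers_{platform}_full.tsv", sep="\t", index=False
        )

    # --- stage: summaries on the selected markers -----------------------
    n_selected = sum(len(v) for v in selected.values())
    outlier_dicts: list[dict[str, Any]] = []
    if n_selected:
        # one parameter id may recur across platforms (e.g. a metabolite
        # measured in serum and liver) — namespace the combined index
        parts = []
        for p in selected:
            if selected[p]:
                blk = deltas[p].values.loc[selected[p]].copy()
                blk.index = pd.Index(
                    [f"{p}:{i}" for i in blk.index], name="parameter_id"
                )
                parts.append(blk)
        combined = pd.concat(parts, axis=0)
        profile = mk.class_profile(combined, classes, list(combined.index))
        prof_df = pd.DataFrame({"grid": profile.grid})
        for c, dens in profile.densities.items():
            prof_df[c] = dens
        prof_df.to_csv(out / "class_profile_density.tsv", sep="\t",
                       index=False)
        profile.means.to_csv(out / "class_profile_means.tsv", sep="\t",
                             index_label="parameter_id")

        heat = mk.heatmap_matrix(deltas, classes, selected, study.vehicle_ids)
        heat.to_tsv(out / "heatmap.tsv")

        top_markers = []
        for platform, ranked in all_results.items():
            sig = [r for r in ranked if r.significant]
            top_markers += [
                f"{platform}:{r.parameter_id}"
                for r in sig[: config.outlier_top_per_platform]
            ]
        if top_markers:
            flags = mk.flag_outliers(
                combined, classes,
                [m for m in top_markers if m in combined.index],
                k_markers=config.k_outlier_markers,
                fold_threshold=config.outlier_fold,
            )
            outlier_dicts = [
                {
                    "sample_id": f.sample_id,
                    "triggers": {m: round(fc, 2) for m, fc in f.triggers},
                }
                for f in flags
            ]
        pd.DataFrame(
            [
                (d["sample_id"], m, fc)
                for d in outlier_dicts
                for m, fc in d["triggers"].items()
            ],
            columns=["sample_id", "marker", "fold_change"],
        ).to_csv(out / "outliers.tsv", sep="\t", index=False)

    # --- stage: enrichment ----------------------------------------------
    n_enriched = None
    tr = all_results.get("transcripts_liver")
    if tr:
        terms = None
        if config.gmt is not None:
            terms = en.read_gmt(config.gmt)
        elif simulated and truth is not None:
            tr_truth = truth.parameters[
                truth.parameters["platform"] == "transcripts_liver"
            ]
            terms = synthetic_term_sets(
                list(tr_truth.index),
                list(tr_truth.index[tr_truth["planted"]]),
                config.seed,
            )
            en.write_gmt(terms, out / "term_sets.gmt")
        if terms is not None:
            background = [r.parameter_id for r in tr]
            sel_tr = en.top_transcripts(tr, config.top_n, config.p_cut)
            enr = en.fisher_enrichment(sel_tr, terms, background)
            en.enrichment_to_frame(enr).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
            n_enriched = sum(r.p_value < config.enrich_p for r in enr)

    # --- summary ---------------------------------------------------------
    summary = RunSummary(
        settings=config.settings_dict(),
        n_samples=len(study.samples),
        class_tally_by_treatment={
            str(t): {c: int(row[c]) for c in ("negative", "increased",
                                              "positive", "total")}
            for t, row in tally_treat.iterrows()
        },
        class_tally_by_platform={
            str(p): {c: int(row[c]) for c in ("negative", "increased",
                                              "positive", "total")}
            for p, row in tally_plat.iterrows()
        },
        confusion={"tp": confusion.tp, "fn": confusion.fn,
                   "fp": confusion.fp, "tn": confusion.tn},
        sensitivity=None if math.isnan(sens) else round(sens, 6),
        specificity=None if math.isnan(spec) else round(spec, 6),
        platform_counts=platform_counts,
        outliers=outlier_dicts,
        control_envelope=(
            {k: round(v, 6) for k, v in envelope.items()}
            if envelope else None
        ),
        n_enriched_terms=n_enriched,
        validation_issues=len(issues),
    )
    summary.to_json(out / "summary.json")
    return summary
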