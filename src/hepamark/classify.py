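"""Phenotype-anchored three-class sample assignment and rule diagnostics.

Classes:

* ``positive`` — any qualifying histopathological finding, irrespective of
  serum enzymes: morphology is the anchor.
* ``increased`` — no finding, but at least a two-fold rise (log2 delta >= 1)
  in either ALT or AST over the time-matched vehicle mean.
* ``negative`` — neither; vehicle animals are negative by definition.

Samples missing both ALT and AST keep their histopathology-driven label with
``alt_ast_evaluable=False`` and are excluded from every confusion-matrix
cell when the enzyme rule is scored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import DeltaMatrix
from .study import HistopathReport, SampleRecord, Study

logger = logging.getLogger("hepamark")

__all__ = [
    "ClassLabel", "ConfusionCounts", "histopath_positive", "alt_ast_increased",
    "assign_class", "classify_study", "rule_confusion", "sens_spec",
    "class_tally_by_treatment", "class_tally_by_platform",
]

#: log2 threshold of "at least a two-fold increase" (inclusive).
LOG2_TWOFOLD = 1.0

CLASS_ORDER = ("negative", "increased", "positive")


@dataclass(frozen=True)
class ClassLabel:
    label: str
    alt_ast_evaluable: bool = True

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {self.label!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


def histopath_positive(report: HistopathReport) -> bool:
    """True iff the toxicity-finding set is nonempty (observations ignored)."""
    return bool(report.findings)


def alt_ast_increased(
    delta_alt: float | None, delta_ast: float | None,
    log2_threshold: float = LOG2_TWOFOLD,
) -> bool | None:
    """Serum-enzyme rule on control-centered log2 deltas.

    Returns True iff the larger available delta is >= the threshold
    (decreases never trigger), ``None`` if both deltas are missing.
    """
    vals = [v for v in (delta_alt, delta_ast)
            if v is not None and not math.isnan(v)]
    if not vals:
        return None
    return max(vals) >= log2_threshold


def assign_class(
    sample: SampleRecord,
    report: HistopathReport | None,
    delta_alt: float | None,
    delta_ast: float | None,
    log2_threshold: float = LOG2_TWOFOLD,
) -> ClassLabel:
    """Assign one sample's class; histopathology overrides the enzyme rule."""
    rule = alt_ast_increased(delta_alt, delta_ast, log2_threshold)
    evaluable = rule is not None
    if sample.is_vehicle:
        if report is not None and histopath_positive(report):
            logger.warning(
                "vehicle sample %s has histopathological findings; forced "
                "negative", sample.sample_id,
            )
        elif rule is True:
            logger.warning(
                "vehicle sample %s exceeds the ALT/AST rule; forced negative",
                sample.sample_id,
            )
        return ClassLabel("negative", evaluable)
    if report is None:
        raise ValueError(
            f"non-vehicle sample {sample.sample_id!r} lacks a histopathology "
            "report"
        )
    if histopath_positive(report):
        return ClassLabel("positive", evaluable)
    if rule is True:
        return ClassLabel("increased", evaluable)
    return ClassLabel("negative", evaluable)


def classify_study(
    study: Study,
    delta_cc: DeltaMatrix | None,
    log2_threshold: float = LOG2_TWOFOLD,
) -> pd.DataFrame:
    """Classify every sample; returns a frame indexed by sample_id.

    ``delta_cc`` is the centered clinical-chemistry matrix; samples absent
    from it (or with both enzymes missing) are not evaluable for the rule.
    """
    reports = study.histopath_map
    rows = {}
    for s in study.samples:
        da = dast = None
        if delta_cc is not None and s.sample_id in delta_cc.values.columns:
            col = delta_cc.values[s.sample_id]
            da = float(col["ALT"]) if "ALT" in col.index else None
            dast = float(col["AST"]) if "AST" in col.index else None
        label = assign_class(s, reports.get(s.sample_id), da, dast,
                             log2_threshold)
        rows[s.sample_id] = (label.label, label.alt_ast_evaluable)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["class", "alt_ast_evaluable"]
    )
    df.index.name = "sample_id"
    return df


def alt_ast_rule_outcomes(
    study: Study,
    delta_cc: DeltaMatrix | None,
    log2_threshold: float = LOG2_TWOFOLD,
) -> pd.Series:
    """ALT/AST rule outcome per sample (True/False/None), study-aligned.

    Vehicle samples are forced False: their deviations define the zero point
    of the centering, so they are negative by definition and the rule is
    scored against treated animals only.
    """
    out = {}
    for s in study.samples:
        da = dast = None
        if delta_cc is not None and s.sample_id in delta_cc.values.columns:
            col = delta_cc.values[s.sample_id]
            da = float(col["ALT"]) if "ALT" in col.index else None
            dast = float(col["AST"]) if "AST" in col.index else None
        rule = alt_ast_increased(da, dast, log2_threshold)
        if s.is_vehicle and rule is True:
            rule = False
        out[s.sample_id] = rule
    return pd.Series(out, name="alt_ast_rule")


def rule_confusion(
    classes: Sequence[str], rule_outcome: Sequence[bool | None]
) -> ConfusionCounts:
    """Confusion counts of a binary rule against the positive class.

    Not-evaluable outcomes (``None``) are excluded from all four cells.
    For the ALT/AST rule the false positives are, by construction of the
    labels, exactly the evaluable "increased" samples.
    """
    if len(classes) != len(rule_outcome):
        raise ValueError("classes and rule outcomes differ in length")
    tp = fn = fp = tn = 0
    for cls, out in zip(classes, rule_outcome):
        if out is None:
            continue
        if cls == "positive":
            if out:
                tp += 1
            else:
                fn += 1
        else:
            if out:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def sens_spec(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, specificity) as fractions; NaN where undefined."""
    sens = (
        counts.tp / (counts.tp + counts.fn)
        if counts.tp + counts.fn > 0 else float("nan")
    )
    spec = (
        counts.tn / (counts.tn + counts.fp)
        if counts.tn + counts.fp > 0 else float("nan")
    )
    return sens, spec


def class_tally_by_treatment(study: Study, classes: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment class counts (rows: treatments plus a Sum row)."""
    frame = study.frame().join(classes)
    tab = (
        frame.groupby("treatment")["class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CLASS_ORDER), fill_value=0)
    )
    tab["total"] = tab.sum(axis=1)
    tab.loc["Sum"] = tab.sum(axis=0)
    tab.columns.name = None
    return tab


def class_tally_by_platform(study: Study, classes: pd.DataFrame) -> pd.DataFrame:
    """Per-platform class counts over the samples each matrix covers."""
    rows = {}
    for platform, m in study.matrices.items():
        observed = m.values.notna().any(axis=0)
        covered = [c for c in m.sample_ids if observed[c]]
        sub = classes.loc[classes.index.isin(covered), "class"]
        counts = sub.value_counts()
        rows[platform] = [int(counts.get(c, 0)) for c in CLASS_ORDER]
    tab = pd.DataFrame.from_dict(rows, orient="index", columns=list(CLASS_ORDER))
    tab["total"] = tab.sum(axis=1)
    tab.index.name = "platform"
    return tab
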