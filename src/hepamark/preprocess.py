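"""Log2 transformation and time-matched vehicle-control centering.

All downstream statistics operate on *deltas*: a sample's log2 value minus
the mean log2 value of the vehicle group with the same ``(study_id, time_h)``
key.  Control means are computed on the log2 scale (a geometric mean on the
raw scale); every vehicle group is therefore centered at zero by
construction.  Cells whose control group has no observed value for the
parameter become missing, with a logged warning, rather than silently
inheriting a global baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .study import MeasurementMatrix, SampleRecord, Study

logger = logging.getLogger("hepamark")

__all__ = ["DeltaMatrix", "to_log2", "center_on_controls", "log2fc_to_fc",
           "center_study"]


@dataclass
class DeltaMatrix:
    """Control-centered log2 deviations for one platform.

    ``provenance`` records, per sample, the control group used and how many
    control animals contributed.
    """

    platform: str
    values: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def to_log2(matrix: MeasurementMatrix) -> MeasurementMatrix:
    """Elementwise log2; refuses to transform an already-log2 matrix."""
    if matrix.scale == "log2":
        raise ValueError(
            f"{matrix.platform}: double transform — matrix is already log2"
        )
    vals = matrix.values
    bad = vals <= 0
    if bad.any(axis=None):
        for p in vals.index:
            row = bad.loc[p]
            if row.any():
                raise ValueError(
                    f"{matrix.platform}: nonpositive value at parameter "
                    f"{p!r}, sample {row.idxmax()!r}"
                )
    return MeasurementMatrix(
        platform=matrix.platform, scale="log2", values=np.log2(vals)
    )


def center_on_controls(
    matrix: MeasurementMatrix, samples: Sequence[SampleRecord]
) -> DeltaMatrix:
    """Subtract the time-matched vehicle-group mean from every cell.

    The matching key is ``(study_id, time_h)``.  A vehicle group of size one
    is allowed with a warning.  Samples whose key has no vehicle group, or
    parameters with zero observed control values in the matched group, yield
    missing cells and a warning.
    """
    if matrix.scale != "log2":
        raise ValueError("center_on_controls expects a log2-scale matrix")
    by_id = {s.sample_id: s for s in samples}
    unknown = [c for c in matrix.values.columns if c not in by_id]
    if unknown:
        raise ValueError(f"matrix sample(s) not in sample table: {unknown}")

    control_cols: dict[tuple[str, float], list[str]] = {}
    for s in samples:
        if s.is_vehicle and s.sample_id in matrix.values.columns:
            control_cols.setdefault(s.control_key, []).append(s.sample_id)
    if not control_cols:
        raise ValueError(f"{matrix.platform}: no vehicle samples in matrix")

    means: dict[tuple[str, float], pd.Series] = {}
    n_ctrl: dict[tuple[str, float], int] = {}
    for key, cols in control_cols.items():
        if len(cols) == 1:
            logger.warning(
                "%s: vehicle group %s has a single animal", matrix.platform, key
            )
        means[key] = matrix.values[cols].mean(axis=1)
        n_ctrl[key] = len(cols)

    out = {}
    prov_rows = []
    for sid in matrix.values.columns:
        key = by_id[sid].control_key
        if key not in means:
            logger.warning(
                "%s: sample %s has no matched vehicle group %s; cells set "
                "missing", matrix.platform, sid, key,
            )
            out[sid] = pd.Series(np.nan, index=matrix.values.index)
            prov_rows.append((sid, key[0], key[1], 0))
            continue
        baseline = means[key]
        centered = matrix.values[sid] - baseline
        n_missing_baseline = int(baseline.isna().sum())
        if n_missing_baseline:
            logger.warning(
                "%s: %d parameter(s) have no observed control value for "
                "group %s", matrix.platform, n_missing_baseline, key,
            )
        out[sid] = centered
        prov_rows.append((sid, key[0], key[1], n_ctrl[key]))
    values = pd.DataFrame(out, index=matrix.values.index)
    values.columns.name = None
    provenance = pd.DataFrame(
        prov_rows, columns=["sample_id", "control_study_id",
                            "control_time_h", "n_controls"]
    ).set_index("sample_id")
    return DeltaMatrix(platform=matrix.platform, values=values,
                       provenance=provenance)


def center_study(study: Study) -> dict[str, DeltaMatrix]:
    """log2-transform (where raw) and center every platform of a study."""
    deltas = {}
    for platform, m in study.matrices.items():
        m2 = to_log2(m) if m.scale == "raw" else m
        deltas[platform] = center_on_controls(m2, study.samples)
    return deltas


def log2fc_to_fc(x: float | np.ndarray) -> float | np.ndarray:
    """Linear fold change of a signed log2 fold change: 2**x."""
    return np.power(2.0, x) if isinstance(x, np.ndarray) else 2.0 ** float(x)
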