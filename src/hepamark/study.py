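"""Domain model and TSV I/O for multi-platform rat toxicology studies.

A *study* is one compound's dosing experiment: a set of animals (samples),
each dosed with the compound or its vehicle at one dose and sacrificed at one
time point, a histopathology report per animal, and one measurement matrix per
analytical platform (clinical chemistry in serum, metabolite profiles in serum
and liver, transcripts in liver).  Several independent studies can live in a
single :class:`Study` container; the ``study_id`` field keeps their vehicle
control groups apart.

Histopathology is the phenotypic anchor: a fixed set of liver finding codes
counts as evidence of hepatotoxicity, everything else (e.g. altered glycogen
content) is kept as a free-text observation that never drives classification.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hepamark")

VEHICLE = "vehicle"

#: Finding codes that count as evidence of liver toxicity.
TOXICITY_FINDINGS = frozenset(
    {
        "apoptosis_single_cell_necrosis",
        "inflammation",
        "hepatocellular_vacuolation_non_fat",
        "hemorrhage",
        "necrosis",
    }
)

#: Measurement platforms, in canonical order.
PLATFORMS = (
    "clinical_chemistry",
    "metabolites_serum",
    "metabolites_liver",
    "transcripts_liver",
)

SCALES = ("raw", "log2")

#: Sentinel finding code for "examined, nothing to report" histopathology rows.
NO_FINDING = "none"

#: Prefix marking a non-toxicity observation in the histopathology table.
OBSERVATION_PREFIX = "obs:"


@dataclass(frozen=True)
class SampleRecord:
    """One animal: treatment, dose, route and sacrifice time.

    ``treatment == "vehicle"`` if and only if ``dose == 0``; doses carry their
    unit as free text and are only ever ordered within one treatment, never
    compared across treatments.
    """

    sample_id: str
    study_id: str
    treatment: str
    dose: float
    dose_unit: str
    route: str
    time_h: float

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.time_h <= 0:
            raise ValueError(f"sample {self.sample_id}: time_h must be > 0")
        if self.dose < 0:
            raise ValueError(f"sample {self.sample_id}: dose must be >= 0")
        if (self.treatment == VEHICLE) != (self.dose == 0):
            raise ValueError(
                f"sample {self.sample_id}: treatment 'vehicle' and dose 0 "
                "must coincide"
            )

    @property
    def is_vehicle(self) -> bool:
        return self.treatment == VEHICLE

    @property
    def control_key(self) -> tuple[str, float]:
        """Key of the time-matched vehicle group this sample is centered on."""
        return (self.study_id, self.time_h)


@dataclass(frozen=True)
class HistopathReport:
    """Liver histopathology for one animal.

    ``findings`` holds toxicity finding codes only; free-text observations
    that do not indicate toxicity (glycogen content and the like) live in
    ``observations`` and are never used for classification.  ``grades`` maps
    a finding code to an integer severity grade where one was recorded — any
    grade of a qualifying finding counts the same for classification.
    """

    sample_id: str
    findings: frozenset[str] = frozenset()
    observations: tuple[str, ...] = ()
    grades: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.findings) - TOXICITY_FINDINGS
        if unknown:
            raise ValueError(
                f"sample {self.sample_id}: unknown finding code(s) "
                f"{sorted(unknown)}"
            )
        if set(self.observations) & TOXICITY_FINDINGS:
            raise ValueError(
                f"sample {self.sample_id}: toxicity findings and observations "
                "must be disjoint"
            )


@dataclass
class MeasurementMatrix:
    """One platform's parameters x samples table.

    ``values`` is a pandas DataFrame indexed by parameter id with one column
    per sample id.  ``scale`` is ``"raw"`` (strictly positive intensities) or
    ``"log2"``.  Missing cells are NaN and are first-class throughout the
    pipeline.
    """

    platform: str
    scale: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate parameter id(s) {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample id(s) {dupes}")
        self.values = self.values.astype(float)
        if self.scale == "raw":
            bad = (self.values <= 0).any(axis=None)
            if bad:
                p, s = _first_nonpositive(self.values)
                raise ValueError(
                    f"{self.platform}: raw-scale value <= 0 at parameter "
                    f"{p!r}, sample {s!r}"
                )

    @property
    def parameter_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _first_nonpositive(values: pd.DataFrame) -> tuple[str, str]:
    mask = values <= 0
    for p in values.index:
        row = mask.loc[p]
        if row.any():
            return str(p), str(row.idxmax())
    raise AssertionError("no nonpositive cell")  # pragma: no cover


@dataclass
class Study:
    """A collection of samples, histopathology reports and platform matrices."""

    samples: tuple[SampleRecord, ...]
    histopath: tuple[HistopathReport, ...]
    matrices: dict[str, MeasurementMatrix]

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.histopath = tuple(self.histopath)
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_id(s): {sorted(dupes)}")
        known = set(ids)
        for rep in self.histopath:
            if rep.sample_id not in known:
                raise ValueError(
                    f"histopathology report for unknown sample {rep.sample_id!r}"
                )
        for platform, m in self.matrices.items():
            if m.platform != platform:
                raise ValueError(
                    f"matrix keyed {platform!r} declares platform {m.platform!r}"
                )
            missing = set(m.sample_ids) - known
            if missing:
                raise ValueError(
                    f"{platform}: matrix sample(s) absent from sample table: "
                    f"{sorted(missing)}"
                )

    # -- lookups ---------------------------------------------------------

    @property
    def sample_map(self) -> dict[str, SampleRecord]:
        return {s.sample_id: s for s in self.samples}

    @property
    def histopath_map(self) -> dict[str, HistopathReport]:
        return {r.sample_id: r for r in self.histopath}

    @property
    def vehicle_ids(self) -> set[str]:
        return {s.sample_id for s in self.samples if s.is_vehicle}

    def control_groups(self) -> dict[tuple[str, float], list[str]]:
        """Vehicle sample ids per (study_id, time_h)."""
        groups: dict[tuple[str, float], list[str]] = {}
        for s in self.samples:
            if s.is_vehicle:
                groups.setdefault(s.control_key, []).append(s.sample_id)
        return groups

    def frame(self) -> pd.DataFrame:
        """Sample annotations as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            {
                "study_id": [s.study_id for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "dose": [s.dose for s in self.samples],
                "dose_unit": [s.dose_unit for s in self.samples],
                "route": [s.route for s in self.samples],
                "time_h": [s.time_h for s in self.samples],
            },
            index=pd.Index([s.sample_id for s in self.samples], name="sample_id"),
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    """One validation finding; never fatal, never mutating."""

    kind: str
    subject: str
    message: str


def validate_study(study: Study) -> list[Issue]:
    """Check a study for conditions that weaken downstream analysis.

    Reported issues: treated samples with no time-matched vehicle group in
    their study; parameters with fewer than two observed vehicle-control
    values; samples missing both ALT and AST (which downgrades their
    classification confidence).  Validation never mutates the study.
    """
    issues: list[Issue] = []
    groups = study.control_groups()
    for s in study.samples:
        if not s.is_vehicle and s.control_key not in groups:
            issues.append(
                Issue(
                    "no_matched_control",
                    s.sample_id,
                    f"no vehicle group for study {s.study_id!r} at "
                    f"{s.time_h} h",
                )
            )
    vehicle = study.vehicle_ids
    for platform, m in study.matrices.items():
        ctrl_cols = [c for c in m.sample_ids if c in vehicle]
        if not ctrl_cols:
            continue
        n_obs = m.values[ctrl_cols].notna().sum(axis=1)
        for pid in n_obs.index[n_obs < 2]:
            issues.append(
                Issue(
                    "few_control_values",
                    str(pid),
                    f"{platform}: parameter {pid!r} has {int(n_obs[pid])} "
                    "observed control value(s) (<2)",
                )
            )
    cc = study.matrices.get("clinical_chemistry")
    if cc is not None:
        for s in study.samples:
            sid = s.sample_id
            if sid not in cc.values.columns:
                both_missing = True
            else:
                col = cc.values[sid]
                alt = col.get("ALT", np.nan)
                ast = col.get("AST", np.nan)
                both_missing = bool(pd.isna(alt) and pd.isna(ast))
            if both_missing:
                issues.append(
                    Issue(
                        "no_alt_ast",
                        sid,
                        f"sample {sid!r} has neither ALT nor AST measured",
                    )
                )
    return issues


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = [
    "sample_id",
    "study_id",
    "treatment",
    "dose",
    "dose_unit",
    "route",
    "time_h",
]

_SIDECAR_RE = re.compile(r"^#platform=(\S+)\s+scale=(\S+)\s*$")


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    ids = df["sample_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate sample_id(s) {dupes}")
    return [
        SampleRecord(
            sample_id=row.sample_id,
            study_id=row.study_id,
            treatment=row.treatment,
            dose=float(row.dose),
            dose_unit=row.dose_unit,
            route=row.route,
            time_h=float(row.time_h),
        )
        for row in df.itertuples()
    ]


def read_histopath_table(path: str | Path) -> list[HistopathReport]:
    """Read the one-row-per-(sample, code) histopathology table.

    Codes are either one of :data:`TOXICITY_FINDINGS`, the sentinel ``none``
    (examined, no findings), or ``obs:<free text>`` for non-toxicity
    observations.  Anything else is a hard error naming the offending code.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "finding_code" not in df.columns:
        raise ValueError(f"{path}: expected columns sample_id, finding_code")
    reports: dict[str, dict] = {}
    for row in df.itertuples():
        rec = reports.setdefault(
            row.sample_id, {"findings": set(), "obs": [], "grades": {}}
        )
        code = row.finding_code
        if code == NO_FINDING:
            continue
        if code.startswith(OBSERVATION_PREFIX):
            rec["obs"].append(code[len(OBSERVATION_PREFIX):])
            continue
        if code not in TOXICITY_FINDINGS:
            raise ValueError(
                f"{path}: unknown finding code {code!r} for sample "
                f"{row.sample_id!r}"
            )
        rec["findings"].add(code)
        grade = getattr(row, "grade", None)
        if grade is not None and not pd.isna(grade) and str(grade) != "":
            rec["grades"][code] = int(float(grade))
    return [
        HistopathReport(
            sample_id=sid,
            findings=frozenset(rec["findings"]),
            observations=tuple(rec["obs"]),
            grades=rec["grades"],
        )
        for sid, rec in reports.items()
    ]


def read_matrix(path: str | Path) -> MeasurementMatrix:
    """Read a platform matrix TSV with its ``#platform=... scale=...`` sidecar line."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        m = _SIDECAR_RE.match(first)
        if not m:
            raise ValueError(
                f"{path}: first line must be '#platform=<p> scale=<raw|log2>'"
            )
        platform, scale = m.group(1), m.group(2)
        # round_trip parsing keeps write->read->write byte-identical
        df = pd.read_csv(fh, sep="\t", index_col=0,
                         float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "parameter_id"
    df.columns = df.columns.astype(str)
    return MeasurementMatrix(platform=platform, scale=scale, values=df)


def read_study(
    sample_table_path: str | Path,
    histopath_table_path: str | Path,
    matrix_paths: Iterable[str | Path],
) -> Study:
    """Assemble and validate a :class:`Study` from its TSV tables."""
    samples = read_sample_table(sample_table_path)
    histopath = read_histopath_table(histopath_table_path)
    matrices: dict[str, MeasurementMatrix] = {}
    for p in matrix_paths:
        m = read_matrix(p)
        if m.platform in matrices:
            raise ValueError(f"duplicate matrix for platform {m.platform!r}")
        matrices[m.platform] = m
    return Study(samples=tuple(samples), histopath=tuple(histopath), matrices=matrices)


def read_study_dir(directory: str | Path) -> Study:
    """Read a study written by :func:`write_study` from one directory."""
    directory = Path(directory)
    matrix_paths = sorted(
        p for p in directory.glob("*.tsv") if p.stem in PLATFORMS
    )
    return read_study(
        directory / "samples.tsv", directory / "histopath.tsv", matrix_paths
    )


def write_study(study: Study, directory: str | Path) -> dict[str, Path]:
    """Write a study as TSV tables; inverse of :func:`read_study_dir`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sp = directory / "samples.tsv"
    study.frame().reset_index().to_csv(sp, sep="\t", index=False)
    paths["samples"] = sp

    hp = directory / "histopath.tsv"
    rows = []
    for rep in study.histopath:
        codes = sorted(rep.findings)
        for code in codes:
            grade = rep.grades.get(code, "")
            rows.append((rep.sample_id, code, grade))
        for obs in rep.observations:
            rows.append((rep.sample_id, OBSERVATION_PREFIX + obs, ""))
        if not codes and not rep.observations:
            rows.append((rep.sample_id, NO_FINDING, ""))
    pd.DataFrame(rows, columns=["sample_id", "finding_code", "grade"]).to_csv(
        hp, sep="\t", index=False
    )
    paths["histopath"] = hp

    for platform, m in study.matrices.items():
        mp = directory / f"{platform}.tsv"
        with open(mp, "w") as fh:
            fh.write(f"#platform={platform} scale={m.scale}\n")
            m.values.to_csv(fh, sep="\t", index_label="parameter_id")
        paths[platform] = mp
    return paths
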