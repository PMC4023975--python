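"""Seeded synthetic toxicology studies with planted marker effects.

The generator stands in for the wet-lab study design: eight hepatotoxicant
treatments plus vehicle, 280 rats in groups of (mostly) five, sacrifice at
1.5/3/6/24 h, four measurement platforms.  Each animal carries a latent
*severity* — a monotone function of dose and time scaled by a per-compound
potency — which drives three observable layers:

* histopathology findings, sampled with probability ``p_histopath(severity)``
  (a logistic ramp around a threshold severity);
* coupled ALT/AST elevations proportional to severity, so that some animals
  exceed the two-fold serum-enzyme rule without histopathological findings —
  these populate the "increased" class *mechanistically*, the classifier has
  to rediscover them;
* planted log2 mean shifts on marker parameters, expressed as a monotone
  fraction of the full positive-class effect (see :func:`effect_fraction`).

Measurement noise is log-normal (Gaussian on the log2 scale) with default
standard deviation 0.5, which puts ~95% of vehicle-control deviations within
two-fold and rare excursions near four-fold — the control-variation envelope
the real studies show.

Randomness is counter-based: every parameter row and every sample draws from
its own Philox stream keyed by (seed, purpose, platform, id), so adding
parameters to a platform never reshuffles draws of existing ones.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .study import (
    PLATFORMS,
    VEHICLE,
    HistopathReport,
    MeasurementMatrix,
    SampleRecord,
    Study,
)

__all__ = [
    "EffectSpec",
    "TreatmentGroup",
    "SimulationConfig",
    "TruthTable",
    "default_design",
    "default_effects",
    "default_config",
    "generate_study",
    "control_envelope",
    "expected_severity",
    "effect_fraction",
    "p_histopath",
]

#: log2 threshold of the serum-enzyme rule (two-fold).
ALT_AST_LOG2_THRESHOLD = 1.0

CLINICAL_CHEMISTRY_PARAMETERS = [
    "ALT", "ALB", "ALP", "AGLOB", "AST", "BGLOB", "Bilirubin", "BA",
    "Ca", "Cl", "Cholesterol", "Creatinine", "GGLOB", "GGT", "Glucose",
    "PI", "LDH", "K", "Na", "SDH", "Total_protein", "Triglycerides", "Urea",
]

_SERUM_MET_PLANTED = [
    ("Taurocholic_acid", 5.35),
    ("Glycocholic_acid", 3.42),
    ("Taurochenodeoxycholic_acid", 3.21),
    ("Glucuronic_acid", 1.39),
    ("Arginine", -1.25),
]

_LIVER_MET_PLANTED = [
    ("Putrescine_agmatine", 2.02),
    ("Glycochenodeoxycholic_acid", -1.34),
    ("Taurocholic_acid", 1.15),
    ("liver_unknown_1", 1.12),
    ("Maltotriose", -1.06),
]

_TRANSCRIPT_PLANTED_NAMED = [
    ("M58634_at", 2.94),        # Igfbp1
    ("AF023087_s_at", 2.73),    # Egr1
    ("U75397UTR1_s_at", 2.65),  # Egr1
    ("M18416_at", 2.63),        # Egr1
    ("D38066exon_s_at", 2.23),  # Ugt1a2
    ("M60921_g_at", 2.20),      # Btg2
    ("rc_AI175959_at", 2.05),   # Jun
    ("rc_AA944156_s_at", 2.04), # Btg2
    ("rc_AA900505_at", 1.97),   # Rhob
    ("M63282_at", 1.86),        # Atf3
]

_CC_PLANTED = [
    ("Bilirubin", 3.18),
    ("BA", 2.94),
    ("GGT", 2.61),
    ("SDH", 2.12),
    ("LDH", 1.74),
]


@dataclass(frozen=True)
class EffectSpec:
    """A planted mean shift on one parameter.

    ``delta_log2_positive`` is the full shift expressed by a histopathology-
    positive animal; ``increased_fraction`` is the fraction of that shift
    expressed by an animal sitting exactly at the serum-enzyme rule threshold
    (the typical "increased" animal).
    """

    parameter_id: str
    platform: str
    delta_log2_positive: float
    increased_fraction: float = 0.5

    def __post_init__(self) -> None:
        if abs(self.delta_log2_positive) > 8:
            raise ValueError("|delta_log2_positive| must be <= 8")
        if not 0 <= self.increased_fraction <= 1:
            raise ValueError("increased_fraction must be in [0, 1]")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")


@dataclass(frozen=True)
class TreatmentGroup:
    """One dosing group: (study, treatment, dose, time) with n animals."""

    study_id: str
    treatment: str
    dose: float
    dose_unit: str
    route: str
    time_h: float
    n: int
    metabolite_profiled: bool = True


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the emulated study design."""

    seed: int = 0
    design: tuple[TreatmentGroup, ...] = ()
    platform_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "clinical_chemistry": 23,
            "metabolites_serum": 50,
            "metabolites_liver": 80,
            "transcripts_liver": 500,
        }
    )
    noise_sd_log2: float = 0.5
    #: expected severity at the treatment's maximum design dose at 24 h.
    severity_potency: dict[str, float] = field(default_factory=dict)
    dose_exponent: float = 1.3
    time_exponent: float = 0.3
    severity_noise_sd: float = 0.25
    #: p_histopath = logistic((severity - threshold) / width)
    hist_threshold: float = 2.0
    hist_width: float = 0.25
    alt_ast_coupling: float = 1.0
    effects: tuple[EffectSpec, ...] = ()
    missing_rates: dict[str, float] = field(default_factory=dict)
    default_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be > 0")
        if self.hist_width <= 0:
            raise ValueError("hist_width must be > 0")
        self.design = tuple(self.design)
        self.effects = tuple(self.effects)


@dataclass
class TruthTable:
    """Ground truth of one generated study.

    ``parameters``: per parameter_id — platform, planted flag, planted shift.
    ``samples``: per sample_id — latent severity and the class the generator's
    own noiseless bookkeeping assigns (histopathology draw, then the enzyme
    rule on the generated pre-missingness ALT/AST deviations).
    """

    parameters: pd.DataFrame
    samples: pd.DataFrame


# ---------------------------------------------------------------------------
# deterministic severity / probability maps
# ---------------------------------------------------------------------------


def p_histopath(severity: float | np.ndarray, threshold: float = 2.0,
                width: float = 0.25) -> np.ndarray:
    """Monotone nondecreasing probability of a qualifying liver finding."""
    s = np.asarray(severity, dtype=float)
    return 1.0 / (1.0 + np.exp(-(s - threshold) / width))


def expected_severity(config: SimulationConfig, treatment: str, dose: float,
                      time_h: float) -> float:
    """Noise-free latent severity: potency x dose ramp x time ramp.

    Monotone nondecreasing in dose at fixed time and in time at fixed dose;
    identically zero for vehicle.
    """
    if treatment == VEHICLE or dose == 0:
        return 0.0
    potency = config.severity_potency.get(treatment, 0.0)
    dmax = max(
        (g.dose for g in config.design if g.treatment == treatment),
        default=dose,
    )
    return (
        potency
        * (dose / dmax) ** config.dose_exponent
        * (time_h / 24.0) ** config.time_exponent
    )


def effect_fraction(severity: float, increased_fraction: float,
                    hist_threshold: float = 2.0) -> float:
    """Fraction of the full positive-class shift expressed at a severity.

    Convex quadratic ramp from 0 up to ``increased_fraction`` at the enzyme-
    rule threshold severity (1.0), then linear up to 1 at the histopathology
    threshold, constant beyond.  Sub-threshold animals therefore express only
    a small part of the molecular response, matching the idea that early
    injury precedes but does not equal overt injury.
    """
    s = float(severity)
    a = ALT_AST_LOG2_THRESHOLD
    if s <= 0:
        return 0.0
    if s < a:
        return increased_fraction * (s / a) ** 2
    if s >= hist_threshold:
        return 1.0
    span = hist_threshold - a
    if span <= 0:
        return 1.0
    return increased_fraction + (1 - increased_fraction) * (s - a) / span


# ---------------------------------------------------------------------------
# default study design (280 animals, 8 compounds + vehicle)
# ---------------------------------------------------------------------------


def default_design() -> tuple[TreatmentGroup, ...]:
    """The emulated dosing design: 180 treated + 100 vehicle animals.

    Group size is 5 except where a printed per-treatment total forces 4
    (three Cyclosporine A groups, two Erythromycin groups).  Metabolite
    profiling skips part of the Cyclosporine A and Phalloidin groups and
    their vehicle groups, so the metabolite platforms cover a sample subset.
    """
    g: list[TreatmentGroup] = []

    def add(study, treatment, dose, unit, route, time_h, n, profiled=True):
        g.append(TreatmentGroup(study, treatment, dose, unit, route, time_h, n,
                                profiled))

    # ANIT: 30/150 mg/kg p.o., 24 h
    for dose in (30.0, 150.0):
        add("ANIT", "ANIT", dose, "mg/kg", "p.o.", 24.0, 5)
    # Amineptine: 0.125 mM/kg at 24 h; 0.25/0.5 mM/kg at 3/6/24 h (i.p.)
    add("Amineptine", "Amineptine", 0.125, "mM/kg", "i.p.", 24.0, 5)
    for dose in (0.25, 0.5):
        for t in (3.0, 6.0, 24.0):
            add("Amineptine", "Amineptine", dose, "mM/kg", "i.p.", t, 5)
    # Cyclosporine A: 5/15/30 mg/kg i.v., 1.5/3/6 h; the 5 mg/kg groups are
    # size 4 and, with the early time points, are not metabolite-profiled.
    for dose in (5.0, 15.0, 30.0):
        for t in (1.5, 3.0, 6.0):
            n = 4 if dose == 5.0 else 5
            profiled = dose != 5.0 and t == 6.0
            add("CyclosporineA", "CyclosporineA", dose, "mg/kg", "i.v.", t, n,
                profiled)
    # Erythromycin: 734 mg/kg i.p., 1.5/3/6 h
    for t, n in ((1.5, 5), (3.0, 4), (6.0, 4)):
        add("Erythromycin", "Erythromycin", 734.0, "mg/kg", "i.p.", t, n)
    # Glibenclamide: 2.5/25 mg/kg i.v., 24 h
    for dose in (2.5, 25.0):
        add("Glibenclamide", "Glibenclamide", dose, "mg/kg", "i.v.", 24.0, 5)
    # Methylene Dianiline: 20/100 mg/kg p.o., 3/6/24 h
    for dose in (20.0, 100.0):
        for t in (3.0, 6.0, 24.0):
            add("MethyleneDianiline", "MethyleneDianiline", dose, "mg/kg",
                "p.o.", t, 5)
    # Phalloidin: 0.2/0.8 mg/kg i.v., 3/6/24 h; 3 and 6 h not profiled.
    for dose in (0.2, 0.8):
        for t in (3.0, 6.0, 24.0):
            add("Phalloidin", "Phalloidin", dose, "mg/kg", "i.v.", t, 5,
                t == 24.0)
    # Tetracycline: 0.2 mM/kg i.p., 3/6 h
    for t in (3.0, 6.0):
        add("Tetracycline", "Tetracycline", 0.2, "mM/kg", "i.p.", t, 5)

    # Vehicle groups: one per (study, time) a treated group references;
    # the ANIT group holds 10 animals so the vehicle total is 100.
    vehicle_times = {
        "ANIT": [24.0],
        "Amineptine": [3.0, 6.0, 24.0],
        "CyclosporineA": [1.5, 3.0, 6.0],
        "Erythromycin": [1.5, 3.0, 6.0],
        "Glibenclamide": [24.0],
        "MethyleneDianiline": [3.0, 6.0, 24.0],
        "Phalloidin": [3.0, 6.0, 24.0],
        "Tetracycline": [3.0, 6.0],
    }
    unprofiled_vehicle = {("CyclosporineA", 1.5), ("CyclosporineA", 3.0),
                          ("Phalloidin", 3.0), ("Phalloidin", 6.0)}
    for study, times in vehicle_times.items():
        for t in times:
            n = 10 if study == "ANIT" else 5
            add(study, VEHICLE, 0.0, "mg/kg", "several", t, n,
                (study, t) not in unprofiled_vehicle)
    return tuple(g)


def _default_potencies() -> dict[str, float]:
    # Expected severity at the maximum design dose at 24 h.  Chosen so the
    # histopathology threshold (2.0) separates the overtly toxic groups
    # (ANIT high dose, Erythromycin, Methylene Dianiline and Phalloidin high
    # doses) from the enzyme-only responders (Amineptine, Tetracycline) and
    # the inert regimens (Cyclosporine A, Glibenclamide).
    return {
        "ANIT": 2.3,
        "Amineptine": 1.5,
        "CyclosporineA": 0.9,
        "Erythromycin": 2.9,
        "Glibenclamide": 0.3,
        "MethyleneDianiline": 4.9,
        "Phalloidin": 4.9,
        "Tetracycline": 2.4,
    }


def default_effects(platform_sizes: Mapping[str, int] | None = None,
                    increased_fraction: float = 0.5) -> tuple[EffectSpec, ...]:
    """The 73 planted marker shifts (ALT and AST come from severity coupling).

    Five clinical chemistry analytes, five metabolites per matrix and 58
    transcripts carry log2 shifts in the range the real marker tables span;
    ten transcripts reuse published probe-set magnitudes, the remaining 48
    are spread over 1.05-1.95 with a minority down-regulated.
    """
    effects = [
        EffectSpec(pid, "clinical_chemistry", d, increased_fraction)
        for pid, d in _CC_PLANTED
    ]
    effects += [
        EffectSpec(pid, "metabolites_serum", d, increased_fraction)
        for pid, d in _SERUM_MET_PLANTED
    ]
    effects += [
        EffectSpec(pid, "metabolites_liver", d, increased_fraction)
        for pid, d in _LIVER_MET_PLANTED
    ]
    effects += [
        EffectSpec(pid, "transcripts_liver", d, increased_fraction)
        for pid, d in _TRANSCRIPT_PLANTED_NAMED
    ]
    deltas = np.linspace(1.95, 1.05, 48)
    down = {5, 13, 21, 29, 37, 45}  # up-regulation dominates, as observed
    for i, d in enumerate(deltas):
        sign = -1.0 if i in down else 1.0
        effects.append(
            EffectSpec(f"probe_{i + 11:04d}_at", "transcripts_liver",
                       sign * round(float(d), 3), increased_fraction)
        )
    return tuple(effects)


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        design=default_design(),
        severity_potency=_default_potencies(),
        effects=default_effects(),
        missing_rates={"GGT": 0.4},
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _stream(*keys) -> np.random.Generator:
    """A Philox stream keyed by a stable hash of the key tuple."""
    digest = hashlib.blake2s(
        ":".join(str(k) for k in keys).encode(), digest_size=16
    ).digest()
    return np.random.Generator(
        np.random.Philox(key=int.from_bytes(digest, "little"))
    )


def _parameter_ids(config: SimulationConfig) -> dict[str, list[str]]:
    sizes = config.platform_sizes
    out: dict[str, list[str]] = {}
    if "clinical_chemistry" in sizes:
        n = sizes["clinical_chemistry"]
        if n != len(CLINICAL_CHEMISTRY_PARAMETERS):
            raise ValueError(
                "clinical_chemistry size must equal the fixed panel of "
                f"{len(CLINICAL_CHEMISTRY_PARAMETERS)} analytes"
            )
        out["clinical_chemistry"] = list(CLINICAL_CHEMISTRY_PARAMETERS)
    prefixes = {
        "metabolites_serum": "serum_met",
        "metabolites_liver": "liver_met",
        "transcripts_liver": "probe",
    }
    for platform, prefix in prefixes.items():
        if platform not in sizes:
            continue
        n = sizes[platform]
        # planted parameters come first, under their own names
        ids = list(dict.fromkeys(
            e.parameter_id for e in config.effects if e.platform == platform
        ))
        if len(ids) > n:
            raise ValueError(
                f"{platform}: platform size {n} smaller than the "
                f"{len(ids)} planted/named parameters"
            )
        i = 1
        suffix = "_at" if platform == "transcripts_liver" else ""
        while len(ids) < n:
            cand = f"{prefix}_{i:04d}{suffix}"
            if cand not in ids:
                ids.append(cand)
            i += 1
        out[platform] = ids
    return out


_BASELINE_RANGES = {
    "clinical_chemistry": (5.0, 1.5),
    "metabolites_serum": (10.0, 2.0),
    "metabolites_liver": (10.0, 2.0),
    "transcripts_liver": (8.0, 2.0),
}

_EXTRA_FINDING_OFFSETS = {
    "inflammation": 0.3,
    "necrosis": 0.5,
    "hemorrhage": 0.7,
}


def generate_study(config: SimulationConfig) -> tuple[Study, TruthTable]:
    """Generate one study and its ground truth; bit-stable for a fixed config."""
    if not config.design:
        raise ValueError("design is empty")
    for g in config.design:
        if g.n < 2:
            raise ValueError(
                f"group ({g.study_id}, {g.treatment}, {g.dose}, {g.time_h} h) "
                f"has n={g.n} < 2"
            )
    param_ids = _parameter_ids(config)
    for e in config.effects:
        if e.platform not in param_ids:
            raise ValueError(
                f"effect {e.parameter_id!r} references absent platform "
                f"{e.platform!r}"
            )
        if e.parameter_id not in param_ids[e.platform]:
            raise ValueError(
                f"effect references unknown parameter {e.parameter_id!r} "
                f"on {e.platform}"
            )
    effect_map: dict[tuple[str, str], EffectSpec] = {
        (e.platform, e.parameter_id): e for e in config.effects
    }

    # --- samples, severity, histopathology -----------------------------
    samples: list[SampleRecord] = []
    profiled: set[str] = set()
    severity: dict[str, float] = {}
    reports: list[HistopathReport] = []
    counter = 0
    for g in config.design:
        exp_sev = expected_severity(config, g.treatment, g.dose, g.time_h)
        for k in range(g.n):
            counter += 1
            sid = f"s{counter:03d}"
            samples.append(
                SampleRecord(sid, g.study_id, g.treatment, g.dose,
                             g.dose_unit, g.route, g.time_h)
            )
            if g.metabolite_profiled:
                profiled.add(sid)
            rng = _stream(config.seed, "sample", sid)
            sev = 0.0
            if exp_sev > 0:
                sev = exp_sev * math.exp(
                    rng.normal(0.0, config.severity_noise_sd)
                )
            else:
                rng.normal()  # keep the draw count aligned
            severity[sid] = sev
            findings: set[str] = set()
            p_pos = float(
                p_histopath(sev, config.hist_threshold, config.hist_width)
            )
            if rng.uniform() < p_pos:
                findings.add("apoptosis_single_cell_necrosis")
                for code, off in _EXTRA_FINDING_OFFSETS.items():
                    p_extra = 1.0 / (1.0 + math.exp(
                        -(sev - config.hist_threshold - off) / config.hist_width
                    ))
                    if rng.uniform() < p_extra:
                        findings.add(code)
                if rng.uniform() < 0.15:
                    findings.add("hepatocellular_vacuolation_non_fat")
            obs: tuple[str, ...] = ()
            if rng.uniform() < 0.08:
                obs = ("glycogen content",)
            reports.append(
                HistopathReport(sid, frozenset(findings), obs)
            )

    sample_ids = [s.sample_id for s in samples]
    sev_arr = np.array([severity[s] for s in sample_ids])

    # --- matrices -------------------------------------------------------
    matrices: dict[str, MeasurementMatrix] = {}
    alt_ast_dev: dict[str, np.ndarray] = {}
    param_rows = []
    for platform, pids in param_ids.items():
        cols = (
            [s for s in sample_ids if s in profiled]
            if platform.startswith("metabolites")
            else list(sample_ids)
        )
        col_sev = np.array([severity[s] for s in cols])
        mu, sd = _BASELINE_RANGES[platform]
        data = np.empty((len(pids), len(cols)))
        for i, pid in enumerate(pids):
            rng = _stream(config.seed, "values", platform, pid)
            baseline = rng.normal(mu, sd)
            effect = np.zeros(len(cols))
            spec = effect_map.get((platform, pid))
            if spec is not None:
                frac = np.array([
                    effect_fraction(s, spec.increased_fraction,
                                    config.hist_threshold)
                    for s in col_sev
                ])
                effect = spec.delta_log2_positive * frac
            if platform == "clinical_chemistry" and pid in ("ALT", "AST"):
                effect = effect + config.alt_ast_coupling * col_sev
            noise = rng.normal(0.0, config.noise_sd_log2, len(cols))
            if platform == "clinical_chemistry" and pid in ("ALT", "AST"):
                alt_ast_dev[pid] = effect + noise
            log2_vals = baseline + effect + noise
            rate = config.missing_rates.get(pid, config.default_missing_rate)
            row = np.power(2.0, log2_vals)
            if rate > 0:
                row[rng.uniform(size=len(cols)) < rate] = np.nan
            data[i] = row
            delta = (
                effect_map[(platform, pid)].delta_log2_positive
                if (platform, pid) in effect_map else 0.0
            )
            frac_inc = (
                effect_map[(platform, pid)].increased_fraction
                if (platform, pid) in effect_map else np.nan
            )
            param_rows.append((pid, platform, (platform, pid) in effect_map,
                               delta, frac_inc))
        matrices[platform] = MeasurementMatrix(
            platform=platform,
            scale="raw",
            values=pd.DataFrame(
                data, index=pd.Index(pids, name="parameter_id"), columns=cols
            ),
        )

    # --- truth ----------------------------------------------------------
    hist_pos = {r.sample_id: bool(r.findings) for r in reports}
    true_class = []
    for j, sid in enumerate(sample_ids):
        if hist_pos[sid]:
            true_class.append("positive")
            continue
        dev = max(
            (alt_ast_dev[p][j] for p in alt_ast_dev if j < len(alt_ast_dev[p])),
            default=-np.inf,
        )
        true_class.append(
            "increased" if dev >= ALT_AST_LOG2_THRESHOLD else "negative"
        )
    truth = TruthTable(
        parameters=pd.DataFrame(
            param_rows,
            columns=["parameter_id", "platform", "planted",
                     "delta_log2_positive", "increased_fraction"],
        ).set_index("parameter_id"),
        samples=pd.DataFrame(
            {"severity": sev_arr, "true_class": true_class},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    study = Study(samples=tuple(samples), histopath=tuple(reports),
                  matrices=matrices)
    return study, truth


# ---------------------------------------------------------------------------
# control envelope
# ---------------------------------------------------------------------------


def control_envelope(study: Study) -> dict[str, float]:
    """Fractions of vehicle-control log2 deviations within 2- and 4-fold.

    Deviations are taken from the time-matched vehicle group mean on the log2
    scale, pooled over all platforms and parameters.  With the default noise
    sd of 0.5 and large groups the two-fold fraction approaches
    P(|N(0, 0.5)| <= 1) ~ 0.954.
    """
    groups = study.control_groups()
    if not groups:
        raise ValueError("study has no vehicle samples")
    devs: list[np.ndarray] = []
    for m in study.matrices.values():
        log2_vals = np.log2(m.values) if m.scale == "raw" else m.values
        for ids in groups.values():
            cols = [c for c in ids if c in log2_vals.columns]
            if not cols:
                continue
            block = log2_vals[cols]
            centered = block.sub(block.mean(axis=1), axis=0)
            devs.append(centered.to_numpy().ravel())
    pooled = np.concatenate(devs)
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("no observed control values")
    return {
        "n_deviations": int(pooled.size),
        "within_2fold": float(np.mean(np.abs(pooled) <= 1.0)),
        "within_4fold": float(np.mean(np.abs(pooled) <= 2.0)),
    }
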