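"""Positive-vs-negative differential testing, FDR, ranking and summaries.

The statistical comparison is a pooled-variance two-sample t-test of the
positive class against the negative class on control-centered log2 deltas,
with the "increased" class held out entirely.  Multiple testing is adjusted
per platform with the Benjamini-Hochberg step-up procedure; a parameter is
*significant* when its FDR is below 0.05 and its absolute log2 fold change
exceeds 1 (|FC| > 2).  The log2 fold change is the difference of class means
(positive minus negative) — since the negative class is approximately
centered at zero this nearly coincides with the positive-class mean itself,
but the difference form is symmetric and directly testable.

The t statistic is computed in-package (vectorized over parameters) so that
library implementations remain available as independent cross-checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import DeltaMatrix

logger = logging.getLogger("hepamark")

__all__ = [
    "MarkerResult", "ClassProfile", "HeatmapData", "OutlierFlag",
    "ttest_equal_var", "bh_fdr", "discover_markers", "rank_markers",
    "class_profile", "heatmap_matrix", "flag_outliers", "markers_to_frame",
]

#: Row-block order of the combined heatmap.
HEATMAP_PLATFORM_ORDER = (
    "transcripts_liver",
    "metabolites_serum",
    "metabolites_liver",
    "clinical_chemistry",
)

#: Column-block order of the combined heatmap.
HEATMAP_CLASS_ORDER = (
    "control_negative", "treated_negative", "increased", "positive",
)


@dataclass(frozen=True)
class MarkerResult:
    """Outcome of one parameter's positive-vs-negative test."""

    parameter_id: str
    platform: str
    t_statistic: float
    p_value: float
    fdr: float
    logfc: float
    fc: float
    n_positive: int
    n_negative: int
    significant: bool
    rank: int | None = None
    note: str | None = None


def ttest_equal_var(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed pooled-variance Student t-test, df = n_a + n_b - 2.

    Missing values are dropped first.  Degenerate inputs: two identical
    constant groups give (0, 1); zero pooled variance with unequal means
    gives (+-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 observed values")
    ma, mb = a.mean(), b.mean()
    pooled = ((a - ma) ** 2).sum() + ((b - mb) ** 2).sum()
    df = na + nb - 2
    se = math.sqrt(pooled / df * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    if se == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved.

    Missing p-values are excluded from the adjustment and returned missing;
    any p outside [0, 1] is an error.
    """
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def discover_markers(
    delta: DeltaMatrix,
    classes: Mapping[str, str] | pd.Series | pd.DataFrame,
    fdr_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> list[MarkerResult]:
    """Test every parameter of one platform, positive vs negative.

    "Increased" samples are excluded before testing; the BH adjustment runs
    over this platform's testable parameters only.  Parameters with fewer
    than two observed values in either class are skipped with a logged
    reason.  Returns unranked results in the matrix's parameter order.
    """
    cls = _as_class_map(classes)
    pos_cols = [c for c in delta.values.columns if cls.get(c) == "positive"]
    neg_cols = [c for c in delta.values.columns if cls.get(c) == "negative"]
    if not pos_cols:
        logger.warning("%s: no positive samples; no markers testable",
                       delta.platform)
        return []
    if not neg_cols:
        logger.warning("%s: no negative samples; no markers testable",
                       delta.platform)
        return []

    A = delta.values[pos_cols].to_numpy(float)
    B = delta.values[neg_cols].to_numpy(float)
    na = (~np.isnan(A)).sum(axis=1)
    nb = (~np.isnan(B)).sum(axis=1)
    testable = (na >= 2) & (nb >= 2)
    for pid in delta.values.index[~testable]:
        logger.warning(
            "%s: parameter %s skipped (<2 observed values in a class)",
            delta.platform, pid,
        )
    if not testable.any():
        return []

    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        ma = np.nanmean(np.where(testable[:, None], A, np.nan), axis=1)
        mb = np.nanmean(np.where(testable[:, None], B, np.nan), axis=1)
        ssa = np.nansum((A - ma[:, None]) ** 2, axis=1)
        ssb = np.nansum((B - mb[:, None]) ** 2, axis=1)
    df = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt((ssa + ssb) / df * (1.0 / na + 1.0 / nb))
        t = (ma - mb) / se
    p = np.where(
        se == 0,
        np.where(ma == mb, 1.0, 0.0),
        2.0 * stats.t.sf(np.abs(np.where(se == 0, 1.0, t)), df),
    )
    t = np.where((se == 0) & (ma == mb), 0.0,
                 np.where(se == 0, np.sign(ma - mb) * np.inf, t))

    fdr = np.full(len(p), np.nan)
    fdr[testable] = bh_fdr(p[testable])
    logfc = ma - mb
    log2_fc_cut = math.log2(fc_threshold)

    results = []
    for i, pid in enumerate(delta.values.index):
        if not testable[i]:
            continue
        note = None
        if se[i] == 0:
            note = "degenerate variance"
        significant = bool(
            fdr[i] < fdr_threshold and abs(logfc[i]) > log2_fc_cut
        )
        results.append(
            MarkerResult(
                parameter_id=str(pid),
                platform=delta.platform,
                t_statistic=float(t[i]),
                p_value=float(p[i]),
                fdr=float(fdr[i]),
                logfc=float(logfc[i]),
                fc=float(2.0 ** logfc[i]),
                n_positive=int(na[i]),
                n_negative=int(nb[i]),
                significant=significant,
                note=note,
            )
        )
    return results


def rank_markers(results: Sequence[MarkerResult]) -> list[MarkerResult]:
    """Rank by p-value, then |logFC| (larger first), then parameter id.

    The parameter-id tie-break makes the ranking deterministic under input
    permutation.  Rank 1 is the best marker.
    """
    ordered = sorted(
        results,
        key=lambda r: (r.p_value, -abs(r.logfc), r.parameter_id),
    )
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def markers_to_frame(
    results: Sequence[MarkerResult], rounded: bool = False
) -> pd.DataFrame:
    """Results as a DataFrame; ``rounded`` emits the 2-decimal report shape."""
    df = pd.DataFrame(
        {
            "parameter_id": [r.parameter_id for r in results],
            "platform": [r.platform for r in results],
            "rank": [r.rank for r in results],
            "t": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "FDR": [r.fdr for r in results],
            "logFC": [r.logfc for r in results],
            "FC": [r.fc for r in results],
            "n_positive": [r.n_positive for r in results],
            "n_negative": [r.n_negative for r in results],
            "significant": [r.significant for r in results],
        }
    )
    if rounded:
        for col in ("FDR", "logFC", "FC"):
            df[col] = df[col].round(2)
    return df


# ---------------------------------------------------------------------------
# class profiles (smoothed distributions of per-parameter class means)
# ---------------------------------------------------------------------------


@dataclass
class ClassProfile:
    """Per-class distribution of per-parameter mean deltas.

    ``means`` is parameters x classes; each density is a Gaussian kernel
    estimate of that class's column, all on the shared ``grid``.
    """

    means: pd.DataFrame
    grid: np.ndarray
    densities: dict[str, np.ndarray]
    bandwidth: float


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if n > 1:
        q75, q25 = np.percentile(x, [75, 25])
        iqr = q75 - q25
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    else:
        spread = 0.0
    if spread <= 0:
        return 0.1  # degenerate spread: fixed narrow kernel
    return 0.9 * spread * n ** (-0.2)


def class_profile(
    delta: DeltaMatrix | pd.DataFrame,
    classes: Mapping[str, str] | pd.Series | pd.DataFrame,
    parameters: Sequence[str],
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> ClassProfile:
    """Class-mean deltas for selected parameters, with smoothed densities.

    Vehicle controls carry the "negative" label and therefore contribute to
    the negative class.  The kernel bandwidth defaults to Silverman's rule
    on the pooled class means; the grid extends six bandwidths beyond the
    data so each density integrates to one to high accuracy.
    """
    values = delta.values if isinstance(delta, DeltaMatrix) else delta
    if len(parameters) == 0:
        raise ValueError("need at least one selected parameter")
    missing = [p for p in parameters if p not in values.index]
    if missing:
        raise ValueError(f"unknown parameter(s) {missing}")
    cls = _as_class_map(classes)
    sub = values.loc[list(parameters)]

    means = {}
    for c in ("negative", "increased", "positive"):
        cols = [s for s in sub.columns if cls.get(s) == c]
        if not cols:
            logger.warning("class %s has no samples; density omitted", c)
            continue
        means[c] = sub[cols].mean(axis=1)
    means_df = pd.DataFrame(means)

    pooled = means_df.to_numpy().ravel()
    pooled = pooled[~np.isnan(pooled)]
    bw = bandwidth if bandwidth is not None else _silverman_bandwidth(pooled)
    lo = float(np.min(pooled)) - 6.0 * bw
    hi = float(np.max(pooled)) + 6.0 * bw
    grid = np.linspace(lo, hi, grid_size)

    densities = {}
    norm = 1.0 / (bw * math.sqrt(2.0 * math.pi))
    for c in means_df.columns:
        m = means_df[c].to_numpy()
        m = m[~np.isnan(m)]
        if m.size == 0:
            continue
        z = (grid[:, None] - m[None, :]) / bw
        densities[c] = norm * np.exp(-0.5 * z * z).mean(axis=1)
    return ClassProfile(means=means_df, grid=grid, densities=densities,
                        bandwidth=bw)


# ---------------------------------------------------------------------------
# heatmap-style combined matrix
# ---------------------------------------------------------------------------


@dataclass
class HeatmapData:
    """Selected-marker deltas, columns grouped by class, rows by platform."""

    values: pd.DataFrame
    row_platforms: pd.Series
    column_groups: pd.Series

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "platform", self.row_platforms)
        header = pd.DataFrame(
            [["__group__"] + list(self.column_groups)],
            columns=["platform"] + list(df.columns[1:]),
            index=pd.Index(["__group__"], name=df.index.name),
        )
        pd.concat([header, df]).to_csv(path, sep="\t", index_label="parameter_id")

    @classmethod
    def from_tsv(cls, path) -> "HeatmapData":
        df = pd.read_csv(path, sep="\t", index_col=0)
        groups = pd.Series(df.loc["__group__"][1:], name="group")
        df = df.drop(index="__group__")
        platforms = df["platform"]
        values = df.drop(columns="platform").astype(float)
        return cls(values=values, row_platforms=platforms,
                   column_groups=groups)


def heatmap_matrix(
    deltas: Mapping[str, DeltaMatrix],
    classes: Mapping[str, str] | pd.Series | pd.DataFrame,
    selected: Mapping[str, Sequence[str]],
    vehicle_ids: Iterable[str],
) -> HeatmapData:
    """Assemble the combined selected-marker matrix.

    Columns are ordered vehicle-control negatives, treated negatives,
    increased, positive (class blocks that are empty are simply absent);
    rows are grouped by platform in the canonical display order.  Missing
    cells stay NaN so a renderer can mark them distinctly.
    """
    cls = _as_class_map(classes)
    vehicles = set(vehicle_ids)

    def group_of(sid: str) -> str | None:
        c = cls.get(sid)
        if c == "negative":
            return "control_negative" if sid in vehicles else "treated_negative"
        return c

    all_cols: list[str] = []
    col_groups: list[str] = []
    seen = set()
    for grp in HEATMAP_CLASS_ORDER:
        for d in deltas.values():
            for sid in d.values.columns:
                if sid not in seen and group_of(sid) == grp:
                    seen.add(sid)
                    all_cols.append(sid)
                    col_groups.append(grp)

    blocks = []
    row_platforms = []
    for platform in HEATMAP_PLATFORM_ORDER:
        if platform not in deltas or platform not in selected:
            continue
        pids = [p for p in selected[platform]]
        if not pids:
            continue
        block = deltas[platform].values.loc[pids].reindex(columns=all_cols)
        blocks.append(block)
        row_platforms += [platform] * len(pids)
    if not blocks:
        raise ValueError("no selected parameters on any platform")
    values = pd.concat(blocks, axis=0)
    return HeatmapData(
        values=values,
        row_platforms=pd.Series(row_platforms, index=values.index,
                                name="platform"),
        column_groups=pd.Series(col_groups, index=pd.Index(all_cols),
                                name="group"),
    )


# ---------------------------------------------------------------------------
# negative-class outlier flagging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlierFlag:
    """A negative-class sample deviating on several top markers at once."""

    sample_id: str
    triggers: tuple[tuple[str, float], ...]  # (marker, linear fold change)


def flag_outliers(
    delta: DeltaMatrix | pd.DataFrame,
    classes: Mapping[str, str] | pd.Series | pd.DataFrame,
    top_markers: Sequence[str],
    k_markers: int = 3,
    fold_threshold: float = 2.0,
) -> list[OutlierFlag]:
    """Flag negative-class samples deviating on >= k of the top markers.

    A marker triggers when |delta| >= log2(fold_threshold).  Each flag lists
    the triggering markers with their linear fold changes — the signal to
    re-evaluate that animal's histopathology.
    """
    if not list(top_markers):
        raise ValueError("top_markers must be nonempty")
    values = delta.values if isinstance(delta, DeltaMatrix) else delta
    missing = [m for m in top_markers if m not in values.index]
    if missing:
        raise ValueError(f"unknown top marker(s) {missing}")
    cls = _as_class_map(classes)
    cut = math.log2(fold_threshold)
    flags = []
    for sid in values.columns:
        if cls.get(sid) != "negative":
            continue
        col = values.loc[list(top_markers), sid]
        trig = [
            (m, float(2.0 ** col[m]))
            for m in top_markers
            if not pd.isna(col[m]) and abs(col[m]) >= cut
        ]
        if len(trig) >= k_markers:
            flags.append(OutlierFlag(sample_id=sid, triggers=tuple(trig)))
    return flags


def _as_class_map(
    classes: Mapping[str, str] | pd.Series | pd.DataFrame
) -> Mapping[str, str]:
    if isinstance(classes, pd.DataFrame):
        return classes["class"].to_dict()
    if isinstance(classes, pd.Series):
        return classes.to_dict()
    return classes
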