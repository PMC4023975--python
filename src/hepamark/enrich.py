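"""Gene-set over-representation of top deregulated transcripts.

The selection is the best-ranked transcripts below a hard p-value cutoff
(defaults: at most 500 with p < 1e-7).  Each annotation term is scored with
the one-sided Fisher exact test — the hypergeometric upper tail
P(X >= overlap) with the annotated transcript universe as the population.
No multiple-testing correction is applied at this stage; reported term
p-values are raw, with a conventional 1e-5 reporting threshold.

Term sets are consumed in GMT format: one term per line,
``term_id<TAB>label<TAB>member1<TAB>member2...``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .markers import MarkerResult, rank_markers

__all__ = [
    "TermSet", "EnrichmentResult", "read_gmt", "write_gmt",
    "top_transcripts", "fisher_enrichment", "enrichment_to_frame",
]


@dataclass(frozen=True)
class TermSet:
    term_id: str
    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    label: str
    overlap: int
    set_size: int
    selected_size: int
    background_size: int
    p_value: float


def read_gmt(path: str | Path) -> list[TermSet]:
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with <3 fields: {line[:60]!r}")
        terms.append(
            TermSet(term_id=fields[0], label=fields[1],
                    members=frozenset(f for f in fields[2:] if f))
        )
    return terms


def write_gmt(terms: Sequence[TermSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.label, *sorted(t.members)]) + "\n")


def top_transcripts(
    results: Sequence[MarkerResult],
    n_top: int = 500,
    p_cut: float = 1e-7,
) -> list[str]:
    """The <= n_top best-ranked transcripts with p below the cutoff.

    Fold change is deliberately ignored here; the output is a prefix of the
    full p-value ranking.
    """
    ranked = rank_markers(results)
    out = []
    for r in ranked:
        if r.p_value < p_cut:
            out.append(r.parameter_id)
            if len(out) == n_top:
                break
    return out


def fisher_enrichment(
    selected: Iterable[str],
    term_sets: Sequence[TermSet],
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """One-sided Fisher exact over-representation per term, sorted by p.

    Term members are intersected with the background first; the selected
    list must be a subset of the background.
    """
    bg = set(background)
    sel = set(selected)
    outside = sorted(sel - bg)
    if outside:
        raise ValueError(
            f"selected id(s) not in background: {outside[:10]}"
        )
    N, n = len(bg), len(sel)
    results = []
    for t in term_sets:
        members = t.members & bg
        K = len(members)
        k = len(members & sel)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        results.append(
            EnrichmentResult(
                term_id=t.term_id, label=t.label, overlap=k, set_size=K,
                selected_size=n, background_size=N, p_value=min(p, 1.0),
            )
        )
    return sorted(results, key=lambda r: (r.p_value, r.term_id))


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "label": [r.label for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "selected_size": [r.selected_size for r in results],
            "background_size": [r.background_size for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
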