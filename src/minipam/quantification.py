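"""Editing-efficiency statistics for injection experiments.

Covers the outcome measures used to benchmark the nuclease variants in
vivo: phenotype-class fractions in injected zebrafish embryos, the
highly-efficient-gRNA classifier, per-P0 editing efficiency in C. elegans
co-CRISPR screens, the edited-allele percentage, HDR knock-in efficiency,
and the two significance tests applied to them (exact Fisher on the
score-vs-efficiency 2x2; chi-squared with Yates continuity correction on
injection comparisons).

Percentages are kept at full precision internally; one-decimal, half-up
rounding is applied only in :func:`report_percent`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: phenotype severity classes, most severe first; the last entry is
#: phenotypically wild-type
PHENOTYPE_CLASSES = ("class_iii", "class_ii", "class_i", "wild_type")


@dataclass(frozen=True)
class PhenotypeCounts:
    """Embryo counts per phenotype class for one injection condition.

    class_iii: albino/golden-like or most extreme (e.g. no notochord,
    extremely short tail); class_ii: severe mosaic; class_i: mild.
    """

    class_iii: int
    class_ii: int
    class_i: int
    wild_type: int
    condition: str = ""

    def __post_init__(self):
        if min(self.class_iii, self.class_ii, self.class_i, self.wild_type) < 0:
            raise ValueError("phenotype counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.class_iii + self.class_ii + self.class_i + self.wild_type

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.class_iii, self.class_ii, self.class_i, self.wild_type)


@dataclass(frozen=True)
class P0Record:
    """Outcome counts for one injected P0 animal."""

    p0_id: str
    n_f1_total: int  # F1s laid, or separated co-edited F1s, per assay design
    n_positive: int  # edited F1s (Dpy/Rol, or segregating knockouts)
    n_hom: int = 0
    n_het: int = 0

    def __post_init__(self):
        if self.n_positive > self.n_f1_total:
            raise ValueError("n_positive cannot exceed n_f1_total")
        if min(self.n_f1_total, self.n_positive, self.n_hom, self.n_het) < 0:
            raise ValueError("counts must be non-negative")


def phenotype_fractions(counts: PhenotypeCounts) -> dict[str, float]:
    if counts.n_total == 0:
        raise ValueError("n_total must be > 0")
    n = counts.n_total
    return {
        cls: c / n for cls, c in zip(PHENOTYPE_CLASSES, counts.as_tuple())
    }


def classify_highly_efficient(
    counts: PhenotypeCounts,
    severe_cutoff: float = 0.5,
    wt_cutoff: float = 0.1,
) -> bool:
    """Highly efficient: at least ``severe_cutoff`` of embryos in the two
    most severe classes AND strictly less than ``wt_cutoff`` phenotypically
    wild-type."""
    fr = phenotype_fractions(counts)
    severe = fr["class_iii"] + fr["class_ii"]
    return severe >= severe_cutoff and fr["wild_type"] < wt_cutoff


def mosaic_mutant_fraction(counts: PhenotypeCounts) -> float:
    """Fraction of embryos in any non-wild-type class."""
    fr = phenotype_fractions(counts)
    return fr["class_iii"] + fr["class_ii"] + fr["class_i"]


EXCLUDED = None  # sentinel: P0 below the F1-count inclusion threshold


def p0_efficiency(record: P0Record, min_f1: int = 0) -> float | None:
    """Per-P0 editing efficiency (positives / total F1s), or None when the
    P0 produced fewer than ``min_f1`` F1s and is excluded (not zero)."""
    if min_f1 < 0:
        raise ValueError("min_f1 must be >= 0")
    if record.n_f1_total == 0 or record.n_f1_total < min_f1:
        return EXCLUDED
    return record.n_positive / record.n_f1_total


def mean_p0_efficiency(records: Sequence[P0Record], min_f1: int = 0) -> float:
    """Mean over included P0s; excluded P0s are dropped, never imputed 0."""
    effs = [e for r in records if (e := p0_efficiency(r, min_f1)) is not None]
    if not effs:
        raise ValueError("no P0 passes the inclusion threshold")
    return float(np.mean(effs))


def edited_allele_percent(n_hom: int, n_het: int, n_screened: int) -> float:
    """(2 x hom + het) / (2 x screened) x 100 over screened F1 animals."""
    if n_screened <= 0:
        raise ValueError("n_screened must be > 0")
    if n_hom + n_het > n_screened:
        raise ValueError("n_hom + n_het cannot exceed n_screened")
    if min(n_hom, n_het) < 0:
        raise ValueError("counts must be non-negative")
    return 100.0 * (2 * n_hom + n_het) / (2 * n_screened)


def hdr_efficiency(n_correct_insertions: int, n_genotyped: int) -> float:
    """Correct-size insertions / genotyped F1s, as a percentage."""
    if n_genotyped <= 0:
        raise ValueError("n_genotyped must be > 0")
    if not 0 <= n_correct_insertions <= n_genotyped:
        raise ValueError("n_correct_insertions must be within [0, n_genotyped]")
    return 100.0 * n_correct_insertions / n_genotyped


def report_percent(value: float) -> float:
    """One-decimal half-up rounding, applied only at the reporting layer."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def fisher_enrichment(table: Sequence[Sequence[int]]) -> float:
    """Two-sided exact Fisher p on a 2x2 table (probability-mass method:
    the p-value sums all tables with point probability <= the observed)."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def chisq_yates(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Chi-squared test of contingency; Yates continuity correction
    (|O-E| reduced by 0.5, floored at 0) for 2x2 tables, uncorrected for
    larger tables. Returns (statistic, p)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or (arr < 0).any():
        raise ValueError("table must be a 2-D non-negative contingency table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    correction = arr.shape == (2, 2)
    stat, p, _dof, _exp = stats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


@dataclass
class EnrichmentTable:
    """2x2 counts: predicted score group x observed efficiency group."""

    high_score_efficient: int
    high_score_not: int
    low_score_efficient: int
    low_score_not: int

    def as_table(self) -> list[list[int]]:
        return [
            [self.high_score_efficient, self.high_score_not],
            [self.low_score_efficient, self.low_score_not],
        ]


def build_enrichment_table(
    scores: Sequence[float],
    phenotype_counts: Sequence[PhenotypeCounts],
    threshold: float = 66.0,
    severe_cutoff: float = 0.5,
    wt_cutoff: float = 0.1,
) -> EnrichmentTable:
    """Cross-tabulate predicted (>threshold) against observed (highly
    efficient) per target."""
    if len(scores) != len(phenotype_counts):
        raise ValueError("scores and phenotype_counts must be parallel")
    cells = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    for score, counts in zip(scores, phenotype_counts):
        pred = score > threshold
        obs = classify_highly_efficient(counts, severe_cutoff, wt_cutoff)
        cells[(pred, obs)] += 1
    return EnrichmentTable(
        high_score_efficient=cells[(True, True)],
        high_score_not=cells[(True, False)],
        low_score_efficient=cells[(False, True)],
        low_score_not=cells[(False, False)],
    )


# ---------------------------------------------------------------------------
# experiment-table I/O (TSV)

def read_phenotype_table(path: str | Path) -> list[PhenotypeCounts]:
    """TSV columns: condition, class_iii, class_ii, class_i, wild_type."""
    df = pd.read_csv(path, sep="\t")
    return [
        PhenotypeCounts(
            class_iii=int(r.class_iii),
            class_ii=int(r.class_ii),
            class_i=int(r.class_i),
            wild_type=int(r.wild_type),
            condition=str(r.condition),
        )
        for r in df.itertuples()
    ]


def read_p0_table(path: str | Path) -> list[P0Record]:
    """TSV columns: p0_id, n_f1_total, n_positive[, n_hom, n_het]."""
    df = pd.read_csv(path, sep="\t")
    return [
        P0Record(
            p0_id=str(r.p0_id),
            n_f1_total=int(r.n_f1_total),
            n_positive=int(r.n_positive),
            n_hom=int(getattr(r, "n_hom", 0)),
            n_het=int(getattr(r, "n_het", 0)),
        )
        for r in df.itertuples()
    ]
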