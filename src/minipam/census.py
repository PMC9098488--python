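"""Genome-wide PAM accessibility censuses.

Two summaries: site counts per region class (CDS / UTR / intron / other /
intergenic), and per-CDS target counts — total and with on-target score
above the activity threshold. A site is assigned to a region by the class
of its *cut position* (between spacer positions 17 and 18, 3 bp 5' of the
PAM), the biologically meaningful anchor for both the census and HDR
edit-distance bookkeeping. A target overlapping two genes' CDS counts for
both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import REGION_CLASSES, FeatureAnnotation, RegionIndex
from .pam_engine import TargetSite
from .scoring import DEFAULT_THRESHOLD, ScoredTarget


def census_by_region(
    sites: Sequence[TargetSite], region_index: RegionIndex, pam_name: str = "pam"
) -> pd.DataFrame:
    """Tidy table: one row per region class with that PAM's site count."""
    counts = {cls: 0 for cls in REGION_CLASSES}
    for site in sites:
        counts[region_index.classify(site.contig, site.cut_position)] += 1
    return pd.DataFrame(
        {
            "pam_name": pam_name,
            "region_class": list(REGION_CLASSES),
            "site_count": [counts[cls] for cls in REGION_CLASSES],
        }
    )


def multi_census(
    sites_by_pam: Mapping[str, Sequence[TargetSite]], region_index: RegionIndex
) -> pd.DataFrame:
    return pd.concat(
        [census_by_region(sites, region_index, name) for name, sites in sites_by_pam.items()],
        ignore_index=True,
    )


@dataclass
class PerCdsSummary:
    per_gene: pd.DataFrame  # gene_id, cds_length, n_targets, n_targets_score_gt_threshold
    threshold: float

    def distribution(self) -> pd.DataFrame:
        """Mean/median/quartiles of the two per-gene count columns."""
        cols = ["n_targets", "n_targets_score_gt_threshold"]
        if self.per_gene.empty:
            return pd.DataFrame(index=["mean", "median", "q1", "q3"], columns=cols)
        rows = {
            "mean": self.per_gene[cols].mean(),
            "median": self.per_gene[cols].median(),
            "q1": self.per_gene[cols].quantile(0.25),
            "q3": self.per_gene[cols].quantile(0.75),
        }
        return pd.DataFrame(rows).T


def _gene_cds_intervals(annotation: FeatureAnnotation):
    genes: dict[str, list] = {}
    for feat in annotation.features:
        if feat.region_class == "CDS" and feat.gene_id:
            genes.setdefault(feat.gene_id, []).append(feat)
    return genes


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, last_end = 0, -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        last_end = max(last_end, e)
    return total


def targets_per_cds(
    sites: Sequence[TargetSite],
    annotation: FeatureAnnotation,
    scored: Sequence[ScoredTarget] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> PerCdsSummary:
    """Count targets per gene CDS; genes with zero targets are included.

    A target counts for a gene when its cut position falls inside any of
    the gene's CDS intervals on the same contig. ``scored`` is the parallel
    list of scored targets for the >threshold column; when omitted that
    column is zero.
    """
    genes = _gene_cds_intervals(annotation)
    scores: list[float | None]
    if scored is None:
        scores = [None] * len(sites)
    else:
        if len(scored) != len(sites):
            raise ValueError("scored must parallel sites")
        scores = [t.score for t in scored]

    rows = []
    for gene_id, feats in sorted(genes.items()):
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for f in feats:
            by_contig.setdefault(f.contig, []).append((f.start, f.end))
        n_total = 0
        n_high = 0
        for site, score in zip(sites, scores):
            ivals = by_contig.get(site.contig)
            if not ivals:
                continue
            pos = site.cut_position
            if any(s <= pos < e for s, e in ivals):
                n_total += 1
                if score is not None and score > threshold:
                    n_high += 1
        cds_length = sum(_union_length(iv) for iv in by_contig.values())
        rows.append((gene_id, cds_length, n_total, n_high))
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "cds_length", "n_targets", "n_targets_score_gt_threshold"]
    )
    return PerCdsSummary(per_gene=per_gene, threshold=threshold)
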