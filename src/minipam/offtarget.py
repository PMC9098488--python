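"""Off-target search and adapted CFD scoring for relaxed-PAM variants.

Candidate off-targets for a spacer are all genomic sites (both strands)
whose PAM matches the variant's own pattern and whose protospacer differs
from the spacer at no more than ``max_mismatches`` positions. Mismatch
positions are numbered 1..20 from the PAM-proximal end; the PAM-proximal
``seed`` (default 12 nt) can be required to match perfectly.

CFD (cutting frequency determination) = product over mismatched positions
of the per-position RNA:DNA mismatch penalty, times a PAM factor. The PAM
factor is the published SpCas9 2-mer factor for NGG searches; for SpG/SpRY
a PAM matching the variant's pattern is scored 1.0 — the variants recognize
these PAMs natively, so the SpCas9-derived PAM penalties do not apply.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .pam_engine import PamSpec, TargetSite, compile_pam, enumerate_sites

DEFAULT_SEED_LENGTH = 12

_BASES = "ACGT"


@dataclass
class CfdTables:
    """Mismatch penalty factors keyed (PAM-proximal position, spacer base,
    genomic base) plus SpCas9 PAM 2-mer factors.

    Spacer bases are RNA; U is normalized to T on load. Matched pairs are
    implicitly 1.0 and must not appear in the table.
    """

    mismatch_penalties: dict[tuple[int, str, str], float]
    pam_factors_spcas9: dict[str, float]

    def __post_init__(self):
        for (pos, rna, dna), f in self.mismatch_penalties.items():
            if rna == dna:
                raise ValueError(f"matched pair at position {pos} must not be tabulated")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"penalty {f} at {(pos, rna, dna)} outside [0,1]")
        for pam2, f in self.pam_factors_spcas9.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"PAM factor {f} for {pam2!r} outside [0,1]")

    @classmethod
    def uniform(cls, penalty: float = 0.5, spacer_length: int = 20,
                ngg_factor: float = 1.0, non_ngg_factor: float = 0.2) -> "CfdTables":
        """Complete synthetic tables with one flat mismatch penalty; for
        tests and examples when the published matrix is not at hand."""
        mm = {
            (pos, r, d): penalty
            for pos in range(1, spacer_length + 1)
            for r in _BASES
            for d in _BASES
            if r != d
        }
        pam = {
            a + b: (ngg_factor if (a, b) == ("G", "G") else non_ngg_factor)
            for a in _BASES
            for b in _BASES
        }
        return cls(mismatch_penalties=mm, pam_factors_spcas9=pam)


def load_cfd_tables(mismatch_path: str | Path, pam_path: str | Path) -> CfdTables:
    """Load the two TSVs: ``position  rna_base  dna_base  factor`` and
    ``pam_2mer  factor`` (header row each; U normalized to T)."""
    mm: dict[tuple[int, str, str], float] = {}
    for line in Path(mismatch_path).read_text().splitlines()[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        pos, rna, dna, factor = line.split("\t")
        key = (int(pos), rna.upper().replace("U", "T"), dna.upper())
        if key in mm:
            raise ValueError(f"duplicate mismatch entry {key}")
        mm[key] = float(factor)
    pam: dict[str, float] = {}
    for line in Path(pam_path).read_text().splitlines()[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        pam2, factor = line.split("\t")
        pam[pam2.upper()] = float(factor)
    return CfdTables(mismatch_penalties=mm, pam_factors_spcas9=pam)


@dataclass(frozen=True)
class OffTargetHit:
    site: TargetSite
    mismatch_positions: frozenset[int]  # 1..20 from the PAM-proximal end
    seed_only: bool  # all mismatches within the seed
    cfd: float | None = None

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


def _mismatch_positions(spacer: str, protospacer: str) -> frozenset[int]:
    L = len(spacer)
    # position 1 is adjacent to the PAM, i.e. the 3' end of the protospacer;
    # genomic N counts as a mismatch to every spacer base
    return frozenset(
        L - i for i, (r, d) in enumerate(zip(spacer, protospacer)) if r != d
    )


def normalize_spacer(spacer: str) -> str:
    spacer = spacer.upper().replace("U", "T")
    if set(spacer) - set(_BASES):
        raise ValueError(f"spacer contains non-ACGT characters: {spacer!r}")
    return spacer


def find_offtargets(
    genome,
    spacer: str,
    pam_spec: PamSpec,
    max_mismatches: int = 4,
    seed_restricted: bool = False,
    seed_length: int = DEFAULT_SEED_LENGTH,
    tables: CfdTables | None = None,
) -> list[OffTargetHit]:
    """All hits with <= max_mismatches; in seed-restricted mode only hits
    whose PAM-proximal ``seed_length`` bases match perfectly are returned.
    The on-target site itself (0 mismatches) is included. CFD is attached
    when ``tables`` is given."""
    spacer = normalize_spacer(spacer)
    if len(spacer) != pam_spec.spacer_length:
        raise ValueError(
            f"spacer length {len(spacer)} != spec spacer_length {pam_spec.spacer_length}"
        )
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    hits: list[OffTargetHit] = []
    for site in enumerate_sites(genome, pam_spec, with_context=False):
        mism = _mismatch_positions(spacer, site.protospacer)
        if len(mism) > max_mismatches:
            continue
        if seed_restricted and any(p <= seed_length for p in mism):
            continue
        hit = OffTargetHit(
            site=site,
            mismatch_positions=mism,
            seed_only=all(p <= seed_length for p in mism),
        )
        if tables is not None:
            hit = OffTargetHit(
                site=site,
                mismatch_positions=mism,
                seed_only=hit.seed_only,
                cfd=cfd_score(spacer, hit, tables, pam_spec),
            )
        hits.append(hit)
    return hits


def cfd_score(
    spacer: str, hit: OffTargetHit, tables: CfdTables, pam_spec: PamSpec
) -> float:
    """Product of mismatch penalties times the PAM factor.

    f_PAM is the SpCas9 2-mer factor for an NGG search; for relaxed-PAM
    variants a PAM matching the variant pattern scores 1.0 (0.0 in the
    audit-only case of a non-matching PAM reaching this function).
    """
    spacer = normalize_spacer(spacer)
    L = len(spacer)
    value = 1.0
    for pos in hit.mismatch_positions:
        idx = L - pos
        key = (pos, spacer[idx], hit.site.protospacer[idx])
        if key not in tables.mismatch_penalties:
            raise KeyError(f"CFD table missing entry for {key}")
        value *= tables.mismatch_penalties[key]
    if pam_spec.pam_pattern == "NGG":
        pam2 = hit.site.pam[1:3]
        if pam2 not in tables.pam_factors_spcas9:
            raise KeyError(f"CFD PAM table missing entry for {pam2!r}")
        value *= tables.pam_factors_spcas9[pam2]
    else:
        value *= 1.0 if compile_pam(pam_spec.pam_pattern).matches(hit.site.pam) else 0.0
    return value


@dataclass
class OffTargetReport:
    counts_by_mismatch: dict[int, int]
    n_seed_perfect: int
    max_offtarget_cfd: float
    hits: list[OffTargetHit]  # sorted by cfd desc, then coordinates


def offtarget_report(hits: Sequence[OffTargetHit]) -> OffTargetReport:
    """Per-spacer summary. One zero-mismatch hit (highest-CFD) is treated
    as the on-target and excluded from the max off-target CFD; remaining
    perfect duplicates count as off-targets."""
    key = lambda h: (
        -(h.cfd if h.cfd is not None else 1.0 - 0.01 * h.n_mismatches),
        h.site.contig,
        h.site.start,
        h.site.strand,
    )
    ordered = sorted(hits, key=key)
    counts: dict[int, int] = {}
    for h in ordered:
        counts[h.n_mismatches] = counts.get(h.n_mismatches, 0) + 1
    seed_perfect = sum(1 for h in ordered if not any(p <= DEFAULT_SEED_LENGTH
                                                    for p in h.mismatch_positions))
    on_target_seen = False
    max_cfd = 0.0
    for h in ordered:
        if h.n_mismatches == 0 and not on_target_seen:
            on_target_seen = True
            continue
        if h.cfd is not None:
            max_cfd = max(max_cfd, h.cfd)
    return OffTargetReport(
        counts_by_mismatch=counts,
        n_seed_perfect=seed_perfect,
        max_offtarget_cfd=max_cfd,
        hits=ordered,
    )
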