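"""IUPAC PAM compilation and genome-wide protospacer enumeration.

A target site is a ``spacer_length`` protospacer immediately 5' of a PAM
matching the variant's IUPAC pattern, on either strand. Reverse-strand sites
are reported with plus-strand coordinates of the same physical bases; the
protospacer/PAM/context strings are always in the protospacer's own 5'->3'
orientation.

Scoring context layout: 6 nt upstream + 20 nt protospacer + 3 nt PAM + 6 nt
downstream = 35-mer, the input of the positional on-target activity model.
This is the single place that convention lives.

N policy: an N in the genome never satisfies a pattern position (even
pattern N), so ambiguous PAMs yield no sites; N inside a protospacer is
allowed but flagged ``contains_N``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

CONTEXT_FLANK = 6  # bases of genomic context on each side of spacer+PAM


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PamSpec:
    """A Cas variant's PAM requirement (3' of the protospacer)."""

    name: str
    pam_pattern: str
    spacer_length: int = 20

    def __post_init__(self):
        bad = set(self.pam_pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters {sorted(bad)!r} in PAM pattern")
        if self.spacer_length < 1:
            raise ValueError("spacer_length must be >= 1")

    @property
    def pam_length(self) -> int:
        return len(self.pam_pattern)


#: built-in variant registry; SpRY is most efficient on NRN and is searched
#: with that pattern, NYN is exposed separately.
PAM_REGISTRY: dict[str, PamSpec] = {
    spec.name: spec
    for spec in (
        PamSpec("SpCas9", "NGG"),
        PamSpec("SpG", "NGN"),
        PamSpec("SpRY", "NRN"),
        PamSpec("SpRY-NYN", "NYN"),
        PamSpec("Cas-NNN", "NNN"),
        PamSpec("NGH", "NGH"),
        PamSpec("NAN", "NAN"),
    )
}
# allow lookup by pattern as well as by variant name
_PATTERN_ALIASES = {spec.pam_pattern: spec for spec in PAM_REGISTRY.values()}


def get_pam_spec(name_or_pattern: str) -> PamSpec:
    """Resolve a registry name, a registered pattern, or a custom IUPAC pattern."""
    key = name_or_pattern
    if key in PAM_REGISTRY:
        return PAM_REGISTRY[key]
    up = key.upper()
    if up in _PATTERN_ALIASES:
        return _PATTERN_ALIASES[up]
    return PamSpec(name=up, pam_pattern=up)


@dataclass(frozen=True)
class TargetSite:
    contig: str
    start: int  # plus-strand, 0-based half-open, protospacer only
    end: int
    strand: str
    protospacer: str  # in its own 5'->3' orientation
    pam: str  # same orientation
    context35: str | None = None
    gg_start: bool = False
    contains_N: bool = False
    edge_truncated: bool = False

    @property
    def cut_position(self) -> int:
        """Plus-strand coordinate of the base at spacer position 18.

        The blunt cut falls between spacer positions 17 and 18 (3 bp 5' of
        the PAM); the position-18 base anchors region assignment.
        """
        idx = len(self.protospacer) - 3  # 0-based index 17 for a 20-mer
        if self.strand == "+":
            return self.start + idx
        return self.start + (len(self.protospacer) - 1 - idx)


class PamMatcher:
    """Predicate over fixed-length nucleotide strings for one IUPAC pattern."""

    def __init__(self, pattern: str):
        bad = set(pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters {sorted(bad)!r}")
        self.pattern = pattern
        self._sets = [set(IUPAC[c]) for c in pattern]
        # character classes contain only ACGT, so genomic N never matches
        self.regex_body = "".join(f"[{IUPAC[c]}]" for c in pattern)

    def matches(self, seq: str) -> bool:
        if len(seq) != len(self._sets):
            return False
        return all(base in allowed for base, allowed in zip(seq, self._sets))

    def __call__(self, seq: str) -> bool:
        return self.matches(seq)


def compile_pam(pattern: str) -> PamMatcher:
    return PamMatcher(pattern)


def _scan_strand(seq: str, spacer_len: int, matcher: PamMatcher):
    """Yield (offset, protospacer, pam) for one strand's sequence."""
    pat = re.compile(
        "(?=(" + "[ACGTN]" * spacer_len + ")(" + matcher.regex_body + "))"
    )
    for m in pat.finditer(seq):
        yield m.start(), m.group(1), m.group(2)


def enumerate_sites(genome, pam_spec: PamSpec, with_context: bool = True) -> list[TargetSite]:
    """Every protospacer+PAM occurrence on both strands, sorted by
    (contig, start, strand)."""
    L, P = pam_spec.spacer_length, pam_spec.pam_length
    matcher = compile_pam(pam_spec.pam_pattern)
    sites: list[TargetSite] = []
    for contig, seq in genome.records.items():
        M = len(seq)
        for off, proto, pam in _scan_strand(seq, L, matcher):
            sites.append(
                _make_site(contig, off, off + L, "+", proto, pam, seq, M, P, with_context)
            )
        rc = reverse_complement(seq)
        for off, proto, pam in _scan_strand(rc, L, matcher):
            # rc[off : off+L+P] occupies plus coords [M-off-L-P, M-off)
            start = M - off - L
            sites.append(
                _make_site(contig, start, start + L, "-", proto, pam, seq, M, P, with_context)
            )
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites


def _make_site(contig, start, end, strand, proto, pam, seq, M, pam_len, with_context):
    site = TargetSite(
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        protospacer=proto,
        pam=pam,
        gg_start=proto.startswith("GG"),
        contains_N="N" in proto or "N" in pam,
    )
    if with_context:
        site = _with_context(site, seq, M, pam_len)
    return site


def _with_context(site: TargetSite, seq: str, M: int, pam_len: int) -> TargetSite:
    f = CONTEXT_FLANK
    if site.strand == "+":
        lo, hi = site.start - f, site.end + pam_len + f
        if lo < 0 or hi > M:
            return replace(site, edge_truncated=True)
        return replace(site, context35=seq[lo:hi])
    lo, hi = site.start - pam_len - f, site.end + f
    if lo < 0 or hi > M:
        return replace(site, edge_truncated=True)
    return replace(site, context35=reverse_complement(seq[lo:hi]))


def extract_context(site: TargetSite, genome) -> TargetSite:
    """(Re)attach the 35-mer scoring context from the genome, or flag the
    site edge_truncated when fewer than 6 flanking bases exist."""
    seq = genome.records[site.contig]
    return _with_context(site, seq, len(seq), len(site.pam))


def filter_gg_start(sites: Iterable[TargetSite]) -> list[TargetSite]:
    """Sites whose protospacer starts with 5'GG (fully matched when
    transcribed from a T7 GG-initiating template)."""
    return [s for s in sites if s.protospacer[:2] == "GG"]
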