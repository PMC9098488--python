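"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's regex-based scanner: they
slide explicit windows and compare characters one by one, so agreement
with the implementation is a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def pam_ok(pam: str, pattern: str) -> bool:
    """Genomic N never satisfies any pattern position."""
    return len(pam) == len(pattern) and all(
        b in IUPAC_SETS[p] for b, p in zip(pam, pattern)
    )


def naive_sites(records: dict[str, str], pattern: str, spacer_len: int = 20):
    """Window-sliding scan of both strands; returns a set of
    (contig, start, strand, protospacer, pam) tuples in the internal
    coordinate convention."""
    P = len(pattern)
    out = set()
    for contig, seq in records.items():
        M = len(seq)
        for i in range(M - spacer_len - P + 1):
            proto = seq[i : i + spacer_len]
            pam = seq[i + spacer_len : i + spacer_len + P]
            if pam_ok(pam, pattern):
                out.add((contig, i, "+", proto, pam))
        rc = revcomp(seq)
        for i in range(M - spacer_len - P + 1):
            proto = rc[i : i + spacer_len]
            pam = rc[i + spacer_len : i + spacer_len + P]
            if pam_ok(pam, pattern):
                out.add((contig, M - i - spacer_len, "-", proto, pam))
    return out


def naive_offtargets(
    records: dict[str, str],
    spacer: str,
    pattern: str,
    max_mm: int,
    seed_restricted: bool,
    seed_len: int = 12,
):
    """Exhaustive off-target scan; returns a set of
    (contig, start, strand, frozenset(mismatch_positions))."""
    L = len(spacer)
    out = set()
    for contig, start, strand, proto, _pam in naive_sites(records, pattern, L):
        mism = frozenset(
            L - i for i in range(L) if spacer[i] != proto[i]
        )
        if len(mism) > max_mm:
            continue
        if seed_restricted and any(p <= seed_len for p in mism):
            continue
        out.add((contig, start, strand, mism))
    return out


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full enumeration of tables with the
    observed margins (probability-mass method)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def random_records(rng: np.random.Generator, n_contigs=1, length=300) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {
        f"c{i}": "".join(rng.choice(bases, size=length)) for i in range(n_contigs)
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20220512)


@pytest.fixture
def tiny_genome():
    from minipam.genome_io import Genome

    # hand-built contig with a known NGG site: spacer GGACGTACGTACGTACGTAC + PAM AGG
    seq = "TTTTTT" + "GGACGTACGTACGTACGTAC" + "AGG" + "TTTTTT"
    return Genome(records={"chr1": seq})
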