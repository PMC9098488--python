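"""Genome and annotation I/O with a single internal coordinate convention.

All coordinates inside the package are 0-based, half-open, on the plus
strand. Conversion to/from external conventions (GTF: 1-based, end-inclusive;
BED: 0-based, half-open) happens only in this module, at the I/O boundary.

The :class:`RegionIndex` resolves every base of every contig to exactly one
region class (``CDS > UTR > intron > other > intergenic`` precedence), which
is what the genome-wide PAM censuses are computed against.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

REGION_CLASSES = ("CDS", "UTR", "intron", "other", "intergenic")

#: precedence rank used when one base is covered by several feature classes;
#: higher wins, uncovered bases stay intergenic (rank 0).
_CLASS_RANK = {"intergenic": 0, "other": 1, "intron": 2, "UTR": 3, "CDS": 4}
_RANK_CLASS = {v: k for k, v in _CLASS_RANK.items()}

# IUPAC ambiguity codes other than N are collapsed to N on load.
_AMBIGUITY = set("RYSWKMBDHV")
_VALID_AFTER_NORM = set("ACGTN")


@dataclass
class Genome:
    """Ordered collection of contig sequences (A/C/G/T/N, uppercase)."""

    records: dict[str, str]
    softmasked: set[str] = field(default_factory=set)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.records

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Feature:
    contig: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+' or '-'
    region_class: str  # CDS / UTR / intron / other
    gene_id: str = ""
    transcript_id: str = ""


@dataclass
class FeatureAnnotation:
    features: list[Feature]
    dialect: str = "gtf"

    def __len__(self) -> int:
        return len(self.features)


class RegionIndex:
    """Maps every base position of a genome to one region class.

    Built by painting per-contig rank arrays in increasing precedence order,
    so the highest-precedence overlapping class wins and uncovered positions
    remain intergenic.
    """

    def __init__(self, ranks: dict[str, np.ndarray]):
        self._ranks = ranks

    def classify(self, contig: str, position: int) -> str:
        arr = self._ranks.get(contig)
        if arr is None:
            raise KeyError(f"unknown contig {contig!r}")
        if not 0 <= position < arr.size:
            raise IndexError(f"position {position} outside contig {contig!r}")
        return _RANK_CLASS[int(arr[position])]

    def class_counts(self) -> dict[str, int]:
        """Base counts per region class summed over all contigs."""
        totals = {cls: 0 for cls in REGION_CLASSES}
        for arr in self._ranks.values():
            counts = np.bincount(arr, minlength=5)
            for rank, n in enumerate(counts):
                totals[_RANK_CLASS[rank]] += int(n)
        return totals

    @property
    def contigs(self) -> list[str]:
        return list(self._ranks)


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Sequences are uppercased; contigs containing any lowercase (soft-masked)
    bases are flagged in ``Genome.softmasked``. IUPAC ambiguity codes other
    than N are converted to N with a warning; any other character is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: dict[str, str] = {}
    softmasked: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        raw = str(rec.seq)
        if any(c.islower() for c in raw):
            softmasked.add(rec.id)
        seq = raw.upper()
        bad = set(seq) - _VALID_AFTER_NORM
        if bad & _AMBIGUITY:
            logger.warning(
                "contig %s: converting ambiguity codes %s to N",
                rec.id,
                "".join(sorted(bad & _AMBIGUITY)),
            )
            seq = re.sub(f"[{''.join(sorted(_AMBIGUITY))}]", "N", seq)
            bad = set(seq) - _VALID_AFTER_NORM
        if bad:
            raise ValueError(
                f"contig {rec.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        records[rec.id] = seq
    return Genome(records=records, softmasked=softmasked)


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# annotation parsing

_UTR_TYPES = {"utr", "five_prime_utr", "three_prime_utr", "5utr", "3utr"}
_CDS_TYPES = {"cds", "start_codon", "stop_codon"}
# structural records define gene models rather than regions; exons are still
# consumed to derive introns.
_STRUCTURAL_TYPES = {"gene", "transcript", "mrna", "exon"}


def _parse_attributes(attr: str, dialect: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if dialect == "gtf":
        for m in re.finditer(r'(\w+)\s+"([^"]*)"', attr):
            out[m.group(1)] = m.group(2)
    else:
        for part in attr.strip().split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                out[k.strip()] = v.strip()
    return out


def _sniff_dialect(lines: Sequence[str]) -> str:
    for line in lines:
        if line.startswith("##gff-version"):
            return "gff3"
        if line.startswith("#") or not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) >= 9:
            return "gff3" if "=" in cols[8] and '"' not in cols[8] else "gtf"
    return "gtf"


def read_annotation(
    path: str | Path,
    dialect: str = "auto",
    genome: Genome | None = None,
) -> FeatureAnnotation:
    """Parse GTF or GFF3 into internal 0-based half-open features.

    Feature-type mapping: CDS (plus start/stop codons) -> CDS; *_utr/UTR ->
    UTR; intron records are used when present, otherwise introns are derived
    as the gaps between each transcript's exons; remaining non-structural
    types -> other. When ``genome`` is given, features on unknown contigs are
    an error.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "auto":
        dialect = _sniff_dialect(lines)
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    features: list[Feature] = []
    exons: dict[str, list[Feature]] = {}
    saw_intron = False
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise ValueError(f"{path}:{lineno}: expected 9 columns")
        contig, _src, ftype, start_s, end_s, _score, strand, _frame, attr = cols[:9]
        start1, end1 = int(start_s), int(end_s)
        if start1 > end1:
            raise ValueError(f"{path}:{lineno}: start {start1} > end {end1}")
        if strand not in "+-":
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        if genome is not None and contig not in genome:
            raise ValueError(f"{path}:{lineno}: unknown contig {contig!r}")
        start, end = start1 - 1, end1  # GTF/GFF 1-based inclusive -> internal
        attrs = _parse_attributes(attr, dialect)
        gene_id = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID", "")
        tx_id = attrs.get("transcript_id") or attrs.get("Parent") or gene_id
        ftype_l = ftype.lower()
        if ftype_l in _CDS_TYPES:
            cls = "CDS"
        elif ftype_l in _UTR_TYPES:
            cls = "UTR"
        elif ftype_l == "intron":
            cls = "intron"
            saw_intron = True
        elif ftype_l in _STRUCTURAL_TYPES:
            if ftype_l == "exon":
                exons.setdefault(tx_id, []).append(
                    Feature(contig, start, end, strand, "other", gene_id, tx_id)
                )
            continue
        else:
            cls = "other"
        features.append(Feature(contig, start, end, strand, cls, gene_id, tx_id))

    if not saw_intron:
        for tx_id, ex in exons.items():
            ex_sorted = sorted(ex, key=lambda f: f.start)
            for a, b in zip(ex_sorted, ex_sorted[1:]):
                if b.start > a.end:
                    features.append(
                        Feature(
                            a.contig, a.end, b.start, a.strand,
                            "intron", a.gene_id, tx_id,
                        )
                    )
    return FeatureAnnotation(features=features, dialect=dialect)


def build_region_index(annotation: FeatureAnnotation, genome: Genome) -> RegionIndex:
    """Paint per-contig class arrays with CDS > UTR > intron > other precedence."""
    ranks = {
        name: np.zeros(length, dtype=np.uint8)
        for name, length in genome.lengths.items()
    }
    # ascending precedence so later (higher) classes overwrite lower ones
    for rank in (1, 2, 3, 4):
        cls = _RANK_CLASS[rank]
        for feat in annotation.features:
            if feat.region_class != cls:
                continue
            arr = ranks.get(feat.contig)
            if arr is None:
                raise ValueError(f"annotation references unknown contig {feat.contig!r}")
            if feat.end > arr.size:
                raise ValueError(
                    f"feature {feat.contig}:{feat.start}-{feat.end} exceeds contig length"
                )
            np.maximum(arr[feat.start:feat.end], rank, out=arr[feat.start:feat.end])
    return RegionIndex(ranks)


def write_bed(sites: Iterable, path: str | Path) -> None:
    """Write sites as BED6 (0-based, half-open).

    Accepts plain ``TargetSite`` objects or ``ScoredTarget`` wrappers; the
    score column is the on-target score rounded to an integer, '.' when the
    site is unscored.
    """
    with open(path, "w") as fh:
        for item in sites:
            site = getattr(item, "site", item)
            score = getattr(item, "score", None)
            score_s = "." if score is None else str(int(round(score)))
            name = f"{site.contig}:{site.start}-{site.end}({site.strand})"
            fh.write(
                f"{site.contig}\t{site.start}\t{site.end}\t{name}\t{score_s}\t{site.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str, str]]:
    """Re-parse a BED6 file (round-trip support for the scan outputs)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        c, s, e, name, score, strand = line.split("\t")[:6]
        rows.append((c, int(s), int(e), name, score, strand))
    return rows
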