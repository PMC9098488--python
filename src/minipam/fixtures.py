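"""Synthetic genomes, annotations, and experiment tables with known truth.

Everything downstream of raw data can be exercised without downloading a
real genome: genomes are i.i.d. background sequence at a stated GC content
with spacer+PAM sites planted at known coordinates (backgrounds are
rejection-resampled until they contain no accidental copy of any planted
spacer on either strand), annotations follow a simple gene plan
(UTR-exon-intron layouts), and experiment tables are binomial/multinomial
draws from stated true efficiencies.

One numpy Generator seeded from a single ``seed`` drives every draw, so a
fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import Feature, FeatureAnnotation, Genome, write_fasta
from .pam_engine import TargetSite, reverse_complement
from .scoring import ScoreModel

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    contig: str
    position: int  # plus-strand start of the protospacer window
    strand: str
    spacer: str  # 20-mer, protospacer orientation
    pam: str  # 3-mer, protospacer orientation


@dataclass
class SyntheticGenomeSpec:
    seed: int
    n_contigs: int = 1
    contig_length: int = 2000
    gc_content: float = 0.4
    planted: list[PlantedSite] = field(default_factory=list)
    max_retries: int = 50


@dataclass
class SyntheticExperimentSpec:
    seed: int
    n_p0: int = 200
    f1_per_p0_mean: float = 100.0
    true_efficiency: float = 0.3
    #: per condition: name -> (n_embryos, class probabilities over
    #: class_iii, class_ii, class_i, wild_type)
    phenotype_conditions: dict[str, tuple[int, tuple[float, float, float, float]]] = field(
        default_factory=dict
    )


def random_sequence(rng: np.random.Generator, length: int, gc_content: float) -> str:
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _contains_spacer(seq: str, spacers: Sequence[str]) -> bool:
    rc = reverse_complement(seq)
    return any(sp in seq or sp in rc for sp in spacers)


def make_genome(spec: SyntheticGenomeSpec) -> tuple[Genome, list[TargetSite]]:
    """Background + planted sites; returns the genome and the truth table
    (one TargetSite per planted site, without scoring context)."""
    rng = np.random.default_rng(spec.seed)
    by_contig: dict[str, list[PlantedSite]] = {}
    for p in spec.planted:
        _validate_planting(p, spec)
        by_contig.setdefault(p.contig, []).append(p)
    spacers = [p.spacer for p in spec.planted]
    records: dict[str, str] = {}
    for i in range(spec.n_contigs):
        name = f"ctg{i + 1}"
        plants = sorted(by_contig.get(name, []), key=lambda p: p.position)
        _check_overlaps(plants)
        for _ in range(spec.max_retries):
            seq = random_sequence(rng, spec.contig_length, spec.gc_content)
            seq = _splice(seq, plants)
            if not spacers or _occurrences_match_plan(seq, spacers, plants):
                records[name] = seq
                break
        else:
            raise RuntimeError(
                f"could not generate contig {name} free of accidental spacer copies "
                f"after {spec.max_retries} attempts"
            )
    genome = Genome(records=records)
    truth = [_planted_to_site(p) for p in spec.planted]
    truth.sort(key=lambda s: (s.contig, s.start, s.strand))
    return genome, truth


def _validate_planting(p: PlantedSite, spec: SyntheticGenomeSpec) -> None:
    if len(p.spacer) != 20 or set(p.spacer) - set("ACGT"):
        raise ValueError(f"planted spacer must be a 20-mer over ACGT: {p.spacer!r}")
    if set(p.pam) - set("ACGT"):
        raise ValueError(f"planted PAM must be concrete ACGT bases: {p.pam!r}")
    lo = p.position - (len(p.pam) if p.strand == "-" else 0)
    hi = p.position + 20 + (len(p.pam) if p.strand == "+" else 0)
    if lo < 6 or hi > spec.contig_length - 6:
        raise ValueError(
            f"planted site at {p.contig}:{p.position} lacks the 6-nt scoring flanks"
        )


def _plant_window(p: PlantedSite) -> tuple[int, int, str]:
    """Plus-strand interval and plus-strand sequence of spacer+PAM."""
    if p.strand == "+":
        return p.position, p.position + 20 + len(p.pam), p.spacer + p.pam
    lo = p.position - len(p.pam)
    return lo, p.position + 20, reverse_complement(p.spacer + p.pam)


def _check_overlaps(plants: Sequence[PlantedSite]) -> None:
    windows = sorted(_plant_window(p)[:2] for p in plants)
    for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
        if s2 < e1:
            raise ValueError("planted sites overlap")


def _splice(seq: str, plants: Sequence[PlantedSite]) -> str:
    chars = list(seq)
    for p in plants:
        lo, hi, sub = _plant_window(p)
        chars[lo:hi] = sub
    return "".join(chars)


def _occurrences_match_plan(
    seq: str, spacers: Sequence[str], plants: Sequence[PlantedSite]
) -> bool:
    """True when every spacer occurs in this contig exactly at its planted
    windows (and nowhere else, on either strand)."""
    planted_fwd: dict[str, set[int]] = {}
    planted_rev: dict[str, set[int]] = {}
    for p in plants:
        if p.strand == "+":
            planted_fwd.setdefault(p.spacer, set()).add(p.position)
        else:
            planted_rev.setdefault(p.spacer, set()).add(p.position - 0)
    for sp in spacers:
        fwd = {m for m in _find_all(seq, sp)}
        if fwd != planted_fwd.get(sp, set()):
            return False
        rc = reverse_complement(sp)
        rev = {m for m in _find_all(seq, rc)}
        expected = planted_rev.get(sp, set())
        if rev != expected:
            return False
    return True


def _find_all(seq: str, sub: str):
    start = 0
    while (idx := seq.find(sub, start)) != -1:
        yield idx
        start = idx + 1


def _planted_to_site(p: PlantedSite) -> TargetSite:
    return TargetSite(
        contig=p.contig,
        start=p.position,
        end=p.position + 20,
        strand=p.strand,
        protospacer=p.spacer,
        pam=p.pam,
        gg_start=p.spacer.startswith("GG"),
        contains_N=False,
    )


def random_planted_sites(
    rng: np.random.Generator,
    n_sites: int,
    contig: str,
    contig_length: int,
    pam_choices: Sequence[str] = ("AGG", "TGG", "CGA", "TGC", "AAT"),
    spacing: int = 40,
) -> list[PlantedSite]:
    """Non-overlapping planted sites with unique random spacers."""
    sites: list[PlantedSite] = []
    spacers: set[str] = set()
    pos = 10
    for _ in range(n_sites):
        if pos + 23 + 6 > contig_length - 6:
            break
        while True:
            spacer = "".join(rng.choice(_BASES, size=20))
            if spacer not in spacers:
                spacers.add(spacer)
                break
        strand = "+" if rng.random() < 0.5 else "-"
        pam = str(rng.choice(list(pam_choices)))
        position = pos + (3 if strand == "-" else 0)
        sites.append(PlantedSite(contig, position, strand, spacer, pam))
        pos += 23 + spacing
    return sites


def make_annotation(
    genome: Genome,
    genes_per_contig: int = 1,
    utr_len: int = 30,
    exon_len: int = 120,
    intron_len: int = 60,
    n_exons: int = 2,
) -> FeatureAnnotation:
    """Deterministic toy gene models: 5'UTR, alternating CDS exons and
    introns, 3'UTR, laid left to right on the plus strand."""
    feats: list[Feature] = []
    gene_no = 0
    gene_span = 2 * utr_len + n_exons * exon_len + (n_exons - 1) * intron_len
    for contig, length in genome.lengths.items():
        cursor = 10
        for _ in range(genes_per_contig):
            if cursor + gene_span > length:
                break
            gene_no += 1
            gid, tid = f"gene{gene_no}", f"tx{gene_no}"
            pos = cursor
            feats.append(Feature(contig, pos, pos + utr_len, "+", "UTR", gid, tid))
            pos += utr_len
            for ex in range(n_exons):
                feats.append(Feature(contig, pos, pos + exon_len, "+", "CDS", gid, tid))
                pos += exon_len
                if ex < n_exons - 1:
                    feats.append(
                        Feature(contig, pos, pos + intron_len, "+", "intron", gid, tid)
                    )
                    pos += intron_len
            feats.append(Feature(contig, pos, pos + utr_len, "+", "UTR", gid, tid))
            cursor = pos + utr_len + 50
    return FeatureAnnotation(features=feats, dialect="gtf")


def write_annotation_gtf(annotation: FeatureAnnotation, path: str | Path) -> None:
    """Serialize internal features back to GTF (1-based, end-inclusive)."""
    type_map = {"CDS": "CDS", "UTR": "UTR", "intron": "intron", "other": "misc_feature"}
    with open(path, "w") as fh:
        for f in annotation.features:
            attrs = f'gene_id "{f.gene_id}"; transcript_id "{f.transcript_id}";'
            fh.write(
                f"{f.contig}\tminipam\t{type_map[f.region_class]}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )


def write_genome_bundle(
    spec: SyntheticGenomeSpec, out_dir: str | Path, genes_per_contig: int = 1
) -> dict[str, Path]:
    """Write FASTA + GTF + planted-truth TSV for a spec; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = make_genome(spec)
    annotation = make_annotation(genome, genes_per_contig=genes_per_contig)
    paths = {
        "fasta": out / "genome.fa",
        "gtf": out / "annotation.gtf",
        "truth": out / "planted_sites.tsv",
    }
    write_fasta(genome, paths["fasta"])
    write_annotation_gtf(annotation, paths["gtf"])
    pd.DataFrame(
        [
            (s.contig, s.start, s.end, s.strand, s.protospacer, s.pam)
            for s in truth
        ],
        columns=["contig", "start", "end", "strand", "protospacer", "pam"],
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# experiments

def make_experiments(
    spec: SyntheticExperimentSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate per-P0 co-CRISPR outcomes and per-condition phenotype
    tables; returns (p0_table, phenotype_table, truth)."""
    rng = np.random.default_rng(spec.seed)
    if not 0.0 <= spec.true_efficiency <= 1.0:
        raise ValueError("true_efficiency must be in [0,1]")
    totals = rng.poisson(spec.f1_per_p0_mean, size=spec.n_p0)
    totals = np.maximum(totals, 1)
    positives = rng.binomial(totals, spec.true_efficiency)
    p0 = pd.DataFrame(
        {
            "p0_id": [f"P0_{i + 1}" for i in range(spec.n_p0)],
            "n_f1_total": totals,
            "n_positive": positives,
        }
    )
    rows = []
    for name, (n_embryos, probs) in spec.phenotype_conditions.items():
        probs_arr = np.asarray(probs, dtype=float)
        if abs(probs_arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"class probabilities for {name!r} must sum to 1")
        counts = rng.multinomial(n_embryos, probs_arr)
        rows.append((name, *counts))
    phenotype = pd.DataFrame(
        rows, columns=["condition", "class_iii", "class_ii", "class_i", "wild_type"]
    )
    truth = {
        "true_efficiency": spec.true_efficiency,
        "f1_per_p0_mean": spec.f1_per_p0_mean,
        "phenotype_conditions": dict(spec.phenotype_conditions),
    }
    return p0, phenotype, truth


def random_score_model(rng: np.random.Generator, n_entries: int = 40) -> ScoreModel:
    """Synthetic positional-weight model covering random 1-/2-mer features;
    scale chosen so typical raw scores land inside (raw_min, raw_max)."""
    entries = []
    seen = set()
    while len(entries) < n_entries:
        k = 2 if rng.random() < 0.4 else 1
        pos = int(rng.integers(1, 35 - (k - 1) + 1))
        feat = "".join(rng.choice(_BASES, size=k))
        if (pos, feat) in seen:
            continue
        seen.add((pos, feat))
        entries.append((pos, feat, float(rng.normal(0.0, 0.3))))
    return ScoreModel(
        entries=entries,
        intercept=float(rng.normal(0.0, 0.2)),
        raw_min=-3.0,
        raw_max=3.0,
        model_id="synthetic",
    )
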