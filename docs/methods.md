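# Methods

This note records the conventions, models, and design choices behind
`minipam`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based, half-open, on the plus strand.
Conversions happen only at I/O boundaries: GTF/GFF3 (1-based,
end-inclusive) on read, BED6 (0-based, half-open) on write. Reverse-strand
sites carry plus-strand coordinates of the same physical bases; their
protospacer/PAM/context strings are in the protospacer's own 5′→3′
orientation.

Annotation feature types map CDS (and start/stop codons) → CDS,
`*_utr`/UTR → UTR, intron → intron; introns are derived from gaps between
each transcript's exons when no intron records exist (GTF dialects
differ). Purely structural records (gene, transcript, mRNA, exon) are not
emitted as region features — a gene record would otherwise blanket its
whole span and erase intron/intergenic classes from the census — while any
other genuine feature type becomes `other`.

Overlapping features resolve by precedence **CDS > UTR > intron > other >
intergenic**, implemented by painting per-contig rank arrays in ascending
precedence; uncovered bases are intergenic. This makes the totality
invariant (every base resolves to exactly one class; class counts sum to
genome length) structural rather than something to patch around.

## PAM matching and site enumeration

PAM patterns are IUPAC strings compiled to per-position base sets; the
engine accepts any length, and the registry fixes length 3 for the named
variants (SpCas9/NGG, SpG/NGN, SpRY/NRN, SpRY-NYN, NGH, NAN, NNN).

**N policy.** A genomic N never satisfies any pattern position, including
pattern N: ambiguous regions should not yield designs one could neither
synthesize nor order. An N *inside* a protospacer does not suppress the
site but sets `contains_N` for diagnostics.

Sites are enumerated per strand with no cross-strand deduplication (the
census counts sites in both strands), sorted by (contig, start, strand).
The scoring context is 6 nt upstream + 20 nt protospacer + 3 nt PAM + 6 nt
downstream = 35-mer in protospacer orientation; a site within 6 nt of a
contig edge is flagged `edge_truncated` and carries no context (and is
later reported unscored, not dropped silently). The cut position used for
region assignment is the base at spacer position 18, i.e. the blunt-cut
boundary 3 bp 5′ of the PAM — the same anchor used for HDR cut-to-edit
distance bookkeeping.

## On-target model

The activity model is a linear positional-feature model over the 35-mer:
indicator features (1-mers and 2-mers at 1-based positions) with real
weights, an intercept, and an affine map of the raw score onto 0–100 given
`(raw_min, raw_max)`, clamped to [0, 100]. Coefficients are **data**: a
TSV of `position, feature, weight` rows plus `intercept/raw_min/raw_max`
footer rows. The published CRISPRscan coefficient set can be transcribed
into this format; the test suite deliberately uses small synthetic models
so that correctness of the machinery never depends on external coefficient
values.

**NGG-substitution rule.** Relaxed-PAM targets are scored with the SpCas9
model *as if* the PAM were NGG: context positions 28–29 (the 2nd and 3rd
PAM bases) are set to G before feature matching; position 27 (the N) is
retained. The testable consequence — scores are invariant under any
substitution at positions 28–29 — is asserted on random models and
contexts.

**Threshold.** Predicted-high-efficiency is *strictly* score > 66
(equivalently ≥ 67 on integer scores). The boundary and the value are both
parameters; strict-greater matches the ">66 vs ≤66" grouping used for the
enrichment analysis.

## Off-target search and adapted CFD

Candidate off-targets for a spacer are sites whose PAM matches the
variant's **own** pattern (SpG→NGN, SpRY→NRN) with ≤ `max_mismatches`
protospacer mismatches; non-matching PAMs are excluded rather than given
an invented penalty (an audit path scores them `f_PAM = 0`). Mismatch
positions are numbered 1..20 from the PAM-proximal end. The seed is the
PAM-proximal 12 nt by default (the convention of the scoring lineage this
package follows; configurable), and seed-restricted search returns only
hits whose seed matches perfectly. The on-target (0-mismatch) hit is
included; the report excludes one such hit from the max-off-target CFD.

CFD = Π over mismatched positions of `penalty(position, spacer base,
genomic base)` × `f_PAM`. For NGG searches `f_PAM` is the tabulated SpCas9
2-mer factor; for SpG/SpRY a variant-matching PAM takes `f_PAM = 1.0`,
because the variants recognize those PAMs natively and the SpCas9-derived
PAM penalties would understate cleavage. Spacer bases are RNA with U≡T
normalized at load; tables must be complete (a missing entry is an error,
never a silent 1.0). NYN PAMs are not scored for SpRY: activity there is
lower and uncharacterized by the 1.0 rule, so they are excluded from the
candidate space.

The scanner and off-target search are defined by exhaustive window-sliding
semantics; the implementation (overlapping regex scan of both strands) is
checked against an independent naive scanner on hundreds of random
genomes, all registered PAMs, mismatches 0–4, both seed modes.

## Censuses

Per-region counts assign each site by its cut position's region class;
counts conserve (sum over classes = number of sites). Per-CDS counts
include genes with zero targets; a target whose cut position lies in two
genes' CDS counts for both (no fractional assignment). Pattern
monotonicity (NGG ⊆ NGN ⊆ NNN, NGH ⊎ NGG = NGN) is inherited and asserted
per gene.

## Efficiency statistics

- **Phenotype classes** (most severe first): class III / albino- or
  golden-like, class II / severe, class I / mild, wild-type. Fractions sum
  to 1.
- **Highly efficient gRNA**: severe+extreme fraction ≥ 0.5 AND wild-type
  fraction < 0.1. The ≥/< boundary pair follows the prose that generated
  the published target counts; both cutoffs are parameters.
- **Mosaic mutant fraction**: any non-wild-type class (= 1 − WT fraction);
  the 10 % reporting cutoff is a parameter.
- **Per-P0 efficiency**: positives / total F1s, with an inclusion
  threshold on F1 count (e.g. ≥ 100 F1s for phenotype scoring, ≥ 5 or ≥ 10
  separated co-edited F1s for fluorescence screens). Excluded P0s are
  dropped from means and tests, never imputed as zero.
- **Edited-allele %**: (2·hom + het) / (2·screened) × 100.
- **HDR efficiency**: correct-size insertions / genotyped F1s × 100.
- **Fisher exact** (two-sided, probability-mass convention: sum of tables
  with point probability ≤ observed) for the score-group × efficiency 2×2;
  computed via `scipy.stats.fisher_exact` and verified against full
  hypergeometric enumeration in the tests. **χ²** with Yates continuity
  correction for 2×2 injection comparisons (uncorrected for r×c), via
  `scipy.stats.chi2_contingency` with a direct-formula cross-check.

Internal values are full precision; one-decimal half-up rounding is
applied only at the reporting layer.

## Oligo and mix arithmetic

Forward fill-in oligo = 17-nt T7 promoter + 20-nt spacer + 15-nt annealing
tail = 52 nt; with the 80-nt universal scaffold oligo and the 15-nt
overlap the product is 52 + 80 − 15 = 117 bp (general formula
fwd + rev − overlap for other geometries). The T7 core
`TAATACGACTCACTATA` is the only 17-mer consistent with that geometry and
is a parameter default; the universal oligo is carried by length and
overlap only, with an optional user-supplied sequence. Spacers without a
5′GG warn (T7 initiation and target match both favour GG) but are not
rejected. Mix arithmetic is exact dilution (`final = stock·vol/total`)
with a mass-balance invariant and ratios normalized to the smallest
component; the RNP assembly check accepts gRNA:protein within ±5 % of
1.3.

## Synthetic data

Genome fixtures are i.i.d. background at a stated GC content (default
0.4, in the range of the worm and fish genomes this toolkit targets) with
spacer+PAM substrings spliced at known coordinates; backgrounds are
rejection-resampled (bounded retries) until no accidental copy of any
planted spacer exists on either strand, so planted truth is exact.
Annotations follow a deterministic toy gene plan (UTR–CDS–intron layouts).
Experiment fixtures draw F1 totals per P0 from a Poisson (mean 100,
matching the ≥100-F1 inclusion scale), positives from
Binomial(total, true efficiency), and phenotype tables from multinomials.
One `numpy` Generator seeded by a single `seed` drives all draws, so
fixtures are byte-reproducible.

What synthetic tests show: the scanners, classifiers, and statistics are
exactly correct on inputs whose truth is known, and the estimators recover
simulated parameters at the expected binomial rates (e.g. mean per-P0
efficiency within 3 SE of truth at 200 P0s × ~100 F1s). What they do not
show: anything about real on-target activity (that requires the published
coefficient set and wet-lab validation), real off-target landscapes
(repeat structure, chromatin), or real GC/repeat composition of genomes.
Problem sizes in the test and acceptance runs (genomes of a few hundred
bp to a few kb, 100–200 simulated replicates) are the package's chosen
fixture scale; all operations are linear in genome length and run
unchanged on full genomes.

## Known limitations

- No bulge-tolerant off-target matching, no 5′-PAM (Cas12a-style) systems.
- The genome-wide censuses of real genomes require the user to supply the
  FASTA/GTF; published full-genome counts are exercised here only through
  the conservation and monotonicity properties on synthetic genomes.
- Published per-target phenotype/indel tables are not redistributable with
  the package; the classifier-reproduction check runs only when the user
  provides that table (see `tests/test_acceptance.py`).
- The naive off-target scan is O(genome × spacers); adequate for the
  intended design workflows, not for genome × genome screens.
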