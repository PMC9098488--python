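# minipam

Target design and quantification for **minimal-PAM CRISPR-Cas9 variants**
(SpG and SpRY) in animal genome editing.

Wild-type SpCas9 requires an NGG protospacer-adjacent motif (PAM), which
excludes many genomic positions — a real constraint when the cut must land
close to a desired edit (HDR knock-ins, short regulatory elements, miRNA
loci). The engineered variants SpG (NGN PAM) and SpRY (NRN ≫ NYN) relax
that requirement. `minipam` implements the computational side of designing
and evaluating gRNAs for these variants:

- **PAM site enumeration** — compile any IUPAC PAM pattern (NGG, NGN, NGH,
  NAN, NRN, NYN, NNN, …) and enumerate every 20-nt protospacer + PAM
  occurrence on both strands of a genome, with the 35-mer scoring context
  (6 nt + spacer + PAM + 6 nt).
- **On-target scoring** — a positional-feature activity model
  (CRISPRscan-style: 1-/2-mer indicator features over the 35-mer, affine
  0–100 scaling). Relaxed-PAM targets are scored *as if the PAM were NGG*
  (context PAM positions 2–3 substituted with GG), and a score **> 66**
  flags a predicted highly efficient gRNA.
- **Off-target search + adapted CFD** — exhaustive mismatch search under
  the variant's own PAM, optional restriction to a perfect PAM-proximal
  seed (default 12 nt), and CFD scoring
  `CFD = Π penalty(position, rRNA:dDNA) × f_PAM` where a PAM matching the
  variant's pattern takes `f_PAM = 1.0` (the SpCas9-derived PAM penalties
  do not apply to variants that recognize those PAMs natively).
- **Genome-wide censuses** — site counts per region class
  (CDS/UTR/intron/other/intergenic, assigned by the cut position 3 bp 5′
  of the PAM) and targets per CDS, total and score-filtered.
- **Efficiency statistics** — phenotype-class fractions and the
  highly-efficient classifier (≥ 50 % severe+extreme AND < 10 % wild-type),
  per-P0 editing efficiency with F1-count inclusion thresholds,
  edited-allele % = (2·hom + het)/(2·screened)·100, HDR efficiency, exact
  Fisher and χ² (Yates) tests.
- **IVT oligo design** — fill-in PCR template arithmetic (52-nt T7 +
  spacer + 15-nt tail forward oligo, 80-nt universal oligo → 117 bp
  product) and reaction-mix molarity checks (10:10:1 ≙ 90/90/9 nM;
  1:1.3 protein:gRNA RNP assembly).
- **Synthetic fixtures** — seeded genomes with planted sites, toy gene
  models, and simulated injection experiments with known truth, so the
  full pipeline is testable without downloading a genome.

## Worked example

```bash
# 1. make a reproducible synthetic genome with 3 planted sites
minipam simulate genome --seed 11 --contig-length 2000 --n-planted 3 --out fx/

# 2. enumerate SpG (NGN) sites on both strands
minipam scan --genome fx/genome.fa --pam SpG --tsv sites.tsv
# stderr: 801 sites (SpG, NGN)

# 3. design the IVT fill-in oligo for a 5'GG spacer
minipam design-oligos --spacer GGACGTACGTACGTACGTAC
# forward_oligo  TAATACGACTCACTATAGGACGTACGTACGTACGTACGTTTTAGAGCTAGAA
# forward_length 52
# product_length 117
# gg_start_ok    1
```

The forward oligo is the 17-nt T7 promoter + the 20-nt spacer + the 15-nt
annealing tail (52 nt); with the 80-nt universal scaffold oligo and the
15-nt overlap the fill-in PCR product is 52 + 80 − 15 = **117 bp**, the
template for T7 transcription of the sgRNA.

In the library:

```python
>>> from minipam import PAM_REGISTRY, read_fasta, enumerate_sites
>>> genome = read_fasta("fx/genome.fa")
>>> sites = enumerate_sites(genome, PAM_REGISTRY["SpRY"])   # NRN PAMs
>>> from minipam.quantification import edited_allele_percent
>>> edited_allele_percent(5, 0, 10)   # 5 homozygous knockouts of 10 F1s
50.0
```

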