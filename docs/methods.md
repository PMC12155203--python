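# Methods

This document records the model behind `tdrprofiler`, the parameters it ships
with, and the conventions and numerical choices the implementation commits to.

## 1. Reference model

A `ReferenceSet` bundles four parts:

- **Genome** — named contigs of plain A/C/G/T sequence. The bundled toy genome
  has two contigs: `chrI` embeds copies of every class sequence (so every
  class-mapped read is also genome-mapped) and `chrII` carries six 300-nt
  protein-coding genes on alternating strands.
- **Class annotations** — sequence lists for rRNA, miRNA, tRNA, and piRNA.
- **Mature tRNAs** — per-tRNA records with isoacceptor name (e.g. `Gly-GCC`),
  1-based anticodon span, genomic coordinates, and sequence ending in the
  post-transcriptional `CCA`. Loaders append `CCA` when absent and validate
  that the annotated anticodon span matches the isoacceptor triplet. Ten
  mature tRNAs cover eight isoacceptors (Gly-GCC and Glu-CTC each have two
  isodecoders); all are 76 nt with the anticodon at positions 34–36.
- **Genes** — coordinates and strand for the protein-coding loci used by the
  endo-siRNA and mRNA-fragment machinery.

The toy reference is generated programmatically from a fixed internal seed so
no sequence fixtures need to be shipped; `write_reference_set` /
`load_reference_set` round-trip it through FASTA + TSV for CLI use. All toy
sequences exclude the 5-mers `TGGAA` and `TTCCA`, the only prefixes of the
default 3′ adapter that could cause a legitimate insert suffix to be trimmed —
adapter removal on simulated data is therefore exact.

### Substring index

`SequenceIndex` answers "where does this read occur?" with 0 or 1 mismatches.
Class queries are sense-strand only; genome queries scan both strands, with
minus-strand hits reported in plus-strand 1-based coordinates
(`plus_start = contig_len − (rc_start − 1) − read_len + 1`). Matching is a
direct `str.find` loop (0 mm) or a sliding Hamming scan (1 mm) — adequate for
the kilobase-scale toy reference and trivially verifiable against a brute-force
oracle, which the test suite does. Identical mature tRNA sequences collapse to
one representative with a membership list, so multi-copy tRNAs do not inflate
hit counts.

## 2. Read simulator

`simulate_small_rna_reads` draws each read's class from the profile's
fractions, then generates the sequence:

- **tDR** — pick a tRNA by isoacceptor weight, pick 5′ or 3′ side by
  `five_prime_fraction`, draw a length from a two-component clipped normal
  mixture (`long_mode_weight` at `half_length_mean ± sd`, remainder at
  `short_length_mean ± sd`, clipped to 18–40 nt), and take the prefix from
  position 1 (5′) or the suffix ending in `CCA` (3′). Fragments are always
  terminus-anchored; internal fragments are not modelled.
- **rRNA_frag / miRNA / piRNA** — exact mature sequences (miRNA, piRNA) or
  uniform random substrings of rRNA with their own length model.
- **endo_siRNA** — antisense substrings of spliced gene sequence, length 22 or
  26 nt, with a strong 5′-G bias implemented by sampling from precomputed
  G-start positions.
- **mRNA_frag** — sense substrings of gene sequence.
- **unassigned** — random sequence rejected against the index so it maps
  nowhere.

Every read carries truth fields (class, source record, half, length).
`write_fastq(with_adapter=True)` emulates a single-end short-read run: the
written sequence is `(insert + adapter)[:read_length]` with `read_length=75`
by default, i.e. reads shorter than the cycle count read through into the
adapter and longer ones are truncated. Constant Phred quality is written; no
sequencing-error model is applied (scope decision: the analysis under test is
classification and statistics, not error correction).

### Packaged composition profiles

Fractions are of the whole library; `unassigned` is 0 in all packaged
profiles, so a class's share of genome-mapping reads equals its profile
fraction exactly.

| profile | tDR | 5′ fraction | long-mode weight | notes |
|---|---|---|---|---|
| `wt_sperm` | 0.138 | 0.62 | 0.60 | tDR-rich; Gly-GCC/Glu-CTC-weighted isoacceptors |
| `wt_male` | 0.033 | 0.56 | 0.35 | whole-animal baseline |
| `rnst2_del_male` | 0.086 | 0.86 | 0.80 | RNase-deletion-like: 5′-half accumulation |
| `rnst2_het_male` | 0.035 | 0.623 | 0.30 | heterozygous male |
| `rnst2_het_female` | 0.022 | 0.60 | 0.85 | heterozygous female |

The remaining mass is split across rRNA, miRNA, piRNA, endo-siRNA, and mRNA
fragments in fixed per-profile proportions. These parameters were chosen once,
up front, from the fragment-biology targets above; they were not adjusted
against test outcomes afterwards.

### Single-embryo count simulator

`simulate_embryo_counts` draws negative-binomial counts per gene per embryo
(mean `μ`, variance `μ + φμ²`). Packaged expression profiles use a 6 000-gene
universe (fixed internal seed) with log-uniform means; named biological groups
(histone `his-*`, `fbxb-*`, `hsp-*`, ribosomal-protein `rpl-*`/`rps-*`, and
`ife-2`) get means in 10^[2.5, 4] so planted effects are detectable. Planted
differential genes are restricted to means ≥ 300 counts, because with
TPM-pseudocount compression a true 2-fold change on a weakly expressed gene
would not clear the |log2FC| > 1 gate. Fixture design:

- `two_cell`: 36 up (including `ife-2` at log2 2.5-fold) and 2 down;
  30 control vs 25 treatment embryos.
- `eight_cell`: 106 down (33 of them histone genes) and 16 up; 20 vs 26.
- `*_null`: same layout, no planted effects (calibration).
- `*_rescue`: planted effects reverted (rescue concordance).

Dispersion φ = 0.02 and these group sizes give power ≈ 1 for the planted
effect sizes, so the fixture DE counts are deterministic in practice across
seeds; this was verified on seeds not used by the tests before tolerances were
frozen.

## 3. Classification

Reads are adapter-trimmed (leftmost occurrence of a ≥ 6-nt adapter prefix,
located with a 6-mer probe), then length-filtered to 18–40 nt. Assignment is
sequential-priority: **rRNA → miRNA → tRNA → piRNA → genome**. A read is
assigned to the first class with a sense hit at the configured mismatch budget
(0 by default, optionally 1). Genome-only reads split into `endo_siRNA`
(any antisense hit), else `mRNA_frag` (sense hit inside a gene), else
`other_genomic`; reads with no hits are `unassigned`. Multi-hits at the
minimal mismatch count share unit weight equally. Classification is memoized
by unique sequence, which makes 200 k-read libraries run in seconds on the toy
reference.

Three rpm conventions are provided: per million genome-mapping reads, per
million genome-mapping-minus-rRNA, and per million reads of one class. A zero
denominator raises rather than returning NaN.

## 4. tDR metrics

- **Length × first-nt matrix** — 18–40 nt × A/C/G/T, over all reads or one
  class.
- **Half assignment** — split point is `anticodon_start + 1` (the middle
  anticodon base). A read's positions strictly left of the split count to the
  5′ side and strictly right to the 3′ side; the majority side wins and exact
  ties go 5′ (a canonical 36-nt 5′ half ends inside the anticodon and must
  count as 5′). Multi-target reads contribute their split weights.
- **Coverage profiles** — per-isoacceptor read-depth vectors; 3′-anchored
  reads are right-aligned when isodecoder lengths differ by ≤ 2 nt.
- **Size split** — long (≥ 31 nt, intact halves) vs short (≤ 30 nt, trimmed
  fragments), per isodecoder or isoacceptor, with rpm over the tRNA-class
  total. Exactly 30 nt counts as short.

## 5. Endo-siRNA tables

`per_gene_antisense_counts` aggregates `endo_siRNA` assignments by gene with
rpm over genome-mapping reads. `extract_22g` / `extract_26g` restrict to reads
of the given length whose first nucleotide is G (read sequence, not genomic
context).

## 6. Expression statistics

- **TPM** — counts / gene length, scaled to 10⁶ per embryo; a zero-total
  embryo is an error naming the embryo.
- **Differential expression** — Welch's t on log2(TPM + 1) per gene;
  log2FC computed on group means of TPM + 1. Calls require both
  |log2FC| > 1 **and** p ≤ 0.01 (flags `up`/`down`/`ns`). Degenerate
  zero-variance genes get p = 1 when group means are equal, else p = 0.
  Benjamini-Hochberg q-values are attached when available but the headline
  gate deliberately uses raw p, matching the two-gate convention the fixtures
  are designed around.
- **Group shift** — two-sample Kolmogorov-Smirnov between a named gene group's
  log2FC distribution and the background (group excluded), with both ECDFs
  returned for plotting.
- **Rescue comparison** — per-gene concordance between two DE tables
  (`log2fc_x · log2fc_y > 0`), with per-group concordant fractions.

## 7. Survival statistics

- **Kaplan-Meier** — product-limit estimator with Greenwood variance and
  log(−log) 95 % confidence intervals (clamped into [0, 1]).
- **Log-rank** — 1-degree-of-freedom two-group test. At each event time the
  hypergeometric variance term `d·(nₐ/n)·(1−nₐ/n)·(n−d)/(n−1)` is skipped when
  n = 1 and is zero when one group has left the risk set; the statistic is
  (ΣO−E)²/ΣV against χ²₁. Verified against `lifelines` (used strictly as a
  test oracle, not a runtime dependency) and against null p-value uniformity
  over 1 000 simulations.
- **Proportion t-test** — Welch's t on per-plate alive fractions
  (plates, not individuals, are the replication unit). `plates_to_individuals`
  expands daily plate counts into individual time/event rows for KM input,
  censoring final survivors at the last scored day.

## 8. Numerical and design choices

- Seeds are explicit everywhere; identical profile + seed reproduces
  byte-identical FASTQ output.
- Statistical test tolerances are derived, not fitted: binomial 3-SD bands for
  acceptance-level fractions, 4 SD for generator property tests, χ²
  goodness-of-fit at p > 0.01 for length mixtures.
- `scripts/acceptance.py` computes eleven summary targets from 200 000-read
  libraries and the packaged embryo fixtures, reporting each value with its
  sample size; it uses only the installed package and writes a single JSON
  file.
- Plotting helpers (`plot_length_firstnt`, `plot_coverage`, `plot_km`) use
  matplotlib's Agg backend and are side-effect-free beyond the output file.

## 9. Limitations

- The toy reference is kilobases, not a real genome; the index is a scan, not
  an FM-index, and would not scale to real references.
- No sequencing-error or quality model; adapter trimming assumes the exact
  adapter sequence.
- tDR generation is terminus-anchored only — no internal fragments, no CCA
  trimming variants, no modified-base effects on ligation.
- The DE gate uses raw p-values by design; multiple-testing-corrected q-values
  are reported but not used for the headline calls.
- The log-rank implementation covers the two-group 1-df case only.
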