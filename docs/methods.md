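# Methods

## The estimator

Let a panel of diagnostic sites be given: autosomal positions where a
great-ape species complex is (nearly) fixed for an allele different from
the human reference and a human cohort is uniformly homozygous for the
reference. For a short-read library mapped to the human genome, let
`T_k` be the filtered read depth summed over the panel sites of
chromosome `k` and `S_k` the depth of bases matching the species allele.
The per-chromosome contamination estimate is

    ĉ_k = 1 − S_k / T_k,

and the genome-wide point estimate pools counts over all chromosomes:

    ĉ = 1 − (Σ_k S_k) / (Σ_k T_k).

The pooled estimate is algebraically identical to the depth-weighted mean
of the `ĉ_k` (tested as an exact identity). Dispersion is reported as the
*unweighted sample* standard deviation (ddof = 1) of `{ĉ_k}` over
chromosomes with data, and is reported as missing (`NA`/`null`) when
fewer than two chromosomes have coverage. `N`, the number of diagnostic
positions observed, counts sites with at least one passing base call;
sites with zero passing coverage contribute nothing (they are not zeros).

Counting is by *subtraction*: every base that is not the species allele —
human reference, third allele, sequencing error — counts toward
contamination. This is what makes the readout clade-specific: a sample
from the wrong species complex produces a large apparent contamination
(the cross-clade experiments below), flagging mix-ups that a
human-specific counter would miss. It also means sequencing error and
reference bias push estimates slightly upward, so estimates on real data
are conservative upper bounds.

## Panel building

Input is a joint cohort VCF (species complex + humans) with per-sample
depth and mapping quality. The pipeline per site, in order:

1. **autosome restriction** (default on; names matching `(chr)?<int>`);
2. **masking**: any site inside a supplied BED interval (repeats, 35-mer
   mappability) is dropped; BED intervals are half-open 0-based, panel
   positions 1-based, with conversion only at I/O boundaries;
3. **genotype filters**: a genotype with depth < 6, depth > 100 or
   MQ < 20 is set to missing (both alleles). The comparatives are strict,
   so depth 6/100 and MQ 20 pass;
4. **biallelic SNP filter**: exactly one single-base alternative allele
   *observed* across both cohorts (multi-allelic records are rejected,
   never decomposed; indel alleles are rejected);
5. **diagnostic criteria**, first failure reported:
   (a) alternative-allele fraction ≥ 0.98 among *observed* species
   chromosomes, (b) missing species chromosomes < 5% of *all* species
   chromosomes, (c) every human chromosome observed and reference.

Criterion (a) tolerates residual human-like genotypes in the species
cohort (reference-set error produces spurious rare variation); criterion
(c) is all-or-nothing. The 0.98 denominator uses observed chromosomes so
that (a) and (b) stay orthogonal; the alternative reading (denominator =
all chromosomes) is available via
`GenotypeFilterConfig(alt_fraction_over_total=True)`. Whether the human
filter runs before or after the species filters does not change the
panel; the implementation checks (a), (b), (c) in that order only to
assign a deterministic rejection reason.

Panels are deterministic (byte-identical for identical input), unique and
naturally sorted (chr2 before chr10). Unsorted or malformed input raises
an error naming the offending position.

## Read filtering and counting

Defaults at estimation time: drop unmapped reads, secondary and
supplementary alignments, duplicates, QC-fail reads, mapping quality
< 30, and fragments shorter than 35 bp (spurious short alignments are
common in microbially dominated libraries). Fragment length is |TLEN|
for properly paired reads and the aligned query length otherwise
(insert length is undefined for single-end data). Bases below quality 13
(the classic pileup floor) are skipped; deletions and reference skips are
not base calls. Overlapping mates both count by default, matching a plain
pileup with overlap detection disabled; `dedup_overlaps=True` counts each
fragment at most once per site.

Two input paths produce identical counts on the same data: direct
counting from an indexed BAM/CRAM, and parsing of `samtools mpileup`
text (full `^$+-*><` column syntax). For the text path the read-level
filters must be applied by the mpileup invocation (`-q 30`, default
flag filters) with `-Q 0`, since only base qualities survive into the
text; the parser applies the base-quality floor itself. Panel/alignment
contig naming (`chr` prefix or not) is reconciled automatically with an
explicit override.

## In-silico validation machinery

**Mixtures.** Contamination is accounted in *base pairs* (aligned query
bases), not read counts, because read lengths differ between libraries.
A mixture keeps all host reads and adds a seeded random subset of
contaminant fragments — mate pairs kept or dropped together, sampled
without replacement — until the contaminant base-pair share is as close
to the target as fragment granularity allows; the realized fraction is
always reported alongside the nominal one. Output BAMs are
coordinate-sorted, indexed, and byte-identical under a fixed seed
(sorting runs with `--no-PG` so headers carry no run-specific paths).

**Gradient.** One mixture + estimate per fraction over an ascending list
(the shipped experiments span ~0.1% to 39%), reporting nominal and
realized fractions, `ĉ`, SD, `N` and total depth.

**Crosstest.** The standard estimate of a clade-B sample against a
clade-A panel. On synthetic clades where B shares the human allele at a
planted fraction `f` of A-diagnostic sites, the expected readout is
`ĉ ≈ f`.

**Downsampling.** Seeded subsets of *production reads* (primary, mapped,
non-duplicate; mate pairs together) at descending target counts with
replicates, down to ~1,000 reads. The original downsampling target of
~1.14 M reads for a ~5% mixture is library-specific; the simulator
targets base-pair fractions and read counts directly instead.

**Randomness.** Every stochastic operation takes one integer seed;
multi-step experiments fan it out through `numpy.random.SeedSequence`
(children reduced mod 2³¹), so results are reproducible across runs and
platforms pinned to the same numpy generator family (PCG64).

## Synthetic data: what it emulates, what it does not

The fixture generator plants truth first and derives files from it, so
every pipeline output has an exact expected value.

- **Reference/clade model** (`CladeModel`): 3 autosome-named chromosomes
  of 100 kb; diagnostic fixed differences at density 1/500 bp (~200 per
  chromosome — toy-scale, but the same order as the real *Pan* panel's
  ~4.5 M sites over ~2.9 Gb once scaled); 20% of candidate variant sites
  segregate within the clade (frequency Uniform(0.2, 0.9)); 5% of
  diagnostic-like sites carry human polymorphism. Sites sit ≥ 1 kb from
  chromosome ends.
- **Cohort** (`make_cohort_vcf`): 68 species individuals and 19 humans by
  default, mirroring the published *Pan* + human design. Individuals are
  diploid with independently drawn alleles — no linkage model, since the
  test is strictly single-site. Seeded subsets of diagnostic sites
  receive perturbations that exercise every rejection path (depth- and
  MQ-driven missingness beyond 5%, reference carriers beyond 2% of
  chromosomes, multi-allelic and indel records, missing human genotypes,
  masked intervals) and benign counterparts that must survive; expected
  panel membership follows from the construction arithmetic, not from
  the panel builder.
- **Reads** (`ReadModel`): exact haplotype substrings, proper pairs,
  100 bp reads / 200 bp fragments, MQ 60 (with optional low-MQ decoys),
  constant Q37 base qualities; optional per-base substitution errors with
  configurable quality. Coverage is uniform.

Not emulated: coalescent genealogies and LD, realistic sequencing-error
profiles, ancient-DNA damage, capture-enrichment bias, mapping/reference
bias, and structural variation. Passing tests therefore demonstrate the
*arithmetic and plumbing* of the method — filters, counting, estimator,
reproducibility — under known truth; they do not quantify real-data
effects such as reference bias, which in practice make estimates
conservative.

## Problem sizes and numerical conventions

The shipped experiments use the toy scale above: panels of ~500 sites,
libraries of 60k–107k reads, gradients of 6 fractions × 10 seeds,
downsampling at {100,000; 10,000; 1,000} reads × 20 replicates. At these
sizes the full suite runs in a few minutes on one CPU; all statistical
checks use 4-standard-error envelopes computed from the realized (not
nominal) fractions and the observed base counts, with the shared-fixture
planting noise accounted separately from downsampling noise. Reports
format numbers to 6 significant digits and are byte-stable; TSV reports
mark an undefined SD as `NA`, JSON as `null`. Ties in downsampling
(overshooting a target by one read versus undershooting by one) resolve
to undershoot, deterministically.

## Known limitations

- The estimator is a ratio of pooled counts; it carries no explicit
  error model, so its SD reflects only between-chromosome dispersion.
- Species-of-origin assignment for detected contamination is out of
  scope (competitive mapping tools exist for that); so are
  mitochondrial-based estimates.
- Panels are built per assembly; no liftover is provided.
- At extreme depths a site's counts are dominated by a handful of
  fragments; `N` and the SD are the intended guide to reliability there.
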