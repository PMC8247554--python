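# hucontest

Human-contamination testing for great-ape short-read sequencing data.

Modern human DNA is a pervasive contaminant in sequencing libraries from
our closest relatives — especially in noninvasive (fecal), museum and
ancient samples with little endogenous DNA, and in capture-enriched data
where mitochondrial methods lose power. `hucontest` detects and
quantifies human contamination from sparse autosomal data: it counts, at
*clade-diagnostic sites*, the reads that do **not** carry the species
complex allele.

A diagnostic site is an autosomal position where a species complex
(e.g. *Pan* = chimpanzee + bonobo) is essentially fixed for an allele
different from the human reference, while a human cohort is uniformly
homozygous reference. For a library mapped to the human genome, the
contamination estimate is

```
ĉ = 1 − (reads matching the species allele) / (total filtered reads)
```

pooled over all diagnostic sites with coverage. The same quantity is
computed per chromosome; the sample standard deviation across chromosomes
and the number of positions observed (N) accompany every point estimate,
so reliability at very shallow depth is visible at a glance. Reads not
matching the species allele count toward contamination whether or not
they match the human reference, which also makes the test flag
cross-species sample mix-ups (a gorilla library run against a *Pan* panel
reads out at tens of percent "contamination").

The package contains:

- **panel building** (`hucontest build-panel`): derive diagnostic sites
  from a joint cohort VCF — mask repeats/low-mappability regions, set
  genotypes missing outside 6–100× depth or below MQ 20, keep biallelic
  SNPs where ≥ 98% of species chromosomes carry the alternative allele,
  < 5% of species chromosomes are missing, and every human chromosome is
  an observed reference allele;
- **estimation** (`hucontest estimate`): filtered allele counting over a
  BAM/CRAM (or `samtools mpileup` text) at panel sites — duplicates,
  non-primary alignments, MQ < 30 and fragments < 35 bp excluded — and
  the per-chromosome/genome-wide estimate;
- **in-silico validation** (`hucontest simulate`): seeded read mixtures
  at a target base-pair fraction, contamination gradients, cross-clade
  tests and downsampling series;
- **synthetic fixtures** (`hucontest fixtures`): seeded toy references,
  cohort VCFs with planted truth, masks and error-free or noisy read
  sets, so the whole pipeline is testable without external data.

## Worked example

Generate a synthetic fixture set, contaminate the host library with 5%
human base pairs, and estimate:

```bash
hucontest fixtures --outdir demo --seed 42
hucontest simulate mix --host demo/host.bam --contaminant demo/human.bam \
    --fraction 0.05 --seed 7 --out demo/mixed.bam
hucontest estimate --bam demo/mixed.bam --panel demo/expected_panel.tsv
```

prints

```
chrom	n_sites	total_depth	species_depth	estimate	sd
chr1	164	3493	3340	0.0438019	NA
chr2	169	3525	3336	0.053617	NA
chr3	165	3457	3283	0.0503327	NA
GENOME	498	10475	9959	0.0492601	0.00499625
```

Read the GENOME row as: 498 diagnostic positions were observed; of the
10,475 filtered bases over them, 9,959 matched the species allele, giving
a contamination estimate of 4.9% ± 0.5% (one SD across chromosomes) for
the 5.0% that was actually injected. On a pure host library the same
command prints 0 exactly; on pure human reads, 1 exactly.

Panels for real data are built from a cohort VCF plus a two-column
sample-to-cohort map and BED masks:

```bash
hucontest build-panel --vcf cohort.vcf.gz --samples samples.tsv \
    --masks repeats.bed --masks mappability35.bed \
    --out panel.tsv --summary panel_summary.json
```

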