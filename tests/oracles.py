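"""Independent oracles: plain re-derivations of the criteria used in tests.

Deliberately written without reusing any package pipeline function, so
agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import re


def _autosome(name: str) -> bool:
    return re.fullmatch(r"(?:chr)?(\d+)", name) is not None


def _natural_key(name: str):
    m = re.fullmatch(r"(?:chr)?(\d+)", name)
    return (0, int(m.group(1)), "") if m else (1, 0, name)


def brute_force_panel(records, masks, config, autosomes_only=True):
    """Site-by-site evaluation of all five diagnostic criteria.

    Returns (chrom, pos, ref, alt) tuples sorted in natural chromosome
    order, exactly what a correct panel build must produce.
    """
    out = []
    for rec in records:
        if autosomes_only and not _autosome(rec.chromosome):
            continue
        masked = False
        for mask in masks:
            for start, end in mask.intervals(rec.chromosome):
                if start <= rec.position - 1 < end:
                    masked = True
        if masked:
            continue

        def genotype_ok(call):
            return (
                config.min_depth <= call.depth <= config.max_depth
                and call.mq >= config.min_genotype_mq
            )

        def alleles_of(call):
            if not genotype_ok(call):
                return None
            if call.alleles[0] is None or call.alleles[1] is None:
                return None
            return call.alleles

        species = [alleles_of(c) for c in rec.species_genotypes]
        humans = [alleles_of(c) for c in rec.human_genotypes]

        observed = set()
        for g in species + humans:
            if g is not None:
                observed.update(g)
        alts = observed - {rec.ref_allele}
        if len(alts) != 1:
            continue
        alt = alts.pop()
        if len(alt) != 1 or len(rec.ref_allele) != 1 or alt not in "ACGT" or rec.ref_allele not in "ACGT":
            continue

        total_chr = 2 * len(species)
        observed_chr = 2 * sum(g is not None for g in species)
        alt_chr = sum(g.count(alt) for g in species if g is not None)
        denom = total_chr if config.alt_fraction_over_total else observed_chr
        if denom == 0 or alt_chr / denom < config.min_alt_fraction:
            continue
        if (total_chr - observed_chr) / total_chr >= config.max_species_missing:
            continue
        human_ok = True
        for g in humans:
            if g is None:
                if not config.human_missing_allowed:
                    human_ok = False
            elif g[0] != rec.ref_allele or g[1] != rec.ref_allele:
                human_ok = False
        if not human_ok:
            continue
        out.append((rec.chromosome, rec.position, rec.ref_allele, alt))
    out.sort(key=lambda t: (_natural_key(t[0]), t[1]))
    return out


def brute_force_allele_counts(bam_path, panel, *, min_mq=30, min_frag=35, min_baseq=13):
    """Naive per-column tally via the pysam pileup engine.

    Uses a different pysam code path (pileup columns) than the package's
    per-read counting, with the same filter semantics.
    """
    import pysam

    counts = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for site in panel:
            total = species = 0
            for col in bam.pileup(
                site.chromosome,
                site.position - 1,
                site.position,
                truncate=True,
                stepper="nofilter",
                min_base_quality=0,
                max_depth=1_000_000,
            ):
                for pr in col.pileups:
                    read = pr.alignment
                    if read.is_unmapped or read.is_secondary or read.is_supplementary:
                        continue
                    if read.is_duplicate or read.is_qcfail:
                        continue
                    if read.mapping_quality < min_mq:
                        continue
                    if read.is_paired and read.is_proper_pair and read.template_length != 0:
                        frag = abs(read.template_length)
                    else:
                        frag = read.query_alignment_length
                    if frag < min_frag:
                        continue
                    if pr.is_del or pr.is_refskip or pr.query_position is None:
                        continue
                    if read.query_qualities[pr.query_position] < min_baseq:
                        continue
                    total += 1
                    if read.query_sequence[pr.query_position].upper() == site.species_alt_allele.upper():
                        species += 1
            if total > 0:
                counts[(site.chromosome, site.position)] = (total, species)
    return counts
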