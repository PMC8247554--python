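"""Allele counting at diagnostic sites and the contamination estimate.

Contamination is the proportion of reads at diagnostic positions that do
not match the species complex allele: at each site the species-allele read
count is subtracted from the filtered total depth, and the remainder —
reads matching the human reference allele or, more strictly, anything
other than the species allele — counts toward contamination. The estimate
is computed per chromosome (giving a dispersion across chromosomes) and
genome-wide from pooled counts.

Two input paths produce identical :class:`AlleleCounts`: direct counting
from an indexed BAM/CRAM, and parsing of ``samtools mpileup`` text.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panel import DiagnosticSite, chromosome_sort_key

__all__ = [
    "ReadFilterConfig",
    "AlleleCounts",
    "ChromosomeCounts",
    "ContaminationEstimate",
    "filter_read",
    "count_alleles",
    "parse_mpileup",
    "estimate",
]


@dataclass(frozen=True)
class ReadFilterConfig:
    """Read- and base-level filters applied before counting.

    Defaults follow the recommended filtering: drop unmapped reads,
    non-primary alignments, duplicates, reads with mapping quality < 30 and
    fragments/inserts shorter than 35 bp (spurious alignments are frequent
    below that in microbially dominated samples). ``min_base_quality``
    defaults to 13, the classic mpileup floor. ``dedup_overlaps`` counts
    each fragment at most once per site when mates overlap; off by default,
    matching a plain pileup without overlap detection.
    """

    min_read_mq: int = 30
    min_fragment_length: int = 35
    exclude_duplicates: bool = True
    exclude_secondary_supplementary: bool = True
    exclude_unmapped: bool = True
    exclude_qcfail: bool = True
    min_base_quality: int = 13
    dedup_overlaps: bool = False

    def __post_init__(self) -> None:
        for name in ("min_read_mq", "min_fragment_length", "min_base_quality"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AlleleCounts:
    """Filtered read counts over one diagnostic site."""

    chromosome: str
    position: int  # 1-based
    total_depth: int
    species_allele_depth: int

    def __post_init__(self) -> None:
        if not (0 <= self.species_allele_depth <= self.total_depth):
            raise ValueError(
                f"invalid counts at {self.chromosome}:{self.position}: "
                f"{self.species_allele_depth}/{self.total_depth}"
            )


@dataclass(frozen=True)
class ChromosomeCounts:
    chromosome: str
    n_sites: int
    total_depth: int
    species_depth: int
    estimate: float


@dataclass(frozen=True)
class ContaminationEstimate:
    """Genome-wide contamination estimate with per-chromosome breakdown.

    ``point_estimate`` is computed from counts pooled over all sites (the
    depth-weighted mean of the per-chromosome estimates); ``sd`` is the
    unweighted sample standard deviation of the per-chromosome estimates,
    or ``None`` when fewer than two chromosomes have data; ``n_positions``
    counts diagnostic sites with at least one passing base call.
    """

    point_estimate: float
    sd: float | None
    n_positions: int
    per_chromosome: tuple[ChromosomeCounts, ...]


def filter_read(read, config: ReadFilterConfig) -> bool:
    """True iff a :class:`pysam.AlignedSegment` passes every enabled filter.

    Fragment length is |TLEN| for properly paired reads and the aligned
    query length otherwise (insert length is undefined for single-end data).
    """
    if config.exclude_unmapped and read.is_unmapped:
        return False
    if config.exclude_secondary_supplementary and (read.is_secondary or read.is_supplementary):
        return False
    if config.exclude_duplicates and read.is_duplicate:
        return False
    if config.exclude_qcfail and read.is_qcfail:
        return False
    if read.mapping_quality < config.min_read_mq:
        return False
    if read.is_paired and read.is_proper_pair and read.template_length != 0:
        fragment = abs(read.template_length)
    else:
        fragment = read.query_alignment_length
    return fragment >= config.min_fragment_length


def _resolve_contig(name: str, available: set[str], contig_style: str) -> str | None:
    if contig_style == "chr":
        candidates = [name if name.startswith("chr") else "chr" + name]
    elif contig_style == "nochr":
        candidates = [name.removeprefix("chr")]
    else:  # auto
        candidates = [name, "chr" + name, name.removeprefix("chr")]
    for cand in candidates:
        if cand in available:
            return cand
    return None


def count_alleles(
    alignment: str | Path,
    panel: Sequence[DiagnosticSite],
    config: ReadFilterConfig | None = None,
    *,
    reference: str | Path | None = None,
    contig_style: str = "auto",
) -> Iterator[AlleleCounts]:
    """Count filtered bases over panel sites in a sorted, indexed BAM/CRAM.

    For every panel site covered by at least one passing base call, yields
    an :class:`AlleleCounts` (panel order). Base calls that are deletions or
    reference skips at the site do not enter ``total_depth``. Sites with no
    passing coverage are silently omitted. Raises if the alignment has no
    index or if no panel contig can be reconciled with the alignment header
    (with or without a ``chr`` prefix) — usually the wrong assembly.
    """
    import pysam

    config = config or ReadFilterConfig()
    mode = "rc" if str(alignment).endswith(".cram") else "rb"
    kwargs = {"reference_filename": str(reference)} if reference else {}
    with pysam.AlignmentFile(str(alignment), mode, **kwargs) as bam:
        if not bam.has_index():
            raise ValueError(f"alignment {alignment} has no index; sort and index it first")
        available = set(bam.references)

        by_chrom: dict[str, list[DiagnosticSite]] = {}
        for site in panel:
            by_chrom.setdefault(site.chromosome, []).append(site)

        resolved = {
            chrom: _resolve_contig(chrom, available, contig_style) for chrom in by_chrom
        }
        if by_chrom and all(v is None for v in resolved.values()):
            raise ValueError(
                f"none of the panel contigs match the alignment {alignment}; "
                "wrong assembly or contig naming?"
            )

        for chrom in sorted(by_chrom, key=chromosome_sort_key):
            contig = resolved[chrom]
            if contig is None:
                continue
            sites = sorted(by_chrom[chrom], key=lambda s: s.position)
            positions = np.array([s.position - 1 for s in sites])  # 0-based
            alt_at = {s.position - 1: s.species_alt_allele.upper() for s in sites}
            total = np.zeros(len(sites), dtype=np.int64)
            species = np.zeros(len(sites), dtype=np.int64)
            index_of = {p: i for i, p in enumerate(positions.tolist())}
            seen_fragments: dict[int, set[str]] | None = (
                {i: set() for i in range(len(sites))} if config.dedup_overlaps else None
            )

            for read in bam.fetch(contig):
                if not filter_read(read, config):
                    continue
                start, end = read.reference_start, read.reference_end
                lo = int(np.searchsorted(positions, start))
                if lo >= len(positions) or positions[lo] >= end:
                    continue
                seq = read.query_sequence
                quals = read.query_qualities
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    i = index_of.get(rpos)
                    if i is None:
                        continue
                    if quals is not None and quals[qpos] < config.min_base_quality:
                        continue
                    if seen_fragments is not None:
                        if read.query_name in seen_fragments[i]:
                            continue
                        seen_fragments[i].add(read.query_name)
                    base = seq[qpos].upper()
                    total[i] += 1
                    if base == alt_at[rpos]:
                        species[i] += 1

            for i, site in enumerate(sites):
                if total[i] > 0:
                    yield AlleleCounts(chrom, site.position, int(total[i]), int(species[i]))


# ---------------------------------------------------------------------------
# samtools mpileup text path


def _parse_pileup_column(bases: str, quals: str) -> list[tuple[str, int]]:
    """Expand one mpileup base string into (symbol, quality) pairs.

    Handles read starts (``^`` + mapping-quality char), read ends (``$``),
    indel descriptors (``+N<seq>``/``-N<seq>``, which carry no quality),
    deletion placeholders (``*``) and reference skips (``></``).
    """
    out: list[tuple[str, int]] = []
    i = qi = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num)
            continue
        out.append((c, ord(quals[qi]) - 33))
        qi += 1
        i += 1
    return out


def parse_mpileup(
    lines: Iterable[str],
    panel: Sequence[DiagnosticSite],
    *,
    min_base_quality: int = 13,
) -> list[AlleleCounts]:
    """Count species-allele and total depth from ``samtools mpileup`` text.

    Read-level filters (mapping quality, duplicates, ...) must have been
    applied when the pileup was produced (e.g. ``samtools mpileup -q 30``);
    this parser applies only the base-quality floor, so generate the text
    with ``-Q 0``. ``.``/``,`` symbols denote the pileup reference allele
    (the human reference at panel sites) and therefore never count as the
    species allele. Deletions and reference skips are not base calls.
    Returns counts in panel order for sites with passing coverage.
    """
    alt_by_site = {(s.chromosome, s.position): s.species_alt_allele.upper() for s in panel}
    counts: dict[tuple[str, int], tuple[int, int]] = {}
    for line in lines:
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        chrom, pos, ref = fields[0], int(fields[1]), fields[2]
        key = (chrom, pos)
        alt = alt_by_site.get(key)
        if alt is None:
            continue
        bases, quals = fields[4], fields[5]
        total = species = 0
        for symbol, quality in _parse_pileup_column(bases, quals):
            if symbol in "*><":
                continue
            if quality < min_base_quality:
                continue
            base = ref.upper() if symbol in ".," else symbol.upper()
            total += 1
            if base == alt:
                species += 1
        if total > 0:
            counts[key] = (total, species)

    out = []
    for site in sorted(panel, key=lambda s: (chromosome_sort_key(s.chromosome), s.position)):
        key = (site.chromosome, site.position)
        if key in counts:
            total, species = counts[key]
            out.append(AlleleCounts(site.chromosome, site.position, total, species))
    return out


def estimate(counts: Iterable[AlleleCounts]) -> ContaminationEstimate:
    """Contamination from allele counts: 1 − species depth / total depth.

    Computed per chromosome (for the across-chromosome standard deviation)
    and genome-wide from pooled counts; the pooled point estimate equals
    the depth-weighted mean of the per-chromosome estimates exactly.
    Raises when no diagnostic position has coverage.
    """
    per: dict[str, list[int]] = {}
    n_positions = 0
    for c in counts:
        n_positions += 1
        agg = per.setdefault(c.chromosome, [0, 0, 0])
        agg[0] += 1
        agg[1] += c.total_depth
        agg[2] += c.species_allele_depth
    if not per:
        raise ValueError("no diagnostic positions observed")

    rows = []
    for chrom in sorted(per, key=chromosome_sort_key):
        n_sites, total, species = per[chrom]
        rows.append(
            ChromosomeCounts(chrom, n_sites, total, species, 1.0 - species / total)
        )
    pooled_total = sum(r.total_depth for r in rows)
    pooled_species = sum(r.species_depth for r in rows)
    point = 1.0 - pooled_species / pooled_total
    per_estimates = [r.estimate for r in rows]
    sd = (
        float(np.std(per_estimates, ddof=1)) if len(per_estimates) >= 2 else None
    )
    if sd is not None and math.isnan(sd):  # defensive; ddof=1 with >=2 values is finite
        sd = None
    return ContaminationEstimate(point, sd, n_positions, tuple(rows))
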