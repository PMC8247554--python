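"""Clade-diagnostic site panels from cohort genotypes.

A diagnostic site is an autosomal position at which a great-ape species
complex is (nearly) fixed for an allele different from the human reference,
while a human cohort is uniformly homozygous for the reference allele.
Reads carrying the human allele at such positions indicate human
contamination. This module derives panels of such sites from joint cohort
genotypes by applying, in order: genomic masks (repeats, 35-mer
mappability), per-genotype depth and mapping-quality filters, a biallelic
SNP filter, and the diagnostic criteria themselves.
"""

from __future__ import annotations

import gzip
import json
import re
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

from intervaltree import IntervalTree

__all__ = [
    "GenotypeCall",
    "CohortGenotypeRecord",
    "GenotypeFilterConfig",
    "DiagnosticSite",
    "SiteRejection",
    "GenomicMask",
    "PanelBuildResult",
    "apply_genotype_filters",
    "is_biallelic_snp",
    "classify_site",
    "build_panel",
    "iter_cohort_records",
    "read_sample_cohorts",
    "read_panel",
    "write_panel",
    "is_autosome",
    "chromosome_sort_key",
]

_SNP_BASES = frozenset("ACGT")

# Rejection reasons, in the order the pipeline applies them.
REASON_NON_AUTOSOME = "non_autosome"
REASON_MASKED = "masked"
REASON_NOT_BIALLELIC = "not_biallelic_snp"
REASON_ALT_FRACTION = "species_alt_fraction_below_min"
REASON_MISSINGNESS = "species_missingness_too_high"
REASON_HUMAN = "human_not_all_reference"


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid genotype with its depth and mapping-quality annotations.

    ``alleles`` holds the two called allele strings; ``None`` marks a
    missing allele. A call with any missing allele is treated as entirely
    missing (both chromosomes uncounted).
    """

    alleles: tuple[str | None, str | None]
    depth: int
    mq: float

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] is None or self.alleles[1] is None

    def as_missing(self) -> "GenotypeCall":
        return GenotypeCall((None, None), self.depth, self.mq)


@dataclass(frozen=True)
class CohortGenotypeRecord:
    """One site's genotypes for the species complex and the human cohort."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    species_genotypes: tuple[GenotypeCall, ...]
    human_genotypes: tuple[GenotypeCall, ...]

    def validate(self) -> None:
        """Raise ``ValueError`` (naming the position) on a malformed record."""
        where = f"{self.chromosome}:{self.position}"
        if self.position < 1:
            raise ValueError(f"position must be >= 1 at {where}")
        if self.ref_allele in self.alt_alleles:
            raise ValueError(f"ref allele listed among alt alleles at {where}")
        allowed = {self.ref_allele, *self.alt_alleles}
        for call in (*self.species_genotypes, *self.human_genotypes):
            if call.depth < 0 or call.mq < 0:
                raise ValueError(f"negative depth or MQ at {where}")
            for a in call.alleles:
                if a is not None and a not in allowed:
                    raise ValueError(f"genotype allele {a!r} not in REF/ALT at {where}")


@dataclass(frozen=True)
class GenotypeFilterConfig:
    """Genotype- and site-level filter thresholds.

    Defaults reproduce the published pipeline: genotypes are set to missing
    below 6x or above 100x depth or below MQ 20; a site is diagnostic when
    >= 98% of observed species chromosomes carry the alternative allele,
    < 5% of species chromosomes are missing, and every human chromosome is
    an observed reference allele.
    """

    min_depth: int = 6
    max_depth: int = 100
    min_genotype_mq: float = 20.0
    min_alt_fraction: float = 0.98
    max_species_missing: float = 0.05
    human_missing_allowed: bool = False
    # Alternative reading of the 98% criterion: use ALL species chromosomes
    # (missing included) as the denominator instead of observed ones.
    alt_fraction_over_total: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_alt_fraction <= 1.0):
            raise ValueError("min_alt_fraction must be in [0, 1]")
        if not (0.0 <= self.max_species_missing <= 1.0):
            raise ValueError("max_species_missing must be in [0, 1]")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")
        if self.min_depth < 0 or self.min_genotype_mq < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True, order=True)
class DiagnosticSite:
    """A clade-diagnostic position: human reference vs. fixed species allele."""

    chromosome: str
    position: int  # 1-based
    human_ref_allele: str
    species_alt_allele: str


@dataclass(frozen=True)
class SiteRejection:
    """A site that failed the diagnostic criteria, tagged with the first reason."""

    chromosome: str
    position: int
    reason: str


def chromosome_sort_key(name: str):
    """Natural ordering: chr2 before chr10; non-numeric names last, lexicographic."""
    m = re.fullmatch(r"(?:chr)?(\d+)", name)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, name)


def is_autosome(name: str) -> bool:
    return re.fullmatch(r"(?:chr)?\d+", name) is not None


class GenomicMask:
    """A set of half-open, 0-based genomic intervals (BED convention)."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._trees: dict[str, IntervalTree] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                for start, end in ivs:
                    self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start < 0 or start >= end:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains(self, chrom: str, position: int) -> bool:
        """True if the 1-based ``position`` falls inside any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(position - 1))

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end) for iv in tree)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomicMask":
        mask = cls()
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                mask.add(fields[0], int(fields[1]), int(fields[2]))
        return mask

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._trees, key=chromosome_sort_key):
                for start, end in self.intervals(chrom):
                    fh.write(f"{chrom}\t{start}\t{end}\n")


def apply_genotype_filters(
    record: CohortGenotypeRecord, config: GenotypeFilterConfig
) -> CohortGenotypeRecord:
    """Set genotypes failing depth/MQ thresholds to missing.

    A genotype with depth < min_depth, depth > max_depth, or MQ <
    min_genotype_mq loses both alleles; boundary values (depth exactly 6 or
    100, MQ exactly 20 under defaults) pass.
    """

    def _filter(call: GenotypeCall) -> GenotypeCall:
        if (
            call.depth < config.min_depth
            or call.depth > config.max_depth
            or call.mq < config.min_genotype_mq
        ):
            return call.as_missing()
        return call

    return replace(
        record,
        species_genotypes=tuple(_filter(c) for c in record.species_genotypes),
        human_genotypes=tuple(_filter(c) for c in record.human_genotypes),
    )


def _observed_alt_alleles(record: CohortGenotypeRecord) -> set[str]:
    observed: set[str] = set()
    for call in (*record.species_genotypes, *record.human_genotypes):
        if call.is_missing:
            continue
        observed.update(a for a in call.alleles if a is not None)
    observed.discard(record.ref_allele)
    return observed


def is_biallelic_snp(record: CohortGenotypeRecord) -> bool:
    """True iff exactly one single-base alternative allele is observed.

    "Observed" means carried by at least one non-missing genotype in either
    cohort; the reference allele must itself be a single base (no indels).
    """
    alts = _observed_alt_alleles(record)
    if len(alts) != 1:
        return False
    (alt,) = alts
    return record.ref_allele in _SNP_BASES and alt in _SNP_BASES


def classify_site(
    record: CohortGenotypeRecord, config: GenotypeFilterConfig
) -> DiagnosticSite | SiteRejection:
    """Apply the diagnostic criteria to a filtered, biallelic, unmasked site.

    Criteria, in order:

    (a) among observed species chromosomes, the alternative-allele fraction
        is >= ``min_alt_fraction`` (inclusive);
    (b) missing species chromosomes are < ``max_species_missing`` of all
        species chromosomes (strict);
    (c) every human chromosome is observed and carries the reference allele
        (unless ``human_missing_allowed``).

    Returns a :class:`DiagnosticSite` on success, otherwise a
    :class:`SiteRejection` tagged with the first failing criterion.
    """
    if not record.species_genotypes:
        raise ValueError(
            f"species cohort is empty at {record.chromosome}:{record.position}"
        )

    alts = _observed_alt_alleles(record)
    alt = next(iter(alts)) if len(alts) == 1 else None

    total_chroms = 2 * len(record.species_genotypes)
    missing_chroms = 2 * sum(c.is_missing for c in record.species_genotypes)
    observed_chroms = total_chroms - missing_chroms
    alt_chroms = sum(
        c.alleles.count(alt) for c in record.species_genotypes if not c.is_missing
    )

    denominator = total_chroms if config.alt_fraction_over_total else observed_chroms
    alt_fraction = alt_chroms / denominator if denominator else 0.0
    if alt is None or alt_fraction < config.min_alt_fraction:
        return SiteRejection(record.chromosome, record.position, REASON_ALT_FRACTION)

    if missing_chroms / total_chroms >= config.max_species_missing:
        return SiteRejection(record.chromosome, record.position, REASON_MISSINGNESS)

    for call in record.human_genotypes:
        if call.is_missing:
            if not config.human_missing_allowed:
                return SiteRejection(record.chromosome, record.position, REASON_HUMAN)
            continue
        if any(a != record.ref_allele for a in call.alleles):
            return SiteRejection(record.chromosome, record.position, REASON_HUMAN)

    return DiagnosticSite(record.chromosome, record.position, record.ref_allele, alt)


@dataclass
class PanelBuildResult:
    """A built panel plus per-reason rejection accounting."""

    sites: list[DiagnosticSite]
    examined: int = 0
    retained: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "sites_examined": self.examined,
            "sites_retained": self.retained,
            "rejected": dict(sorted(self.rejected.items())),
        }


def build_panel(
    records: Iterable[CohortGenotypeRecord],
    masks: Sequence[GenomicMask] = (),
    config: GenotypeFilterConfig | None = None,
    *,
    autosomes_only: bool = True,
) -> PanelBuildResult:
    """Run the full panel pipeline over position-sorted cohort records.

    Pipeline per site: autosome restriction -> mask filter -> per-genotype
    depth/MQ filter -> biallelic-SNP filter -> diagnostic classification.
    Input must be sorted by (chromosome, position) with no chromosome
    revisited; the output panel is unique and sorted in natural chromosome
    order. Deterministic: identical inputs give byte-identical panels.
    """
    config = config or GenotypeFilterConfig()
    result = PanelBuildResult(sites=[])
    seen_chroms: set[str] = set()
    current_chrom: str | None = None
    last_pos = 0

    def _reject(reason: str) -> None:
        result.rejected[reason] = result.rejected.get(reason, 0) + 1

    for record in records:
        record.validate()
        if record.chromosome != current_chrom:
            if record.chromosome in seen_chroms:
                raise ValueError(
                    "input not sorted: chromosome "
                    f"{record.chromosome} revisited at position {record.position}"
                )
            if current_chrom is not None:
                seen_chroms.add(current_chrom)
            current_chrom = record.chromosome
            last_pos = 0
        if record.position <= last_pos:
            raise ValueError(
                "input not sorted: "
                f"{record.chromosome}:{record.position} after position {last_pos}"
            )
        last_pos = record.position

        result.examined += 1
        if autosomes_only and not is_autosome(record.chromosome):
            _reject(REASON_NON_AUTOSOME)
            continue
        if any(m.contains(record.chromosome, record.position) for m in masks):
            _reject(REASON_MASKED)
            continue
        filtered = apply_genotype_filters(record, config)
        if not is_biallelic_snp(filtered):
            _reject(REASON_NOT_BIALLELIC)
            continue
        outcome = classify_site(filtered, config)
        if isinstance(outcome, SiteRejection):
            _reject(outcome.reason)
            continue
        result.sites.append(outcome)
        result.retained += 1

    result.sites.sort(key=lambda s: (chromosome_sort_key(s.chromosome), s.position))
    return result


# ---------------------------------------------------------------------------
# I/O: cohort VCF, sample map, panel TSV


def read_sample_cohorts(path: str | Path) -> dict[str, str]:
    """Read the two-column sample-to-cohort TSV (sample_id, species|human)."""
    cohorts: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, cohort = line.split("\t")[:2]
            if cohort not in ("species", "human"):
                raise ValueError(f"unknown cohort {cohort!r} for sample {sample!r}")
            cohorts[sample] = cohort
    if "species" not in cohorts.values():
        raise ValueError(f"no species samples listed in {path}")
    return cohorts


def iter_cohort_records(
    vcf_path: str | Path,
    sample_cohorts: Mapping[str, str],
    *,
    dp_field: str = "DP",
    mq_field: str = "MQ",
    mq_source: str = "format",
) -> Iterator[CohortGenotypeRecord]:
    """Stream :class:`CohortGenotypeRecord` objects from a VCF.

    Per-sample depth comes from ``FORMAT/<dp_field>``; mapping quality from
    ``FORMAT/<mq_field>`` when ``mq_source == "format"`` or from
    ``INFO/<mq_field>`` (one value applied to every sample) when
    ``mq_source == "info"``. Samples absent from ``sample_cohorts`` are
    ignored.
    """
    import cyvcf2

    if mq_source not in ("format", "info"):
        raise ValueError("mq_source must be 'format' or 'info'")
    vcf = cyvcf2.VCF(str(vcf_path))
    species_idx = [i for i, s in enumerate(vcf.samples) if sample_cohorts.get(s) == "species"]
    human_idx = [i for i, s in enumerate(vcf.samples) if sample_cohorts.get(s) == "human"]
    if not species_idx:
        raise ValueError(f"no species-cohort samples found in {vcf_path}")

    def _scalar(arr, i, default=0.0):
        if arr is None:
            return default
        v = arr[i]
        try:
            v = v.item() if hasattr(v, "item") else v[0]
        except (TypeError, IndexError):
            pass
        if v is None or v != v or v < 0:  # NaN or sentinel negative
            return default
        return v

    for variant in vcf:
        alleles = [variant.REF, *variant.ALT]
        gts = variant.genotypes
        dp = variant.format(dp_field)
        if mq_source == "format":
            mq = variant.format(mq_field)
            site_mq = None
        else:
            mq = None
            site_mq = variant.INFO.get(mq_field)
            site_mq = float(site_mq) if site_mq is not None else 0.0

        def _call(i: int) -> GenotypeCall:
            a1, a2 = gts[i][0], gts[i][1]
            def decode(a):
                return alleles[a] if 0 <= a < len(alleles) else None
            depth = int(_scalar(dp, i, 0))
            quality = site_mq if site_mq is not None else float(_scalar(mq, i, 0.0))
            return GenotypeCall((decode(a1), decode(a2)), depth, quality)

        yield CohortGenotypeRecord(
            chromosome=variant.CHROM,
            position=variant.POS,
            ref_allele=variant.REF,
            alt_alleles=tuple(variant.ALT),
            species_genotypes=tuple(_call(i) for i in species_idx),
            human_genotypes=tuple(_call(i) for i in human_idx),
        )


PANEL_HEADER = "chrom\tpos\tref\talt"


def write_panel(
    sites: Sequence[DiagnosticSite],
    path: str | Path,
    summary: dict | None = None,
    summary_path: str | Path | None = None,
) -> None:
    """Write a panel TSV (1-based positions); bgzips when path ends in .gz."""
    path = Path(path)
    text = PANEL_HEADER + "\n" + "".join(
        f"{s.chromosome}\t{s.position}\t{s.human_ref_allele}\t{s.species_alt_allele}\n"
        for s in sites
    )
    if path.suffix == ".gz":
        import pysam

        plain = path.with_suffix("")
        plain.write_text(text)
        pysam.tabix_compress(str(plain), str(path), force=True)
        plain.unlink()
    else:
        path.write_text(text)
    if summary is not None and summary_path is not None:
        Path(summary_path).write_text(json.dumps(summary, indent=2) + "\n")


def read_panel(path: str | Path) -> list[DiagnosticSite]:
    """Read a panel TSV (optionally gzip/bgzip-compressed) into sorted sites."""
    opener = gzip.open if str(path).endswith(".gz") else open
    sites: list[DiagnosticSite] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "chrom\t")):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            sites.append(DiagnosticSite(chrom, int(pos), ref, alt))
    sites.sort(key=lambda s: (chromosome_sort_key(s.chromosome), s.position))
    return sites
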