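"""Self-contained synthetic substrate: references, cohorts, panels, reads.

Everything the other modules consume — a toy multi-chromosome reference, a
species-complex cohort with planted fixed differences against the (human)
reference, within-clade polymorphism, deliberately failing sites, genomic
masks, and error-free or error-rate-parameterized aligned reads — is
generated here with a planted truth table, so pipelines are testable end
to end without any external data.

Individuals are diploid pairs of haplotypes with independently drawn
alleles at polymorphic sites; no linkage model is used, because the
contamination test is strictly single-site.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import DiagnosticSite, GenomicMask

__all__ = [
    "CladeModel",
    "ReadModel",
    "Reference",
    "CohortFixture",
    "FixtureSet",
    "make_reference",
    "write_reference",
    "make_cohort_vcf",
    "make_reads",
    "species_haplotypes",
    "human_haplotypes",
    "crossclade_haplotypes",
    "random_cohort_records",
    "make_fixture_set",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

SITE_DIAGNOSTIC = "diagnostic"
SITE_POLYMORPHIC = "species_polymorphic"
SITE_HUMAN_POLY = "human_polymorphic"

# Perturbations applied to diagnostic-class sites by make_cohort_vcf. The
# "benign" modes keep the site in the expected panel; the others knock it out.
FAIL_NONE = "none"
FAIL_BENIGN_MISSING = "benign_missing"
FAIL_BENIGN_REF = "benign_ref_carrier"
FAIL_LOW_DP = "low_dp_missingness"
FAIL_LOW_MQ = "low_mq_missingness"
FAIL_ALT_FRACTION = "alt_fraction"
FAIL_MULTIALLELIC = "multiallelic"
FAIL_INDEL = "indel"
FAIL_HUMAN_MISSING = "human_missing"
FAIL_MASKED = "masked"


@dataclass(frozen=True)
class CladeModel:
    """Parameters of one synthetic species complex vs. the human reference.

    ``diagnostic_density`` is the realized per-bp density of planted fixed
    differences (~200 per 100 kb chromosome at the default 1/500);
    ``polymorphic_fraction`` is the fraction of candidate variant sites
    that segregate within the clade instead of being fixed;
    ``human_like_fraction`` is used for cross-clade haplotypes: the
    fraction of another clade's diagnostic sites at which this clade
    carries the human allele.
    """

    n_chromosomes: int = 3
    chromosome_length: int = 100_000
    diagnostic_density: float = 1 / 500
    polymorphic_fraction: float = 0.2
    human_polymorphic_fraction: float = 0.05
    human_like_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("diagnostic_density", "polymorphic_fraction",
                     "human_polymorphic_fraction", "human_like_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.polymorphic_fraction >= 1.0:
            raise ValueError("polymorphic_fraction must be < 1")


@dataclass(frozen=True)
class ReadModel:
    """Parameters of the synthetic sequencing process.

    Reads are exact haplotype substrings (plus seeded substitution errors at
    ``error_rate``) in proper pairs with MQ 60 and constant base quality;
    erroneous bases get ``error_base_quality`` so the base-quality filter
    can be exercised. ``low_mq_fraction`` makes that share of fragments
    MQ-10 decoys for the mapping-quality filter.
    """

    read_length: int = 100
    paired: bool = True
    mean_depth: float = 20.0
    error_rate: float = 0.0
    fragment_length: int = 200
    base_quality: int = 37
    error_base_quality: int = 37
    low_mq_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.paired and self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")


@dataclass
class Reference:
    """A toy reference genome plus the planted-site truth table.

    ``truth`` columns: chrom, pos (1-based), site_class, ref, alt,
    species_af (alt-allele frequency within the clade; 1.0 at fixed sites).
    """

    sequences: dict[str, str]
    truth: pd.DataFrame
    model: CladeModel

    def chromosome_names(self) -> list[str]:
        return list(self.sequences)


def make_reference(model: CladeModel) -> Reference:
    """Generate a seeded random reference with planted site classes."""
    rng = np.random.default_rng(model.seed)
    sequences: dict[str, str] = {}
    rows = []
    margin = 1_000
    p = model.polymorphic_fraction
    for k in range(1, model.n_chromosomes + 1):
        chrom = f"chr{k}"
        L = model.chromosome_length
        seq = rng.choice(_BASES, size=L)
        sequences[chrom] = seq.tobytes().decode()

        n_diag = round(L * model.diagnostic_density)
        n_cand = round(n_diag / (1.0 - p)) if n_diag else 0
        n_poly = n_cand - n_diag
        n_hpoly = round(n_diag * model.human_polymorphic_fraction)
        total = n_diag + n_poly + n_hpoly
        if total == 0:
            continue
        positions = np.sort(
            rng.choice(np.arange(margin, L - margin), size=total, replace=False)
        )
        classes = np.array(
            [SITE_DIAGNOSTIC] * n_diag
            + [SITE_POLYMORPHIC] * n_poly
            + [SITE_HUMAN_POLY] * n_hpoly
        )
        rng.shuffle(classes)
        for pos0, cls in zip(positions.tolist(), classes.tolist()):
            ref = sequences[chrom][pos0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            af = 1.0 if cls != SITE_POLYMORPHIC else float(rng.uniform(0.2, 0.9))
            rows.append((chrom, pos0 + 1, cls, ref, str(alt), af))

    truth = pd.DataFrame(
        rows, columns=["chrom", "pos", "site_class", "ref", "alt", "species_af"]
    )
    return Reference(sequences, truth, model)


def write_reference(reference: Reference, fasta_path: str | Path) -> None:
    """Write the reference as FASTA (60-column) and index it with faidx."""
    import pysam

    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        for chrom, seq in reference.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(fasta_path))


# ---------------------------------------------------------------------------
# Cohort VCF with planted expected panel


@dataclass
class CohortFixture:
    """A written cohort VCF and everything needed to check a panel build."""

    vcf_path: Path
    samples_path: Path
    mask: GenomicMask
    mask_path: Path | None
    expected_panel: list[DiagnosticSite]
    truth: pd.DataFrame  # per-site truth incl. fail_mode and expected_in_panel


def _gt(a1: int | None, a2: int | None) -> str:
    fmt = lambda a: "." if a is None else str(a)
    return f"{fmt(a1)}/{fmt(a2)}"


def make_cohort_vcf(
    reference: Reference,
    out_dir: str | Path,
    *,
    n_species: int = 68,
    n_human: int = 19,
    seed: int = 0,
    fail_fractions: Mapping[str, float] | None = None,
    write_mask: bool = True,
) -> CohortFixture:
    """Write a cohort VCF with per-sample GT:DP:MQ and planted failures.

    Diagnostic-class sites are clade-fixed alternative and human
    homozygous-reference; a seeded subset gets perturbations exercising
    every rejection path (depth/MQ-driven missingness beyond 5%, species
    reference carriers beyond 2%, multi-allelic and indel records, missing
    human genotypes, masked intervals) and benign counterparts that must
    survive. The expected panel is implied directly by the construction
    arithmetic, independently of the panel-builder implementation.

    Cohort sizes default to the Pan design: 68 species individuals
    (chimpanzees plus bonobos) and 19 humans.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fractions = {
        FAIL_BENIGN_MISSING: 0.03,
        FAIL_BENIGN_REF: 0.03,
        FAIL_LOW_DP: 0.03,
        FAIL_LOW_MQ: 0.02,
        FAIL_ALT_FRACTION: 0.03,
        FAIL_MULTIALLELIC: 0.02,
        FAIL_INDEL: 0.01,
        FAIL_HUMAN_MISSING: 0.02,
        FAIL_MASKED: 0.04,
        **(fail_fractions or {}),
    }

    truth = reference.truth.copy()
    truth["fail_mode"] = FAIL_NONE
    diag_idx = truth.index[truth.site_class == SITE_DIAGNOSTIC].to_numpy()
    perm = rng.permutation(diag_idx)
    cursor = 0
    for mode, frac in fractions.items():
        k = round(frac * len(diag_idx))
        truth.loc[perm[cursor : cursor + k], "fail_mode"] = mode
        cursor += k

    # Smallest perturbation sizes that cross each threshold. Missingness: k
    # missing samples give k/n missing chromosomes, failing when k/n >= 0.05.
    # Reference carriers are counted in chromosomes (a het carries one): k ref
    # chromosomes of 2n give alt fraction 1 - k/(2n), failing when k > 0.04n.
    k_missing_fail = int(np.ceil(0.05 * n_species - 1e-9))
    k_missing_ok = max(1, k_missing_fail - 1)
    ref_chrom_ok = int(np.floor(0.04 * n_species + 1e-9))
    ref_chrom_fail = ref_chrom_ok + 1
    if k_missing_fail < 2 or ref_chrom_ok < 1:
        raise ValueError(
            "n_species too small to plant both benign and failing perturbations"
        )

    def _plant_ref_chromosomes(sp_gt, k_chrom):
        hit = rng.choice(n_species, size=(k_chrom + 1) // 2, replace=False)
        for j, i in enumerate(hit):
            # last carrier is a het when k_chrom is odd
            sp_gt[i] = (0, 1) if (k_chrom % 2 and j == len(hit) - 1) else (0, 0)

    mask = GenomicMask()
    for _, row in truth[truth.fail_mode == FAIL_MASKED].iterrows():
        start0 = max(0, int(row.pos) - 1 - int(rng.integers(0, 10)))
        mask.add(str(row.chrom), start0, start0 + 25)
    # a couple of site-free intervals so masks are not only around variants
    for chrom in reference.chromosome_names():
        mask.add(chrom, 0, 200)

    samples = [f"species_{i:03d}" for i in range(n_species)] + [
        f"human_{i:03d}" for i in range(n_human)
    ]

    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=MQ,Number=1,Type=Float,Description="Genotype mapping quality">',
    ]
    for chrom, seq in reference.sequences.items():
        lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))

    expected: list[DiagnosticSite] = []
    expected_flags = []
    for _, row in truth.iterrows():
        chrom, pos, ref, alt = str(row.chrom), int(row.pos), str(row.ref), str(row.alt)
        cls, mode = str(row.site_class), str(row.fail_mode)
        alt_field = alt
        dp = rng.integers(10, 61, size=len(samples))
        mq = np.full(len(samples), 60.0)
        sp_gt = [(1, 1)] * n_species
        hu_gt = [(0, 0)] * n_human

        if cls == SITE_POLYMORPHIC:
            draws = rng.random((n_species, 2)) < float(row.species_af)
            sp_gt = [tuple(int(v) for v in d) for d in draws]
            # polymorphic sites must stay below the 98% fixation threshold
            if sum(a + b for a, b in sp_gt) >= 0.98 * 2 * n_species:
                sp_gt[0] = (0, 0)
        elif cls == SITE_HUMAN_POLY:
            het = rng.choice(n_human, size=max(1, n_human // 6), replace=False)
            for i in het:
                hu_gt[i] = (0, 1)
        elif mode == FAIL_BENIGN_MISSING:
            dp[rng.choice(n_species, size=k_missing_ok, replace=False)] = 5
        elif mode == FAIL_BENIGN_REF:
            _plant_ref_chromosomes(sp_gt, ref_chrom_ok)
        elif mode == FAIL_LOW_DP:
            hit = rng.choice(n_species, size=k_missing_fail, replace=False)
            dp[hit] = 5
            dp[hit[0]] = 101  # exercise the upper depth bound too
        elif mode == FAIL_LOW_MQ:
            mq[rng.choice(n_species, size=k_missing_fail, replace=False)] = 10.0
        elif mode == FAIL_ALT_FRACTION:
            _plant_ref_chromosomes(sp_gt, ref_chrom_fail)
        elif mode == FAIL_MULTIALLELIC:
            alt2 = next(b for b in "ACGT" if b not in (ref, alt))
            alt_field = f"{alt},{alt2}"
            sp_gt[int(rng.integers(n_species))] = (1, 2)
        elif mode == FAIL_INDEL:
            alt_field = alt + ref
        elif mode == FAIL_HUMAN_MISSING:
            dp[n_species + int(rng.integers(n_human))] = 5

        in_panel = (
            cls == SITE_DIAGNOSTIC
            and mode in (FAIL_NONE, FAIL_BENIGN_MISSING, FAIL_BENIGN_REF)
            # a mask interval planted for one site can cover a close neighbour
            and not mask.contains(chrom, pos)
        )
        expected_flags.append(in_panel)
        if in_panel:
            expected.append(DiagnosticSite(chrom, pos, ref, alt))

        cells = []
        for i, (a1, a2) in enumerate([*sp_gt, *hu_gt]):
            cells.append(f"{_gt(a1, a2)}:{dp[i]}:{mq[i]:g}")
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt_field}\t.\t.\t.\tGT:DP:MQ\t" + "\t".join(cells)
        )

    truth["expected_in_panel"] = expected_flags

    vcf_path = out_dir / "cohort.vcf"
    vcf_path.write_text("\n".join(lines) + "\n")
    samples_path = out_dir / "samples.tsv"
    with open(samples_path, "w") as fh:
        for s in samples:
            cohort = "species" if s.startswith("species") else "human"
            fh.write(f"{s}\t{cohort}\n")
    mask_path = None
    if write_mask:
        mask_path = out_dir / "masks.bed"
        mask.to_bed(mask_path)

    expected.sort(key=lambda s: (s.chromosome, s.position))
    return CohortFixture(vcf_path, samples_path, mask, mask_path, expected, truth)


# ---------------------------------------------------------------------------
# Haplotypes and reads


def _apply_alleles(seq: str, sites: pd.DataFrame, use_alt: np.ndarray) -> str:
    hap = bytearray(seq, "ascii")
    for (pos, alt), alt_here in zip(
        zip(sites.pos.tolist(), sites.alt.tolist()), use_alt.tolist()
    ):
        if alt_here:
            hap[pos - 1] = ord(alt)
    return hap.decode()


def species_haplotypes(
    reference: Reference, rng: np.random.Generator | None = None
) -> dict[str, tuple[str, str]]:
    """Diploid haplotypes of one species individual.

    Homozygous for the species allele at every fixed site (diagnostic and
    human-polymorphic classes); polymorphic-site alleles drawn per
    haplotype at the planted frequency when an ``rng`` is given, reference
    otherwise.
    """
    haps = {}
    for chrom, seq in reference.sequences.items():
        sites = reference.truth[reference.truth.chrom == chrom]
        out = []
        for _ in range(2):
            fixed = sites.site_class.isin([SITE_DIAGNOSTIC, SITE_HUMAN_POLY]).to_numpy()
            if rng is not None:
                poly = (sites.site_class == SITE_POLYMORPHIC).to_numpy()
                draw = rng.random(len(sites)) < sites.species_af.to_numpy()
                use_alt = fixed | (poly & draw)
            else:
                use_alt = fixed
            out.append(_apply_alleles(seq, sites, use_alt))
        haps[chrom] = (out[0], out[1])
    return haps


def human_haplotypes(reference: Reference) -> dict[str, tuple[str, str]]:
    """A human individual: the reference allele everywhere that matters."""
    return {chrom: (seq, seq) for chrom, seq in reference.sequences.items()}


def crossclade_haplotypes(
    reference: Reference, human_like_fraction: float, seed: int
) -> dict[str, tuple[str, str]]:
    """Haplotypes of a sister clade sharing the human allele at a planted
    fraction of the focal clade's diagnostic sites (shared ancestry), and
    the species allele at the rest."""
    rng = np.random.default_rng(seed)
    haps = {}
    for chrom, seq in reference.sequences.items():
        sites = reference.truth[reference.truth.chrom == chrom]
        fixed = sites.site_class.isin([SITE_DIAGNOSTIC, SITE_HUMAN_POLY]).to_numpy()
        human_like = rng.random(len(sites)) < human_like_fraction
        use_alt = fixed & ~human_like
        hap = _apply_alleles(seq, sites, use_alt)
        haps[chrom] = (hap, hap)
    return haps


def make_reads(
    haplotypes: Mapping[str, tuple[str, str]],
    model: ReadModel,
    out_bam: str | Path,
    *,
    name_prefix: str = "frag",
) -> pd.DataFrame:
    """Simulate proper read pairs from diploid haplotypes into a sorted,
    indexed BAM; returns the per-read truth table.

    Fragment starts are uniform, the source haplotype is drawn per
    fragment, and reads are exact substrings with deterministic coordinates
    (the haplotypes differ from the reference only by substitutions).
    Truth columns: name, chrom, start (0-based leftmost), haplotype.
    """
    import pysam

    rng = np.random.default_rng(model.seed)
    out_bam = Path(out_bam)
    chroms = list(haplotypes)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(haplotypes[c][0])} for c in chroms],
    }
    frag_len = model.fragment_length if model.paired else model.read_length
    rl = model.read_length
    truth_rows = []
    tmp = out_bam.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
        for tid, chrom in enumerate(chroms):
            hap_pair = haplotypes[chrom]
            L = len(hap_pair[0])
            if L < frag_len:
                raise ValueError(f"chromosome {chrom} shorter than fragment length")
            per_read = 2 * rl if model.paired else rl
            n_frags = round(model.mean_depth * L / per_read)
            starts = rng.integers(0, L - frag_len + 1, size=n_frags)
            hap_idx = rng.integers(0, 2, size=n_frags)
            low_mq = rng.random(n_frags) < model.low_mq_fraction
            for j in range(n_frags):
                start = int(starts[j])
                hap = hap_pair[int(hap_idx[j])]
                name = f"{name_prefix}_{chrom}_{j:07d}"
                mapq = 10 if low_mq[j] else 60
                seq1 = hap[start : start + rl]
                if model.paired:
                    end = start + frag_len
                    # SEQ is stored in reference-forward orientation, so the
                    # reverse-strand mate is the plain haplotype substring too
                    seq2 = hap[end - rl : end]
                    reads = [
                        (seq1, start, 99, end - rl, frag_len),
                        (seq2, end - rl, 147, start, -frag_len),
                    ]
                else:
                    reads = [(seq1, start, 0, -1, 0)]
                for seq, pos, flag, mpos, tlen in reads:
                    seq_arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                    quals = np.full(rl, model.base_quality, dtype=np.uint8)
                    if model.error_rate > 0:
                        errs = np.flatnonzero(rng.random(rl) < model.error_rate)
                        for e in errs.tolist():
                            cur = seq_arr[e].decode()
                            seq_arr[e] = rng.choice(
                                [b for b in "ACGT" if b != cur]
                            ).encode()
                        quals[errs] = model.error_base_quality
                    a = pysam.AlignedSegment()
                    a.query_name = name
                    a.query_sequence = seq_arr.tobytes().decode()
                    a.flag = flag
                    a.reference_id = tid
                    a.reference_start = pos
                    a.mapping_quality = mapq
                    a.cigarstring = f"{rl}M"
                    a.next_reference_id = tid if model.paired else -1
                    a.next_reference_start = mpos
                    a.template_length = tlen
                    a.query_qualities = quals.tolist()
                    bam.write(a)
                truth_rows.append((name, chrom, start, int(hap_idx[j])))
    pysam.sort("--no-PG", "-o", str(out_bam), str(tmp))
    tmp.unlink()
    pysam.index(str(out_bam))
    return pd.DataFrame(truth_rows, columns=["name", "chrom", "start", "haplotype"])


# ---------------------------------------------------------------------------
# Random in-memory cohorts (for oracle-equivalence exercises)


def random_cohort_records(
    rng: np.random.Generator,
    n_sites: int = 500,
    n_species: int = 20,
    n_human: int = 10,
    n_chromosomes: int = 3,
):
    """Random position-sorted cohort records spanning every filter boundary.

    Depths, mapping qualities, allele configurations and missingness are
    drawn so that all genotype- and site-level criteria are exercised near
    their thresholds (depths around 5-101, MQ around 19-21, alt fractions
    around 98%, occasional multi-allelic and indel records, occasional
    human carriers and missing human genotypes).
    """
    from .panel import CohortGenotypeRecord, GenotypeCall

    records = []
    per_chrom = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_sites, replace=False))
    chrom_of = np.sort(rng.integers(1, n_chromosomes + 1, size=n_sites))
    bases = list("ACGT")

    for pos, k in zip(per_chrom.tolist(), chrom_of.tolist()):
        ref = rng.choice(bases)
        others = [b for b in bases if b != ref]
        shape = rng.random()
        if shape < 0.05:
            alts = tuple(rng.choice(others, size=2, replace=False))
        elif shape < 0.08:
            alts = (ref + rng.choice(bases),)  # indel-like allele
        else:
            alts = (rng.choice(others),)

        def draw_call(p_alt: float) -> GenotypeCall:
            depth = int(rng.choice([3, 5, 6, 30, 100, 101, 120], p=[0.03, 0.03, 0.1, 0.66, 0.1, 0.04, 0.04]))
            mq = float(rng.choice([10, 19, 20, 21, 60], p=[0.03, 0.03, 0.05, 0.05, 0.84]))
            if rng.random() < 0.03:
                return GenotypeCall((None, None), depth, mq)
            pool = [ref, *(a for a in alts)]
            probs = [1 - p_alt] + [p_alt / len(alts)] * len(alts)
            a1, a2 = rng.choice(pool, size=2, p=probs)
            return GenotypeCall((str(a1), str(a2)), depth, mq)

        p_alt_species = float(rng.choice([1.0, 0.99, 0.985, 0.95, 0.5], p=[0.5, 0.1, 0.1, 0.15, 0.15]))
        p_alt_human = float(rng.choice([0.0, 0.05, 0.5], p=[0.8, 0.1, 0.1]))
        records.append(
            CohortGenotypeRecord(
                chromosome=f"chr{k}",
                position=int(pos),
                ref_allele=str(ref),
                alt_alleles=tuple(str(a) for a in alts),
                species_genotypes=tuple(draw_call(p_alt_species) for _ in range(n_species)),
                human_genotypes=tuple(draw_call(p_alt_human) for _ in range(n_human)),
            )
        )
    # enforce strictly increasing positions within each chromosome
    out = []
    last: dict[str, int] = {}
    for r in records:
        if r.position <= last.get(r.chromosome, 0):
            continue
        last[r.chromosome] = r.position
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# One-call fixture set


@dataclass
class FixtureSet:
    """Paths and in-memory objects for a complete generated fixture tree."""

    outdir: Path
    reference: Reference
    fasta: Path
    cohort: CohortFixture
    expected_panel_path: Path
    host_bam: Path
    human_bam: Path
    truth_path: Path
    extras: dict = field(default_factory=dict)


def make_fixture_set(
    outdir: str | Path,
    seed: int = 42,
    *,
    clade: CladeModel | None = None,
    reads: ReadModel | None = None,
    n_species: int = 68,
    n_human: int = 19,
) -> FixtureSet:
    """Write a complete fixture tree: FASTA+fai, cohort VCF, samples TSV,
    mask BED, expected panel TSV, host and contaminant BAMs (+bai), and a
    truth JSON; everything derived from one seed."""
    from .panel import write_panel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    clade = clade or CladeModel(seed=seeds[0])
    reads = reads or ReadModel(seed=seeds[1])
    reference = make_reference(clade)
    fasta = outdir / "reference.fa"
    write_reference(reference, fasta)

    cohort = make_cohort_vcf(reference, outdir, n_species=n_species, n_human=n_human, seed=seeds[2])
    expected_panel_path = outdir / "expected_panel.tsv"
    write_panel(cohort.expected_panel, expected_panel_path)

    host_bam = outdir / "host.bam"
    make_reads(species_haplotypes(reference), reads, host_bam, name_prefix="host")
    human_bam = outdir / "human.bam"
    human_model = ReadModel(
        read_length=reads.read_length,
        paired=reads.paired,
        mean_depth=reads.mean_depth,
        error_rate=reads.error_rate,
        fragment_length=reads.fragment_length,
        seed=seeds[3],
    )
    make_reads(human_haplotypes(reference), human_model, human_bam, name_prefix="human")

    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "seed": seed,
                "clade": clade.__dict__,
                "reads": reads.__dict__,
                "sites": cohort.truth.to_dict(orient="records"),
            },
            indent=2,
            default=str,
        )
        + "\n"
    )
    return FixtureSet(
        outdir, reference, fasta, cohort, expected_panel_path, host_bam, human_bam, truth_path
    )
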