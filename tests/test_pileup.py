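"""Pileup estimator: read filters, allele counting, the estimate arithmetic."""

import statistics
import subprocess

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hucontest.panel import DiagnosticSite
from hucontest.pileup import (
    AlleleCounts,
    ReadFilterConfig,
    count_alleles,
    estimate,
    filter_read,
    parse_mpileup,
)
from oracles import brute_force_allele_counts

CFG = ReadFilterConfig()


def make_read(
    name="r1",
    chrom_id=0,
    start=0,
    seq="ACGT" * 25,
    mapq=60,
    flag=0,
    tlen=0,
    mate_start=-1,
    quals=None,
    cigar=None,
):
    a = pysam.AlignedSegment()
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = chrom_id
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = cigar or f"{len(seq)}M"
    a.next_reference_id = chrom_id if mate_start >= 0 else -1
    a.next_reference_start = mate_start
    a.template_length = tlen
    a.query_qualities = quals if quals is not None else [37] * len(seq)
    return a


def write_bam(path, reads, lengths=(10_000,)):
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": f"chr{i + 1}", "LN": L} for i, L in enumerate(lengths)],
    }
    tmp = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
        for r in reads:
            bam.write(r)
    pysam.sort("--no-PG", "-o", str(path), str(tmp))
    tmp.unlink()
    pysam.index(str(path))
    return path


class TestFilterRead:
    def test_mapping_quality_boundary(self):
        assert not filter_read(make_read(mapq=29, flag=99, tlen=200, mate_start=100), CFG)
        assert filter_read(make_read(mapq=30, flag=99, tlen=200, mate_start=100), CFG)

    def test_fragment_length_boundary_paired(self):
        # |TLEN| is the fragment length for proper pairs; 35 passes (>=), 34 fails
        assert filter_read(make_read(flag=99, tlen=35, mate_start=10), CFG)
        assert not filter_read(make_read(flag=99, tlen=-34, mate_start=10), CFG)

    def test_fragment_length_unpaired_uses_aligned_length(self):
        assert filter_read(make_read(seq="A" * 35), CFG)
        assert not filter_read(make_read(seq="A" * 34), CFG)

    @pytest.mark.parametrize(
        "flag,reason",
        [(1024, "duplicate"), (256, "secondary"), (2048, "supplementary"), (512, "qcfail")],
    )
    def test_flag_driven_exclusions(self, flag, reason):
        assert not filter_read(make_read(flag=flag, seq="A" * 100), CFG)

    def test_flag_exclusions_can_be_disabled(self):
        cfg = ReadFilterConfig(exclude_duplicates=False)
        assert filter_read(make_read(flag=1024, seq="A" * 100), cfg)


class TestCountAlleles:
    def test_planted_bases_counted(self, tmp_path):
        # 10 passing reads over chr1:51 (1-based); 9 carry the species allele G
        reads = []
        for i in range(9):
            reads.append(make_read(f"g{i}", start=10, seq="G" * 100))
        reads.append(make_read("ref", start=30, seq="A" * 100))
        bam = write_bam(tmp_path / "t.bam", reads)
        site = DiagnosticSite("chr1", 51, "A", "G")
        counts = list(count_alleles(bam, [site]))
        assert counts == [AlleleCounts("chr1", 51, 10, 9)]

    def test_low_mapq_site_not_emitted(self, tmp_path):
        bam = write_bam(tmp_path / "t.bam", [make_read(mapq=29, seq="G" * 100)])
        assert list(count_alleles(bam, [DiagnosticSite("chr1", 51, "A", "G")])) == []

    def test_low_base_quality_excluded(self, tmp_path):
        quals = [37] * 100
        quals[50] = 5  # below the default floor of 13
        reads = [make_read("lo", start=0, quals=quals, seq="G" * 100),
                 make_read("hi", start=0, seq="G" * 100)]
        bam = write_bam(tmp_path / "t.bam", reads)
        counts = list(count_alleles(bam, [DiagnosticSite("chr1", 51, "A", "G")]))
        assert counts == [AlleleCounts("chr1", 51, 1, 1)]

    def test_deletion_at_site_not_a_base_call(self, tmp_path):
        # read spans the site but deletes it: 50M2D48M skips positions 51-52
        deleted = make_read("del", start=0, seq="G" * 98, cigar="50M2D48M")
        covering = make_read("cov", start=0, seq="G" * 100)
        bam = write_bam(tmp_path / "t.bam", [deleted, covering])
        counts = list(count_alleles(bam, [DiagnosticSite("chr1", 51, "A", "G")]))
        assert counts == [AlleleCounts("chr1", 51, 1, 1)]

    def test_third_allele_counts_toward_contamination(self, tmp_path):
        # "not matching the target species complex allele": a T read at an A/G
        # site adds to total depth but not to the species-allele depth
        reads = [make_read("g", seq="G" * 100), make_read("t", seq="T" * 100)]
        bam = write_bam(tmp_path / "t.bam", reads)
        counts = list(count_alleles(bam, [DiagnosticSite("chr1", 51, "A", "G")]))
        assert counts == [AlleleCounts("chr1", 51, 2, 1)]
        est = estimate(counts)
        assert est.point_estimate == pytest.approx(0.5)

    def test_contig_style_reconciliation(self, tmp_path):
        bam = write_bam(tmp_path / "t.bam", [make_read(seq="G" * 100)])
        # panel names the contig without the "chr" prefix
        counts = list(count_alleles(bam, [DiagnosticSite("1", 51, "A", "G")]))
        assert counts == [AlleleCounts("1", 51, 1, 1)]

    def test_all_contigs_unresolvable_errors(self, tmp_path):
        bam = write_bam(tmp_path / "t.bam", [make_read(seq="G" * 100)])
        with pytest.raises(ValueError, match="wrong assembly"):
            list(count_alleles(bam, [DiagnosticSite("scaffold_7", 51, "A", "G")]))

    def test_matches_pileup_engine_oracle(self, host_bam, expected_panel):
        """Per-read counting agrees with an independent pileup-column tally."""
        panel = expected_panel[::5]
        ours = {
            (c.chromosome, c.position): (c.total_depth, c.species_allele_depth)
            for c in count_alleles(host_bam, panel)
        }
        assert ours == brute_force_allele_counts(host_bam, panel)

    def test_overlap_dedup_counts_fragment_once(self, tmp_path):
        # mates overlap the site; with dedup_overlaps each fragment counts once
        r1 = make_read("f", start=0, seq="G" * 100, flag=99, tlen=150, mate_start=50)
        r2 = make_read("f", start=50, seq="G" * 100, flag=147, tlen=-150, mate_start=0)
        bam = write_bam(tmp_path / "t.bam", [r1, r2])
        site = DiagnosticSite("chr1", 71, "A", "G")
        both = list(count_alleles(bam, [site]))
        deduped = list(count_alleles(bam, [site], ReadFilterConfig(dedup_overlaps=True)))
        assert both[0].total_depth == 2
        assert deduped[0].total_depth == 1


class TestEstimate:
    def test_single_chromosome_point_estimate(self):
        counts = [AlleleCounts("chr1", i + 1, 20, 19) for i in range(10)]
        est = estimate(counts)
        assert est.point_estimate == pytest.approx(1 - 190 / 200)
        assert est.sd is None  # undefined with a single chromosome
        assert est.n_positions == 10

    def test_two_chromosomes_pooled_and_sd(self):
        counts = [AlleleCounts("chr1", 1, 100, 95), AlleleCounts("chr2", 1, 100, 97)]
        est = estimate(counts)
        assert est.point_estimate == pytest.approx(0.04)
        assert est.sd == pytest.approx(statistics.stdev([0.05, 0.03]))
        assert est.sd == pytest.approx(0.014142135623730951)

    def test_all_species_alleles_gives_zero(self):
        est = estimate([AlleleCounts("chr1", 1, 50, 50), AlleleCounts("chr2", 1, 30, 30)])
        assert est.point_estimate == 0.0

    def test_no_coverage_errors(self):
        with pytest.raises(ValueError, match="no diagnostic positions observed"):
            estimate([])

    def test_pooled_equals_depth_weighted_mean(self):
        """Exact identity on random inputs, not just a numerical coincidence."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = []
            for k in range(1, rng.integers(2, 6)):
                for i in range(rng.integers(1, 30)):
                    total = int(rng.integers(1, 50))
                    counts.append(
                        AlleleCounts(f"chr{k}", i + 1, total, int(rng.integers(0, total + 1)))
                    )
            est = estimate(counts)
            weighted = sum(r.total_depth * r.estimate for r in est.per_chromosome) / sum(
                r.total_depth for r in est.per_chromosome
            )
            assert est.point_estimate == pytest.approx(weighted, abs=1e-12)

    @given(
        data=st.lists(
            st.tuples(
                st.integers(1, 4),          # chromosome index
                st.integers(1, 10**6),      # position
                st.integers(1, 100),        # total depth
                st.floats(0.0, 1.0),        # species-allele share
            ),
            min_size=1,
            max_size=50,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_estimate_invariants_hold_for_arbitrary_counts(self, data):
        """Bounds, sd definedness and the pooled identity on arbitrary counts."""
        counts = [
            AlleleCounts(f"chr{c}", p, t, min(t, int(round(f * t))))
            for c, p, t, f in data
        ]
        est = estimate(counts)
        assert 0.0 <= est.point_estimate <= 1.0
        assert all(0.0 <= r.estimate <= 1.0 for r in est.per_chromosome)
        assert est.n_positions == len(counts)
        assert (est.sd is None) == (len(est.per_chromosome) < 2)
        if est.sd is not None:
            assert est.sd >= 0.0
        total = sum(r.total_depth for r in est.per_chromosome)
        weighted = sum(r.total_depth * r.estimate for r in est.per_chromosome) / total
        assert est.point_estimate == pytest.approx(weighted, abs=1e-12)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(6)
        counts = [
            AlleleCounts(f"chr{rng.integers(1, 4)}", int(p), 10, int(rng.integers(0, 11)))
            for p in rng.choice(100_000, size=50, replace=False)
        ]
        forward = estimate(counts)
        backward = estimate(list(reversed(counts)))
        assert forward.point_estimate == backward.point_estimate
        assert forward.sd == backward.sd
        assert forward.per_chromosome == backward.per_chromosome


class TestMpileupText:
    def test_hand_written_column_syntax(self):
        # ^X starts, $ ends, +N/-N indels, * deletions must all be handled
        panel = [DiagnosticSite("chr1", 100, "A", "G")]
        line = "chr1\t100\tA\t8\t^].GgG+2ATg$*,\tIIIII!II\n"
        # symbols: . G g G(+2AT) g($) * ,  -> quals I I I I I ! I I
        # '*' is no base call; ',' and '.' are reference (A); '!' (qual 0) drops the g
        counts = parse_mpileup([line], panel)
        assert counts == [AlleleCounts("chr1", 100, 6, 4)]

    def test_reference_dots_never_count_as_species(self):
        panel = [DiagnosticSite("chr1", 10, "A", "G")]
        counts = parse_mpileup(["chr1\t10\tA\t4\t..,,\tIIII"], panel)
        assert counts == [AlleleCounts("chr1", 10, 4, 0)]
        est = estimate(counts)
        assert est.point_estimate == 1.0

    def test_lines_outside_panel_ignored(self):
        panel = [DiagnosticSite("chr1", 10, "A", "G")]
        lines = ["chr1\t9\tC\t2\tGG\tII", "chr1\t10\tA\t2\tGG\tII", "chr2\t10\tA\t2\tGG\tII"]
        assert parse_mpileup(lines, panel) == [AlleleCounts("chr1", 10, 2, 2)]

    def test_bam_and_mpileup_paths_identical(self, host_bam, expected_panel, tmp_path):
        """The two input paths must produce the same AlleleCounts on one BAM."""
        cfg = ReadFilterConfig()
        bam_counts = list(count_alleles(host_bam, expected_panel, cfg))
        bed = tmp_path / "sites.bed"
        with open(bed, "w") as fh:
            for s in expected_panel:
                fh.write(f"{s.chromosome}\t{s.position - 1}\t{s.position}\n")
        # -x: no overlap trimming, -B: no BAQ, -Q0: parser applies the base floor
        proc = subprocess.run(
            ["samtools", "mpileup", "-x", "-B", "-Q", "0", "-q", str(cfg.min_read_mq),
             "-d", "100000", "-l", str(bed), str(host_bam)],
            capture_output=True, text=True, check=True,
        )
        text_counts = parse_mpileup(
            proc.stdout.splitlines(), expected_panel, min_base_quality=cfg.min_base_quality
        )
        assert text_counts == bam_counts

    def test_mixture_paths_identical(self, host_bam, human_bam, expected_panel, tmp_path):
        from hucontest.mixer import MixtureSpec, mix

        mixed = tmp_path / "mixed.bam"
        mix(MixtureSpec(host_bam, human_bam, 0.10, seed=3), mixed)
        cfg = ReadFilterConfig()
        bam_counts = list(count_alleles(mixed, expected_panel, cfg))
        bed = tmp_path / "sites.bed"
        with open(bed, "w") as fh:
            for s in expected_panel:
                fh.write(f"{s.chromosome}\t{s.position - 1}\t{s.position}\n")
        proc = subprocess.run(
            ["samtools", "mpileup", "-x", "-B", "-Q", "0", "-q", str(cfg.min_read_mq),
             "-d", "100000", "-l", str(bed), str(mixed)],
            capture_output=True, text=True, check=True,
        )
        text_counts = parse_mpileup(proc.stdout.splitlines(), expected_panel)
        assert text_counts == bam_counts
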