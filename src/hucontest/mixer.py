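"""In-silico contamination: read mixing, gradients, crosstests, downsampling.

The validation machinery for the contamination test: merge a seeded subset
of contaminant reads into a host alignment so that a target fraction of
the mixture's base pairs is contaminant (base pairs, not read counts,
because read lengths differ between libraries), sweep a gradient of
fractions, estimate contamination in cross-clade samples, and downsample
alignments to very shallow depths.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` fan-out, so every operation is reproducible.
"""

from __future__ import annotations

import tempfile
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import DiagnosticSite
from .pileup import ContaminationEstimate, ReadFilterConfig, count_alleles, estimate

__all__ = [
    "MixtureSpec",
    "DownsampleSeries",
    "MixResult",
    "MixError",
    "mix",
    "gradient_experiment",
    "crosstest",
    "downsample",
    "downsample_series",
    "spawn_seeds",
]


class MixError(ValueError):
    """A mixture or downsampling recipe that cannot be realized."""


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan one top-level seed out into ``n`` independent child seeds."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class MixtureSpec:
    """Recipe for one in-silico contaminated alignment.

    ``target_fraction`` is the proportion of base pairs in the mixture that
    should come from the contaminant source. ``max_reads`` optionally caps
    the number of contaminant reads added.
    """

    host_source: str | Path
    contaminant_source: str | Path
    target_fraction: float
    seed: int
    max_reads: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DownsampleSeries:
    """Recipe for a downsampling experiment over one alignment."""

    source: str | Path
    target_read_counts: tuple[int, ...]
    replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if list(self.target_read_counts) != sorted(self.target_read_counts, reverse=True):
            raise ValueError("target_read_counts must be in descending order")


@dataclass(frozen=True)
class MixResult:
    path: Path
    realized_fraction: float
    host_reads: int
    contaminant_reads: int
    host_bp: int
    contaminant_bp: int


def _read_bp(read) -> int:
    return 0 if read.is_unmapped else read.query_alignment_length


def _load_fragments(path: str | Path, *, production_only: bool = False):
    """Read an alignment grouped into fragments (mate pairs stay together).

    With ``production_only``, keep only primary, mapped, non-duplicate reads
    ("production reads").
    """
    import pysam

    fragments: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if production_only and (
                read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate
            ):
                continue
            fragments.setdefault(read.query_name, []).append(read)
    return list(fragments.values())


def _write_sorted(reads, template_path: str | Path, out_path: str | Path) -> None:
    import pysam

    out_path = Path(out_path)
    tmp = out_path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(template_path), "rb") as template:
        header = template.header
        with pysam.AlignmentFile(str(tmp), "wb", header=header) as out:
            name_to_tid = {name: i for i, name in enumerate(header.references)}
            for read in reads:
                if read.reference_id >= 0:
                    contig = read.reference_name
                    tid = name_to_tid.get(contig)
                    if tid is None:
                        raise MixError(
                            f"contig {contig!r} absent from the host alignment header"
                        )
                    # remap tid into the output header's numbering
                    read.reference_id = tid
                    if read.next_reference_id >= 0:
                        read.next_reference_id = tid
                out.write(read)
    pysam.sort("--no-PG", "-o", str(out_path), str(tmp))
    tmp.unlink()
    pysam.index(str(out_path))


def mix(spec: MixtureSpec, out_path: str | Path) -> MixResult:
    """Create the contaminated alignment described by ``spec``.

    All host reads are kept; a seeded random subset of contaminant
    fragments (mate pairs together, sampled without replacement) is added
    until the contaminant base-pair share is as close to
    ``target_fraction`` as read granularity allows. The output is
    coordinate-sorted and indexed, and byte-identical across runs of the
    same spec. Raises :class:`MixError` when the contaminant source is too
    small to reach the target, stating the maximum achievable fraction.
    """
    rng = np.random.default_rng(spec.seed)
    host_fragments = _load_fragments(spec.host_source)
    host_reads = [r for frag in host_fragments for r in frag]
    host_bp = sum(_read_bp(r) for r in host_reads)

    chosen: list = []
    chosen_bp = 0
    if spec.target_fraction > 0:
        if spec.target_fraction >= 1.0 and host_bp > 0:
            raise MixError("target_fraction must be < 1 when the host has reads")
        contaminant_fragments = _load_fragments(spec.contaminant_source)
        frag_bp = np.array(
            [sum(_read_bp(r) for r in frag) for frag in contaminant_fragments], dtype=np.int64
        )
        target = spec.target_fraction
        needed = target / (1.0 - target) * host_bp
        available = int(frag_bp.sum())
        max_fraction = available / (host_bp + available) if host_bp + available else 0.0
        if available < needed and max_fraction < target - 1e-3:
            raise MixError(
                f"contaminant source too small: maximum achievable fraction is "
                f"{max_fraction:.6f} (target {target:.6f})"
            )
        order = rng.permutation(len(contaminant_fragments))
        n_reads = 0
        for idx in order.tolist():
            if chosen_bp >= needed:
                break
            frag = contaminant_fragments[idx]
            if spec.max_reads is not None and n_reads + len(frag) > spec.max_reads:
                break
            chosen.append(frag)
            chosen_bp += int(frag_bp[idx])
            n_reads += len(frag)
        # drop the last fragment if that lands closer to the target fraction
        if chosen:
            with_last = chosen_bp / (host_bp + chosen_bp)
            bp_wo = chosen_bp - sum(_read_bp(r) for r in chosen[-1])
            without_last = bp_wo / (host_bp + bp_wo) if host_bp + bp_wo else 0.0
            if abs(without_last - target) < abs(with_last - target):
                chosen.pop()
                chosen_bp = bp_wo

    contaminant_reads = [r for frag in chosen for r in frag]
    _write_sorted(host_reads + contaminant_reads, spec.host_source, out_path)
    total_bp = host_bp + chosen_bp
    realized = chosen_bp / total_bp if total_bp else 0.0
    return MixResult(
        Path(out_path), realized, len(host_reads), len(contaminant_reads), host_bp, chosen_bp
    )


def gradient_experiment(
    host: str | Path,
    contaminant: str | Path,
    fractions: Sequence[float],
    panel: Sequence[DiagnosticSite],
    filter_config: ReadFilterConfig | None = None,
    seed: int = 0,
    workdir: str | Path | None = None,
) -> pd.DataFrame:
    """One mix + estimate per nominal contamination fraction.

    Returns a table with columns nominal_fraction, realized_fraction,
    estimate, sd, n_positions. Fractions must be sorted ascending.
    """
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    filter_config = filter_config or ReadFilterConfig()
    seeds = spawn_seeds(seed, len(fractions))
    rows = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for frac, child_seed in zip(fractions, seeds):
            out = Path(tmp) / f"mix_{frac:.6f}.bam"
            result = mix(MixtureSpec(host, contaminant, frac, child_seed), out)
            est = estimate(count_alleles(out, panel, filter_config))
            total_depth = sum(r.total_depth for r in est.per_chromosome)
            rows.append(
                (frac, result.realized_fraction, est.point_estimate, est.sd,
                 est.n_positions, total_depth)
            )
    return pd.DataFrame(
        rows,
        columns=["nominal_fraction", "realized_fraction", "estimate", "sd", "n_positions",
                 "total_depth"],
    )


def crosstest(
    alignment: str | Path,
    panel: Sequence[DiagnosticSite],
    filter_config: ReadFilterConfig | None = None,
    *,
    reference: str | Path | None = None,
) -> ContaminationEstimate:
    """Run the contamination test on a sample against another clade's panel.

    On a sample from clade B tested against clade A's diagnostic sites, the
    expected estimate is the fraction of A-diagnostic sites at which B
    carries the human-like allele (shared ancestry), not true human
    contamination — large values flag a species mix-up.
    """
    return estimate(
        count_alleles(alignment, panel, filter_config or ReadFilterConfig(), reference=reference)
    )


def _select_fragments(fragments, n_reads: int, seed: int):
    """Seeded without-replacement fragment subset totalling ~``n_reads`` reads."""
    total_reads = sum(len(f) for f in fragments)
    if n_reads > total_reads:
        raise MixError(
            f"target of {n_reads} reads exceeds the {total_reads} production reads"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(fragments))
    chosen = []
    count = 0
    for idx in order.tolist():
        if count >= n_reads:
            break
        frag = fragments[idx]
        if count + len(frag) > n_reads and abs(count - n_reads) <= abs(
            count + len(frag) - n_reads
        ):
            continue
        chosen.append(frag)
        count += len(frag)
    return chosen, count


def downsample(
    source: str | Path, n_reads: int, seed: int, out_path: str | Path
) -> int:
    """Write a seeded random subset of ~``n_reads`` production reads.

    Production reads are primary, mapped, non-duplicate reads; other reads
    are dropped. Mate pairs are kept or dropped together, so the realized
    count can differ from the target by one read. Returns the realized read
    count. Raises :class:`MixError` when the target exceeds the source.
    """
    fragments = _load_fragments(source, production_only=True)
    chosen, count = _select_fragments(fragments, n_reads, seed)
    _write_sorted([r for frag in chosen for r in frag], source, out_path)
    return count


def downsample_series(
    series: DownsampleSeries,
    panel: Sequence[DiagnosticSite],
    filter_config: ReadFilterConfig | None = None,
    workdir: str | Path | None = None,
) -> pd.DataFrame:
    """Estimate contamination across seeded downsampling replicates.

    Returns a table with columns target_reads, replicate, n_reads,
    estimate, sd, n_positions — the robustness-at-shallow-depth experiment.
    """
    filter_config = filter_config or ReadFilterConfig()
    seeds = spawn_seeds(series.seed, len(series.target_read_counts) * series.replicates)
    fragments = _load_fragments(series.source, production_only=True)  # load source once
    rows = []
    i = 0
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for target in series.target_read_counts:
            for rep in range(series.replicates):
                out = Path(tmp) / f"ds_{target}_{rep}.bam"
                chosen, realized = _select_fragments(fragments, target, seeds[i])
                _write_sorted([r for frag in chosen for r in frag], series.source, out)
                i += 1
                est = estimate(count_alleles(out, panel, filter_config))
                total_depth = sum(r.total_depth for r in est.per_chromosome)
                rows.append(
                    (target, rep, realized, est.point_estimate, est.sd, est.n_positions,
                     total_depth)
                )
    return pd.DataFrame(
        rows,
        columns=["target_reads", "replicate", "n_reads", "estimate", "sd", "n_positions",
                 "total_depth"],
    )
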