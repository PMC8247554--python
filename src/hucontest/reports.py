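"""Report writers and run-configuration round-tripping.

Reports carry exactly the quantities the test is defined to emit: the
genome-wide point estimate, one standard deviation across chromosomes (or
a missing marker when fewer than two chromosomes have data), the number of
diagnostic positions observed, and the per-chromosome table. Numbers are
formatted to 6 significant digits and the output is byte-stable for a
fixed input.
"""

from __future__ import annotations

import json
from pathlib import Path

from .pileup import AlleleCounts, ChromosomeCounts, ContaminationEstimate

__all__ = [
    "format_number",
    "estimate_to_tsv",
    "estimate_to_json",
    "estimate_from_json",
    "write_report",
    "write_run_config",
    "read_run_config",
]

GENOME_ROW = "GENOME"
_TSV_HEADER = "chrom\tn_sites\ttotal_depth\tspecies_depth\testimate\tsd"


def format_number(x: float) -> str:
    """6 significant digits; fixed point for the magnitudes seen here."""
    return f"{x:.6g}"


def estimate_to_tsv(est: ContaminationEstimate) -> str:
    lines = [_TSV_HEADER]
    for row in est.per_chromosome:
        lines.append(
            f"{row.chromosome}\t{row.n_sites}\t{row.total_depth}\t{row.species_depth}"
            f"\t{format_number(row.estimate)}\tNA"
        )
    total = sum(r.total_depth for r in est.per_chromosome)
    species = sum(r.species_depth for r in est.per_chromosome)
    sd = "NA" if est.sd is None else format_number(est.sd)
    lines.append(
        f"{GENOME_ROW}\t{est.n_positions}\t{total}\t{species}"
        f"\t{format_number(est.point_estimate)}\t{sd}"
    )
    return "\n".join(lines) + "\n"


def estimate_to_json(est: ContaminationEstimate) -> str:
    payload = {
        "point_estimate": float(format_number(est.point_estimate)),
        "sd": None if est.sd is None else float(format_number(est.sd)),
        "n_positions": est.n_positions,
        "per_chromosome": [
            {
                "chromosome": r.chromosome,
                "n_sites": r.n_sites,
                "total_depth": r.total_depth,
                "species_depth": r.species_depth,
                "estimate": float(format_number(r.estimate)),
            }
            for r in est.per_chromosome
        ],
    }
    return json.dumps(payload, indent=2) + "\n"


def estimate_from_json(text: str) -> ContaminationEstimate:
    data = json.loads(text)
    rows = tuple(
        ChromosomeCounts(
            r["chromosome"], r["n_sites"], r["total_depth"], r["species_depth"], r["estimate"]
        )
        for r in data["per_chromosome"]
    )
    return ContaminationEstimate(
        data["point_estimate"], data["sd"], data["n_positions"], rows
    )


def write_report(
    est: ContaminationEstimate,
    path: str | Path,
    fmt: str = "tsv",
) -> None:
    """Write the estimate as TSV or JSON."""
    if fmt == "tsv":
        text = estimate_to_tsv(est)
    elif fmt == "json":
        text = estimate_to_json(est)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    Path(path).write_text(text)


def counts_to_tsv(counts: list[AlleleCounts]) -> str:
    lines = ["chrom\tpos\ttotal_depth\tspecies_depth"]
    for c in counts:
        lines.append(f"{c.chromosome}\t{c.position}\t{c.total_depth}\t{c.species_allele_depth}")
    return "\n".join(lines) + "\n"


def write_run_config(config: dict, path: str | Path) -> None:
    """Persist a resolved run configuration (round-trips via JSON text)."""
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")


def read_run_config(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
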