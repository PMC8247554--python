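"""Session-wide synthetic fixtures shared across the test modules.

Everything is generated programmatically from fixed seeds; nothing is
downloaded or stored in the repository.
"""

from __future__ import annotations

import pytest

from hucontest.fixtures import (
    CladeModel,
    ReadModel,
    human_haplotypes,
    make_cohort_vcf,
    make_reads,
    make_reference,
    species_haplotypes,
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("hucontest-fixtures")


@pytest.fixture(scope="session")
def reference():
    return make_reference(CladeModel(seed=11))


@pytest.fixture(scope="session")
def cohort(reference, fixture_dir):
    return make_cohort_vcf(reference, fixture_dir / "cohort", seed=12)


@pytest.fixture(scope="session")
def expected_panel(cohort):
    return cohort.expected_panel


@pytest.fixture(scope="session")
def host_bam(reference, fixture_dir):
    path = fixture_dir / "host.bam"
    make_reads(species_haplotypes(reference), ReadModel(mean_depth=20.0, seed=21), path,
               name_prefix="host")
    return path


@pytest.fixture(scope="session")
def human_bam(reference, fixture_dir):
    path = fixture_dir / "human.bam"
    make_reads(human_haplotypes(reference), ReadModel(mean_depth=16.0, seed=22), path,
               name_prefix="human")
    return path


@pytest.fixture(scope="session")
def deep_host_bam(reference, fixture_dir):
    """Deeper host library for downsampling experiments (>100k reads)."""
    path = fixture_dir / "host_deep.bam"
    make_reads(species_haplotypes(reference), ReadModel(mean_depth=35.0, seed=23), path,
               name_prefix="hostdeep")
    return path
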