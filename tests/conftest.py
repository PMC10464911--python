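"""Shared fixtures: small synthetic genomes generated once per session."""

import pytest

from trbannot.pipeline import annotate_genome
from trbannot.synth import (
    MUTATION_OPS,
    LocusSpec,
    SynthConfig,
    default_config,
    generate_locus_genome,
)


def small_config(seed: int = 1) -> SynthConfig:
    return SynthConfig(
        seed=seed,
        loci=[LocusSpec({"1": 3, "2": 2}, n_j=4, orientation="+")],
        head_to_head=False,
    )


def panel_config(seed: int) -> SynthConfig:
    """One V gene per mutation operation, in a single small locus."""
    muts = {i: op for i, op in enumerate(MUTATION_OPS)}
    return SynthConfig(
        seed=seed,
        loci=[LocusSpec({"1": len(MUTATION_OPS)}, n_j=3, orientation="+", v_mutations=muts)],
        head_to_head=False,
    )


@pytest.fixture(scope="session")
def small_truth():
    return generate_locus_genome(small_config())


@pytest.fixture(scope="session")
def small_result(small_truth):
    return annotate_genome(small_truth.genome, small_truth.reference_library())


@pytest.fixture(scope="session")
def full_truth():
    """The trout-like two-contig default genome (head-to-head + remnant)."""
    return generate_locus_genome(default_config(seed=1))


@pytest.fixture(scope="session")
def full_result(full_truth):
    return annotate_genome(full_truth.genome, full_truth.reference_library())
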