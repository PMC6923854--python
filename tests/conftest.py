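"""Shared fixtures: seeded synthetic genomes and their alignments."""

import pytest

from clonalpair import (
    AncestorParams,
    DivergenceParams,
    VariantRecord,
    align_genomes,
    call_variants,
    generate_ancestor,
    simulate_divergence,
)


@pytest.fixture(scope="session")
def ancestor_100k():
    return generate_ancestor(AncestorParams(replicon_lengths=[100_000], seed=1))


@pytest.fixture(scope="session")
def pair_100k(ancestor_100k):
    derived, truth = simulate_divergence(ancestor_100k, DivergenceParams(seed=2))
    return ancestor_100k, derived, truth


@pytest.fixture(scope="session")
def aligned_100k(pair_100k):
    anc, div, truth = pair_100k
    pa = align_genomes(anc, div)
    vs = call_variants(pa, anc.sequences, div.sequences)
    return pa, vs


@pytest.fixture(scope="session")
def pair_200k():
    anc = generate_ancestor(AncestorParams(replicon_lengths=[200_000], seed=11))
    derived, truth = simulate_divergence(anc, DivergenceParams(seed=12))
    return anc, derived, truth


def truth_variants(truth, replicon="chromosome"):
    """Truth SNPs as variant records (for truth-based profiling)."""
    return [
        VariantRecord(s.replicon, s.replicon, s.position, s.position, "snp", s.ref, s.alt, 1)
        for s in truth.snps
        if s.replicon == replicon
    ]
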