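"""Shared fixtures: small synthetic plastomes with known ground truth."""

import pytest

from plastokit.simulate import (
    EvolutionSpec,
    PlantedRepeat,
    PlantedSSR,
    PlastomeSpec,
    generate_plastome,
    evolve_genomes,
)


@pytest.fixture(scope="session")
def small_spec():
    return PlastomeSpec(
        lsc_len=20_000,
        ir_len=6_000,
        ssc_len=4_000,
        n_genes=12,
        ssrs=[
            PlantedSSR("AT", 6, "LSC"),
            PlantedSSR("A", 12, "SSC"),
            PlantedSSR("AAG", 5, "LSC"),
        ],
        repeats=[
            PlantedRepeat(40, "F", 0),
            PlantedRepeat(35, "P", 2),
            PlantedRepeat(32, "R", 0),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_plastome(small_spec):
    return generate_plastome(small_spec)


@pytest.fixture(scope="session")
def evolved_pair(small_plastome):
    """Two leaf genomes diverged from the small synthetic ancestor, with
    non-coding loci evolving faster than coding ones."""
    ancestor, truth = small_plastome
    evo = EvolutionSpec(
        tree="(left:0.02,right:0.02);",
        coding_rate=0.3,
        noncoding_rate=1.5,
        ir_rate_factor=0.3,
        indel_rate=0.002,
        seed=5,
    )
    genomes, out_truth = evolve_genomes(ancestor, truth, evo)
    return genomes, out_truth
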