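"""Shared fixtures: one default synthetic dataset reused across tests.

The heavy objects (genome, truth peaks, called peak sets) are
session-scoped; the seed is fixed once for the whole suite.
"""

import pytest

from fairedyn.peakcall import (
    PeakCallParams,
    call_peaks,
    filter_to_assembly,
    merge_fragment_sets,
)
from fairedyn.simulate import (
    CONDITIONS,
    DECOY_CONDITIONS,
    SimulationConfig,
    ap1_like_motif,
    plant_motif_instances,
    plant_truth_peaks,
    simulate_fragments,
    simulate_genome,
)

SUITE_SEED = 0


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def genome(sim_config):
    return simulate_genome(sim_config)


@pytest.fixture(scope="session")
def truth(genome, sim_config):
    return plant_truth_peaks(genome, sim_config)


@pytest.fixture(scope="session")
def planted_genome(genome, truth, sim_config):
    """Genome with the AP-1-like consensus written into barrier-deficient
    peaks (mutates truth motif_planted flags in place)."""
    motif = ap1_like_motif()
    assembly, log = plant_motif_instances(genome, truth, motif, sim_config)
    return assembly, motif, log


@pytest.fixture(scope="session")
def called_peak_sets(genome, truth, sim_config):
    """Merged-replicate, assembly-filtered peak calls for all 8 samples."""
    params = PeakCallParams()
    sets = {}
    for sample in CONDITIONS + DECOY_CONDITIONS:
        reps = [
            simulate_fragments(genome, truth, sample, sim_config, replicate=r)
            for r in range(2)
        ]
        merged = merge_fragment_sets(reps)
        if merged.source_tags is not None:
            merged = filter_to_assembly(merged, "human")
        sets[sample] = call_peaks(merged, genome.chrom_sizes, params, assembly=genome)
    return sets
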