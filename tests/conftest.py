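import numpy as np
import pytest

from phasikit import phas
from phasikit.core_align import Reference, build_index, map_tags
from phasikit.preprocess import collapse_unique
from phasikit.synthetic import (
    LibraryPlan,
    PhasPlan,
    SimulationConfig,
    make_genome,
    simulate_srna_library,
)

_BASES = np.array(list("ACGT"))


def random_sequence(rng, length):
    return "".join(rng.choice(_BASES, length))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_genome(rng):
    return Reference("toy", {"Chr1": random_sequence(rng, 2000)})


def detect_phas(config: SimulationConfig, phase_length: int = 21,
                score_threshold: float = 5.0):
    """Simulate all configured libraries and run the full PHAS detector."""
    genome, truth = make_genome(config)
    reads = []
    for plan in config.library_plan:
        for rec in simulate_srna_library(genome, truth, plan, config):
            reads.append((plan.library_id, rec.splitlines()[1]))
    tags = collapse_unique(reads)
    p_tags = [t for t in tags if len(t.sequence) == phase_length]
    idx = build_index(genome)
    alignments = map_tags(p_tags, idx, 0) if p_tags else []
    counts = {t.sequence: t.total for t in p_tags}
    track = phas.scan(alignments, genome, phase_length, counts=counts)
    regions = phas.merge_and_correct(track)
    loci = phas.call_loci(track, regions, score_threshold=score_threshold)
    return genome, truth, track, loci
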