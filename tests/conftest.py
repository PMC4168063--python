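import numpy as np
import pytest

from tirkit.io import copies_to_frame
from tirkit.pipeline import annotate_genome
from tirkit.simulate import (
    DegradationSpec,
    SyntheticGenomeSpec,
    default_decoy_library,
    default_element_template,
    default_templates,
    simulate_genome,
)


@pytest.fixture(scope="session")
def template():
    return default_element_template()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def decoys():
    return default_decoy_library()


@pytest.fixture(scope="session")
def small_sim(decoys):
    """A 600-kb genome with 18 planted copies at 3% substitution degradation."""
    spec = SyntheticGenomeSpec(
        n_copies=18, seed=5, contig_lengths=(600_000,),
        degradation=DegradationSpec(substitution_rate=0.03),
        decoy_library=decoys,
    )
    contigs, truth = simulate_genome(spec)
    return contigs, truth


@pytest.fixture(scope="session")
def annotated(small_sim, decoys):
    contigs, truth = small_sim
    result = annotate_genome(contigs, te_library=decoys)
    return contigs, truth, result


def match_truth(truth, copies_frame):
    """Pair each planted copy with the annotated copies overlapping it."""
    out = []
    for _, t in truth.iterrows():
        m = copies_frame[(copies_frame.start - 1 < t.end) & (copies_frame.end > t.start)]
        out.append((t, m))
    return out


@pytest.fixture(scope="session")
def matched(annotated):
    contigs, truth, result = annotated
    return match_truth(truth, copies_to_frame(result.copies))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
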