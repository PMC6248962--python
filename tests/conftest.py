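import numpy as np
import pytest
from hypothesis import settings

from dompop import MarkerMatrix, paper_like_preset, simulate

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_matrix(bands, pops=None, primers=None):
    """Build a MarkerMatrix from a plain array with auto-generated labels."""
    bands = np.asarray(bands, dtype=float)
    n, L = bands.shape
    if pops is None:
        pops = ["P1"] * n
    locus_ids = [f"L{j + 1}" for j in range(L)]
    if primers is None:
        primer_of_locus = {l: "PR1" for l in locus_ids}
    else:
        primer_of_locus = dict(zip(locus_ids, primers))
    return MarkerMatrix(
        sample_ids=[f"S{i + 1}" for i in range(n)],
        pop_labels=list(pops),
        locus_ids=locus_ids,
        primer_of_locus=primer_of_locus,
        bands=bands,
    )


@pytest.fixture
def tiny_two_pop():
    """4 samples, 2 loci, 2 populations — the hand-worked AMOVA example."""
    return make_matrix(
        [[1, 0], [1, 1], [0, 0], [0, 1]],
        pops=["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def preset_dataset():
    """One draw of the 108 x 195 six-population preset (seed fixed)."""
    return simulate(paper_like_preset(seed=1))
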