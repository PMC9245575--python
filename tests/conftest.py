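import numpy as np
import pytest
import scipy.sparse as sp

from tastools.counting import BarcodeGeometry, BarcodeSection
from tastools.io import CountMatrix


def make_whitelist(rng, n, length, min_distance):
    """Random whitelist with guaranteed pairwise Hamming separation."""
    wl = []
    while len(wl) < n:
        cand = "".join(rng.choice(list("ACGT"), length))
        if all(sum(a != b for a, b in zip(cand, w)) >= min_distance
               for w in wl):
            wl.append(cand)
    return wl


def make_geometry(seed=7, n_per_section=12, section_length=9,
                  min_distance=3, with_umi=True):
    """Three-section bead-style geometry with spacer gaps and an UMI."""
    rng = np.random.default_rng(seed)
    offsets = [0, 21, 43]
    sections = [BarcodeSection(off, section_length,
                               frozenset(make_whitelist(
                                   rng, n_per_section, section_length,
                                   min_distance)))
                for off in offsets]
    return BarcodeGeometry(sections,
                           umi_offset=52 if with_umi else None,
                           umi_length=8)


@pytest.fixture
def geometry():
    return make_geometry()


@pytest.fixture
def separated_geometry():
    # pairwise Hamming >= 5: a double substitution can never reach
    # within distance 1 of another whitelist entry
    return make_geometry(seed=11, min_distance=5)


@pytest.fixture
def toy_matrix():
    counts = np.array([[3, 0, 1],
                       [0, 1, 0],
                       [2, 2, 2]])
    return CountMatrix(["gA", "gB", "gC"], ["b1", "b2", "b3"],
                       sp.csr_matrix(counts))


def random_count_matrix(rng, n_genes, n_cells, density=0.3, max_count=50):
    m = sp.random(n_genes, n_cells, density=density, random_state=rng,
                  data_rvs=lambda k: rng.integers(1, max_count, k))
    return CountMatrix([f"g{i:04d}" for i in range(n_genes)],
                       [f"c{j:04d}" for j in range(n_cells)],
                       m.tocsr().astype(np.int64))
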