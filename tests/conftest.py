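import numpy as np
import pytest

from radkin.containers import GenotypeMatrix, LocusPanel


@pytest.fixture
def single_locus_panel():
    def make(p):
        return LocusPanel(
            np.array(["L1"], dtype=object),
            np.array(["s1"], dtype=object),
            np.array([1]),
            np.array([p]),
        )

    return make


@pytest.fixture
def small_gm():
    """5 individuals x 4 loci with all channels, hand-constructed."""
    panel = LocusPanel(
        np.array(["L1", "L2", "L3", "L4"], dtype=object),
        np.array(["s1", "s1", "s2", "s2"], dtype=object),
        np.array([100, 2_000_200, 100, 5_000_000]),
        np.array([0.5, 0.2, 0.1, 0.4]),
    )
    g = np.array(
        [
            [0, 1, 2, -1],
            [1, 1, 0, 0],
            [2, 0, 1, 1],
            [0, -1, 1, 2],
            [1, 2, 0, 0],
        ],
        dtype=np.int8,
    )
    depth = np.where(g >= 0, 20, 0).astype(np.int32)
    ref = np.where(g == 0, 20, np.where(g == 1, 10, 0)).astype(np.int32)
    ref[g == -1] = 0
    ad = np.stack([ref, depth - ref], axis=2)
    gq = np.where(g >= 0, 60, 0).astype(np.int16)
    samples = np.array([f"i{k}" for k in range(5)], dtype=object)
    return GenotypeMatrix(samples, panel, g, gq=gq, depth=depth, allele_depths=ad)
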