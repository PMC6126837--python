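import numpy as np
import pytest

from nucnet.io import AnchorAnnotation, NucleosomeCall
from nucnet.pairs import IndexedNucleosome, NucleosomePair
from nucnet.simulate import LandscapeConfig, simulate_landscape


def make_call(chrom, summit, width=80.0, klass="MainPeak", half=73, occupancy=5.0):
    return NucleosomeCall(
        chrom=chrom, start=summit - half, end=summit + half + 1,
        summit=summit, width_bp=width, peak_class=klass, occupancy=occupancy,
    )


def make_pair(anchor_id, before_summit, after_summit, chrom="chr1",
              before_slot=1, after_slot=2, side="downstream"):
    before = IndexedNucleosome(
        anchor_id, before_slot, side, make_call(chrom, before_summit)
    )
    after = IndexedNucleosome(
        anchor_id, after_slot, side, make_call(chrom, after_summit)
    )
    return NucleosomePair(anchor_id, before, after, side, "neither")


@pytest.fixture(scope="session")
def small_landscape():
    """30 TSS anchors with tight phasing; shared across read-only tests."""
    cfg = LandscapeConfig(n_anchors=30, seed=11)
    return simulate_landscape(cfg)


@pytest.fixture
def tss_anchor():
    return AnchorAnnotation("g1_TSS", "chr1", "TSS", 10_000, "+")


def rng(seed=0):
    return np.random.default_rng(seed)
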