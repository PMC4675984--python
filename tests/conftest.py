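import numpy as np
import pytest

from bruuv.annotations_io import BinnedTrack, GeneModel, GeneSet, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20151211)


@pytest.fixture
def simple_geneset():
    """Three plus/minus genes on one chromosome."""
    genes = [
        GeneModel("alpha", GenomicInterval("chr1", 10_000, 80_000, "+"), 10_000),
        GeneModel("beta", GenomicInterval("chr1", 150_000, 220_000, "-"), 219_999),
        GeneModel("gamma", GenomicInterval("chr1", 300_000, 310_000, "+"), 300_000),
    ]
    return GeneSet(genes)


def make_track(values, bin_width=250, total=None, chrom="chr1"):
    v = np.asarray(values, dtype=float)
    return BinnedTrack(bin_width, {chrom: v}, float(v.sum()) if total is None else total)


@pytest.fixture
def make_track_fn():
    return make_track
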