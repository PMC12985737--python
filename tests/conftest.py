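import pytest

from xomap import synthetic
from xomap.landscape import HotspotAnnotation
from xomap.xo_mapper import CallStatus, CrossoverCall, Orientation


@pytest.fixture(scope="session")
def snp_map():
    """Uniform 101-marker map over a 40-kb interval (the study scale)."""
    return synthetic.make_snp_map(40_000, 101, rng_seed=0)


@pytest.fixture(scope="session")
def mixture_model(snp_map):
    """Three-hotspot mixture with marker-snapped spans."""
    return synthetic.chp_like_model(snp_map)


@pytest.fixture(scope="session")
def hotspot_annotations(mixture_model):
    return [
        HotspotAnnotation(c.name, c.start, c.end) for c in mixture_model.components
    ]


def make_ok_call(midpoint, rid="r", chrom="chrSim", halfwidth=1):
    """Minimal OK crossover call centred on a given midpoint."""
    return CrossoverCall(
        recombinant_id=rid,
        status=CallStatus.OK,
        chrom=chrom,
        left_pos=midpoint - halfwidth,
        right_pos=midpoint + halfwidth,
        left_id="l",
        right_id="r",
        midpoint=midpoint,
        orientation=Orientation.LER_TO_HET,
    )
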