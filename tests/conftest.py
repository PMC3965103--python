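import pytest

from mirhc.core import Thresholds
from mirhc.simulate import LocusSpec, make_bundle, make_hairpin


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def ideal_bundle():
    """A clean canonical locus: deep homogeneous reads, 2-nt overhangs."""
    return make_bundle(LocusSpec(seed=7))


@pytest.fixture
def perfect_stem():
    """Perfect 30-bp stem hairpin with its annotated mature pair."""
    return make_hairpin(LocusSpec(seed=11))
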