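import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def tiny_catalog():
    """Six proteins, two keywords, hand-countable memberships.

    Keyword 'ves': carried by positives p1, p2 and negative n1.
    Keyword 'nuc': carried by negative n2, n3.
    """
    from granulekit.confidence import AnnotationCatalog, LabelledSet

    loc = {
        "p1": frozenset({"ves"}),
        "p2": frozenset({"ves"}),
        "p3": frozenset(),
        "n1": frozenset({"ves"}),
        "n2": frozenset({"nuc"}),
        "n3": frozenset({"nuc"}),
    }
    intloc = {
        "p1": ("ves", "ves"),
        "p2": ("ves",),
        "p3": (),
        "n1": (),
        "n2": ("nuc",),
        "n3": (),
    }
    proteomes = {
        "p1": frozenset({"P1", "P2", "P3"}),
        "p2": frozenset({"P1", "P2"}),
        "p3": frozenset({"P1"}),
        "n1": frozenset({"P2"}),
        "n2": frozenset({"P1"}),
        "n3": frozenset({"P3"}),
    }
    catalog = AnnotationCatalog(loc=loc, intloc=intloc, proteomes=proteomes)
    labels = LabelledSet(frozenset({"p1", "p2", "p3"}), frozenset({"n1", "n2", "n3"}))
    return catalog, labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
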