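import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ventmix import ConsumerObservation, IsotopeSummary, SourcePool, TDFSet


def make_pool(name, c_mean, c_sd, n_mean, n_sd, n=2):
    return SourcePool(
        name,
        summaries={
            "C13": IsotopeSummary("C13", c_mean, c_sd, n),
            "N15": IsotopeSummary("N15", n_mean, n_sd, n),
        },
    )


def make_tdf(guild="guild", c=0.0, n=0.0, c_sd=0.0, n_sd=0.0):
    return TDFSet(guild=guild, means={"C13": c, "N15": n}, sds={"C13": c_sd, "N15": n_sd})


def make_consumer(d13c, d15n, guild="guild", cid="c1"):
    return ConsumerObservation(id=cid, taxon="taxon", guild=guild, d13c=d13c, d15n=d15n)


@pytest.fixture
def two_source_problem():
    """A fixed, well-conditioned two-source problem used across tests."""
    from ventmix import MixingProblem

    s1 = make_pool("alpha", -15.0, 0.8, 4.0, 0.9)
    s2 = make_pool("beta", -22.0, 0.6, -1.0, 0.7)
    tdf = make_tdf(c=0.5, n=2.0, c_sd=0.5, n_sd=0.5)
    cons = make_consumer(-18.0, 2.5)
    return MixingProblem(sources=[s1, s2], tdf=tdf, consumers=[cons])


@pytest.fixture
def three_source_problem():
    from ventmix import MixingProblem

    s1 = make_pool("alpha", -15.0, 0.8, 4.0, 0.9)
    s2 = make_pool("beta", -22.0, 0.6, -1.0, 0.7)
    s3 = make_pool("gamma", -19.0, 0.5, 7.0, 0.8)
    tdf = make_tdf(c=0.5, n=2.0, c_sd=0.5, n_sd=0.5)
    cons = make_consumer(-18.5, 3.5)
    return MixingProblem(sources=[s1, s2, s3], tdf=tdf, consumers=[cons])
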