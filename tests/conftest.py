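import numpy as np
import pytest

from oligoforge import design as dm
from oligoforge import testkit


@pytest.fixture(scope="session")
def ecoli_table():
    return testkit.ecoli_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_job():
    """A small synthetic job that optimizes in well under a second."""
    return testkit.synthetic_job(
        3, length=45, skew=0.6, variant_specs=("10:NNK",), iterations=200
    )


def make_design(dna_codons, boundaries, five_prime="", three_prime="",
                specs=(), active=None):
    """Hand-build a GeneDesign from explicit codons and boundaries."""
    design = dm.GeneDesign(
        codons=list(dna_codons),
        variant_active=list(active) if active is not None
        else [True] * len(specs),
        boundaries=list(boundaries),
        five_prime=five_prime,
        three_prime=three_prime,
        specs=tuple(specs),
    )
    dm.build_dna(design)
    return design
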