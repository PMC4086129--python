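"""Fixtures and synthetic-input generators: every job is testable offline.

All generators are pure functions of their parameters and the supplied RNG.
The packaged EGFP fixture uses GFP numbering (238 residues, no Val2), so the
classic chromophore and surface tyrosines sit at positions 66 and 145.  The
5'/3' cloning sequences are *synthetic* 20-base placeholders (an RBS-like 5'
leader and a double-stop 3' tail), not sequences from any real construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import codons as cm
from . import design as dm
from . import io as oio

#: Synthetic placeholder cloning sequences (20 bases each).
SYNTHETIC_FIVE_PRIME = "CTTTAAGAAGGAGATATACC"
SYNTHETIC_THREE_PRIME = "TAATGAGGATCCGAATTCGA"

EGFP_VARIANT_SPECS = ("66:YAT", "145:TWT")


def _data_text(name: str) -> str:
    return (resources.files("oligoforge") / "data" / name).read_text()


def egfp_protein() -> str:
    """The packaged 238-residue EGFP amino-acid sequence (GFP numbering)."""
    return oio.read_protein(_data_text("egfp.fasta"))


def ecoli_table() -> cm.CodonUsageTable:
    """The packaged E. coli K-12 codon-usage table."""
    return oio.parse_codon_usage(
        _data_text("ecoli_k12_usage.tsv"), organism="Escherichia coli K-12"
    )


@dataclass(frozen=True)
class EgfpFixture:
    protein: str
    five_prime: str
    three_prime: str
    specs: tuple[dm.VariantCodonSpec, ...]
    target_tm: float
    max_oligo_length: int
    table: cm.CodonUsageTable


def egfp_fixture() -> EgfpFixture:
    """The EGFP variant-library design job: YAT@66 + TWT@145, Tm 60, max 60."""
    protein = egfp_protein()
    return EgfpFixture(
        protein=protein,
        five_prime=SYNTHETIC_FIVE_PRIME,
        three_prime=SYNTHETIC_THREE_PRIME,
        specs=oio.parse_variant_specs(EGFP_VARIANT_SPECS, protein),
        target_tm=60.0,
        max_oligo_length=60,
        table=ecoli_table(),
    )


def egfp_design_input(seed: int = 1, **overrides) -> dm.DesignInput:
    """A ready-to-run DesignInput for the EGFP job (defaults everywhere)."""
    fixture = egfp_fixture()
    params = dict(
        protein=fixture.protein,
        target_tm=fixture.target_tm,
        table=fixture.table,
        five_prime=fixture.five_prime,
        three_prime=fixture.three_prime,
        variants=fixture.specs,
        max_oligo_length=fixture.max_oligo_length,
        seed=seed,
        name="egfp",
    )
    params.update(overrides)
    inp = dm.DesignInput(**params)
    inp.validate()
    return inp


def random_protein(
    length: int, rng: np.random.Generator, composition: dict[str, float] | None = None
) -> str:
    """I.i.d. amino-acid draws; default composition is uniform over the 20."""
    if length < 1:
        raise ValueError("length must be >= 1")
    letters = cm.AMINO_ACIDS if composition is None else tuple(composition)
    if composition is None:
        probabilities = None
    else:
        weights = np.array([composition[aa] for aa in letters], dtype=float)
        probabilities = weights / weights.sum()
    draws = rng.choice(len(letters), size=length, p=probabilities)
    return "".join(letters[i] for i in draws)


def toy_codon_table(
    skew: float, rng: np.random.Generator, organism: str = "toy"
) -> cm.CodonUsageTable:
    """Synthetic usage table: one favoured codon per family, weight 1, the
    rest weight ``1 - skew``.

    ``skew=1`` makes back-translation deterministic (and CAI of any
    back-translation 1); ``skew=0`` makes every synonymous codon maximal.
    The favoured codon of each family is drawn from the RNG.
    """
    if not 0.0 <= skew <= 1.0:
        raise ValueError("skew must be in [0, 1]")
    freqs: dict[str, float] = {}
    for aa, family in cm.SYNONYMS.items():
        if aa == cm.STOP:
            for codon in family:
                freqs[codon] = 1.0
            continue
        favoured = int(rng.integers(0, len(family)))
        for i, codon in enumerate(family):
            freqs[codon] = 1.0 if i == favoured else (1.0 - skew)
    return cm.CodonUsageTable.from_frequencies(freqs, organism)


def job_with_positive_initial_scores(seed: int, length: int = 100,
                                     skew: float = 0.85) -> dm.DesignInput:
    """A synthetic job whose four initial objective scores are all positive.

    The random protein carries a duplicated deterministic MWMW motif (Met
    and Trp have single codons, so both copies back-translate to the same
    12-base sequence: an exact direct repeat whose Tm falls inside the
    misanneal retention band) and a block of consecutive NNK variant codons
    wider than any stretch an oligo junction can avoid, so at least one
    variant codon necessarily starts inside an overlap.  Candidate seeds
    are searched until every initial objective is strictly positive.
    """
    from . import anneal  # deferred: anneal is heavy relative to generators

    rng = np.random.default_rng(seed)
    for _ in range(100):
        sub = int(rng.integers(2**31))
        srng = np.random.default_rng(sub)
        aa = random_protein(length, srng)
        protein = aa[:20] + "MWMW" + aa[24:60] + "MWMW" + aa[64:]
        table = toy_codon_table(skew, srng)
        specs = oio.parse_variant_specs(
            [f"{pos}:NNK" for pos in range(68, 86)], protein
        )
        inp = dm.DesignInput(
            protein=protein,
            target_tm=60.0,
            table=table,
            variants=specs,
            seed=sub,
            name=f"allpos{sub}",
        )
        inp.validate()
        _, init, _, _ = anneal.initialize(inp, np.random.default_rng(sub))
        if init.cai > 0 and init.tm > 0 and init.mis > 0 and init.fixed > 0:
            return inp
    raise RuntimeError("no job with all-positive initial scores found")


def calibration_acceptance_rate(
    inp: dm.DesignInput, proposals: int = 2000
) -> tuple[float, float]:
    """Measured acceptance rate of worse neighbours at the calibrated T0.

    Initializes the job, calibrates the starting annealing temperature,
    then draws ``proposals`` fresh neighbours of the initial solution and
    simulates the acceptance rule for those scoring worse.  Returns
    ``(acceptance_fraction, t0)``.
    """
    import math

    from . import anneal, scoring

    rng = np.random.default_rng(inp.seed)
    design, init, scores, ctx = anneal.initialize(inp, rng)
    t0 = anneal.calibrate_initial_temperature(
        design, scores.composite, init, inp, ctx, rng
    )
    worse = accepted = 0
    for _ in range(proposals):
        neighbour = anneal.mutate(design, inp, rng)
        nb_scores, _, _ = scoring.score_design(neighbour, ctx)
        delta = (
            scoring.composite_score(nb_scores, init, ctx.include_fixed)
            - scores.composite
        )
        if delta > 0:
            worse += 1
            if rng.random() < math.exp(-delta / t0):
                accepted += 1
    if worse == 0:
        raise RuntimeError("no worse neighbours sampled")
    return accepted / worse, t0


def synthetic_job(
    seed: int,
    length: int = 100,
    skew: float = 0.7,
    variant_specs: tuple[str, ...] = ("1:NNK",),
    target_tm: float = 60.0,
    **overrides,
) -> dm.DesignInput:
    """A fully synthetic design job, determined by ``seed`` and parameters."""
    rng = np.random.default_rng(seed)
    protein = random_protein(length, rng)
    table = toy_codon_table(skew, rng)
    specs = oio.parse_variant_specs(variant_specs, protein) if variant_specs else ()
    params = dict(
        protein=protein,
        target_tm=target_tm,
        table=table,
        variants=specs,
        seed=seed,
        name=f"synthetic{seed}",
    )
    params.update(overrides)
    inp = dm.DesignInput(**params)
    inp.validate()
    return inp
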