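"""Simulated-annealing optimization of an oligo design.

The loop minimizes the initial-score-normalized composite of four
objectives (CAI, overlap-Tm homogeneity, misanneal separation, variant-codon
viability).  The annealing temperature is geometrically cooled from a value
T0 at which roughly 10 % of worse neighbour solutions are accepted down to a
floor of 1e-6 T0; a worse neighbour with score excess d is accepted with
probability exp(-d / T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import codons as cm
from . import design as dm
from . import scoring
from .thermo import tm_from_counts


class InitializationError(RuntimeError):
    """Raised when no acceptable initial solution can be generated."""


#: Initial oligos are seeded this many bases short of the maximum length,
#: leaving room for boundary mutations to both grow and shrink them.
SEED_SHORTFALL = 5

#: Proposal sample size used to calibrate the initial temperature.  With a
#: few hundred samples the T0 estimate is noisy enough that the realized
#: worse-neighbour acceptance ranges ~7-14 % instead of ~10 %; 1000 samples
#: tighten it to ~10 +- 1 percentage point at negligible cost relative to
#: the annealing run itself.
CALIBRATION_SAMPLES = 1000

#: Target fraction of worse neighbours accepted at the initial temperature.
CALIBRATION_ACCEPTANCE = 0.10

#: Geometric cooling floor, as a fraction of T0.
TEMPERATURE_FLOOR = 1.0e-6

_BACKTRANSLATION_ATTEMPTS = 1000


@dataclass
class ProgressRecord:
    iteration: int
    temperature: float
    cai_s: float
    tm_s: float
    mis_s: float
    fixed_s: int
    composite: float
    best_composite: float


@dataclass
class DesignResult:
    """Everything the reporting layer needs about the best design found."""

    input: dm.DesignInput
    best: dm.GeneDesign
    best_scores: scoring.ObjectiveScores
    initial_scores: scoring.InitialScores
    initial_design: dm.GeneDesign
    oligos: list[dm.Oligo]
    overlaps: list[dm.Overlap]
    mean_overlap_tm: float
    misanneals: scoring.MisannealReport
    variant_viable: list[bool]
    cai: float
    initial_temperature: float | None
    iterations_run: int
    progress: list[ProgressRecord] = field(default_factory=list)


#: How far an oligo end may be pulled back from its seeded position during
#: initial placement to route a junction around a variant codon.
_PLACEMENT_SLACK = 12


def place_overlaps(dna: str, inp: dm.DesignInput,
                   salt_term: float) -> list[tuple[int, int]]:
    """Greedy left-to-right oligo placement on a (pure-base) construct.

    Oligos are seeded at ``max_oligo_length - 5``.  At each junction the
    overlap grows one base at a time from the minimum overlap length and the
    length whose Tm is closest to the target is kept.  Junction candidates
    that would cover a variant codon are avoided whenever a variant-free
    candidate exists within a few bases of slack on the oligo end: boundary
    mutations move endpoints only +-10 bp later, which cannot cheaply carry
    an overlap across a variant once the Tm profile has been homogenized.
    The first and last oligos are anchored at the construct ends.
    """
    length = len(dna)
    seed_len = inp.max_oligo_length - SEED_SHORTFALL
    if seed_len <= inp.min_overlap:
        raise ValueError("max oligo length too small for the minimum overlap")
    if length <= seed_len:
        return [(0, length)]
    offset = len(inp.five_prime)
    variant_intervals = [
        (offset + 3 * (spec.position - 1), offset + 3 * spec.position)
        for spec in inp.variants
    ]
    starts = [0]
    ends: list[int] = []
    while True:
        s = starts[-1]
        if s + seed_len >= length:
            ends.append(length)
            break
        e_default = s + seed_len
        floor = ends[-1] if ends else 0  # next start may not re-enter the
        # previous junction overlap
        e_min = max(e_default - _PLACEMENT_SLACK, floor + 1,
                    s + inp.min_overlap + 2)
        chosen = None
        fallback = None
        # keep the seeded oligo end; pull it back only as far as needed to
        # route the junction around a variant codon
        for e in range(e_default, e_min - 1, -1):
            max_ov = e - max(floor, s + 1)
            # cap: consuming more than seed_len - min_overlap bases in the
            # overlap would leave the next oligo unable to clear this
            # junction, stalling the tiling
            max_ov = min(max_ov, seed_len - inp.min_overlap)
            best_clean = None  # (delta, end, ov) among variant-free windows
            best_any = None
            for ov in range(inp.min_overlap, max_ov + 1):
                a = e - ov
                seg = dna[a:e]
                gc = seg.count("G") + seg.count("C")
                delta = abs(tm_from_counts(gc, ov, salt_term) - inp.target_tm)
                candidate = (delta, e, ov)
                if best_any is None or delta < best_any[0]:
                    best_any = candidate
                clean = all(vb <= a or va >= e for va, vb in variant_intervals)
                if clean and (best_clean is None or delta < best_clean[0]):
                    best_clean = candidate
            if fallback is None:
                fallback = best_any  # seeded end, variant constraint ignored
            if best_clean is not None:
                chosen = best_clean
                break
        if chosen is None:
            chosen = fallback
        if chosen is None:
            raise ValueError(
                "cannot place overlaps: no legal overlap length at position "
                f"{e_default}"
            )
        _, e, ov = chosen
        ends.append(e)
        starts.append(e - ov)
    boundaries = list(zip(starts, ends))
    if not dm.boundaries_valid(
        boundaries, length, inp.max_oligo_length, inp.min_overlap
    ):
        raise ValueError("cannot place overlaps: constraints conflict")
    return boundaries


def initialize(
    inp: dm.DesignInput, rng: np.random.Generator
) -> tuple[dm.GeneDesign, scoring.InitialScores, scoring.ObjectiveScores,
           scoring.ScoreContext]:
    """Monte-Carlo back-translation, oligo seeding and initial scoring.

    Back-translation is retried (up to 1000 times) until the construct
    respects the maximum homopolymer run, both before and after variant
    substitution.
    """
    inp.validate()
    ctx = scoring.ScoreContext(inp)
    design = None
    for _ in range(_BACKTRANSLATION_ATTEMPTS):
        codons = [cm.sample_codon(aa, inp.table, rng) for aa in inp.protein]
        candidate = dm.GeneDesign(
            codons=codons,
            variant_active=[True] * len(inp.variants),
            boundaries=[],
            five_prime=inp.five_prime,
            three_prime=inp.three_prime,
            specs=inp.variants,
        )
        backbone = dm.backbone_dna(candidate)
        if dm.longest_repeat_run(backbone) > inp.max_repeat:
            continue
        candidate.boundaries = place_overlaps(backbone, inp, ctx.salt_term)
        dm.set_variant_states(candidate)
        if dm.longest_repeat_run(candidate.dna) > inp.max_repeat:
            continue  # a variant codon's pure symbols extended a run
        design = candidate
        break
    if design is None:
        raise InitializationError(
            f"could not satisfy max repeating nucleotides ({inp.max_repeat}) "
            f"in {_BACKTRANSLATION_ATTEMPTS} back-translation attempts"
        )
    scores, _, _ = scoring.score_design(design, ctx)
    init = scoring.InitialScores(
        cai=scores.cai_s, tm=scores.tm_s, mis=scores.mis_s, fixed=scores.fixed_s
    )
    scores.composite = scoring.composite_score(scores, init, ctx.include_fixed)
    return design, init, scores, ctx


def _shift(rng: np.random.Generator) -> int:
    """Uniform draw from {-10..-1, 1..10} (a no-op shift is not a mutation)."""
    r = int(rng.integers(0, 20))
    return r - 10 if r < 10 else r - 9


def mutate(
    design: dm.GeneDesign,
    inp: dm.DesignInput,
    rng: np.random.Generator,
) -> dm.GeneDesign:
    """One neighbour proposal: boundary shifts and synonymous codon swaps.

    Each interior boundary endpoint moves by a uniform +-10 bp shift with
    probability ``oligo_mutation_rate``; illegal shifts are dropped in
    place.  Each non-variant codon is redrawn from the frequency-weighted
    synonymous pool with probability ``codon_mutation_rate``; a swap that
    creates a homopolymer run beyond ``max_repeat`` is dropped.  Variant
    viability is re-evaluated afterwards and the whole proposal is discarded
    if the realized construct violates the repeat constraint.
    """
    neighbour = design.clone()
    length = len(design.dna)
    bounds = neighbour.boundaries
    n = len(bounds)
    for i in range(n):
        if i > 0 and rng.random() < inp.oligo_mutation_rate:
            start, end = bounds[i]
            trial = bounds.copy()
            trial[i] = (start + _shift(rng), end)
            if dm.boundaries_valid(
                trial, length, inp.max_oligo_length, inp.min_overlap
            ):
                bounds[:] = trial
        if i < n - 1 and rng.random() < inp.oligo_mutation_rate:
            start, end = bounds[i]
            trial = bounds.copy()
            trial[i] = (start, end + _shift(rng))
            if dm.boundaries_valid(
                trial, length, inp.max_oligo_length, inp.min_overlap
            ):
                bounds[:] = trial

    # codon mutations operate on the pure backbone
    active_positions = {
        spec.position - 1
        for spec, active in zip(neighbour.specs, neighbour.variant_active)
        if active
    }
    offset = len(inp.five_prime)
    backbone = dm.backbone_dna(neighbour)
    draws = rng.random(len(neighbour.codons))
    for pos in np.nonzero(draws < inp.codon_mutation_rate)[0]:
        pos = int(pos)
        if pos in active_positions:
            continue  # variant codons are fixed by contract
        candidate = cm.sample_codon(inp.protein[pos], inp.table, rng)
        if candidate == neighbour.codons[pos]:
            continue
        start = offset + 3 * pos
        trial = backbone[:start] + candidate + backbone[start + 3 :]
        lo = max(0, start - inp.max_repeat)
        hi = min(len(trial), start + 3 + inp.max_repeat)
        if dm.longest_repeat_run(trial[lo:hi]) > inp.max_repeat:
            continue  # rejected: exceeds max repeating nucleotides
        backbone = trial
        neighbour.codons[pos] = candidate

    dm.set_variant_states(neighbour)
    if dm.longest_repeat_run(neighbour.dna) > inp.max_repeat:
        return design.clone()  # realized construct broke the run constraint
    return neighbour


def acceptance_probability(
    score_current: float, score_neighbour: float, temperature: float
) -> float:
    """1 for improvements; exp(-delta/T) otherwise; greedy when T <= 0."""
    if score_neighbour < score_current:
        return 1.0
    if temperature <= 0.0:
        return 0.0
    return math.exp(-(score_neighbour - score_current) / temperature)


def solve_initial_temperature(
    worse_deltas, acceptance: float = CALIBRATION_ACCEPTANCE,
    lo: float = 1.0e-9, hi: float = 1.0e3, rel_tol: float = 1.0e-6,
) -> float:
    """T0 such that mean(exp(-delta/T0)) over worse deltas = ``acceptance``.

    Solved by bisection (the mean is increasing in T0).  With a single
    delta d this reduces to d / ln(1/acceptance).
    """
    deltas = [float(d) for d in worse_deltas]

    def mean_accept(t: float) -> float:
        return sum(math.exp(-d / t) for d in deltas) / len(deltas)

    if mean_accept(lo) >= acceptance:
        return lo
    if mean_accept(hi) <= acceptance:
        return hi
    while hi - lo > rel_tol * hi:
        mid = math.sqrt(lo * hi)  # bisect in log space
        if mean_accept(mid) < acceptance:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def calibrate_initial_temperature(
    design: dm.GeneDesign,
    current_composite: float,
    init: scoring.InitialScores,
    inp: dm.DesignInput,
    ctx: scoring.ScoreContext,
    rng: np.random.Generator,
    samples: int = CALIBRATION_SAMPLES,
) -> float:
    """T0 at which ~10 % of worse neighbours of the initial design accept."""
    worse = []
    for _ in range(samples):
        neighbour = mutate(design, inp, rng)
        scores, _, _ = scoring.score_design(neighbour, ctx)
        delta = (
            scoring.composite_score(scores, init, ctx.include_fixed)
            - current_composite
        )
        if delta > 0:
            worse.append(delta)
    if not worse:
        return 1.0e-3
    return solve_initial_temperature(worse)


def optimize(
    inp: dm.DesignInput,
    progress_every: int = 0,
    progress_callback=None,
) -> DesignResult:
    """Run the full annealing job and return the best design found.

    Identical seed and input produce a bit-identical result.  Rejected
    proposals still advance the cooling schedule, so the schedule length
    always equals ``inp.iterations``.
    """
    rng = np.random.default_rng(inp.seed)
    design, init, scores, ctx = initialize(inp, rng)
    initial_design = design.clone()
    current, current_scores = design, scores
    best, best_scores = design.clone(), scores
    progress: list[ProgressRecord] = []

    t0 = None
    if inp.iterations > 0:
        t0 = calibrate_initial_temperature(
            design, scores.composite, init, inp, ctx, rng
        )
        alpha = TEMPERATURE_FLOOR ** (1.0 / inp.iterations)
        temperature = t0
        for iteration in range(inp.iterations):
            temperature = t0 * alpha**iteration
            neighbour = mutate(current, inp, rng)
            nb_scores, _, _ = scoring.score_design(neighbour, ctx)
            nb_scores.composite = scoring.composite_score(
                nb_scores, init, ctx.include_fixed
            )
            if nb_scores.composite < current_scores.composite:
                accepted = True
            else:
                p = acceptance_probability(
                    current_scores.composite, nb_scores.composite, temperature
                )
                accepted = rng.random() < p
            if accepted:
                current, current_scores = neighbour, nb_scores
                if nb_scores.composite < best_scores.composite:
                    best, best_scores = neighbour.clone(), nb_scores
            if progress_every and (iteration + 1) % progress_every == 0:
                record = ProgressRecord(
                    iteration + 1,
                    temperature,
                    current_scores.cai_s,
                    current_scores.tm_s,
                    current_scores.mis_s,
                    current_scores.fixed_s,
                    current_scores.composite,
                    best_scores.composite,
                )
                progress.append(record)
                if progress_callback is not None:
                    progress_callback(record)

    final_scores, overlaps, report = scoring.score_design(best, ctx)
    final_scores.composite = scoring.composite_score(
        final_scores, init, ctx.include_fixed
    )
    overlap_tms = [o.tm for o in overlaps]
    return DesignResult(
        input=inp,
        best=best,
        best_scores=final_scores,
        initial_scores=init,
        initial_design=initial_design,
        oligos=dm.oligos_of(best, inp.name),
        overlaps=overlaps,
        mean_overlap_tm=sum(overlap_tms) / len(overlap_tms) if overlap_tms
        else math.nan,
        misanneals=report,
        variant_viable=dm.variant_viability(best),
        cai=1.0 - final_scores.cai_s,
        initial_temperature=t0,
        iterations_run=inp.iterations,
        progress=progress,
    )
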