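"""The four design objectives and the initial-score-normalized composite.

Objectives (all "lower is better"):

* ``cai_s`` = 1 - CAI of the coding region;
* ``tm_s``  = RMS deviation of overlap Tms about the target, over the target;
* ``mis_s`` = 3 (sigma_p + sigma_n) / |mu_p - mu_n|, a separation statistic
  between the designed-overlap Tms (positive set) and the Tms of candidate
  misannealing segment pairs (negative set);
* ``fixed_s`` = count of unviable variant codons (those inside overlaps).

The composite is the mean of each objective scaled by its own value in the
initial solution, so the initial solution scores exactly 1 and later
solutions are measured relative to it.

Misanneal negative set
----------------------

Misannealing happens when two *different* segments of the construct can form
a stable duplex: a segment repeated at a second locus (the complementary
oligo then primes at both) or an inverted-repeat pair (a segment annealing
to the wrong strand).  The negative set therefore enumerates maximal exact
repeat and inverted-repeat segment pairs of at least the minimum overlap
length, in both orientations, and retains the duplex Tm of each matched
segment when it lies within 25 deg C of the target melting temperature.  An
optional, off-by-default mismatch-tolerant scan extends each pair outward
using the %MM term of the Wetmur formula; it is reported but never scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import codons as cm
from . import design as dm
from . import thermo

_PURE = frozenset("ACGT")

#: Retention band around the target Tm for candidate misanneals, deg C.
MISANNEAL_BAND = 25.0

#: Sentinel for mis_s when positive and negative Tm means coincide.
MIS_SENTINEL = 1.0e6


@dataclass
class ObjectiveScores:
    cai_s: float
    tm_s: float
    mis_s: float
    fixed_s: int
    composite: float | None = None


@dataclass(frozen=True)
class InitialScores:
    """The objective values of the initial solution; recorded once per job."""

    cai: float
    tm: float
    mis: float
    fixed: int


@dataclass(frozen=True)
class MisannealSite:
    """One candidate misanneal: two matched segment loci and their duplex Tm.

    ``orientation`` is "direct" (segment repeated on the same strand) or
    "inverted" (segment equal to the reverse complement of another).
    """

    interval: tuple[int, int]
    partner: tuple[int, int]
    orientation: str
    tm: float
    mismatch_percent: float = 0.0


@dataclass
class MisannealReport:
    positive_tms: list[float]
    negative_tms: list[float]
    sites: list[MisannealSite]
    repeat_runs: list[tuple[int, int, str]] = field(default_factory=list)


def cai_score(design: dm.GeneDesign, w: dict[str, float]) -> float:
    """1 - CAI of the protein-coding region (cloning sequences excluded)."""
    start = len(design.five_prime)
    coding = design.dna[start : start + 3 * len(design.codons)]
    return 1.0 - cm.cai(coding, w)


def tm_score(overlap_tms, target: float) -> float:
    """RMS deviation of overlap Tms about the target, divided by the target.

    Note the deviation is taken about the *target*, not the sample mean.
    """
    tms = list(overlap_tms)
    if not tms:
        raise ValueError("no overlaps to score (single-oligo design)")
    if target <= 0:
        raise ValueError("target melting temperature must be > 0")
    return math.sqrt(
        sum((t - target) ** 2 for t in tms) / len(tms)
    ) / target


def fixed_score(design: dm.GeneDesign) -> int:
    """Count of requested variant codons falling inside overlap regions."""
    return sum(not viable for viable in dm.variant_viability(design))


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    """Positions of every pure k-mer (windows with degenerate symbols skipped)."""
    degenerate = [i for i, ch in enumerate(seq) if ch not in _PURE]
    kmers: dict[str, list[int]] = {}
    di = 0
    ndeg = len(degenerate)
    for i in range(len(seq) - k + 1):
        while di < ndeg and degenerate[di] < i:
            di += 1
        if di < ndeg and degenerate[di] < i + k:
            continue
        kmers.setdefault(seq[i : i + k], []).append(i)
    return kmers


def _merge_seed_runs(pairs_by_diag: dict[int, list[int]], k: int):
    """Merge consecutive seed starts on a diagonal into maximal matches."""
    for diag, starts in pairs_by_diag.items():
        starts.sort()
        run_start = starts[0]
        prev = starts[0]
        for p in starts[1:] + [None]:
            if p is not None and p == prev + 1:
                prev = p
                continue
            yield diag, run_start, prev - run_start + k  # (diag, start, length)
            if p is not None:
                run_start = prev = p


def find_repeat_pairs(dna: str, k: int):
    """Maximal exact repeat / inverted-repeat segment pairs of length >= k.

    Yields ``(start_a, start_b, length, orientation)`` with
    ``dna[a:a+len] == dna[b:b+len]`` for direct pairs and
    ``dna[a:a+len] == reverse_complement(dna[b:b+len])`` for inverted ones
    (a <= b; a palindromic segment pairs with itself once).
    """
    length = len(dna)
    kmers = _kmer_positions(dna, k)

    direct: dict[int, list[int]] = {}
    for positions in kmers.values():
        if len(positions) > 1:
            for ai in range(len(positions)):
                for bi in range(ai + 1, len(positions)):
                    direct.setdefault(
                        positions[bi] - positions[ai], []
                    ).append(positions[ai])
    for diag, start, mlen in _merge_seed_runs(direct, k):
        yield start, start + diag, mlen, "direct"

    rc = dm.reverse_complement(dna)
    rc_kmers = _kmer_positions(rc, k)
    # a maximal inverted match is a run of seeds (i, j) on a constant
    # diagonal j - i between the sequence and its reverse complement; the
    # partner segment on the top strand starts at length - j - match_length
    inverted: dict[int, list[int]] = {}
    for kmer, positions in kmers.items():
        rc_positions = rc_kmers.get(kmer)
        if rc_positions:
            for i in positions:
                for j in rc_positions:
                    inverted.setdefault(j - i, []).append(i)
    seen = set()
    for diag, start, mlen in _merge_seed_runs(inverted, k):
        partner = length - (start + diag) - mlen
        a, b = sorted((start, partner))
        if (a, b, mlen) in seen:
            continue  # each inverted pair is seeded from both sides
        seen.add((a, b, mlen))
        yield a, b, mlen, "inverted"


def find_misanneals(
    design: dm.GeneDesign,
    target: float,
    buffer: thermo.BufferConditions,
    min_overlap: int,
    max_repeat: int | None = None,
    extended: bool = False,
) -> MisannealReport:
    """Positive (designed-overlap) and negative (misanneal-candidate) Tm sets.

    Negatives are Tms of repeat / inverted-repeat segment pairs within
    :data:`MISANNEAL_BAND` of the target.  With ``extended=True`` each pair
    is also widened outward, scoring mismatches through the %MM term, and
    any widened duplex still inside the band is reported (never scored).
    Homopolymer runs longer than ``max_repeat`` are reported alongside.
    """
    salt = thermo.wetmur_salt_term(buffer)
    positives = [o.tm for o in dm.overlaps_of(design, buffer)]
    sites: list[MisannealSite] = []
    dna = design.dna
    for a, b, mlen, orientation in find_repeat_pairs(dna, min_overlap):
        seg = dna[a : a + mlen]
        gc = seg.count("G") + seg.count("C")
        tm = thermo.tm_from_counts(gc, mlen, salt)
        if abs(tm - target) <= MISANNEAL_BAND:
            sites.append(
                MisannealSite((a, a + mlen), (b, b + mlen), orientation, tm)
            )
        elif extended:
            site = _extend_with_mismatches(
                dna, a, b, mlen, orientation, salt, target
            )
            if site is not None:
                sites.append(site)
    runs = []
    if max_repeat is not None:
        pos = 0
        while pos < len(dna):
            end = pos
            while end < len(dna) and dna[end] == dna[pos]:
                end += 1
            if end - pos > max_repeat:
                runs.append((pos, end, dna[pos]))
            pos = end
    return MisannealReport(
        positive_tms=positives,
        negative_tms=[s.tm for s in sites],
        sites=sites,
        repeat_runs=runs,
    )


def _extend_with_mismatches(dna, a, b, mlen, orientation, salt, target):
    """Widen an exact pair outward, penalizing mismatches via %MM."""
    length = len(dna)
    best = None
    for extra in range(1, 11):
        width = mlen + 2 * extra
        a0, b0 = a - extra, b - extra
        if a0 < 0 or b0 < 0 or a0 + width > length or b0 + width > length:
            break
        seg_a = dna[a0 : a0 + width]
        seg_b = dna[b0 : b0 + width]
        if orientation == "inverted":
            seg_b = dm.reverse_complement(seg_b)
        if set(seg_a) - _PURE or set(seg_b) - _PURE:
            break
        mismatches = sum(x != y for x, y in zip(seg_a, seg_b))
        gc = seg_a.count("G") + seg_a.count("C")
        tm = thermo.tm_from_counts(
            gc, width, salt, 100.0 * mismatches / width
        )
        if abs(tm - target) <= MISANNEAL_BAND:
            site = MisannealSite(
                (a0, a0 + width), (b0, b0 + width), orientation, tm,
                100.0 * mismatches / width,
            )
            if best is None or abs(tm - target) < abs(best.tm - target):
                best = site
    return best


def _population_std(values) -> float:
    mean = sum(values) / len(values)
    return math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))


def misanneal_score(report: MisannealReport) -> float:
    """3 (sigma_p + sigma_n) / |mu_p - mu_n| with population deviations.

    0 when the negative set is empty (nothing can misanneal); a large
    sentinel when the two means coincide (no separation at all).
    """
    if not report.positive_tms:
        raise ValueError("misanneal score needs at least one overlap Tm")
    if not report.negative_tms:
        return 0.0
    mu_p = sum(report.positive_tms) / len(report.positive_tms)
    mu_n = sum(report.negative_tms) / len(report.negative_tms)
    if mu_p == mu_n:
        return MIS_SENTINEL
    sigma_p = _population_std(report.positive_tms)
    sigma_n = _population_std(report.negative_tms)
    return 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)


def composite_score(
    scores: ObjectiveScores, init: InitialScores, include_fixed: bool = True
) -> float:
    """Mean of per-objective ratios against the initial solution.

    Objectives whose initial value is 0 contribute their raw (unscaled)
    value, keeping the term finite while still penalizing regressions.  When
    the job has no variant codons the fixed term is omitted and the mean
    runs over the three remaining objectives.
    """
    pairs = [
        (scores.cai_s, init.cai),
        (scores.tm_s, init.tm),
        (scores.mis_s, init.mis),
    ]
    if include_fixed:
        pairs.append((float(scores.fixed_s), float(init.fixed)))
    terms = [raw / ref if ref > 0 else raw for raw, ref in pairs]
    return sum(terms) / len(terms)


class ScoreContext:
    """Precomputed, job-constant pieces of the scoring pipeline."""

    def __init__(self, inp: dm.DesignInput):
        self.w = cm.relative_adaptiveness(inp.table)
        self.logw = {
            c: (math.log(v) if v > 0 else None) for c, v in self.w.items()
        }
        self.salt_term = thermo.wetmur_salt_term(inp.buffer)
        self.target = inp.target_tm
        self.buffer = inp.buffer
        self.min_overlap = inp.min_overlap
        self.max_repeat = inp.max_repeat
        self.include_fixed = bool(inp.variants)


def score_design(
    design: dm.GeneDesign, ctx: ScoreContext
) -> tuple[ObjectiveScores, list[dm.Overlap], MisannealReport]:
    """All four raw objectives of a design (composite left unset)."""
    # CAI over the coding region, degenerate variant codons skipped
    total = 0.0
    counted = 0
    for codon in _current_coding_codons(design):
        logw = ctx.logw.get(codon)
        if logw is None:
            if set(codon) - _PURE:
                continue
            total = -math.inf  # zero-usage codon: CAI collapses to 0
            counted += 1
            continue
        total += logw
        counted += 1
    cai_value = math.exp(total / counted) if counted else 0.0

    overlaps = []
    dna = design.dna
    for j, (a, b) in enumerate(dm.overlap_intervals(design.boundaries)):
        seg = dna[a:b]
        gc = seg.count("G") + seg.count("C")
        overlaps.append(
            dm.Overlap(j + 1, (a, b), thermo.tm_from_counts(gc, b - a, ctx.salt_term))
        )

    report = find_misanneals(
        design, ctx.target, ctx.buffer, ctx.min_overlap, ctx.max_repeat
    )
    report.positive_tms = [o.tm for o in overlaps]

    scores = ObjectiveScores(
        cai_s=1.0 - cai_value,
        tm_s=tm_score([o.tm for o in overlaps], ctx.target),
        mis_s=misanneal_score(report),
        fixed_s=fixed_score(design),
    )
    return scores, overlaps, report


def _current_coding_codons(design: dm.GeneDesign):
    offset = len(design.five_prime)
    dna = design.dna
    for i in range(len(design.codons)):
        yield dna[offset + 3 * i : offset + 3 * i + 3]
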