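# Methods

This note documents the model, the algorithm, the defaults and the design
choices behind `oligoforge`, and what the synthetic test data do and do not
establish about real designs.

## Problem statement

A gene is assembled by PCR from single-stranded oligos (~60 nt) that tile
the construct on alternating strands; consecutive oligos share an overlap
whose duplex melting temperature governs correct annealing. The design
problem is to choose (i) a codon for every residue of the protein and
(ii) the oligo boundary positions, such that codon usage matches the
expression host, every overlap melts near one target temperature, no other
segment pair of the construct can form a comparably stable duplex, and any
user-requested degenerate "variant codons" lie outside the overlaps.
The 5′/3′ cloning sequences are fixed DNA and are never altered.

## Melting-temperature model

Duplex Tm uses the Wetmur GC/length/salt formula

    Tm = 81.5 + 16.6 log10([Na_eq] / (1 + 0.7 [Na_eq]))
         + 0.41 %GC − 500/L − %MM

with the von Ahsen monovalent equivalent

    [Na_eq] = [Na+] + [K+] + [Tris]/2 + 3.79 sqrt([Mg2+] − [dNTP]).

All concentrations are molar. The default buffer is a typical PCR mix
(Na⁺ 0.05 M, Mg²⁺ 2 mM, dNTP 0.2 mM, no K⁺/Tris), giving
[Na_eq] ≈ 0.211 M; every concentration is a CLI flag. The formula is
implemented directly — no nearest-neighbour correction, no secondary
structure — so temperatures are smooth in GC count and length, which the
optimizer exploits. Designed overlaps are perfect complements (%MM = 0);
the mismatch term is used only by the optional extended misanneal scan.
Temperatures are computed and compared at full precision and rounded to
one decimal only for display.

## Objectives

* `cai_s = 1 − CAI` over the protein-coding region only. CAI is the
  geometric mean of relative adaptiveness `w_i = f_i / max_j f_j` within
  each synonymous family; usage tables may arrive as per-thousand values,
  counts or fractions (only within-family ratios matter) and are
  normalized per family on load. Codons containing degenerate symbols are
  excluded from the mean; stop codons have no `w` and may not occur in
  frame. A zero-usage codon collapses CAI to 0.
* `tm_s` is the RMS deviation of the overlap Tms about the *target* (not
  the sample mean), divided by the target.
* `mis_s = 3(σ_p + σ_n)/|μ_p − μ_n|` with population (n-denominator)
  standard deviations, since both sets are complete enumerations rather
  than samples. The positive set is the designed-overlap Tms. The
  negative set enumerates candidate misanneals: maximal exact repeat and
  inverted-repeat segment pairs of at least the minimum overlap length
  (k-mer seeding on the sequence and its reverse complement, seeds merged
  along diagonals into maximal matches), keeping the duplex Tm of each
  matched segment when it lies within 25 °C of the target. The rationale:
  misannealing requires two *different* loci that can form a stable
  duplex — a repeated segment lets the complementary oligo prime at both
  loci, an inverted repeat lets a segment anneal to the wrong strand.
  Isolated windows with no partner elsewhere in the construct cannot
  misanneal and are not counted (a per-window reading would flag hundreds
  of ordinary 10–20-mers in any construct and could never report a clean
  design). An empty negative set gives `mis_s = 0`; coincident means give
  a large finite sentinel (10⁶) so annealing arithmetic never sees
  infinity. Windows containing degenerate symbols are skipped. A
  mismatch-tolerant extension (widening each exact pair and charging the
  %MM term) is available behind `--extended-misanneal-scan`; it is
  report-only and never scored. Homopolymer runs beyond the allowed
  maximum are likewise reported, not scored — the run constraint is
  enforced as a hard reject during search.
* `fixed_s` counts variant codons whose three bases intersect any overlap
  interval; such codons are reverted to the retained back-translation
  codon for the original residue (and re-substituted if a later boundary
  move frees the site).

The composite is the mean of each objective divided by its initial-solution
value, so the initial solution scores exactly 1 and subsequent scores are
relative optimality. If an initial objective is 0 (common: no misanneals,
or all variants viable at initialization), that term contributes its raw
value instead of a 0/0 ratio — finite, and still penalizing regressions.
Jobs without variant codons average the three remaining objectives.

## Search

**Initialization.** Back-translation samples each codon from the host
table with probability proportional to its frequency; a draw violating the
maximum homopolymer run (checked on the full construct including cloning
sequences) is retried up to 1000 times. Variant codons are then
substituted and the replaced codons retained for possible reversion.
Oligos are seeded at `max_oligo_length − 5` bases, leaving room for later
growth and shrinkage. Overlaps are placed greedily left to right: each
junction's overlap grows one base at a time from the minimum overlap
length (floor 10 bases — below that the −500/L term leaves no plausible
priming footprint) and the length whose Tm is closest to the target is
kept, capped so the next oligo can always clear the junction. Placement
is variant-aware: if a variant-free junction candidate exists with the
oligo end pulled back at most 12 bases, the best-Tm variant-free candidate
is preferred. This matters because boundary mutations move endpoints only
±10 bp: once the overlap Tm profile is homogenized, carrying an overlap
across a variant codon costs far more (through the Tm term, scaled by a
small initial `tm_s`) than the fixed-codon term recovers, so a variant
buried under a junction at initialization tends to stay buried. The first
and last oligos are anchored at the construct ends — they double as the
outer PCR primers.

**Mutation.** One neighbour per iteration; both mutation kinds fire
independently. Each interior boundary endpoint moves with probability
`oligo_mutation_rate` by a uniform draw from {−10…−1, 1…10} (zero is a
no-op, not a mutation); a shift that breaks any boundary invariant
(anchored ends, max oligo length, min overlap, strictly increasing
starts/ends, junction overlaps pairwise disjoint) is dropped in place.
Each non-variant codon is redrawn from the frequency-weighted synonymous
pool with probability `codon_mutation_rate`; a swap creating a homopolymer
run beyond the maximum is dropped. Variant viability is then re-evaluated
and the whole proposal is discarded if the realized construct (degenerate
codons substituted) violates the run constraint — a variant codon's pure
symbols can extend an adjacent run that the pure backbone check misses.

**Schedule.** The initial temperature T₀ is calibrated so that the mean
acceptance probability of worse neighbours of the initial solution is
10 %: 1000 proposal mutations are sampled, the positive score deltas kept,
and `mean(exp(−Δ/T₀)) = 0.10` solved by bisection in log-space (relative
tolerance 10⁻⁶; closed form `d/ln 10` when all deltas are equal; fallback
T₀ = 10⁻³ when no worse neighbour appears). A thousand samples are used
because a 200-sample calibration leaves enough noise in T₀ that the
realized acceptance ranges ~7–14 % instead of ~10 %. Cooling is geometric
over the requested iterations down to a floor of 10⁻⁶ T₀ (a geometric
schedule never reaches zero; below the floor only improvements are
accepted). A worse neighbour with excess Δ is accepted with probability
`exp(−Δ/T)`; equal scores accept with probability 1. Rejected proposals
still advance the schedule, so its length always equals `iterations`.
The best-ever design is tracked and returned.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| `target_tm` | required | overlap target Tm, °C |
| `max_oligo_length` | 60 nt | synthesis length limit |
| `min_overlap` | 10 nt | overlap floor; also misanneal seed length |
| `max_repeat` | 5 | longest allowed homopolymer run |
| `iterations` | 50 000 | annealing steps |
| `codon_mutation_rate` | 0.02 /codon | per-iteration swap probability |
| `oligo_mutation_rate` | 0.1 /endpoint | per-iteration shift probability |
| buffer | 50 mM Na⁺, 2 mM Mg²⁺, 0.2 mM dNTP | molar CLI flags |
| seed | 1 | all randomness flows from this |

`iterations = 50 000` was set by watching convergence on the packaged
EGFP-scale job (≈750-base construct): at 10 000–30 000 steps the CAI
objective is still descending; by 50 000 it has reached its plateau
region. Such a job takes about a minute on one CPU; scores are recomputed
in full every iteration (no incremental caching), keeping the
implementation the reference against which any future optimization must be
bit-identical. `max_repeat = 5` is the usual synthesis guideline. The
number of oligos is fixed at initialization — the mutation set has no
split/merge move — so it is determined by the construct length, the seeded
oligo length and the Tm-chosen overlap lengths.

## Fixtures and synthetic data

The packaged EGFP fixture is the 238-residue GFP-numbered EGFP sequence
(without the Val2 insertion), so the chromophore tyrosine is residue 66
and the surface tyrosine residue 145 — the classic Y66H (blue chromophore)
and Y145F sites addressed by the variant codons `66:YAT` ({Y,H}) and
`145:TWT` ({Y,F}), a four-member library. The 5′/3′ cloning sequences are
*synthetic* 20-base placeholders (an RBS-like leader; a double-stop tail),
not sequences from any real construct. The *E. coli* K-12 usage
table is vendored as a two-column TSV of per-1000 frequencies.

The synthetic generators (`testkit`) produce i.i.d. random proteins and
"toy" usage tables with one favoured codon per family (weight 1 against
`1 − skew`). They are pure functions of their seed. What they emulate:
realistic construct lengths, GC heterogeneity, codon-choice freedom,
variant placement conflicts, and (via a duplicated single-codon Met/Trp
motif) guaranteed exact repeats for exercising the misanneal scan. What
they do not emulate: real genomes' codon-pair and local GC structure,
synthesis error profiles, or secondary structure — so passing tests show
the optimizer satisfies its stated objectives on realistic problem sizes,
not that assembled product yields will match any particular wet protocol.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; 1-based inclusive in all
  rendered output.
* Ties in greedy overlap placement go to the shorter overlap (first
  scanned); ties in sampling are impossible (cumulative sums are strict).
* A construct no longer than the seeded oligo length yields a single
  oligo; such a design has no overlaps and cannot be scored (`tm_s` is
  undefined) — the optimizer rejects it up front.
* `mg < dntp` is rejected at buffer construction (negative square root);
  `[Na_eq] ≤ 0` is rejected at Tm evaluation (log undefined).
* Determinism: one `numpy` Generator seeded from the job seed drives
  back-translation, calibration, mutation and acceptance; identical input
  and seed give byte-identical output files.

## Known limitations

* The misanneal negative set considers exact repeat/inverted-repeat pairs
  at seed resolution `min_overlap`; near-repeats whose longest exact core
  is shorter than the seed are invisible to the score (the extended scan
  reports, but does not score, mismatched pairs).
* No hairpin/secondary-structure model, no nearest-neighbour
  thermodynamics, no codon-pair bias, no restriction-site screening.
* The oligo count cannot change during optimization; constructs whose
  length sits near a tiling boundary may settle one oligo above or below
  the count a different back-translation would give.
* Variant codons are honoured only outside overlaps; a variant that no
  legal boundary arrangement can free is silently reverted (and counted
  in `fixed_s`, flagged `[-]` in the alignment).
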