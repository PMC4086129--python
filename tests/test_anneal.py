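"""Initialization, mutation, calibration and the annealing loop."""

import math

import numpy as np
import pytest

from oligoforge import anneal, codons as cm, design as dm, scoring, testkit


def small_input(**overrides):
    params = dict(length=45, skew=0.6, variant_specs=("10:NNK",),
                  iterations=200)
    params.update(overrides)
    seed = params.pop("seed", 3)
    return testkit.synthetic_job(seed, **params)


class TestInitialize:
    def test_seeded_oligo_length(self):
        inp = small_input(variant_specs=())
        design, *_ = anneal.initialize(inp, np.random.default_rng(0))
        seed_len = inp.max_oligo_length - anneal.SEED_SHORTFALL
        starts, ends = zip(*design.boundaries)
        # without variants the greedy keeps every seeded end: all oligos
        # except the final one have exactly the seeded length
        assert all(e - s == seed_len for s, e in design.boundaries[:-1])
        assert design.boundaries[0][0] == 0
        assert design.boundaries[-1][1] == len(design.dna)

    def test_initial_composite_is_one_when_all_objectives_positive(self):
        inp = testkit.job_with_positive_initial_scores(5)
        _, init, scores, _ = anneal.initialize(
            inp, np.random.default_rng(inp.seed)
        )
        assert min(init.cai, init.tm, init.mis) > 0 and init.fixed > 0
        assert scores.composite == 1.0

    def test_design_invariants_hold(self):
        inp = small_input()
        design, *_ = anneal.initialize(inp, np.random.default_rng(0))
        dm.validate_design(design, inp)

    def test_unsatisfiable_repeat_constraint(self):
        table = testkit.toy_codon_table(0.5, np.random.default_rng(0))
        inp = dm.DesignInput(protein="KKKKKKKKKK", target_tm=60.0,
                             table=table, max_repeat=1, min_overlap=4,
                             max_oligo_length=12)
        with pytest.raises(anneal.InitializationError, match="repeat"):
            anneal.initialize(inp, np.random.default_rng(0))

    def test_repeat_constraint_respected(self):
        inp = small_input(max_repeat=4)
        design, *_ = anneal.initialize(inp, np.random.default_rng(1))
        assert dm.longest_repeat_run(design.dna) <= 4


class TestPlacement:
    def test_overlap_length_is_local_tm_argmin(self):
        # without variants, each junction's overlap must beat every other
        # scanned length at the same oligo end
        from oligoforge.thermo import tm_from_counts, wetmur_salt_term

        inp = small_input(variant_specs=())
        design, *_ = anneal.initialize(inp, np.random.default_rng(2))
        salt = wetmur_salt_term(inp.buffer)
        dna = dm.backbone_dna(design)
        seed_len = inp.max_oligo_length - anneal.SEED_SHORTFALL
        bounds = design.boundaries
        for i in range(len(bounds) - 1):
            end = bounds[i][1]
            floor = bounds[i - 1][1] if i > 0 else 0
            chosen_ov = end - bounds[i + 1][0]
            max_ov = end - max(floor, bounds[i][0] + 1)

            def delta(ov):
                seg = dna[end - ov : end]
                gc = seg.count("G") + seg.count("C")
                return abs(tm_from_counts(gc, ov, salt) - inp.target_tm)

            best = min(
                delta(ov)
                for ov in range(inp.min_overlap,
                                min(max_ov, seed_len - 1) + 1)
            )
            assert delta(chosen_ov) == pytest.approx(best)

    def test_gc_rich_regions_get_shorter_overlaps(self):
        # Lys/Ile-rich (AT) vs Gly/Ala-rich (GC) proteins under the
        # E. coli table: higher GC reaches the target Tm at shorter lengths
        ecoli = testkit.ecoli_table()
        jobs = {}
        for label, protein in (("at", "KNKIKNKIKN" * 6),
                               ("gc", "GAGAGAGAGA" * 6)):
            inp = dm.DesignInput(protein=protein, target_tm=60.0,
                                 table=ecoli, seed=1)
            design, *_ = anneal.initialize(inp, np.random.default_rng(1))
            overlaps = dm.overlap_intervals(design.boundaries)
            jobs[label] = sum(b - a for a, b in overlaps) / len(overlaps)
        assert jobs["gc"] < jobs["at"]


class TestMutation:
    def test_zero_rates_give_identical_neighbour(self):
        inp = small_input(codon_mutation_rate=0.0, oligo_mutation_rate=0.0)
        design, *_ = anneal.initialize(inp, np.random.default_rng(0))
        neighbour = anneal.mutate(design, inp, np.random.default_rng(1))
        assert neighbour.dna == design.dna
        assert neighbour.boundaries == design.boundaries

    def test_single_codon_families_never_change(self):
        table = testkit.toy_codon_table(0.5, np.random.default_rng(0))
        inp = dm.DesignInput(protein="MWMWMWMWMWMWMWMWMWMW", target_tm=60.0,
                             table=table, codon_mutation_rate=1.0,
                             oligo_mutation_rate=0.0)
        design, *_ = anneal.initialize(inp, np.random.default_rng(0))
        neighbour = anneal.mutate(design, inp, np.random.default_rng(5))
        assert neighbour.codons == design.codons

    def test_mutation_preserves_invariants_and_protein(self):
        inp = small_input(codon_mutation_rate=0.2, oligo_mutation_rate=0.5)
        design, *_ = anneal.initialize(inp, np.random.default_rng(0))
        rng = np.random.default_rng(7)
        for _ in range(200):
            design = anneal.mutate(design, inp, rng)
        dm.validate_design(design, inp)
        assert dm.translate_backbone(design) == inp.protein
        assert dm.longest_repeat_run(design.dna) <= inp.max_repeat

    def test_deterministic_given_rng_state(self):
        inp = small_input(codon_mutation_rate=0.3, oligo_mutation_rate=0.5)
        design, *_ = anneal.initialize(inp, np.random.default_rng(0))
        a = anneal.mutate(design, inp, np.random.default_rng(42))
        b = anneal.mutate(design, inp, np.random.default_rng(42))
        assert a.dna == b.dna and a.boundaries == b.boundaries


class TestAcceptance:
    def test_improvement_always_accepted(self):
        assert anneal.acceptance_probability(1.0, 0.9, 0.5) == 1.0

    def test_equal_scores_accepted(self):
        assert anneal.acceptance_probability(1.0, 1.0, 0.5) == 1.0

    def test_boltzmann_factor(self):
        assert anneal.acceptance_probability(1.0, 1.1, 0.1) == pytest.approx(
            math.exp(-1.0)
        )

    def test_zero_temperature_is_greedy(self):
        assert anneal.acceptance_probability(1.0, 1.1, 0.0) == 0.0
        assert anneal.acceptance_probability(1.0, 0.9, 0.0) == 1.0


class TestCalibration:
    def test_equal_deltas_closed_form(self):
        # mean(exp(-d/T)) = 0.1 with all deltas d  =>  T = d / ln 10
        for d in (0.01, 0.2, 3.0):
            t0 = anneal.solve_initial_temperature([d] * 50)
            assert t0 == pytest.approx(d / math.log(10), rel=1e-4)

    def test_mixed_deltas_satisfy_target(self):
        deltas = [0.05, 0.1, 0.4, 0.9]
        t0 = anneal.solve_initial_temperature(deltas)
        mean = sum(math.exp(-d / t0) for d in deltas) / len(deltas)
        assert mean == pytest.approx(0.10, rel=1e-4)

    def test_no_worse_neighbours_fallback(self):
        inp = small_input(codon_mutation_rate=0.0, oligo_mutation_rate=0.0)
        design, init, scores, ctx = anneal.initialize(
            inp, np.random.default_rng(0)
        )
        t0 = anneal.calibrate_initial_temperature(
            design, scores.composite, init, inp, ctx,
            np.random.default_rng(0), samples=20,
        )
        assert t0 == pytest.approx(1.0e-3)


class TestOptimize:
    def test_zero_iterations_returns_initial_solution(self):
        inp = testkit.job_with_positive_initial_scores(5)
        inp.iterations = 0
        result = anneal.optimize(inp)
        assert result.best.dna == result.initial_design.dna
        assert result.best_scores.composite == 1.0
        assert result.initial_temperature is None

    def test_best_composite_monotone_non_increasing(self):
        inp = small_input(iterations=400)
        result = anneal.optimize(inp, progress_every=20)
        best_trace = [r.best_composite for r in result.progress]
        assert all(b <= a + 1e-12 for a, b in zip(best_trace,
                                                  best_trace[1:]))

    def test_result_design_satisfies_invariants(self):
        inp = small_input(iterations=300)
        result = anneal.optimize(inp)
        dm.validate_design(result.best, inp)
        assert dm.translate_backbone(result.best) == inp.protein
        assert dm.longest_repeat_run(result.best.dna) <= inp.max_repeat
        # active variant positions translate to a set containing the
        # original amino acid
        for active, spec in zip(result.best.variant_active,
                                result.best.specs):
            a, b = dm.spec_interval(result.best, spec)
            encoded = set(cm.encoded_amino_acids(result.best.dna[a:b]))
            if active:
                assert spec.original_amino_acid in encoded or spec.codon \
                    == result.best.dna[a:b]
            else:
                assert encoded == {spec.original_amino_acid}

    def test_seed_determinism(self):
        inp_a = small_input(iterations=300)
        inp_b = small_input(iterations=300)
        res_a = anneal.optimize(inp_a)
        res_b = anneal.optimize(inp_b)
        assert res_a.best.dna == res_b.best.dna
        assert res_a.best.boundaries == res_b.best.boundaries
        assert res_a.best_scores.composite == res_b.best_scores.composite

    def test_best_not_worse_than_initial(self):
        inp = small_input(iterations=500)
        result = anneal.optimize(inp)
        # recompute the initial composite directly
        ctx = scoring.ScoreContext(inp)
        init_scores, _, _ = scoring.score_design(result.initial_design, ctx)
        init_composite = scoring.composite_score(
            init_scores, result.initial_scores, ctx.include_fixed
        )
        assert result.best_scores.composite <= init_composite + 1e-12
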