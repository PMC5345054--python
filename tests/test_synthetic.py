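"""The ground-truth world generator and inconsistency injector."""

import pytest

from rcc5align import (
    Rel,
    SyntheticSpec,
    compute_mir,
    derive_true_relations,
    emit_problem,
    is_consistent,
    perturb_inconsistent,
    sample_world,
    scelianoma_problem,
    validate_problem,
)
from rcc5align.model import ConceptLabel, relation_of


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"universe_size": 4, "n_taxonomies": 1},
            {"universe_size": 4, "n_taxonomies": 6},
            {"universe_size": 2, "n_taxonomies": 3},
            {"universe_size": 4, "n_taxonomies": 2, "p_gap": 1.5},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticSpec(**kwargs).validate()


class TestSampleWorld:
    def test_singleton_universe_forces_congruence(self):
        spec = SyntheticSpec(universe_size=2, n_taxonomies=2, max_depth=0, seed=1)
        world = sample_world(spec)
        truths = derive_true_relations(world)
        for (a, b), rel in truths.items():
            assert rel in set(Rel)

    def test_deterministic_under_seed(self):
        spec = SyntheticSpec(universe_size=8, n_taxonomies=3, max_depth=2, p_gap=0.3, seed=42)
        w1, w2 = sample_world(spec), sample_world(spec)
        assert w1.regions == w2.regions
        assert [t.children for t in w1.taxonomies] == [t.children for t in w2.taxonomies]

    def test_every_concept_nonempty(self):
        for seed in range(5):
            spec = SyntheticSpec(universe_size=6, n_taxonomies=3, max_depth=2, p_gap=0.4, seed=seed)
            world = sample_world(spec)
            assert all(region for region in world.regions.values())

    def test_no_gap_means_exact_partition(self):
        spec = SyntheticSpec(universe_size=8, n_taxonomies=2, max_depth=3, p_gap=0.0, seed=3)
        world = sample_world(spec)
        for tax in world.taxonomies:
            assert all(tax.covered.values())
            for parent, kids in tax.children.items():
                union = frozenset().union(
                    *(world.regions[ConceptLabel(tax.tag, k)] for k in kids)
                )
                assert union == world.regions[ConceptLabel(tax.tag, parent)]

    def test_gap_parents_keep_nonempty_residue(self):
        hits = 0
        for seed in range(10):
            spec = SyntheticSpec(universe_size=9, n_taxonomies=2, max_depth=2, p_gap=0.8, seed=seed)
            world = sample_world(spec)
            for tax in world.taxonomies:
                for parent, kids in tax.children.items():
                    if not tax.covered[parent]:
                        hits += 1
                        union = frozenset().union(
                            *(world.regions[ConceptLabel(tax.tag, k)] for k in kids)
                        )
                        residue = world.regions[ConceptLabel(tax.tag, parent)] - union
                        assert residue
        assert hits > 0  # the construction actually exercises relaxed coverage


class TestDeriveTrueRelations:
    def test_agreement_with_zone_semantics(self):
        spec = SyntheticSpec(universe_size=7, n_taxonomies=3, max_depth=2, p_gap=0.2, seed=9)
        world = sample_world(spec)
        for (a, b), rel in derive_true_relations(world).items():
            ra, rb = world.regions[a], world.regions[b]
            assert relation_of(bool(ra - rb), bool(ra & rb), bool(rb - ra)) is rel


class TestEmitProblem:
    def test_zero_density_keeps_problem_consistent(self):
        spec = SyntheticSpec(universe_size=5, n_taxonomies=2, max_depth=1, seed=2)
        problem = emit_problem(sample_world(spec), density=0.0, seed=2)
        assert problem.articulations == []
        assert validate_problem(problem) == []
        assert is_consistent(problem)

    def test_full_density_articulates_every_cross_pair(self):
        spec = SyntheticSpec(universe_size=5, n_taxonomies=2, max_depth=1, seed=2)
        world = sample_world(spec)
        problem = emit_problem(world, density=1.0, seed=2)
        assert len(problem.articulations) == problem.n_cross_pairs()
        assert all(len(a.relset) == 1 for a in problem.articulations)

    def test_seed_reproducibility(self):
        spec = SyntheticSpec(universe_size=6, n_taxonomies=3, max_depth=2, seed=5)
        world = sample_world(spec)
        p1 = emit_problem(world, density=0.5, seed=17)
        p2 = emit_problem(world, density=0.5, seed=17)
        p3 = emit_problem(world, density=0.5, seed=18)
        assert p1.articulations == p2.articulations
        assert p1.articulations != p3.articulations


class TestPerturbInconsistent:
    def test_always_detected(self, scelianoma):
        for seed in range(5):
            bad = perturb_inconsistent(scelianoma, seed=seed)
            assert not is_consistent(bad)
            assert not compute_mir(bad).consistent

    def test_deterministic_choice(self, scelianoma):
        b1 = perturb_inconsistent(scelianoma, seed=7)
        b2 = perturb_inconsistent(scelianoma, seed=7)
        assert b1.articulations[-1] == b2.articulations[-1]

    def test_unresolvable_problem_rejected(self):
        from rcc5align.model import AlignmentProblem, Taxonomy

        free = AlignmentProblem(
            [Taxonomy("A", "", {}, order=["a"]), Taxonomy("B", "", {}, order=["b"])], []
        )
        with pytest.raises(ValueError, match="resolved"):
            perturb_inconsistent(free)
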