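"""The finite-model reasoner: places, consistency, induced relations, MIR,
world patterns, and the merged congruence graph."""

import pytest

from rcc5align import (
    AlignmentProblem,
    Articulation,
    ConceptLabel,
    InconsistentProblem,
    Rel,
    SyntheticSpec,
    Taxonomy,
    World,
    build_places,
    compute_mir,
    count_label_regions,
    derive_true_relations,
    emit_problem,
    enumerate_worlds,
    induced_relation,
    is_consistent,
    merged_graph,
    perturb_inconsistent,
    sample_world,
)
from rcc5align.model import converse_set
from rcc5align.reasoner import PlaceCapExceeded, Placement, _brute_worlds


def single_concept_pair(relset=None):
    a = Taxonomy("A", "", {}, order=["a"])
    b = Taxonomy("B", "", {}, order=["b"])
    arts = []
    if relset is not None:
        arts = [Articulation(ConceptLabel("A", "a"), ConceptLabel("B", "b"), frozenset(relset))]
    return AlignmentProblem([a, b], arts)


class TestBuildPlaces:
    def test_two_singleton_taxonomies(self):
        assert len(build_places(single_concept_pair())) == 2 * 2

    def test_scelianoma_slot_product(self, scelianoma):
        # slots: 2009 {species, outside}; 2012 {species, outside};
        # 2017 {elydimorpha, compacta, outside}
        assert len(build_places(scelianoma)) == 2 * 2 * 3

    def test_relaxed_coverage_adds_gap_slot(self, scelianoma):
        t2017 = scelianoma.taxonomies[2]
        relaxed = Taxonomy(t2017.tag, t2017.title, t2017.children, t2017.order, {"Scelianoma": False})
        problem = AlignmentProblem(scelianoma.taxonomies[:2] + [relaxed], scelianoma.articulations)
        assert len(build_places(problem)) == 2 * 2 * 4

    def test_place_cap(self, scelianoma):
        with pytest.raises(PlaceCapExceeded):
            build_places(scelianoma, cap=5)


class TestIsConsistent:
    def test_contradictory_articulations(self):
        a = ConceptLabel("A", "a")
        b = ConceptLabel("B", "b")
        problem = single_concept_pair()
        problem.articulations = [
            Articulation(a, b, frozenset({Rel.EQ})),
            Articulation(a, b, frozenset({Rel.DJ})),
        ]
        res = is_consistent(problem)
        assert not res
        assert res.conflict  # nonempty unsatisfiable core

    def test_scelianoma_consistent_with_witness(self, scelianoma):
        res = is_consistent(scelianoma)
        assert res and isinstance(res.witness, World) and len(res.witness) >= 1

    @pytest.mark.parametrize("backend", ["brute", "sat"])
    def test_synthetic_problems_consistent_by_construction(self, backend):
        for seed in range(5):
            spec = SyntheticSpec(
                universe_size=4, n_taxonomies=2, max_depth=1, max_children=2, seed=seed
            )
            problem = emit_problem(sample_world(spec), density=1.0, seed=seed)
            assert is_consistent(problem, backend=backend)

    def test_conflict_core_contains_injected_articulation(self, scelianoma):
        perturbed = perturb_inconsistent(scelianoma, seed=5)
        res = is_consistent(perturbed)
        assert not res
        injected = perturbed.articulations[-1]
        assert injected in res.conflict


class TestInducedRelation:
    def test_identity_is_congruence(self, scelianoma):
        res = is_consistent(scelianoma)
        a = ConceptLabel("2009", "Scelianoma")
        assert induced_relation(scelianoma, res.witness, a, a) is Rel.EQ

    def test_agrees_with_region_masks_over_all_worlds(self, scelianoma):
        """Brute-force oracle: for every consistent world of the 12-place
        problem and every cross pair, occupancy-zone classification equals
        direct region-set comparison."""
        placement = Placement(scelianoma)
        worlds = _brute_worlds(placement)
        pairs = scelianoma.cross_pairs()
        for w in worlds[:200]:
            mask = int(w)
            world = placement.world_from_mask(mask)
            for a, b in pairs:
                ra = {i for i in range(placement.n_places) if (placement.region[a] & mask) >> i & 1}
                rb = {i for i in range(placement.n_places) if (placement.region[b] & mask) >> i & 1}
                expected = Rel.EQ if ra == rb else (
                    Rel.GT if ra > rb else Rel.LT if ra < rb else Rel.OV if ra & rb else Rel.DJ
                )
                assert induced_relation(scelianoma, world, a, b) is expected


class TestComputeMir:
    def test_scelianoma_sixteen_fully_resolved_rows(self, scelianoma):
        table = compute_mir(scelianoma)
        assert len(table) == 16 and table.consistent
        assert all(len(row.relset) == 1 for row in table.rows)

    def test_single_pair_equals(self):
        table = compute_mir(single_concept_pair({Rel.EQ}))
        assert len(table) == 1 and table.rows[0].relset == {Rel.EQ}

    def test_congruence_with_covered_parent_entails_inclusion_of_child(self):
        """C == P with P a covered parent of two children forces C > D."""
        a = Taxonomy("A", "", {}, order=["C"])
        b = Taxonomy("B", "", {"P": ["D", "E"]})
        problem = AlignmentProblem(
            [a, b],
            [Articulation(ConceptLabel("A", "C"), ConceptLabel("B", "P"), frozenset({Rel.EQ}))],
        )
        table = compute_mir(problem, backend="brute")
        assert table.relset(ConceptLabel("A", "C"), ConceptLabel("B", "D")) == {Rel.GT}
        assert compute_mir(problem, backend="sat").relset(
            ConceptLabel("A", "C"), ConceptLabel("B", "D")
        ) == {Rel.GT}

    def test_unconstrained_pair_admits_all_five(self):
        table = compute_mir(single_concept_pair())
        assert table.rows[0].relset == set(Rel)

    def test_inconsistent_problem_gives_empty_relsets_and_flag(self, scelianoma):
        table = compute_mir(perturb_inconsistent(scelianoma, seed=1))
        assert not table.consistent
        assert all(row.relset == frozenset() for row in table.rows)

    def test_symmetry_under_converse(self):
        spec = SyntheticSpec(universe_size=6, n_taxonomies=3, max_depth=2, seed=11)
        problem = emit_problem(sample_world(spec), density=0.4, seed=11)
        table = compute_mir(problem)
        for row in table.rows:
            assert table.relset(row.right, row.left) == converse_set(row.relset)

    def test_monotone_under_added_articulations(self):
        spec = SyntheticSpec(universe_size=6, n_taxonomies=2, max_depth=2, seed=4)
        world = sample_world(spec)
        sparse = emit_problem(world, density=0.3, seed=4)
        dense = emit_problem(world, density=1.0, seed=4)
        t_sparse = compute_mir(sparse)
        t_dense = compute_mir(dense)
        for row in t_dense.rows:
            assert row.relset <= t_sparse.relset(row.left, row.right)

    def test_relaxing_coverage_never_shrinks_relsets(self, scelianoma):
        table = compute_mir(scelianoma)
        relaxed_taxa = []
        for t in scelianoma.taxonomies:
            covered = {p: False for p in t.children}
            relaxed_taxa.append(Taxonomy(t.tag, t.title, t.children, t.order, covered))
        relaxed = AlignmentProblem(relaxed_taxa, scelianoma.articulations)
        t_relaxed = compute_mir(relaxed)
        for row in table.rows:
            assert row.relset <= t_relaxed.relset(row.left, row.right)


class TestEnumerateWorlds:
    def test_fully_articulated_scelianoma_has_unique_pattern(self, scelianoma):
        for backend in ("brute", "sat"):
            pats = enumerate_worlds(scelianoma, backend=backend)
            assert len(pats) == 1 and not pats.truncated

    def test_unconstrained_pair_yields_five_patterns(self):
        problem = single_concept_pair()
        for backend in ("brute", "sat"):
            pats = enumerate_worlds(problem, backend=backend)
            assert sorted(p[0].name for p in pats.patterns) == sorted(r.name for r in Rel)

    def test_cap_truncates(self):
        pats = enumerate_worlds(single_concept_pair(), cap=2)
        assert len(pats) == 2 and pats.truncated

    def test_inconsistent_problem_raises(self, scelianoma):
        with pytest.raises(InconsistentProblem):
            enumerate_worlds(perturb_inconsistent(scelianoma, seed=2))


class TestMergedGraph:
    def test_all_congruent_collapses_to_one_class(self):
        table = compute_mir(single_concept_pair({Rel.EQ}))
        graph = merged_graph(table)
        assert len(graph.classes) == 1
        assert graph.inclusion_edges == [] and graph.overlap_edges == []

    def test_scelianoma_widened_genus(self, scelianoma):
        graph = merged_graph(compute_mir(scelianoma))
        early = graph.class_of(ConceptLabel("2009", "Scelianoma"))
        assert graph.class_of(ConceptLabel("2012", "Scelianoma")) == early
        late = graph.class_of(ConceptLabel("2017", "Scelianoma"))
        assert late != early
        assert (late, early) in graph.inclusion_edges  # 2017 concept is wider

    def test_overlap_edges_from_resolved_overlap(self):
        table = compute_mir(single_concept_pair({Rel.OV}))
        graph = merged_graph(table)
        assert graph.overlap_edges == [(0, 1)]

    def test_count_label_regions(self, scelianoma):
        graph = merged_graph(compute_mir(scelianoma))
        assert count_label_regions(graph, "Scelianoma") == 2
        assert count_label_regions(graph, "Scelianoma_elydimorpha") == 1
        assert count_label_regions(graph, "Exophthalmus") == 0


class TestBackendAgreement:
    @pytest.mark.parametrize("seed", range(8))
    def test_mir_identical_across_backends(self, seed):
        spec = SyntheticSpec(
            universe_size=4, n_taxonomies=2, max_depth=1, p_gap=0.3, seed=seed
        )
        problem = emit_problem(sample_world(spec), density=(seed % 4) / 3.0, seed=seed)
        tb = compute_mir(problem, backend="brute")
        ts = compute_mir(problem, backend="sat")
        assert tb.consistent == ts.consistent
        for rb, rs in zip(tb.rows, ts.rows):
            assert (rb.left, rb.right, rb.relset) == (rs.left, rs.right, rs.relset)


class TestGroundTruthRecovery:
    @pytest.mark.parametrize("seed", range(6))
    def test_truth_in_mir_and_singleton_at_full_density(self, seed):
        spec = SyntheticSpec(
            universe_size=5 + seed % 3,
            n_taxonomies=2 + seed % 3,
            max_depth=2,
            p_gap=0.2,
            seed=seed,
        )
        world = sample_world(spec)
        truths = derive_true_relations(world)
        partial = emit_problem(world, density=0.5, seed=seed)
        table = compute_mir(partial)
        assert all(rel in table.relset(a, b) for (a, b), rel in truths.items())
        full = compute_mir(emit_problem(world, density=1.0, seed=seed))
        assert all(full.relset(a, b) == {rel} for (a, b), rel in truths.items())
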