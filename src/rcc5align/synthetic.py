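"""Ground-truth world generator for alignment reasoning tests.

A synthetic "world" assigns every concept of 2-5 generated taxonomies an
explicit nonempty set of atoms from a shared universe, so the true RCC-5
relation of every cross-taxonomy pair is known by direct set comparison.
Each taxonomy is built by recursive partition: children partition their
parent exactly (covered) or, with probability ``p_gap``, leave a nonempty
unsampled residue (non-covered) — emulating incompletely sampled parent
concepts in real treatments.  Emitted problems articulate a seeded random
subset of cross pairs with their true (singleton) relations, so reasoning
stages can be checked for exact ground-truth recovery.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    AlignmentProblem,
    Articulation,
    ConceptLabel,
    Rel,
    Taxonomy,
    relation_of,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruthWorld",
    "sample_world",
    "derive_true_relations",
    "emit_problem",
    "perturb_inconsistent",
]

_CANONICAL = (Rel.EQ, Rel.GT, Rel.LT, Rel.OV, Rel.DJ)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic alignment scenario.

    ``universe_size``
        number of atoms in the shared region universe;
    ``n_taxonomies``
        2-5 classifications drawn over that universe;
    ``max_depth`` / ``max_children``
        partition recursion bounds (a concept with >=2 atoms above depth
        ``max_depth`` always splits into 2..``max_children`` children);
    ``p_gap``
        probability a splitting parent withholds a nonempty residue from its
        children (relaxed coverage);
    ``articulation_density``
        fraction of cross-taxonomy pairs emitted as articulations;
    ``seed``
        the single source of randomness.
    """

    universe_size: int
    n_taxonomies: int
    max_depth: int = 3
    max_children: int = 3
    p_gap: float = 0.1
    articulation_density: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 2 <= self.n_taxonomies <= 5:
            raise ValueError("n_taxonomies must be within [2, 5]")
        if self.universe_size < self.n_taxonomies:
            raise ValueError("universe_size must be >= n_taxonomies")
        if self.universe_size < 1:
            raise ValueError("universe_size must be positive")
        if not (0.0 <= self.p_gap <= 1.0 and 0.0 <= self.articulation_density <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.max_children < 2 or self.max_depth < 0:
            raise ValueError("max_children >= 2 and max_depth >= 0 required")


@dataclass
class GroundTruthWorld:
    """Generated taxonomies plus the atom set denoted by every concept."""

    spec: SyntheticSpec
    taxonomies: list[Taxonomy]
    regions: dict[ConceptLabel, frozenset[int]]
    universe: frozenset[int] = field(default_factory=frozenset)

    def problem(self) -> AlignmentProblem:
        return AlignmentProblem(self.taxonomies, [])


def sample_world(spec: SyntheticSpec) -> GroundTruthWorld:
    """Draw taxonomies with explicit regions; deterministic under the seed."""
    spec.validate()
    rng = random.Random(spec.seed)
    universe = list(range(spec.universe_size))
    taxonomies: list[Taxonomy] = []
    regions: dict[ConceptLabel, frozenset[int]] = {}
    for k in range(spec.n_taxonomies):
        tag = f"t{k + 1}"
        # the treatment's root circumscription: a random nonempty subset,
        # biased wide so roots of different treatments usually overlap
        root_atoms = [a for a in universe if rng.random() < 0.9]
        if not root_atoms:
            root_atoms = [rng.choice(universe)]
        children: dict[str, list[str]] = {}
        covered: dict[str, bool] = {}
        order: list[str] = []
        counter = [0]

        def fresh() -> str:
            counter[0] += 1
            return f"n{counter[0]}"

        def build(atoms: list[int], depth: int) -> str:
            name = fresh()
            order.append(name)
            regions[ConceptLabel(tag, name)] = frozenset(atoms)
            if depth >= spec.max_depth or len(atoms) < 2:
                return name
            pool = list(atoms)
            has_gap = spec.p_gap > 0 and len(pool) >= 3 and rng.random() < spec.p_gap
            if has_gap:
                n_res = rng.randint(1, len(pool) - 2)
                rng.shuffle(pool)
                pool = pool[n_res:]
            k_children = rng.randint(2, min(spec.max_children, len(pool)))
            rng.shuffle(pool)
            cuts = sorted(rng.sample(range(1, len(pool)), k_children - 1))
            blocks = [
                sorted(pool[i:j]) for i, j in zip([0] + cuts, cuts + [len(pool)])
            ]
            covered[name] = not has_gap
            children[name] = [build(block, depth + 1) for block in blocks]
            return name

        build(sorted(root_atoms), 0)
        taxonomies.append(Taxonomy(tag, f"synthetic treatment {tag}", children, order, covered))
    return GroundTruthWorld(spec, taxonomies, regions, frozenset(universe))


def _set_relation(a: frozenset[int], b: frozenset[int]) -> Rel:
    return relation_of(bool(a - b), bool(a & b), bool(b - a))


def derive_true_relations(
    world: GroundTruthWorld,
) -> dict[tuple[ConceptLabel, ConceptLabel], Rel]:
    """The true relation of every cross-taxonomy pair by set comparison."""
    return {
        (a, b): _set_relation(world.regions[a], world.regions[b])
        for a, b in world.problem().cross_pairs()
    }


def emit_problem(
    world: GroundTruthWorld,
    density: float | None = None,
    seed: int | None = None,
) -> AlignmentProblem:
    """An alignment problem articulating a seeded random fraction of the
    cross pairs with their true singleton relations.  ``density=1`` yields
    the complete articulation set; defaults come from the world's spec."""
    density = world.spec.articulation_density if density is None else density
    seed = world.spec.seed if seed is None else seed
    rng = random.Random(seed ^ 0x5EED)
    truths = derive_true_relations(world)
    arts = [
        Articulation(a, b, frozenset({rel}))
        for (a, b), rel in truths.items()
        if rng.random() < density
    ]
    return AlignmentProblem(world.taxonomies, arts)


def perturb_inconsistent(
    problem: AlignmentProblem, seed: int = 0, backend: str = "auto"
) -> AlignmentProblem:
    """Add one articulation contradicting an entailed relation, guaranteeing
    an inconsistent problem.

    Picks a seeded random cross pair whose MIR relation set is a singleton
    (fully resolved) and asserts a relation outside it; raises ``ValueError``
    if no pair is fully resolved.
    """
    from .reasoner import compute_mir

    table = compute_mir(problem, backend=backend)
    if not table.consistent:
        raise ValueError("problem is already inconsistent")
    resolved = [row for row in table.rows if len(row.relset) == 1]
    if not resolved:
        raise ValueError("no fully resolved pair to contradict")
    rng = random.Random(seed ^ 0xBAD)
    row = rng.choice(resolved)
    wrong = rng.choice([r for r in _CANONICAL if r not in row.relset])
    return AlignmentProblem(
        problem.taxonomies,
        list(problem.articulations) + [Articulation(row.left, row.right, frozenset({wrong}))],
    )
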