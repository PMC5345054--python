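"""Finite-model RCC-5 reasoning over taxonomy alignments.

The joint partition of all taxonomies is encoded as a finite set of *places*:
one slot per taxonomy, each slot a childless concept, the coverage gap of a
non-covered parent, or "outside" the taxonomy.  A concept's region is the set
of places lying under it, so sibling disjointness, parent-child nesting and
the coverage constraint hold by construction; a *possible world* is an
assignment of nonempty/empty to every place that keeps every concept nonempty
and satisfies every articulation.

Two interchangeable backends decide satisfiability questions:

``brute``
    vectorised enumeration of all occupancy assignments (reference
    implementation, exact, for small place counts);
``sat``
    a propositional encoding over place-occupancy variables solved with the
    in-package DPLL solver (production, scales to the real alignments).

``auto`` picks ``brute`` at or below ``brute_threshold`` places.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .model import (
    AlignmentProblem,
    Articulation,
    ConceptLabel,
    MergedGraph,
    MIRRow,
    MIRTable,
    Place,
    Rel,
    Taxonomy,
    World,
    relation_of,
    validate_problem,
)

__all__ = [
    "Placement",
    "PlaceCapExceeded",
    "InconsistentProblem",
    "ConsistencyResult",
    "WorldPatterns",
    "build_places",
    "is_consistent",
    "induced_relation",
    "compute_mir",
    "enumerate_worlds",
    "merged_graph",
    "count_label_regions",
]

DEFAULT_PLACE_CAP = 10 ** 6
DEFAULT_BRUTE_THRESHOLD = 16

# zone-emptiness signature of each base relation: (A∖B, A∩B, B∖A) nonempty?
_REL_ZONES = {
    Rel.EQ: (False, True, False),
    Rel.GT: (True, True, False),
    Rel.LT: (False, True, True),
    Rel.OV: (True, True, True),
    Rel.DJ: (True, False, True),
}
_CANONICAL = (Rel.EQ, Rel.GT, Rel.LT, Rel.OV, Rel.DJ)


class PlaceCapExceeded(RuntimeError):
    """The joint partition is larger than the configured cap."""


class InconsistentProblem(RuntimeError):
    """Raised where an operation requires a consistent alignment."""


def _check_valid(problem: AlignmentProblem) -> None:
    violations = validate_problem(problem)
    if violations:
        raise ValueError("invalid alignment problem: " + "; ".join(violations))


class Placement:
    """The joint-partition encoding of an alignment problem.

    Precomputes, per concept, the bitmask (over places) of its region, and
    the list of slot tuples per taxonomy.  With ``sibling_disjointness=False``
    a slot is any nonempty subset of the taxonomy's atomic parts, letting
    sibling regions overlap.

    Place ``i`` corresponds to bit ``1 << i``; the place order is the mixed-
    radix product of the per-taxonomy slot lists (last taxonomy varies
    fastest), which lets each slot's place set be laid down as a periodic bit
    pattern instead of place-by-place.
    """

    def __init__(
        self,
        problem: AlignmentProblem,
        sibling_disjointness: bool = True,
        cap: int = DEFAULT_PLACE_CAP,
    ):
        _check_valid(problem)
        self.problem = problem
        self.sibling_disjointness = sibling_disjointness
        slot_lists: list[list[tuple]] = []
        for tax in problem.taxonomies:
            atoms: list[tuple] = []
            for name in tax.preorder():
                if name not in tax.children:
                    atoms.append(("concept", name))
            for name in tax.preorder():
                if name in tax.children and not tax.covered.get(name, True):
                    atoms.append(("gap", name))
            if sibling_disjointness:
                slots = atoms + [("outside",)]
            else:
                slots = [
                    ("multi", combo)
                    for r in range(1, len(atoms) + 1)
                    for combo in itertools.combinations(atoms, r)
                ] + [("outside",)]
            slot_lists.append(slots)
        total = 1
        for slots in slot_lists:
            total *= len(slots)
            if total > cap:
                raise PlaceCapExceeded(
                    f"joint partition exceeds {cap} places; raise the cap or "
                    "reduce the problem"
                )
        self.slot_lists = slot_lists
        self.n_places = total
        self._places: list[Place] | None = None
        all_places_mask = (1 << total) - 1
        # per (taxonomy, slot) bitmask via periodic-pattern doubling
        strides: list[int] = []
        stride = 1
        for slots in reversed(slot_lists):
            strides.append(stride)
            stride *= len(slots)
        strides.reverse()
        digit_masks: list[list[int]] = []
        for ti, slots in enumerate(slot_lists):
            st = strides[ti]
            period = st * len(slots)
            reps = total // period
            masks = []
            for s in range(len(slots)):
                m = ((1 << st) - 1) << (s * st)
                have = 1
                while have < reps:
                    m |= m << (have * period)
                    have *= 2
                masks.append(m & all_places_mask)
            digit_masks.append(masks)
        # region bitmask per concept: union of the slots lying under it
        self.region: dict[ConceptLabel, int] = {}
        for ti, tax in enumerate(problem.taxonomies):
            for name in tax.order:
                mask = 0
                for si, slot in enumerate(slot_lists[ti]):
                    if _slot_under(tax, slot, name):
                        mask |= digit_masks[ti][si]
                self.region[ConceptLabel(tax.tag, name)] = mask
        # nonemptiness obligations: childless concepts (ancestors follow)
        self.leaf_masks: list[int] = [
            self.region[ConceptLabel(tax.tag, name)]
            for tax in problem.taxonomies
            for name in tax.preorder()
            if name not in tax.children
        ]

    @property
    def places(self) -> list[Place]:
        if self._places is None:
            self._places = [
                Place(slots=combo) for combo in itertools.product(*self.slot_lists)
            ]
        return self._places

    def world_from_mask(self, mask: int) -> World:
        return World(
            occupied=frozenset(p for i, p in enumerate(self.places) if mask >> i & 1)
        )

    def mask_from_world(self, world: World) -> int:
        index = {p: i for i, p in enumerate(self.places)}
        mask = 0
        for p in world.occupied:
            mask |= 1 << index[p]
        return mask


def _atom_under(tax: Taxonomy, atom: tuple, concept: str) -> bool:
    # both leaf concepts and gaps of non-covered parents belong to the
    # carrying concept and all of its ancestors
    name = atom[1]
    return name == concept or tax.is_ancestor(concept, name)


def _slot_under(tax: Taxonomy, slot: tuple, concept: str) -> bool:
    if slot[0] == "outside":
        return False
    if slot[0] == "multi":
        return any(_atom_under(tax, a, concept) for a in slot[1])
    return _atom_under(tax, slot, concept)


def build_places(
    problem: AlignmentProblem,
    sibling_disjointness: bool = True,
    cap: int = DEFAULT_PLACE_CAP,
) -> list[Place]:
    """The joint partition of all taxonomies as a list of places."""
    return Placement(problem, sibling_disjointness, cap).places


# ---------------------------------------------------------------------------
# induced relations

def _mask_relation(region_a: int, region_b: int, occupied: int) -> Rel:
    a = region_a & occupied
    b = region_b & occupied
    if not a or not b:
        raise ValueError("concept region is empty in this world")
    return relation_of(bool(a & ~region_b), bool(a & b), bool(b & ~region_a))


def induced_relation(
    problem: AlignmentProblem, world: World, a: ConceptLabel, b: ConceptLabel
) -> Rel:
    """The RCC-5 base relation between two concepts in one possible world."""
    ta = problem.taxonomy(a.tag)
    tb = problem.taxonomy(b.tag)
    ia = problem.taxonomies.index(ta)
    ib = problem.taxonomies.index(tb)
    in_a = in_b = in_both = only_a = only_b = False
    for place in world.occupied:
        ma = _slot_under(ta, place.slots[ia], a.name)
        mb = _slot_under(tb, place.slots[ib], b.name)
        in_a |= ma
        in_b |= mb
        in_both |= ma and mb
        only_a |= ma and not mb
        only_b |= mb and not ma
    if not in_a or not in_b:
        raise ValueError("concept region is empty in this world")
    return relation_of(only_a, in_both, only_b)


# ---------------------------------------------------------------------------
# brute-force backend (vectorised enumeration)

def _brute_worlds(placement: Placement) -> np.ndarray:
    """All occupancy masks satisfying nonemptiness and every articulation."""
    n = placement.n_places
    if n > 24:
        raise PlaceCapExceeded(
            f"brute-force enumeration over {n} places is not supported; use the sat backend"
        )
    worlds = np.arange(1, 1 << n, dtype=np.int64)
    for mask in placement.leaf_masks:
        worlds = worlds[(worlds & mask) != 0]
    for art in placement.problem.articulations:
        ra = placement.region[art.left]
        rb = placement.region[art.right]
        za, zab, zb = ra & ~rb, ra & rb, rb & ~ra
        fa = (worlds & za) != 0
        fab = (worlds & zab) != 0
        fb = (worlds & zb) != 0
        keep = np.zeros(len(worlds), dtype=bool)
        for rel in art.relset:
            wa, wab, wb = _REL_ZONES[rel]
            keep |= (fa == wa) & (fab == wab) & (fb == wb)
        worlds = worlds[keep]
    return worlds


def _pair_zone_masks(
    placement: Placement, pair: tuple[ConceptLabel, ConceptLabel]
) -> tuple[int, int, int]:
    ra = placement.region[pair[0]]
    rb = placement.region[pair[1]]
    return ra & ~rb, ra & rb, rb & ~ra


def _pair_rel_codes(placement: Placement, worlds: np.ndarray) -> np.ndarray:
    """(n_pairs, n_worlds) array of zone-signature codes 4a+2ab+b."""
    pairs = placement.problem.cross_pairs()
    codes = np.empty((len(pairs), len(worlds)), dtype=np.int8)
    for i, pair in enumerate(pairs):
        za, zab, zb = _pair_zone_masks(placement, pair)
        codes[i] = (
            ((worlds & za) != 0) * 4 + ((worlds & zab) != 0) * 2 + ((worlds & zb) != 0)
        )
    return codes


_CODE_TO_REL = {4 * a + 2 * ab + b: rel for rel, (a, ab, b) in _REL_ZONES.items()}


# ---------------------------------------------------------------------------
# SAT backend

_BYTE_BITS = [[j for j in range(8) if i >> j & 1] for i in range(256)]


def _mask_bits(mask: int, n_bits: int) -> list[int]:
    """Indices of the set bits of ``mask`` (little-endian byte scan)."""
    out: list[int] = []
    for i, byte in enumerate(mask.to_bytes((n_bits + 7) // 8, "little")):
        if byte:
            base = i * 8
            out.extend(base + j for j in _BYTE_BITS[byte])
    return out


class _Encoding:
    """CNF over place-occupancy variables (place i ↦ variable i+1), held in
    a persistent solver so satisfiability probes share the base formula."""

    def __init__(self, placement: Placement, articulations: Sequence[Articulation] | None = None):
        from .sat import Solver

        self.placement = placement
        self.n_vars = placement.n_places
        clauses: list[list[int]] = []
        for mask in placement.leaf_masks:
            clauses.append(self._pos_lits(mask))
        arts = placement.problem.articulations if articulations is None else articulations
        self._pending: list[list[int]] = clauses
        self._zone_lits_cache: dict[tuple[ConceptLabel, ConceptLabel], tuple[list[int], ...]] = {}
        for art in arts:
            self._encode_articulation(art)
        self.solver = Solver(self.n_vars)
        self.solver.add_clauses(self._pending)

    def _pos_lits(self, mask: int) -> list[int]:
        return [i + 1 for i in _mask_bits(mask, self.placement.n_places)]

    def _zone_lits(self, pair: tuple[ConceptLabel, ConceptLabel]) -> tuple[list[int], ...]:
        cached = self._zone_lits_cache.get(pair)
        if cached is None:
            cached = tuple(self._pos_lits(m) for m in _pair_zone_masks(self.placement, pair))
            self._zone_lits_cache[pair] = cached
        return cached

    def _relation_clauses(
        self, pair: tuple[ConceptLabel, ConceptLabel], rel: Rel, selector: int | None = None
    ) -> list[list[int]]:
        """Clauses asserting ``rel`` on the pair (guarded by ``selector``)."""
        zones = self._zone_lits(pair) if selector is None else tuple(
            self._pos_lits(m) for m in _pair_zone_masks(self.placement, pair)
        )
        guard = [-selector] if selector is not None else []
        out: list[list[int]] = []
        for lits, want_nonempty in zip(zones, _REL_ZONES[rel]):
            if want_nonempty:
                out.append(guard + lits)  # no lits -> unsatisfiable (guard forced off)
            else:
                out.extend(guard + [-lit] for lit in lits)
        return out

    def _encode_articulation(self, art: Articulation) -> None:
        pair = (art.left, art.right)
        rels = [r for r in _CANONICAL if r in art.relset]
        if len(rels) == 1:
            self._pending.extend(self._relation_clauses(pair, rels[0]))
            return
        selectors = []
        for rel in rels:
            self.n_vars += 1
            s = self.n_vars
            selectors.append(s)
            self._pending.extend(self._relation_clauses(pair, rel, selector=s))
        self._pending.append(selectors)

    def relation_probe(
        self, pair: tuple[ConceptLabel, ConceptLabel], rel: Rel
    ) -> tuple[list[int], list[list[int]]] | None:
        """(assumptions, temp clauses) asserting ``rel``, or None if the
        assertion is structurally unsatisfiable (a required zone has no
        places at all)."""
        zones = self._zone_lits(pair)
        assumptions: list[int] = []
        temps: list[list[int]] = []
        for lits, want_nonempty in zip(zones, _REL_ZONES[rel]):
            if want_nonempty:
                if not lits:
                    return None
                temps.append(lits)
            else:
                assumptions.extend(-lit for lit in lits)
        return assumptions, temps

    def solve(
        self,
        assumptions: Iterable[int] = (),
        temp_clauses: Iterable[Sequence[int]] = (),
    ) -> int | None:
        """Return an occupancy mask over places, or None if unsatisfiable."""
        model = self.solver.solve(assumptions, temp_clauses)
        if model is None:
            return None
        mask = 0
        for i in range(self.placement.n_places):
            if model[i + 1]:
                mask |= 1 << i
        return mask


def _choose_backend(backend: str, placement: Placement, brute_threshold: int) -> str:
    if backend == "auto":
        return "brute" if placement.n_places <= brute_threshold else "sat"
    if backend not in ("brute", "sat"):
        raise ValueError(f"unknown backend {backend!r}")
    return backend


# ---------------------------------------------------------------------------
# public operations

@dataclass
class ConsistencyResult:
    consistent: bool
    witness: World | None = None
    conflict: list[Articulation] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.consistent


def is_consistent(
    problem: AlignmentProblem,
    backend: str = "auto",
    sibling_disjointness: bool = True,
    cap: int = DEFAULT_PLACE_CAP,
    brute_threshold: int = DEFAULT_BRUTE_THRESHOLD,
) -> ConsistencyResult:
    """Decide whether any possible world satisfies the alignment.

    On success the result carries a witness world; on failure, a best-effort
    minimal subset of articulations that is already unsatisfiable (found by
    iterative deletion — minimal, not guaranteed minimum).
    """
    placement = Placement(problem, sibling_disjointness, cap)
    mode = _choose_backend(backend, placement, brute_threshold)
    if mode == "brute":
        worlds = _brute_worlds(placement)
        if len(worlds):
            return ConsistencyResult(True, placement.world_from_mask(int(worlds[0])))
    else:
        mask = _Encoding(placement).solve()
        if mask is not None:
            return ConsistencyResult(True, placement.world_from_mask(mask))
    return ConsistencyResult(False, None, _conflict_core(placement))


def _subset_consistent(placement: Placement, arts: Sequence[Articulation]) -> bool:
    return _Encoding(placement, arts).solve() is not None


def _conflict_core(placement: Placement) -> list[Articulation]:
    """Iterative-deletion reduction of the articulation set to an
    unsatisfiable core (relative to the taxonomy structure)."""
    core = list(placement.problem.articulations)
    i = 0
    while i < len(core):
        trial = core[:i] + core[i + 1:]
        if not _subset_consistent(placement, trial):
            core = trial
        else:
            i += 1
    return core


def compute_mir(
    problem: AlignmentProblem,
    backend: str = "auto",
    sibling_disjointness: bool = True,
    cap: int = DEFAULT_PLACE_CAP,
    brute_threshold: int = DEFAULT_BRUTE_THRESHOLD,
) -> MIRTable:
    """The Maximally Informative Relations table: for every cross-taxonomy
    concept pair, the set of base relations realizable in at least one
    consistent world.

    If the problem is inconsistent every relation set is empty and the table
    is flagged ``consistent=False``.
    """
    placement = Placement(problem, sibling_disjointness, cap)
    mode = _choose_backend(backend, placement, brute_threshold)
    pairs = problem.cross_pairs()
    if mode == "brute":
        worlds = _brute_worlds(placement)
        if not len(worlds):
            rows = [MIRRow(a, b, frozenset()) for a, b in pairs]
            return MIRTable(rows, consistent=False, problem=problem)
        codes = _pair_rel_codes(placement, worlds)
        rows = []
        for i, (a, b) in enumerate(pairs):
            rels = frozenset(_CODE_TO_REL[int(c)] for c in np.unique(codes[i]))
            rows.append(MIRRow(a, b, rels))
        return MIRTable(rows, consistent=True, problem=problem)

    enc = _Encoding(placement)
    witnessed: dict[tuple[ConceptLabel, ConceptLabel], set[Rel]] = {p: set() for p in pairs}
    zone_masks = {p: _pair_zone_masks(placement, p) for p in pairs}

    def absorb(mask: int) -> None:
        # one model fixes the induced relation of every pair at once
        for p in pairs:
            za, zab, zb = zone_masks[p]
            code = (
                (4 if mask & za else 0)
                + (2 if mask & zab else 0)
                + (1 if mask & zb else 0)
            )
            witnessed[p].add(_CODE_TO_REL[code])

    first = enc.solve()
    if first is None:
        rows = [MIRRow(a, b, frozenset()) for a, b in pairs]
        return MIRTable(rows, consistent=False, problem=problem)
    absorb(first)
    for p in pairs:
        for rel in _CANONICAL:
            if rel in witnessed[p]:
                continue
            probe = enc.relation_probe(p, rel)
            if probe is None:
                continue
            mask = enc.solve(*probe)
            if mask is not None:
                absorb(mask)
    rows = [MIRRow(a, b, frozenset(witnessed[(a, b)])) for a, b in pairs]
    return MIRTable(rows, consistent=True, problem=problem)


@dataclass
class WorldPatterns:
    """Distinct induced-relation patterns over all cross-taxonomy pairs."""

    pairs: list[tuple[ConceptLabel, ConceptLabel]]
    patterns: list[tuple[Rel, ...]]
    witnesses: list[World]
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.patterns)


def enumerate_worlds(
    problem: AlignmentProblem,
    cap: int = 1000,
    backend: str = "auto",
    sibling_disjointness: bool = True,
    place_cap: int = DEFAULT_PLACE_CAP,
    brute_threshold: int = DEFAULT_BRUTE_THRESHOLD,
) -> WorldPatterns:
    """Enumerate the distinct cross-pair relation patterns realizable by the
    alignment (each with one witness world), up to ``cap`` patterns."""
    placement = Placement(problem, sibling_disjointness, place_cap)
    mode = _choose_backend(backend, placement, brute_threshold)
    pairs = problem.cross_pairs()
    if mode == "brute":
        worlds = _brute_worlds(placement)
        if not len(worlds):
            raise InconsistentProblem("the alignment has no possible world")
        codes = _pair_rel_codes(placement, worlds)
        _, first_idx = np.unique(codes, axis=1, return_index=True)
        first_idx = sorted(int(i) for i in first_idx)
        truncated = len(first_idx) > cap
        first_idx = first_idx[:cap]
        patterns = [
            tuple(_CODE_TO_REL[int(c)] for c in codes[:, i]) for i in first_idx
        ]
        witnesses = [placement.world_from_mask(int(worlds[i])) for i in first_idx]
        return WorldPatterns(pairs, patterns, witnesses, truncated)

    # SAT: depth-first search over per-pair relation choices, pruned by
    # satisfiability of the partial assertion; branch sets come from the MIR
    table = compute_mir(
        problem, backend="sat", sibling_disjointness=sibling_disjointness, cap=place_cap
    )
    if not table.consistent:
        raise InconsistentProblem("the alignment has no possible world")
    enc = _Encoding(placement)
    options = [
        [r for r in _CANONICAL if r in table.relset(a, b)] for a, b in pairs
    ]
    patterns: list[tuple[Rel, ...]] = []
    witnesses: list[World] = []
    truncated = False

    def dfs(
        idx: int,
        assumptions: list[int],
        temps: list[list[int]],
        chosen: list[Rel],
        model_mask: int,
    ) -> bool:
        nonlocal truncated
        if len(patterns) >= cap:
            truncated = True
            return False
        if idx == len(pairs):
            patterns.append(tuple(chosen))
            witnesses.append(placement.world_from_mask(model_mask))
            return True
        for rel in options[idx]:
            probe = enc.relation_probe(pairs[idx], rel)
            if probe is None:
                continue
            a2 = assumptions + probe[0]
            t2 = temps + probe[1]
            mask = enc.solve(a2, t2)
            if mask is not None:
                if not dfs(idx + 1, a2, t2, chosen + [rel], mask):
                    return False
        return True

    dfs(0, [], [], [], 0)
    return WorldPatterns(pairs, patterns, witnesses, truncated)


# ---------------------------------------------------------------------------
# merged graph

def merged_graph(table: MIRTable) -> MergedGraph:
    """Collapse the MIR table into the alignment summary: congruence classes,
    transitively reduced proper-inclusion order, and overlap edges.

    Only fully resolved rows (singleton relation sets) contribute; ambiguous
    rows carry no edge.  Within-taxonomy parenthood contributes inclusion.
    """
    if not table.consistent:
        raise InconsistentProblem("cannot merge an inconsistent alignment")
    problem = table.problem
    if problem is None:
        raise ValueError("MIR table carries no problem reference")
    labels = problem.concept_labels()
    parent: dict[ConceptLabel, ConceptLabel] = {l: l for l in labels}

    def find(x: ConceptLabel) -> ConceptLabel:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: ConceptLabel, b: ConceptLabel) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for row in table.rows:
        if row.relset == frozenset({Rel.EQ}):
            union(row.left, row.right)

    index = {l: i for i, l in enumerate(labels)}
    groups: dict[ConceptLabel, list[ConceptLabel]] = {}
    for l in labels:
        groups.setdefault(find(l), []).append(l)
    classes = sorted(
        (frozenset(members) for members in groups.values()),
        key=lambda cls: min(index[m] for m in cls),
    )
    cls_of = {m: i for i, cls in enumerate(classes) for m in cls}

    g = nx.DiGraph()
    g.add_nodes_from(range(len(classes)))
    for row in table.rows:
        if row.relset == frozenset({Rel.GT}):
            g.add_edge(cls_of[row.left], cls_of[row.right])
        elif row.relset == frozenset({Rel.LT}):
            g.add_edge(cls_of[row.right], cls_of[row.left])
    if any(u == v for u, v in g.edges):
        # a {GT}/{LT} row between congruent concepts contradicts the table;
        # solver-produced tables cannot yield this
        raise AssertionError("inclusion edge inside a congruence class")
    for tax in problem.taxonomies:
        for p, cs in tax.children.items():
            for c in cs:
                u = cls_of[ConceptLabel(tax.tag, p)]
                v = cls_of[ConceptLabel(tax.tag, c)]
                # a covered parent with a single child is congruent with it;
                # parenthood contributes inclusion only across classes
                if u != v:
                    g.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(g):
        raise AssertionError("cycle in the inferred inclusion order")
    reduced = nx.transitive_reduction(g)
    inclusion = sorted(reduced.edges)
    overlaps = sorted(
        {
            (min(cls_of[row.left], cls_of[row.right]), max(cls_of[row.left], cls_of[row.right]))
            for row in table.rows
            if row.relset == frozenset({Rel.OV})
        }
    )
    return MergedGraph(classes=list(classes), inclusion_edges=inclusion, overlap_edges=overlaps)


def count_label_regions(graph: MergedGraph, name: str) -> int:
    """How many merged regions (congruence classes) carry a concept with the
    given taxon name, across all treatments."""
    return sum(1 for cls in graph.classes if any(m.name == name for m in cls))
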