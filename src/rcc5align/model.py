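"""Domain model for RCC-5 taxonomic concept alignment.

A taxonomic concept is one specific circumscription of a taxon name as used
in one treatment; concepts from different treatments are compared with the
five RCC-5 base relations (congruence ``==``, proper inclusion ``>``, inverse
proper inclusion ``<``, overlap ``><``, exclusion ``!``), which are jointly
exhaustive and pairwise disjoint over pairs of nonempty regions.

This module holds the pure data types shared by the parser, the reasoner and
the generators; it performs no I/O and no solving.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Rel",
    "RELATION_KEYWORDS",
    "relset_symbol",
    "converse",
    "converse_set",
    "relation_of",
    "ConceptLabel",
    "Taxonomy",
    "Articulation",
    "AlignmentProblem",
    "Place",
    "World",
    "MIRRow",
    "MIRTable",
    "MergedGraph",
    "validate_problem",
]

MIN_TAXONOMIES = 2
MAX_TAXONOMIES = 5


class Rel(enum.Enum):
    """The five RCC-5 base relations, in canonical rendering order."""

    EQ = "=="   # congruence
    GT = ">"    # left properly includes right
    LT = "<"    # left properly included in right
    OV = "><"   # overlap (proper, neither contains the other)
    DJ = "!"    # exclusion / disjointness

    @property
    def symbol(self) -> str:
        return self.value

    def __repr__(self) -> str:  # compact in test output
        return f"Rel.{self.name}"


#: Euler/X articulation keyword -> base relation (left-to-right orientation).
RELATION_KEYWORDS: Mapping[str, Rel] = {
    "equals": Rel.EQ,
    "includes": Rel.GT,
    "is_included_in": Rel.LT,
    "overlaps": Rel.OV,
    "disjoint": Rel.DJ,
}

_CANONICAL_ORDER = (Rel.EQ, Rel.GT, Rel.LT, Rel.OV, Rel.DJ)

_CONVERSE = {Rel.EQ: Rel.EQ, Rel.GT: Rel.LT, Rel.LT: Rel.GT, Rel.OV: Rel.OV, Rel.DJ: Rel.DJ}


def converse(rel: Rel) -> Rel:
    """Relation of (B, A) given the relation of (A, B)."""
    return _CONVERSE[rel]


def converse_set(relset: frozenset[Rel]) -> frozenset[Rel]:
    return frozenset(_CONVERSE[r] for r in relset)


def relset_symbol(relset: Iterable[Rel]) -> str:
    """Render a relation set: a lone relation by its symbol, several inside braces."""
    rels = [r for r in _CANONICAL_ORDER if r in set(relset)]
    if not rels:
        raise ValueError("relation set must be nonempty")
    if len(rels) == 1:
        return rels[0].symbol
    return "{" + " ".join(r.symbol for r in rels) + "}"


def relation_of(a_only_nonempty: bool, both_nonempty: bool, b_only_nonempty: bool) -> Rel:
    """Classify two nonempty regions A, B from the emptiness of the three zones
    A∖B, A∩B, B∖A.

    Exactly five of the eight flag combinations are possible for nonempty A and
    B; the remaining ones imply A or B empty and raise ``ValueError``.
    """
    key = (a_only_nonempty, both_nonempty, b_only_nonempty)
    table = {
        (False, True, False): Rel.EQ,
        (True, True, False): Rel.GT,
        (False, True, True): Rel.LT,
        (True, True, True): Rel.OV,
        (True, False, True): Rel.DJ,
    }
    try:
        return table[key]
    except KeyError:
        raise ValueError(f"zone flags {key} imply an empty region; A and B must be nonempty")


@dataclass(frozen=True, order=True)
class ConceptLabel:
    """One usage of a taxon name anchored to a treatment, rendered ``tag.name``."""

    tag: str
    name: str

    def __str__(self) -> str:
        return f"{self.tag}.{self.name}"


class Taxonomy:
    """One treatment's classification: a forest of concepts sharing a tag.

    ``covered`` records, per concept with children, whether the parent's region
    is exactly the union of its children's regions (the coverage constraint).
    Parents flagged non-covered ("nc") may hold an additional unsampled residue.
    """

    def __init__(
        self,
        tag: str,
        title: str = "",
        children: Mapping[str, Sequence[str]] | None = None,
        order: Sequence[str] | None = None,
        covered: Mapping[str, bool] | None = None,
    ):
        self.tag = tag
        self.title = title
        self.children: dict[str, list[str]] = {p: list(cs) for p, cs in (children or {}).items()}
        self.parent: dict[str, str] = {}
        for p, cs in self.children.items():
            for c in cs:
                if c in self.parent:
                    raise ValueError(f"{tag}.{c} has more than one parent")
                self.parent[c] = p
        names: list[str] = []
        seen: set[str] = set()

        def mention(n: str) -> None:
            if n not in seen:
                seen.add(n)
                names.append(n)

        if order is not None:
            for n in order:
                mention(n)
        for p, cs in self.children.items():
            mention(p)
            for c in cs:
                mention(c)
        # normalize to preorder (roots in mention order, parents before
        # children, siblings in declaration order) — the canonical concept
        # order used by every output
        roots = [n for n in names if n not in self.parent]
        ordered: list[str] = []
        stack = list(reversed(roots))
        while stack:
            n = stack.pop()
            ordered.append(n)
            stack.extend(reversed(self.children.get(n, ())))
        ordered.extend(n for n in names if n not in set(ordered))  # cycle leftovers
        self.order = ordered
        self.covered: dict[str, bool] = {p: True for p in self.children}
        if covered:
            for name, flag in covered.items():
                self.covered[name] = bool(flag)

    @property
    def concepts(self) -> list[str]:
        return list(self.order)

    @property
    def roots(self) -> list[str]:
        return [n for n in self.order if n not in self.parent]

    def labels(self) -> list[ConceptLabel]:
        return [ConceptLabel(self.tag, n) for n in self.order]

    def is_ancestor(self, anc: str, desc: str) -> bool:
        """True if ``anc`` lies strictly above ``desc`` in the forest."""
        n = desc
        while n in self.parent:
            n = self.parent[n]
            if n == anc:
                return True
        return False

    def descendants_or_self(self, name: str) -> list[str]:
        out = [name]
        stack = list(self.children.get(name, ()))
        while stack:
            n = stack.pop(0)
            out.append(n)
            stack[:0] = self.children.get(n, ())
        return out

    def preorder(self) -> list[str]:
        """Parents before children, siblings in declaration order."""
        out: list[str] = []
        stack = list(reversed(self.roots))
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children.get(n, ())))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return (
            self.tag == other.tag
            and self.title == other.title
            and self.children == other.children
            and self.order == other.order
            and self.covered == other.covered
        )

    def __repr__(self) -> str:
        return f"Taxonomy({self.tag!r}, concepts={len(self.order)})"


@dataclass(frozen=True)
class Articulation:
    """An expert-asserted RCC-5 relation (or disjunction) between two concepts
    from different treatments."""

    left: ConceptLabel
    right: ConceptLabel
    relset: frozenset[Rel]

    def __str__(self) -> str:
        return f"[{self.left} {relset_symbol(self.relset)} {self.right}]"


class AlignmentProblem:
    """2-5 taxonomies plus the cross-taxonomy articulations relating them."""

    def __init__(self, taxonomies: Sequence[Taxonomy], articulations: Sequence[Articulation] = ()):
        self.taxonomies = list(taxonomies)
        self.articulations = list(articulations)
        self._by_tag = {t.tag: t for t in self.taxonomies}

    def taxonomy(self, tag: str) -> Taxonomy:
        return self._by_tag[tag]

    def has_concept(self, label: ConceptLabel) -> bool:
        t = self._by_tag.get(label.tag)
        return t is not None and label.name in set(t.order)

    def concept_labels(self) -> list[ConceptLabel]:
        """All concepts in canonical order: taxonomy input order, then preorder."""
        out: list[ConceptLabel] = []
        for t in self.taxonomies:
            out.extend(ConceptLabel(t.tag, n) for n in t.preorder())
        return out

    def cross_pairs(self) -> list[tuple[ConceptLabel, ConceptLabel]]:
        """Every unordered cross-taxonomy concept pair, canonically ordered:
        taxonomy pairs (i, j) with i < j in input order, concepts in preorder."""
        pairs: list[tuple[ConceptLabel, ConceptLabel]] = []
        for i, ti in enumerate(self.taxonomies):
            for tj in self.taxonomies[i + 1:]:
                for a in ti.preorder():
                    for b in tj.preorder():
                        pairs.append((ConceptLabel(ti.tag, a), ConceptLabel(tj.tag, b)))
        return pairs

    def n_cross_pairs(self) -> int:
        sizes = [len(t.order) for t in self.taxonomies]
        return sum(
            sizes[i] * sizes[j] for i in range(len(sizes)) for j in range(i + 1, len(sizes))
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignmentProblem):
            return NotImplemented
        return self.taxonomies == other.taxonomies and self.articulations == other.articulations

    def __repr__(self) -> str:
        return (
            f"AlignmentProblem(tags={[t.tag for t in self.taxonomies]}, "
            f"articulations={len(self.articulations)})"
        )


# ---------------------------------------------------------------------------
# finite-model plumbing

@dataclass(frozen=True)
class Place:
    """An atomic region of the joint partition: one slot per taxonomy, each a
    childless concept, the coverage gap of a non-covered parent, or 'outside'."""

    slots: tuple[tuple[str, ...], ...]  # per taxonomy: ("concept", name) | ("gap", name) | ("outside",)

    def __str__(self) -> str:
        parts = []
        for s in self.slots:
            if s[0] == "concept":
                parts.append(s[1])
            elif s[0] == "gap":
                parts.append(f"gap({s[1]})")
            else:
                parts.append("*")
        return "(" + ", ".join(parts) + ")"


@dataclass(frozen=True)
class World:
    """A possible world: the set of places assigned a nonempty region."""

    occupied: frozenset[Place]

    def __len__(self) -> int:
        return len(self.occupied)


@dataclass(frozen=True)
class MIRRow:
    left: ConceptLabel
    right: ConceptLabel
    relset: frozenset[Rel]


class MIRTable:
    """Maximally Informative Relations: for every cross-taxonomy concept pair,
    the set of base relations realizable in at least one consistent world."""

    def __init__(self, rows: Sequence[MIRRow], consistent: bool, problem: AlignmentProblem | None = None):
        self.rows = list(rows)
        self.consistent = consistent
        self.problem = problem

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[MIRRow]:
        return iter(self.rows)

    def relset(self, a: ConceptLabel, b: ConceptLabel) -> frozenset[Rel]:
        for row in self.rows:
            if (row.left, row.right) == (a, b):
                return row.relset
            if (row.left, row.right) == (b, a):
                return converse_set(row.relset)
        raise KeyError(f"no MIR row for ({a}, {b})")

    def __repr__(self) -> str:
        return f"MIRTable(rows={len(self.rows)}, consistent={self.consistent})"


@dataclass
class MergedGraph:
    """Alignment summary: congruence classes ordered by inferred proper
    inclusion, with overlap edges for partially shared regions."""

    classes: list[frozenset[ConceptLabel]]
    inclusion_edges: list[tuple[int, int]] = field(default_factory=list)  # includer -> included
    overlap_edges: list[tuple[int, int]] = field(default_factory=list)    # unordered, i < j

    def class_of(self, label: ConceptLabel) -> int:
        for i, cls in enumerate(self.classes):
            if label in cls:
                return i
        raise KeyError(str(label))


# ---------------------------------------------------------------------------
# validation

def validate_problem(problem: AlignmentProblem) -> list[str]:
    """Check every structural invariant; violations are returned as data, one
    human-readable description each, never raised."""
    v: list[str] = []
    n = len(problem.taxonomies)
    if not (MIN_TAXONOMIES <= n <= MAX_TAXONOMIES):
        v.append(f"taxonomy count {n} outside [{MIN_TAXONOMIES}, {MAX_TAXONOMIES}]")
    tags = [t.tag for t in problem.taxonomies]
    for tag in sorted({t for t in tags if tags.count(t) > 1}):
        v.append(f"duplicate taxonomy tag {tag!r}")
    for t in problem.taxonomies:
        for name in t.order:
            if not name:
                v.append(f"taxonomy {t.tag}: empty concept name")
        # cycle check: walk each concept to a root
        for name in t.order:
            seen = {name}
            cur = name
            while cur in t.parent:
                cur = t.parent[cur]
                if cur in seen:
                    v.append(f"{t.tag}.{name} is its own ancestor")
                    break
                seen.add(cur)
        for p, cs in t.children.items():
            if len(cs) != len(set(cs)):
                v.append(f"{t.tag}.{p} lists a repeated child")
        for name, flag in t.covered.items():
            if name not in t.children:
                v.append(f"{t.tag}.{name}: coverage flag on a childless concept")
    for art in problem.articulations:
        if art.left.tag == art.right.tag:
            v.append(f"articulation {art} relates two concepts of taxonomy {art.left.tag}")
        for side in (art.left, art.right):
            if not problem.has_concept(side):
                v.append(f"articulation {art} references undeclared concept {side}")
        if not art.relset:
            v.append(f"articulation {art.left} ? {art.right} has an empty relation set")
    return v
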