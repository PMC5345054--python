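"""Worked alignment inputs reconstructible from published prose.

The *Scelianoma* alignment relates three genus-level classifications of this
Puerto Rican / Hispaniolan weevil genus: the 2009 original description and a
2012 reanalysis each recognise the genus with its single species
*S. elydimorpha*; the 2017 treatment adds the Miocene amber fossil
*S. compacta*, widening the genus circumscription.  Species-level concepts
sharing a name across treatments are asserted congruent; the genus-level
articulations record the 2009/2012 congruence and the wider 2017 concept.
"""

from __future__ import annotations

from .model import AlignmentProblem, Articulation, ConceptLabel, Rel, Taxonomy

__all__ = ["scelianoma_problem", "scelianoma_text"]

_GENUS = "Scelianoma"
_ELY = "Scelianoma_elydimorpha"
_COM = "Scelianoma_compacta"


def scelianoma_problem() -> AlignmentProblem:
    """The three-classification *Scelianoma* alignment (7 concepts,
    16 cross-taxonomy pairs)."""
    t2009 = Taxonomy("2009", "Franz & Giron 2009", {_GENUS: [_ELY]})
    t2012 = Taxonomy("2012", "Franz 2012", {_GENUS: [_ELY]})
    t2017 = Taxonomy("2017", "Franz & Zhang 2017", {_GENUS: [_ELY, _COM]})
    arts = [
        Articulation(
            ConceptLabel("2009", _GENUS), ConceptLabel("2012", _GENUS), frozenset({Rel.EQ})
        ),
        Articulation(
            ConceptLabel("2009", _ELY), ConceptLabel("2012", _ELY), frozenset({Rel.EQ})
        ),
        Articulation(
            ConceptLabel("2012", _GENUS), ConceptLabel("2017", _GENUS), frozenset({Rel.LT})
        ),
        Articulation(
            ConceptLabel("2012", _ELY), ConceptLabel("2017", _ELY), frozenset({Rel.EQ})
        ),
    ]
    return AlignmentProblem([t2009, t2012, t2017], arts)


def scelianoma_text() -> str:
    """The same alignment in the Euler/X-dialect text format."""
    from .eulerx import write_input

    return write_input(scelianoma_problem())
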