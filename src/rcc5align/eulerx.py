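"""Reading and writing the Euler/X-dialect alignment text format, the MIR
CSV, and DOT graph exports.

File grammar (line oriented; blank lines and ``#`` comments ignored)::

    taxonomy <tag> <title...>
    (<parent> <child1> ... <childN>)     # one or more groups
    (<lone-root>)                        # childless single-concept taxonomy

    articulation <tag1>-<tag2> <title...>
    [<tag1>.<name> <relation> <tag2>.<name>]

Relations are ``equals``, ``includes`` (left properly includes right),
``is_included_in``, ``overlaps``, ``disjoint``, or a braced disjunction
``{includes overlaps}``.  A parent token may carry the prefix ``nc_``,
marking the coverage constraint relaxed for that concept (its region need
not equal the union of its children's regions); the prefix is stripped at
parse time and restored on writing.  Names are ASCII tokens of letters,
digits, underscore and hyphen.
"""

from __future__ import annotations

import csv
import io
import re

from .model import (
    AlignmentProblem,
    Articulation,
    ConceptLabel,
    MergedGraph,
    MIRTable,
    Rel,
    RELATION_KEYWORDS,
    Taxonomy,
    relset_symbol,
    validate_problem,
)

__all__ = [
    "EulerXParseError",
    "parse_input",
    "write_input",
    "write_mir_csv",
    "export_graph",
    "MIR_CSV_HEADER",
]

MIR_CSV_HEADER = ("left", "relation", "right")

_NAME_RE = re.compile(r"^[A-Za-z0-9_-]+$")
_KEYWORD_BY_REL = {v: k for k, v in RELATION_KEYWORDS.items()}


class EulerXParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _check_name(token: str, lineno: int) -> str:
    if not _NAME_RE.match(token):
        raise EulerXParseError(f"illegal name token {token!r}", lineno)
    return token


def _parse_qualified(token: str, lineno: int) -> ConceptLabel:
    if token.count(".") != 1:
        raise EulerXParseError(f"expected tag.name, got {token!r}", lineno)
    tag, name = token.split(".")
    return ConceptLabel(_check_name(tag, lineno), _check_name(name, lineno))


def _parse_relset(tokens: list[str], lineno: int) -> frozenset[Rel]:
    rels = []
    for tok in tokens:
        if tok not in RELATION_KEYWORDS:
            raise EulerXParseError(f"unknown relation keyword {tok!r}", lineno)
        rels.append(RELATION_KEYWORDS[tok])
    if not rels:
        raise EulerXParseError("empty relation disjunction", lineno)
    return frozenset(rels)


def parse_input(text: str) -> AlignmentProblem:
    """Parse an alignment source text into an :class:`AlignmentProblem`.

    Raises :class:`EulerXParseError` (with the offending line number) on any
    grammar or referential error; the returned problem always passes
    :func:`~rcc5align.model.validate_problem`.
    """
    taxonomies: list[Taxonomy] = []
    articulations: list[Articulation] = []
    # state while inside a taxonomy block
    cur_tag: str | None = None
    cur_title = ""
    cur_children: dict[str, list[str]] = {}
    cur_order: list[str] = []
    cur_covered: dict[str, bool] = {}
    art_tags: tuple[str, str] | None = None

    def flush_taxonomy(lineno: int) -> None:
        nonlocal cur_tag
        if cur_tag is None:
            return
        if any(t.tag == cur_tag for t in taxonomies):
            raise EulerXParseError(f"duplicate taxonomy tag {cur_tag!r}", lineno)
        taxonomies.append(
            Taxonomy(cur_tag, cur_title, cur_children, cur_order, cur_covered)
        )
        cur_tag = None

    def mention(name: str) -> None:
        if name not in cur_order:
            cur_order.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("taxonomy"):
            flush_taxonomy(lineno)
            parts = line.split(None, 2)
            if len(parts) < 2:
                raise EulerXParseError("taxonomy line needs a tag", lineno)
            cur_tag = _check_name(parts[1], lineno)
            cur_title = parts[2] if len(parts) > 2 else ""
            cur_children, cur_order, cur_covered = {}, [], {}
        elif line.startswith("("):
            if cur_tag is None:
                raise EulerXParseError("concept group outside a taxonomy block", lineno)
            if not line.endswith(")"):
                raise EulerXParseError("unterminated concept group", lineno)
            tokens = line[1:-1].split()
            if not tokens:
                raise EulerXParseError("empty concept group", lineno)
            parent = tokens[0]
            covered = True
            if parent.startswith("nc_"):
                parent = parent[3:]
                covered = False
            _check_name(parent, lineno)
            children = [_check_name(t, lineno) for t in tokens[1:]]
            if not children and not covered:
                raise EulerXParseError("'nc_' prefix on a childless concept", lineno)
            if parent in cur_children:
                raise EulerXParseError(f"concept {parent!r} declared twice as parent", lineno)
            if len(children) != len(set(children)):
                raise EulerXParseError(f"parent {parent!r} lists a repeated child", lineno)
            mention(parent)
            for c in children:
                mention(c)
            if children:
                cur_children[parent] = children
                cur_covered[parent] = covered
        elif line.startswith("articulation"):
            flush_taxonomy(lineno)
            parts = line.split(None, 2)
            if len(parts) < 2 or "-" not in parts[1]:
                raise EulerXParseError("articulation line needs tag1-tag2", lineno)
            t1, _, t2 = parts[1].partition("-")
            art_tags = (_check_name(t1, lineno), _check_name(t2, lineno))
        elif line.startswith("["):
            flush_taxonomy(lineno)
            if art_tags is None:
                raise EulerXParseError("articulation outside an articulation block", lineno)
            if not line.endswith("]"):
                raise EulerXParseError("unterminated articulation", lineno)
            body = line[1:-1].strip()
            m = re.match(r"^(\S+)\s+(\{[^}]*\}|\S+)\s+(\S+)$", body)
            if not m:
                raise EulerXParseError(f"malformed articulation {line!r}", lineno)
            left = _parse_qualified(m.group(1), lineno)
            rel_tok = m.group(2)
            if rel_tok.startswith("{"):
                relset = _parse_relset(rel_tok[1:-1].split(), lineno)
            else:
                relset = _parse_relset([rel_tok], lineno)
            right = _parse_qualified(m.group(3), lineno)
            if (left.tag, right.tag) != art_tags:
                raise EulerXParseError(
                    f"articulation tags {left.tag}/{right.tag} do not match block "
                    f"header {art_tags[0]}-{art_tags[1]}",
                    lineno,
                )
            articulations.append(Articulation(left, right, relset))
        else:
            raise EulerXParseError(f"unrecognized line {line!r}", lineno)
    flush_taxonomy(len(text.splitlines()) + 1)

    problem = AlignmentProblem(taxonomies, articulations)
    by_tag = {t.tag for t in taxonomies}
    for art in articulations:
        for side in (art.left, art.right):
            if side.tag not in by_tag or not problem.has_concept(side):
                raise EulerXParseError(f"articulation references undeclared concept {side}", 0)
    violations = validate_problem(problem)
    if violations:
        raise EulerXParseError("; ".join(violations), 0)
    return problem


def write_input(problem: AlignmentProblem) -> str:
    """Serialize a problem; ``parse_input(write_input(p)) == p`` holds for
    every valid problem."""
    violations = validate_problem(problem)
    if violations:
        raise ValueError("invalid problem: " + "; ".join(violations))
    lines: list[str] = []
    for tax in problem.taxonomies:
        header = f"taxonomy {tax.tag}"
        if tax.title:
            header += f" {tax.title}"
        lines.append(header)
        emitted_children: set[str] = set()
        for name in tax.order:
            if name in tax.children:
                token = name if tax.covered.get(name, True) else f"nc_{name}"
                lines.append("(" + " ".join([token] + tax.children[name]) + ")")
                emitted_children.update(tax.children[name])
            elif name not in tax.parent:
                lines.append(f"({name})")
        lines.append("")
    # a new block starts whenever the tag pair changes, so the original
    # articulation order is preserved exactly through a round trip
    prev_pair: tuple[str, str] | None = None
    for art in problem.articulations:
        pair = (art.left.tag, art.right.tag)
        if pair != prev_pair:
            if prev_pair is not None:
                lines.append("")
            lines.append(f"articulation {pair[0]}-{pair[1]}")
            prev_pair = pair
        rels = [r for r in (Rel.EQ, Rel.GT, Rel.LT, Rel.OV, Rel.DJ) if r in art.relset]
        if len(rels) == 1:
            rel_tok = _KEYWORD_BY_REL[rels[0]]
        else:
            rel_tok = "{" + " ".join(_KEYWORD_BY_REL[r] for r in rels) + "}"
        lines.append(f"[{art.left} {rel_tok} {art.right}]")
    lines.append("")
    return "\n".join(lines)


def write_mir_csv(table: MIRTable) -> str:
    """Render a MIR table as CSV with header ``left,relation,right``; relation
    sets use the RCC-5 symbols, braced when ambiguous (e.g. ``{< ><}``)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(MIR_CSV_HEADER)
    for row in table.rows:
        writer.writerow([str(row.left), relset_symbol(row.relset), str(row.right)])
    return buf.getvalue()


def export_graph(obj: AlignmentProblem | MergedGraph, mode: str = "input") -> str:
    """DOT text for either the input visualization (one node per concept,
    solid parent-child edges, dashed articulation edges labelled with their
    RCC-5 symbols) or the alignment visualization (one node per congruence
    class, solid inferred-inclusion edges, dashed overlap edges)."""
    if mode == "input":
        if not isinstance(obj, AlignmentProblem):
            raise TypeError("input mode expects an AlignmentProblem")
        return _export_input(obj)
    if mode == "alignment":
        if not isinstance(obj, MergedGraph):
            raise TypeError("alignment mode expects a MergedGraph")
        return _export_alignment(obj)
    raise ValueError(f"unknown mode {mode!r}")


def _quote(s: str) -> str:
    return '"' + s.replace('"', '\\"') + '"'


def _export_input(problem: AlignmentProblem) -> str:
    lines = ["digraph input {"]
    for tax in problem.taxonomies:
        for name in tax.preorder():
            lines.append(f"  {_quote(f'{tax.tag}.{name}')};")
    for tax in problem.taxonomies:
        for p, cs in tax.children.items():
            for c in cs:
                lines.append(
                    f"  {_quote(f'{tax.tag}.{p}')} -> {_quote(f'{tax.tag}.{c}')} [style=solid];"
                )
    for art in problem.articulations:
        lines.append(
            f"  {_quote(str(art.left))} -> {_quote(str(art.right))} "
            f"[style=dashed, color=magenta, label={_quote(relset_symbol(art.relset))}];"
        )
    lines.append("}")
    return "\n".join(lines)


def _class_label(cls: frozenset) -> str:
    return "\\n".join(sorted(str(m) for m in cls))


def _export_alignment(graph: MergedGraph) -> str:
    lines = ["digraph alignment {"]
    for i, cls in enumerate(graph.classes):
        style = "shape=box, style=rounded" if len(cls) > 1 else "shape=ellipse"
        lines.append(f"  n{i} [label={_quote(_class_label(cls))}, {style}];")
    for u, v in graph.inclusion_edges:
        lines.append(f"  n{u} -> n{v} [style=solid];")
    for u, v in graph.overlap_edges:
        lines.append(f"  n{u} -> n{v} [style=dashed, color=blue, dir=none];")
    lines.append("}")
    return "\n".join(lines)
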