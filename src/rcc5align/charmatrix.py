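"""Cladistic character matrices: parsing, coded-coverage statistics,
diagnostic state-combination queries, and morphometric ratio checks.

Cells are single symbols: digit states ``0``-``9``, ``?`` for missing
information, ``-`` for inapplicable.  Characters are indexed 1-based
throughout, following the usual presentation of such matrices.  ``-`` counts
as assessed for coverage statistics (the character was examined and found
inapplicable) but never matches a state in a diagnostic query.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

__all__ = [
    "CharacterMatrix",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "coded_stats",
    "CodedStats",
    "diagnostic_match",
    "ratio_check",
    "fossil_matrix",
    "FOSSIL_TAXA",
]

_LEGAL = set("0123456789?-")


class MatrixParseError(ValueError):
    pass


@dataclass
class CharacterMatrix:
    """Taxa × characters table of discrete state codings."""

    taxa: list[str]
    rows: dict[str, str]  # taxon -> length-n_chars symbol string

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise MatrixParseError("rows have unequal lengths")
        for taxon, row in self.rows.items():
            bad = set(row) - _LEGAL
            if bad:
                raise MatrixParseError(f"illegal symbols {sorted(bad)} in row for {taxon!r}")

    @property
    def n_chars(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def cell(self, taxon: str, char_index: int) -> str:
        """The coding of ``taxon`` for the 1-based ``char_index``."""
        if not 1 <= char_index <= self.n_chars:
            raise IndexError(f"character index {char_index} outside 1..{self.n_chars}")
        return self.rows[taxon][char_index - 1]

    def subset(self, taxa: Sequence[str]) -> "CharacterMatrix":
        missing = [t for t in taxa if t not in self.rows]
        if missing:
            raise KeyError(f"unknown taxa: {missing}")
        return CharacterMatrix(list(taxa), {t: self.rows[t] for t in taxa})


def read_matrix(text: str) -> CharacterMatrix:
    """Parse a NONA/Hennig86-style ``.ss`` source or the tab-separated
    dialect (auto-detected: any tab on a data line means TSV)."""
    stripped = [ln for ln in text.splitlines() if ln.strip() and not ln.strip().startswith("#")]
    if any("\t" in ln for ln in stripped):
        return _read_tsv(stripped)
    return _read_ss(stripped)


def _read_tsv(lines: list[str]) -> CharacterMatrix:
    taxa: list[str] = []
    rows: dict[str, str] = {}
    for ln in lines:
        fields = [f.strip() for f in ln.split("\t")]
        if not taxa and fields[0].lower() in ("taxon", "label", "taxon/character", "label / character"):
            continue  # header row of character indices
        name, cells = fields[0], fields[1:]
        if len(cells) == 1 and len(cells[0]) > 1:
            row = cells[0]  # single column holding the full coding string
        else:
            for c in cells:
                if len(c) != 1:
                    raise MatrixParseError(f"multi-symbol cell {c!r} in row for {name!r}")
            row = "".join(cells)
        if name in rows:
            raise MatrixParseError(f"duplicate taxon {name!r}")
        taxa.append(name)
        rows[name] = row
    if not rows:
        raise MatrixParseError("no data rows")
    return _finish(taxa, rows, expected=None)


def _read_ss(lines: list[str]) -> CharacterMatrix:
    i = 0
    if i < len(lines) and lines[i].strip().lower().startswith("xread"):
        i += 1
    if i < len(lines) and lines[i].strip().startswith(("'", '"')):
        i += 1  # optional quoted title
    header = lines[i].split() if i < len(lines) else []
    if len(header) != 2 or not all(tok.isdigit() for tok in header):
        raise MatrixParseError("expected header line '<n_chars> <n_taxa>'")
    n_chars, n_taxa = int(header[0]), int(header[1])
    i += 1
    taxa: list[str] = []
    rows: dict[str, str] = {}
    for ln in lines[i:]:
        ln = ln.strip()
        if ln == ";":
            break
        if ln.endswith(";"):
            ln = ln[:-1].strip()
        parts = ln.split()
        if not parts:
            continue
        name = parts[0]
        row = "".join(parts[1:])
        if name in rows:
            raise MatrixParseError(f"duplicate taxon {name!r}")
        taxa.append(name)
        rows[name] = row
    if len(taxa) != n_taxa:
        raise MatrixParseError(f"header declares {n_taxa} taxa, found {len(taxa)}")
    return _finish(taxa, rows, expected=n_chars)


def _finish(taxa: list[str], rows: dict[str, str], expected: int | None) -> CharacterMatrix:
    lengths = {t: len(r) for t, r in rows.items()}
    ref = expected if expected is not None else lengths[taxa[0]]
    for t, n in lengths.items():
        if n != ref:
            raise MatrixParseError(f"row for {t!r} has {n} cells, expected {ref}")
    return CharacterMatrix(taxa, rows)


def write_matrix(matrix: CharacterMatrix, fmt: str = "ss") -> str:
    """Serialize as NONA-style ``.ss`` (default) or TSV."""
    if fmt == "ss":
        lines = ["xread", f"{matrix.n_chars} {len(matrix.taxa)}"]
        lines += [f"{t} {matrix.rows[t]}" for t in matrix.taxa]
        lines.append(";")
        return "\n".join(lines) + "\n"
    if fmt == "tsv":
        header = "taxon\t" + "\t".join(str(i) for i in range(1, matrix.n_chars + 1))
        lines = [header]
        lines += [t + "\t" + "\t".join(matrix.rows[t]) for t in matrix.taxa]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


@dataclass
class CodedStats:
    """Coverage of the coded character range for a set of taxa.

    ``max_coded_index`` is the highest 1-based character for which any
    selected taxon has a non-missing cell (inapplicable counts as assessed);
    ``percent_of_total`` relates that index to the matrix width, rounded
    half-up to one decimal. ``coded_counts`` gives the strict per-taxon count
    of non-missing cells, which can be smaller than the coded range when
    internal characters are missing.
    """

    max_coded_index: int
    coded_counts: dict[str, int]
    percent_of_total: float


def coded_stats(matrix: CharacterMatrix, taxa: Sequence[str] | None = None) -> CodedStats:
    selected = list(matrix.taxa) if taxa is None else list(taxa)
    if not selected:
        raise ValueError("empty taxon set")
    sub = matrix.subset(selected)
    max_idx = 0
    for i in range(sub.n_chars, 0, -1):
        if any(sub.cell(t, i) != "?" for t in selected):
            max_idx = i
            break
    counts = {t: sum(1 for c in sub.rows[t] if c != "?") for t in selected}
    if sub.n_chars:
        pct = Decimal(max_idx * 100) / Decimal(sub.n_chars)
        percent = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    else:
        percent = 0.0
    return CodedStats(max_idx, counts, percent)


def diagnostic_match(
    matrix: CharacterMatrix, assignments: Mapping[int, int | str]
) -> list[str]:
    """Taxa whose coding equals the queried state at every queried 1-based
    character; missing and inapplicable cells never match.  An empty query
    matches every taxon."""
    for idx in assignments:
        if not 1 <= idx <= matrix.n_chars:
            raise IndexError(f"character index {idx} outside 1..{matrix.n_chars}")
    out = []
    for t in matrix.taxa:
        if all(matrix.cell(t, idx) == str(state) for idx, state in assignments.items()):
            out.append(t)
    return out


def ratio_check(numerator: float, denominator: float) -> float:
    """Length/width-style ratio, rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    r = Decimal(str(numerator)) / Decimal(str(denominator))
    return float(r.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# the three Miocene amber fossil codings (143 characters each)

FOSSIL_TAXA = (
    "Scelianoma_compacta",
    "Tropirhinus_palpebratus",
    "Diaprepes_anticus",
)

# transcribed table blocks; one tuple of space-separated token rows per taxon
_FOSSIL_BLOCKS: dict[str, tuple[str, ...]] = {
    "Scelianoma_compacta": (
        "0 0 2 0 0 0 1 0 0 0 0 0 0 0 0 0 - 1 0 0 0 0 0 0 0",        # 1-25
        "1 0 0 0 0 0 0 0 1 1 0 0 0 0 0 0 0 0 0 0 - - 0 ? ?",        # 26-50
        "0 0 0 0 0 0 0 2 0 0 0 1 0 0 0 1 0 0 0 0 - - 0 - 0",        # 51-75
        "0 0 0 0 0 - - 1 - - 0 0 0 ? ? ? ? ? ? ? ? ? ? ? ?",        # 76-100
        "? " * 24 + "?",                                             # 101-125
        "? " * 17 + "?",                                             # 126-143
    ),
    "Tropirhinus_palpebratus": (
        "0 0 2 0 0 0 1 0 1 0 0 0 0 0 0 1 0 0 0 0 0 0 1 0 0",
        "0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 - - 0 ? ?",
        "0 0 0 0 0 0 0 2 0 0 0 0 0 0 0 0 1 0 0 0 - - 0 - 0",
        "0 0 0 0 0 0 0 ? ? ? 0 0 0 ? ? ? ? ? ? ? ? ? ? ? ?",
        "? " * 24 + "?",
        "? " * 17 + "?",
    ),
    "Diaprepes_anticus": (
        "0 0 2 0 0 0 1 0 0 0 0 0 0 1 0 1 1 0 0 0 0 0 0 0 0",
        "0 0 1 2 0 0 0 0 0 0 0 0 0 0 0 0 0 0 0 1 - - 0 ? ?",
        "0 0 0 0 0 0 0 2 0 0 0 0 0 0 0 0 0 0 0 0 - - 0 - 0",
        "0 0 0 0 0 - - 0 0 0 1 0 0 ? ? ? ? ? ? ? ? ? ? ? ?",
        "? " * 24 + "?",
        "? " * 17 + "?",
    ),
}


def fossil_matrix() -> CharacterMatrix:
    """The character codings of the three Dominican-amber fossil weevils
    against the 143-character entimine matrix (the fossil rows only)."""
    rows = {}
    for taxon in FOSSIL_TAXA:
        row = "".join("".join(block.split()) for block in _FOSSIL_BLOCKS[taxon])
        assert len(row) == 143, (taxon, len(row))
        rows[taxon] = row
    return CharacterMatrix(list(FOSSIL_TAXA), rows)
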