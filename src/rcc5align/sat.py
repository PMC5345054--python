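"""A small propositional satisfiability solver (iterative DPLL with
two-watched literals and chronological backtracking).

The alignment encodings this package produces are shallow: at-least-one
clauses over place-occupancy variables, negative units from asserted-empty
zones, and implication chains from articulation selectors, so DPLL with unit
propagation handles them comfortably.  The solver is persistent: the base
formula is loaded once and each :meth:`solve` call may add assumption
literals and temporary clauses that are retracted afterwards, which keeps
repeated satisfiability probes (the MIR loop) cheap.

Literals follow DIMACS convention: variable ``v`` > 0, negation ``-v``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

__all__ = ["Solver", "solve_cnf"]


class Solver:
    def __init__(self, n_vars: int):
        self.n_vars = n_vars
        self.clauses: list[list[int]] = []
        self.watches: dict[int, list[int]] = {}
        self._units: list[int] = []
        self._trivially_unsat = False
        self._order: list[int] | None = None

    def _intern(self, lits: Iterable[int]) -> list[int] | None:
        """Deduplicate; None for tautologies."""
        seen: set[int] = set()
        out: list[int] = []
        for lit in lits:
            if lit == 0 or abs(lit) > self.n_vars:
                raise ValueError(f"literal {lit} out of range")
            if -lit in seen:
                return None
            if lit not in seen:
                seen.add(lit)
                out.append(lit)
        return out

    def add_clause(self, lits: Iterable[int]) -> None:
        out = self._intern(lits)
        if out is None:
            return
        if not out:
            self._trivially_unsat = True
        elif len(out) == 1:
            self._units.append(out[0])
        else:
            ci = len(self.clauses)
            self.clauses.append(out)
            self.watches.setdefault(out[0], []).append(ci)
            self.watches.setdefault(out[1], []).append(ci)
        self._order = None

    def add_clauses(self, clauses: Iterable[Sequence[int]]) -> None:
        for c in clauses:
            self.add_clause(c)

    def _branch_order(self) -> list[int]:
        # static: most frequent variables first
        if self._order is None:
            freq = [0] * (self.n_vars + 1)
            for clause in self.clauses:
                for lit in clause:
                    freq[abs(lit)] += 1
            self._order = sorted(range(1, self.n_vars + 1), key=lambda v: -freq[v])
        return self._order

    def solve(
        self,
        assumptions: Iterable[int] = (),
        temp_clauses: Iterable[Sequence[int]] = (),
    ) -> list[bool] | None:
        """Return an assignment indexed 1..n_vars (index 0 unused), or None.

        ``assumptions`` are literals forced before search; ``temp_clauses``
        are clauses active for this call only.
        """
        if self._trivially_unsat:
            return None
        order = self._branch_order()

        # install temporary clauses (retracted in finally)
        temp_ids: list[int] = []
        temp_units: list[int] = []
        temp_unsat = False
        for c in temp_clauses:
            out = self._intern(c)
            if out is None:
                continue
            if not out:
                temp_unsat = True
            elif len(out) == 1:
                temp_units.append(out[0])
            else:
                ci = len(self.clauses)
                self.clauses.append(out)
                self.watches.setdefault(out[0], []).append(ci)
                self.watches.setdefault(out[1], []).append(ci)
                temp_ids.append(ci)
        try:
            if temp_unsat:
                return None
            return self._search(list(assumptions) + temp_units, order)
        finally:
            for ci in reversed(temp_ids):
                clause = self.clauses[ci]
                self.watches[clause[0]].remove(ci)
                self.watches[clause[1]].remove(ci)
                self.clauses.pop()

    def _search(self, forced: list[int], order: list[int]) -> list[bool] | None:
        n = self.n_vars
        clauses = self.clauses
        watches = self.watches
        assign = [0] * (n + 1)  # 0 unassigned, +1 true, -1 false
        trail: list[int] = []
        qhead = 0
        decisions: list[list] = []  # [trail mark, decided literal, flipped?]

        def value(lit: int) -> int:
            a = assign[abs(lit)]
            if a == 0:
                return 0
            return a if lit > 0 else -a

        def enqueue(lit: int) -> bool:
            v = value(lit)
            if v == -1:
                return False
            if v == 0:
                assign[abs(lit)] = 1 if lit > 0 else -1
                trail.append(lit)
            return True

        def propagate() -> bool:
            nonlocal qhead
            while qhead < len(trail):
                lit = trail[qhead]
                qhead += 1
                false_lit = -lit
                ws = watches.get(false_lit)
                if not ws:
                    continue
                watches[false_lit] = keep = []
                i, m = 0, len(ws)
                while i < m:
                    ci = ws[i]
                    i += 1
                    clause = clauses[ci]
                    if clause[0] == false_lit:
                        clause[0], clause[1] = clause[1], clause[0]
                    first = clause[0]
                    if value(first) == 1:
                        keep.append(ci)
                        continue
                    for k in range(2, len(clause)):
                        if value(clause[k]) != -1:
                            clause[1], clause[k] = clause[k], clause[1]
                            watches.setdefault(clause[1], []).append(ci)
                            break
                    else:
                        keep.append(ci)
                        if not enqueue(first):
                            keep.extend(ws[i:])
                            return False
                continue
            return True

        for u in self._units:
            if not enqueue(u):
                return None
        for u in forced:
            if not enqueue(u):
                return None
        while True:
            if propagate():
                branch_var = 0
                for v in order:
                    if assign[v] == 0:
                        branch_var = v
                        break
                if branch_var == 0:
                    return [False] + [assign[v] == 1 for v in range(1, n + 1)]
                # positive polarity first: occupancy constraints are mostly
                # at-least-one clauses, satisfied by occupying places
                decisions.append([len(trail), branch_var, False])
                enqueue(branch_var)
            else:
                while decisions and decisions[-1][2]:
                    decisions.pop()
                if not decisions:
                    return None
                mark, lit, _ = decisions[-1]
                for undone in trail[mark:]:
                    assign[abs(undone)] = 0
                del trail[mark:]
                qhead = mark
                decisions[-1] = [mark, -lit, True]
                enqueue(-lit)


def solve_cnf(
    clauses: Iterable[Sequence[int]], n_vars: int, extra: Iterable[Sequence[int]] = ()
) -> list[bool] | None:
    """One-shot convenience wrapper; returns the assignment or None."""
    s = Solver(n_vars)
    s.add_clauses(clauses)
    return s.solve(temp_clauses=extra)
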