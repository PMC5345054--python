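# Methods

## Model

An alignment problem consists of 2–5 taxonomies (forests of concepts, each
concept one treatment's usage of a name) over an implicit shared region
universe, plus cross-taxonomy articulations.  Each articulation asserts a
nonempty subset of the five RCC-5 base relations between two concepts; a
singleton set is a definite assertion, a larger set a disjunction.

Semantics are finite-model.  The joint partition of all taxonomies is
represented by *places*: one slot per taxonomy, where a slot is either a
childless concept, the coverage gap of a non-covered parent, or "outside"
the taxonomy.  A possible world assigns nonempty/empty to every place such
that every concept's region (the union of the places under it) is nonempty
and every articulation holds.  Three structural assumptions are built into
this encoding:

- **Sibling disjointness** — children of one parent denote disjoint regions.
  Standard in this alignment framework; exposed as a flag
  (`sibling_disjointness=False` replaces atomic slots with arbitrary
  nonempty slot subsets, at exponential cost in slot count).
- **Coverage** — a parent's region equals the union of its children's
  regions, unless the parent is flagged non-covered (`nc_` in the text
  format), in which case a dedicated gap place lets it hold an unsampled
  residue.  Coverage is the default because relaxations are the marked
  exception in practice.
- **Nonemptiness** — every concept denotes a nonempty region; outside and
  gap places are optional.  Only childless concepts need explicit
  nonemptiness constraints (every concept dominates some leaf).

The three-zone classification (A∖B, A∩B, B∖A empty or not) maps occupancy
onto exactly one base relation for any two nonempty regions; the five legal
zone signatures are the JEPD property the test suite checks exhaustively on
universes of up to four atoms.

## Reasoning backends

Two interchangeable backends answer every satisfiability question and are
required to agree:

- **brute** (reference): enumerate all `2^n − 1` occupancy assignments with
  vectorised numpy mask arithmetic, filter by nonemptiness and
  articulations.  Exact and fast up to ~16 places; refused above 24.
- **sat** (production): one propositional variable per place; nonemptiness
  becomes at-least-one clauses, a definite articulation becomes per-zone
  constraints (empty zone → negative units, required-nonempty zone → one
  positive clause), and a disjunctive articulation gets one selector
  variable per disjunct with an at-least-one clause over selectors.  The
  solver is a small iterative DPLL with two-watched literals, chronological
  backtracking, a static most-frequent-variable order and positive polarity
  first (occupying places satisfies the dominant at-least-one clauses).  It
  is persistent: the base formula is loaded once and each probe adds only
  assumption literals and temporary clauses, retracted afterwards.

`auto` picks brute at ≤ 16 places.  MIR computation probes, for each
cross-taxonomy pair and each base relation not yet witnessed, whether the
problem plus that relation is satisfiable.  Every model found fixes the
induced relation of *all* pairs at once and is absorbed into the table,
which removes most satisfiable probes; the unavoidable cost is the
unsatisfiable probes (at most four per fully resolved pair).  The reasoner
is entirely deterministic: canonical concept order is taxonomy input order
then preorder, relations are probed in the fixed order `==, >, <, ><, !`,
and no randomness exists anywhere in the reasoning path.

**Possible worlds** are reported as distinct induced-relation patterns over
the cross pairs, not as raw models (occupancy of optional places would
otherwise multiply counts meaninglessly).  The satisfiability backend
enumerates patterns by depth-first search over per-pair relation choices
drawn from the MIR sets, pruning unsatisfiable prefixes; a cap bounds the
pattern count and marks truncation.

**Inconsistency reports** reduce the articulation list by iterative
deletion to a subset that is still unsatisfiable together with the taxonomy
structure — minimal in the sense that removing any single member restores
satisfiability, not guaranteed minimum.

## Merged graph

Congruence classes are the connected components of the relation "MIR is
exactly `{==}`"; classes are ordered by their first member in canonical
order.  Class-level proper inclusion comes from singleton `{>}`/`{<}` rows
and from within-taxonomy parenthood, transitively reduced (networkx);
overlap edges come from singleton `{><}` rows.  Ambiguous rows contribute
no edge.  A covered parent with a single child is extensionally congruent
with that child, so such parent–child arcs fall inside one class and are
dropped rather than treated as inclusion; a `{>}` row inside a class, by
contrast, cannot arise from a sound solver and triggers an internal error.
One consequence worth knowing: in the *Scelianoma* example the earlier
genus class also contains the species concepts congruent with it, because
each pre-2017 genus concept covers exactly its single species.

## Synthetic worlds

The generator draws, per taxonomy, a wide random subset of a shared atom
universe as the root region (each atom kept with probability 0.9, so roots
of different treatments usually overlap — as genus circumscriptions do) and
recursively partitions it: any concept with ≥ 2 atoms above the depth bound
splits into 2–`max_children` random blocks; with probability `p_gap` a
nonempty residue is withheld first and the parent marked non-covered.
Nonemptiness and sibling disjointness therefore hold by construction, so
these tests exercise the reasoner, not the generator.  Every concept's atom
set is retained, giving the true relation of every cross pair by direct set
comparison; emitted problems articulate a seeded random fraction of pairs
with their true singleton relations.  A single seeded `random.Random`
drives everything; equal seeds give byte-identical outputs.

What the generator does *not* emulate: name reuse across treatments (names
are opaque and taxonomy-local), nomenclatural synonymy text, misspellings,
and expert articulation errors (emitted articulations are always true of
the generating world, except for the explicit single-contradiction
injector).  Passing recovery tests therefore show the reasoner is sound and
complete relative to its region semantics, not that real expert input is
error-free.

## Character matrix conventions

Characters are 1-based.  `?` is missing information; `-` is inapplicable
and counts as *assessed* for coverage statistics but never matches a state
in diagnostic queries.  The coded-coverage statistic reports the highest
character index any selected taxon has assessed (the "coded range" — for
the three fossil rows, 88 of 143, i.e. 61.5%) alongside strict per-taxon
counts of non-missing cells (86/83/86), which differ because characters
49–50 are unknown in all three rows.  Percentages and morphometric ratios
round half-up to one decimal.  The fossil codings are embedded as the
printed table blocks and re-assembled at call time; `.ss` (NONA-style) and
TSV serializations parse back identically.

## Sizes and tolerances used in the test suite

- Oracle equivalence: 200 generated two-taxonomy problems filtered to ≤ 16
  places, mixing articulation densities 0–1, disjunctive articulations and
  injected inconsistencies; brute and sat tables must match exactly.
- Recovery: 104 seeded specs cycling 2–5 taxonomies, universes of 5–7
  atoms, depth 2 for ≤ 3 taxonomies and 1 otherwise, `p_gap` 0.2,
  densities cycling {0, 0.4, 0.7, 1}.  These sizes keep the joint
  partition in the hundreds of places, which the satisfiability backend
  solves in well under a second per problem while still spanning the full
  taxonomy-count range.
- All comparisons are exact (set equality, integer counts); the only
  tolerances anywhere are the one-decimal half-up roundings defined above.

## Limitations

- The DPLL solver has no clause learning; pathological encodings (e.g.
  pigeonhole-like structures) would degrade it, but alignment encodings are
  shallow and have not come close to that in practice.  Place counts scale
  multiplicatively with taxonomy breadth; the configurable cap (default
  10⁶) aborts cleanly rather than thrash.
- Within-taxonomy concept pairs are not part of MIR output (cross-taxonomy
  only), matching the published row counts.
- The world-pattern count is patterns-up-to-induced-relations; it is not
  claimed to equal model counts reported by other toolkits.
- Answer-set-programming–style repair lattices and ambiguity resolution are
  out of scope.
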