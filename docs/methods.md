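# Methods

## Fragmentation model

A matched molecular pair (MMP) is a pair of compounds differing at a
single site. The package realizes the standard single-cut convention:
eligible bonds are acyclic single bonds between two heavy atoms (no ring,
double, or aromatic bonds; never the bond to an existing attachment
point). Each cut splits a molecule into a key (core) and a value
(substituent); the smaller piece is the value, with ties broken toward the
lexicographically smaller canonical notation so results are deterministic.
Attachment points are mapped wildcard atoms (`[*:1]`, second-step cuts add
`[*:2]`), which makes reassembly unambiguous: `reassemble(key, value)`
reconstructs exactly the parent graph, and the test suite asserts this for
every cut of randomly assembled molecules.

Two size caps keep "analog" semantics and are deliberately configurable
because no single convention is canonical:

| parameter | default | meaning |
|---|---|---|
| `max_value_fraction` | 0.5 | value ≤ 50% of the parent's heavy atoms |
| `max_distinguishing_fraction` | 1/3 | second-step distinguishing fragment ≤ 33% of the core's heavy atoms |

A cut producing a bare hydrogen cannot arise (both bond atoms are heavy);
H-analogs participate only as library compounds. Stereodescriptors are
retained by default (`keep_stereo=True`) so stereoisomers occupy distinct
cells; a flag strips them for stereo-insensitive analyses. No structure
standardization (salt stripping, tautomer canonicalization) is applied —
that is the caller's responsibility and is documented as out of scope.

## Matrix construction

Matrices are keyed by the shared second-step scaffold, not by connected
components of the core-relation graph: scaffold keying is deterministic,
and avoids chaining structurally dissimilar cores through intermediate
relatives. Consequently a core appears in one matrix per scaffold it
yields. Rows and columns are sorted by canonical notation and matrix ids
follow sorted scaffold order, so identical inputs give byte-identical
outputs. Matrices need at least two rows and two columns; a cell claimed
by two distinct compounds (identical molecules under different ids) is an
error rather than a silent merge, since it signals an upstream data
problem.

On symmetric scaffolds (e.g. para-disubstituted benzene) the two cut
orientations produce isomorphic labelled scaffolds, so both analog
directions merge into one larger matrix. This is correct systematics — the
merged matrix simply contains more virtual cells.

**Row overlap** is the mean over rows of the fraction of a row's filled
columns also filled in at least one other row. The quantitative definition
is declared here (the qualitative notion — shared substitution patterns —
admits variants), and the informative-matrix filter keeps matrices with
overlap strictly above `min_overlap` (default 0.5) and at least
`min_compounds` (default 5) filled cells. Both thresholds are exposed
because the operational choice is data-set dependent.

## Neighborhood potency prediction

Free-Wilson additivity assumes log-scale potency decomposes into
independent core and substituent contributions; potencies must therefore
be on a negative-log-molar scale (pIC50-like) — converting raw IC50s is
upstream work. All qualifying (D, E, G) triples across all matrices are
pooled into a single mean and population SD (a per-matrix-then-grand mean
is not taken); duplicate triples recurring in several matrices are counted
once, keyed by their id triple. A single-triple prediction reports SD 0.
No applicability-domain gate is applied: SD and neighborhood count are
reported and filtering is the caller's decision, since SD is an indicator
of SAR discontinuity rather than a hard rule. Predictions for VCs in
non-informative matrices are included by default for the same reason.

## Conditional-probability activity prediction

The classifier follows the five steps described in the README. Numerical
choices:

- **Smoothing** α defaults to 0.1; contributions are
  `(α + Σw) / (2α + N)`, so an unobserved fragment/class combination
  contributes `α / (2α + N) > 0` and no zero division can occur.
- **All intermediate math is unrounded.** Two-decimal values appear only
  at display time via `display_value`, which floors at the third decimal
  (1.125 → 1.12, 0.7659 → 0.76). Reference tabulations of this worked
  example elsewhere mix floor- and round-to-nearest display; the exact
  fractions (e.g. normalized c3 probabilities 1.1/4.7 and 3.6/4.7) are the
  authoritative values and the tests assert them to 1e−12.
- **Cross-matrix aggregation** of a VC occurring in several informative
  matrices is the arithmetic mean of per-matrix probabilities (mirroring
  the neighborhood module's pooling); `strategy="max"` is available since
  an optimistic aggregation is sometimes preferred for hit expansion.
- **Classification threshold** defaults to 0.5 and is exposed; operational
  campaigns typically choose stricter values to shortlist candidates.

Useful invariants, all property-tested: fragment probabilities sum to 1;
relabelling active↔inactive maps p_x to 1 − p_x; p_x approaches 0.5
monotonically as α → ∞ (infinite smoothing erases evidence).

## Synthetic libraries and what they do (not) show

`LibraryPlan` generates scaffold × core × value grids with planted truth:

- **Additive potency**: potency = μ + a_core + b_value (+ noise σ on the
  measured channel), defaults μ = 5, a ~ N(0, 0.5), b ~ N(0, 1), σ = 0.3 —
  pIC50-scale magnitudes typical of a lead-optimization data set. Binary
  labels in this mode derive from the noise-free planted potency at
  `active_threshold` (default pPot ≥ 6).
- **Planted activity cliffs**: one cell offset by δ; the cliff cell is
  always included among measured compounds.
- **Planted fragment roles** (`LibraryPlan.binary_screen`): an exact
  fraction of values (30%) and cores (50%) is designated active-driving
  and a compound is active iff both fragments are. This condition uses
  dense matrices (8 cores × 12 values at 80% fill, ~460 compounds):
  the classifier is a per-fragment counting statistic, so in very sparse
  matrices a planted role can be entirely unexpressed in the measured
  cells (an active core observed only with inactive substituents is
  indistinguishable from an inactive one) and a benchmark at such
  sparsity probes identifiability, not the classifier. Prediction
  quality is expected to grow with sample size and matrix density, which
  is exactly why the informative-matrix filter exists.
- **Structural mode** assembles real molecules from two-site ring
  scaffolds with disjoint core/value substituent alphabets (disjointness
  prevents two planned combinations from assembling into the same
  molecule). Test sizes: oracle-equivalence checks use 20 random
  instances of matrices up to 10×10 and libraries of 20–60 molecules;
  recovery and ranking checks use libraries of a few hundred cells.

These generators emulate the combinatorial structure of analog-series
data, not its chemistry: real screens have uneven series sizes, correlated
substituent effects, assay artifacts and non-additive interactions beyond
single planted cliffs. Passing tests therefore demonstrate correctness of
the machinery and behavior under controlled SAR continuity/discontinuity,
not prospective hit rates on real libraries.

## Degenerate inputs and tie-breaks

- Molecules with no eligible bond (single heavy atom, all-ring) yield no
  fragmentation and silently contribute nothing to matrices.
- A 50/50 cut is allowed at the default cap; the value is the
  lexicographically smaller piece.
- Unparseable SMILES are logged and skipped with a count; zero parseable
  rows, missing files and duplicate ids are fatal.
- Virtual compounds occurring in no informative matrix are omitted from
  activity prediction with a logged count.

## Known limitations

- Single-cut fragmentation only; multi-site analog relationships (three
  or more variation points) are represented as separate two-piece
  decompositions rather than higher-order matrices.
- The conditional-probability combination treats core and value evidence
  as independent within a matrix (naive-Bayes-like); strongly interacting
  fragments violate this and are flagged only indirectly (via the NBH
  module's SD on numeric data).
- Scaffold-keyed grouping can place one core in many matrices; downstream
  per-VC aggregation de-duplicates by (core, value), but matrix counts are
  not comparable across grouping conventions.
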