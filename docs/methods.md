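# Methods

## Model and lethality

A model is a stoichiometric matrix S with per-reaction flux bounds
(mmol gDW⁻¹ h⁻¹ by convention), optional gene-protein-reaction (GPR)
boolean rules, and one objective reaction. FBA maximizes objective flux
subject to `S·v = 0` and the bounds; all linear programs go through the
HiGHS solver (`scipy.optimize.linprog`), which is deterministic for a fixed
problem. Reversibility is encoded purely by a negative lower bound;
reactions are never split into forward/backward halves, so a knockout
removes both directions at once.

A knockout set is *lethal* when the optimum of the knocked-out model is at
or below `max(1e-6, 1e-3 × wild-type optimum)`; an infeasible program
counts as lethal. A pure zero test is numerically meaningless in floating
LP, so a threshold is unavoidable; the adaptive form keeps the absolute
floor for models whose objective is O(1) while scaling for models with very
small optima. The threshold is a declared package default
(`AnalysisConfig.lethality_epsilon` overrides it); on the bundled *E. coli*
core model the enumerated lethal sets are identical for any epsilon between
1e-6 absolute and 1% of wild-type growth, so results are not
threshold-brittle at the scales the package targets.

Gene deletions act through the GPR rules. Before gene-level analysis every
rule is canonicalized to its minimal disjunctive normal form (monotone
boolean logic: compute the disjunct sets recursively and drop superset
disjuncts, which yields exactly the prime implicants). The transformation
provably never changes any deletion outcome; it makes enzyme redundancy
explicit and lets the enumerator skip, without an LP call, any gene set
whose disabled-reaction signature was already classified.

## Enumeration

Minimal lethal sets up to level n are found level by level. The pruning
device: let v be a minimum-L1-norm optimal flux distribution of the current
knockout model (objective pinned within a 1e-6 relative slack of its
optimum; support read at |v| > 1e-6). Any reaction outside supp(v) can be
deleted on top of the current set without disturbing v, so only support
members can extend the set toward lethality; at the gene level, only genes
appearing in the GPR of a support reaction can disable one, alone or in
combination. Applying this recursively covers every minimal lethal set:
each such set, ordered suitably, is a chain of support-extending steps.
Candidate sets that contain an already-stored lethal subset are skipped
(that is also the minimality filter — levels are completed in order, so the
stored smaller sets are exhaustive when a larger set is tested). Pruning is
always on; it is sound by the argument above, and the exhaustive
`brute_force_lethal_sets` oracle — combination-budget-guarded — exists
precisely to validate it, which the test suite does on dozens of seeded
random models (both targetings) and which has also been confirmed
pair-for-pair on the bundled core model at level 2.

The candidate universe (the normalization constant X) is all reactions (or
genes) minus the user's exclusion list minus the objective reaction, which
is never a legitimate knockout target. Blocked reactions stay candidates —
they inflate X but never appear in lethal sets, which is the behavior the
normalization needs to stay comparable across models sharing a namespace.
Maintenance pseudo-reactions (e.g. ATP maintenance in the core model)
should be excluded explicitly. Levels above 3 are permitted but warned
about; cost grows roughly with the support-branching factor to the n-th
power. Long runs can checkpoint per level and resume
(`checkpoint_dir`; the checkpoint stores a model/config fingerprint, the
stored sets, and the search frontier).

Determinism: candidates, extensions and stored sets are iterated in
lexicographic order, lethality verdicts are cached by blocked-reaction
signature, and HiGHS is deterministic, so two runs on the same model yield
identical collections regardless of primal degeneracy (only the *support*
of the minimum-norm solution enters the algorithm, and any sound support
yields the same final collection because lethality tests are exact).

## Scoring

`ES_i = y_i1 + Σ_{j≥2} y_ij (j−1)!/X^(j−1)`, with y counted over unordered
minimal sets and the (j−1)! factor applied only in the formula — for one
fixed target, (j−1)! times the unordered count reproduces exactly the
ordered-with-repetition combination count of the X^(j−1) population.
Essential targets score exactly 1 (minimality removes them from all larger
sets). Scores are reported at full float precision; TSV output rounds to 6
decimals. The ≤ 1 bound for non-essential targets holds in every collection
the tests generate; because it is asserted rather than proven here, a
violation emits a warning and reports the raw, unclamped value instead of
hiding the disagreement.

## Topology baselines

MMN/RRN/GGN graphs are built by the production→consumption rule, widened
for reversible reactions. The currency-metabolite list shipped by default
(ATP/ADP/AMP, NAD(P)(H), H₂O, H⁺, CO₂, Pi, PPi, CoA, O₂, matched per
compartment) is applied to RRN/GGN construction; it is fully overridable,
and removing an entry can only add edges. Centralities are computed on the
largest *weakly* connected component (the common convention; it retains
more nodes than strong connectivity), with eccentricity taken on the
undirected view so it stays finite, betweenness unnormalized by default
(rankings are unaffected), and degree = in+out within the component. Nodes
outside the component carry zeros and a flag. Zero/non-zero partitions of
scores against centralities use exact 0.0 on the score side — uninvolved
targets are structurally zero, no epsilon involved. Counts in such
partitions, and any count derived from betweenness, are sensitive to the
currency list and connectivity convention; the shipped defaults are
reasonable, not canonical.

## Model comparison

`compare_escores` aligns two score tables, computes deltas (b − a) and
classifies each target as up/down/unchanged at a 1e-9 tolerance. A mutant
built by *removing* a reaction loses that reaction from its own table (and
its X shrinks by one); the carry-over mechanism copies the wild-type score
for the removed reaction into the mutant table before deltas are taken so
the removal itself does not register as a change. Up/down counts of such
comparisons inherit every convention above (candidate universe, epsilon,
minimality), so they are reproducible within the package but only
approximately portable across independent implementations. Spearman rank
correlation (average ranks for ties, two-sided t-approximation p-value) is
provided for benchmarking score vectors against external ones; the
p-value method is a declared choice.

## Synthetic models

The generator realizes a requested minimal-lethal structure as a chain of
mass-balanced segments with unit stoichiometry and uptake bound 10: serial
segments (essential singletons), k-way parallel bundles (cardinality-k
minimal sets), skip-over-series motifs (families of pairs sharing a hub
member), blocked dead-end decoys to pad X, and optional randomized GPRs
(single genes, isozyme pairs, complexes, shared enzymes). Segment order and
decoy placement derive from the seed; the same spec + seed yields an
identical serialization. Overlap patterns other than disjoint groups and
shared-hub pair families are rejected rather than realized incorrectly. At
build time the generator re-derives the realized structure with the
exhaustive oracle and refuses to return a model that deviates from its
specification.

What these fixtures emulate is the *lethal-set combinatorics* of metabolic
networks, not their biochemistry: no cofactor coupling, no reversible
internal cycles, no alternate optima plateaus, no compartmentalization.
Passing the oracle-equivalence suite therefore demonstrates the
enumerator's combinatorial correctness, not its behavior under the numeric
pathologies of real GEMs — that is what the genome-scale core-model checks
in the test suite are for.

## Problem sizes

The default test and reproduction workloads: toy models (4 candidates),
50 random models with ≤ 12 candidates at level 3 (both reaction and gene
targeting), and the 95-reaction core model at level 3 (93 candidates after
excluding the maintenance reaction and the objective; on the order of 10⁵
LP solves, about a minute per model). These sizes make the full pipeline —
enumeration, scoring, topology, comparison — rerunnable from scratch in a
few minutes on one CPU while still exercising a genome-scale input.

## Known limitations

- Completeness of the pruned path beyond level 3 is supported by the same
  argument but not separately validated; exhaustive mode is the fallback.
- Support extraction trusts the LP solution at a 1e-6 flux tolerance; a
  true flux below it would hide a candidate (never observed against the
  oracle, but conceivable in badly scaled models).
- RAVEN-style SBML without a declared objective requires an explicit
  `--objective`; no guessing is attempted.
- Centrality-derived counts are convention-dependent (see above).
- Gene-level enumeration cost grows with GPR redundancy; the
  disabled-signature memoization helps but genome-scale gene-level level-3
  runs remain hours-scale.
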