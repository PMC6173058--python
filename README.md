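# ess — Essentiality Score Simulator

Quantitative reaction and gene essentiality for constraint-based metabolic
models (GEMs).

Binary essentiality analysis answers only "does the model grow without this
reaction?", while raw synthetic-lethality analysis (SLA) drowns the answer in
thousands of knockout combinations. `ess` turns SLA output into a single
per-target number: it enumerates all *minimal* lethal knockout sets up to a
user-chosen level *n* with flux balance analysis (FBA), counts how often each
target participates, and normalizes the counts into an essentiality score
(EScore) that is comparable across models. Intended users are systems
biologists comparing GEMs — wild-type vs. mutant, organism vs. organism,
tissue vs. tissue — or benchmarking stoichiometry-aware essentiality against
network-topology centralities.

## The score

For target *i* (a reaction or a gene) in a model with *X* knockout
candidates, analyzed up to level *n*:

```
ES_i = y_i1 + Σ_{j=2..n}  y_ij · (j−1)! / X^(j−1)
```

where `y_ij` is the number of minimal lethal sets of cardinality *j* that
contain *i*. Only *minimal* ("true synthetic lethal") sets are counted: a
lethal set is discarded if any proper subset is already lethal. The weight
has a counting interpretation — a fixed target appears in `X^(j−1)` ordered
level-*j* knockout combinations (with repetition), and each unordered
minimal set containing it accounts for `(j−1)!` of them — so `ES_i` is the
fraction of that population, an essential target scores exactly 1 at every
level, and scores are comparable between models because each is normalized
by its own *X*.

Lethality of a knockout set is decided by FBA: block the targeted reactions
(for genes: the reactions whose GPR rule evaluates false under the deletion,
after canonicalizing every rule to minimal disjunctive normal form) and test
whether the optimal objective flux falls to numerical zero. Enumeration uses
the Fast-SL pruning device — only targets carrying flux in a minimum-L1-norm
optimal solution of the current knockout model can extend it into a lethal
set — and is validated against an exhaustive oracle.

## Worked example

```
$ ess score --preset fig1a --level 2 --out demo
scored 4 reactions at level 2: 1 essential, 2 minimal lethal sets -> demo

$ cat demo/escores.tsv
target_id	escore	y_1	y_2	X	n
A	1.000000	1	0	4	2
B	0.000000	0	0	4	2
C	0.250000	0	1	4	2
D	0.250000	0	1	4	2
```

The `fig1a` preset is a five-reaction toy pathway: trunk reaction A feeds a
metabolite that parallel branches C and D both convert into the objective
precursor, and B leads into a dead end. A alone is lethal (`y_1 = 1`, score
1). C is not essential, but knocking out C *and* D is — {C, D} is the only
minimal synthetic-lethal set, so C scores `1!/4¹ = 0.25` of the 4 possible
level-2 combinations involving it. B participates in nothing and scores 0.
The pair {C, A} is *not* counted for C: it contains the already-lethal {A},
so it adds no information ("true SL" minimality).

The same pipeline runs on genome-scale input, e.g. the 95-reaction
*E. coli* core model at level 3 (about a minute):

```python
import ess
model = ess.load_ecoli_core()
cfg = ess.AnalysisConfig(level_n=3, excluded_ids={"ATPM"})  # pseudo reaction
table = ess.compute_escore(ess.enumerate_minimal_lethal_sets(model, cfg))
table["EX_glc__D_e"]   # 1.0 — glucose uptake is essential
```

Other commands: `ess topology` (metabolite/reaction/gene graphs with
betweenness, closeness, eccentricity and degree baselines), `ess compare`
(score two models and report per-target deltas, with score carry-over for
removed reactions), `ess fixture` (export the toy models), and
`ess oracle-check` (pruned vs. exhaustive enumeration on random models).

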