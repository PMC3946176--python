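# Methods

## Inferability from steady-state perturbation data

The package models one experimental design: complete single-gene knock-out
and knock-down over an `n`-gene network, observed at steady state. Under
that design, ideal data identify exactly which genes respond to each
perturbation — the reachability relation of the true digraph — and nothing
finer. All digraphs with the same transitive closure form an ensemble `D`
indistinguishable from the data, so an assessment that treats the gold
standard as the unique answer conflates data limits with method error.

Auto-regulation is excluded everywhere (edge universe `n(n−1)`), matching
the challenge design this mirrors: a self-loop is unobservable under a
perturbation of its own gene, and the gold standards in question omit them.

### Ensemble bounds

- `G_U` is the transitive closure of the gold standard (self-loops
  stripped). This is exact: every ensemble member is a subgraph of `G_U`,
  and `G_U` itself is a member.
- `G_L` approximates the intersection of the ensemble: condense the gold
  standard into its DAG of strongly connected components, transitively
  reduce that DAG (unique for DAGs, order-independent pruning), then
  - drop every condensed edge whose tail or head component has size ≥ 2:
    reachability cannot identify *which* node inside a cycle an incoming or
    outgoing edge attaches to;
  - expand components to gene level, keeping internal edges only for
    components of size 2 (a 2-cycle is the unique minimal strongly
    connected digraph on two nodes); internal edges of larger components
    are all dropped.
- `Ē = G_U \ G_L` is the non-inferable set.

For acyclic gold standards `G_L` equals the ensemble intersection exactly
(verified in tests against exhaustive enumeration of the closure class).
With cycles the construction is deliberately conservative: `G_L` may be a
strict subset of the intersection, never a superset — a pessimistic
approximation that errs toward calling edges non-inferable. The enumeration
oracle (`enumerate_closure_class`, exhaustive over subsets of the closure's
edges, capped at 5 nodes) reports per-instance whether equality held; over
all 3-node digraphs and random 4-node samples, equality holds on every DAG
and the subset relation on every cyclic instance.

### Redefined confusion matrix

Inferable mode restricts scoring to the decidable part of the universe:
positives are `G_L` (`P′ = |G_L|`), negatives are the complement of `G_U`
(`N′ = n(n−1) − |G_U|`), and edges of `Ē` touch no cell. Cells therefore
sum to `n(n−1) − |Ē|` at every ranking prefix. A gold standard whose
decidable part is empty (`P′ = 0` or `N′ = 0`, e.g. a pure 3-cycle) raises
`DegenerateGoldError` rather than returning silent NaNs.

## Curves, AUCs and truncation

Curves are prefix sweeps of the ranked list, one edge per step, in
submitted order; ties in confidence keep file order (stable sort on read),
since a submission is an ordering, not a calibrated probability. ROC points
are `(FP/N′, TP/P′)` anchored at `(0, 0)`; PR points are
`(TP/P′, TP/(TP+FP))`, skipping prefixes where `TP+FP = 0` (possible in
inferable mode when only `Ē` edges have been listed) and anchored at recall
0 with the first defined precision. Both areas are trapezoidal.

Lists shorter than the edge universe are completed, by default, with the
expected-value tail: the unlisted edges are treated as uniformly randomly
ordered, so remaining positives arrive at constant rate
`p_rem/(p_rem+n_rem)` per step (a straight ROC segment to `(1, 1)` and the
matching PR tail). A `strict` policy rejects incomplete lists instead.

Numerical note: AUCs are IEEE doubles; recall steps of `k/P′` are not
exactly representable when `P′` is not a power of two, so an
exactly-perfect curve can integrate to 1.0 minus one ulp. Tests asserting
perfection use an absolute tolerance of 1e-12. A consequence of trapezoidal
PR integration worth knowing: false positives ranked *after* recall reaches
1 add no area, so classic-mode AUPR of a closure-ranked list is below 1
only when some shortcut precedes a gold edge.

## Scoring against an empirical null

For each network and metric, `n_reps` uniformly random permutations of the
full edge universe are scored and `AUC_α` is taken as the linearly
interpolated `100·(1−α)`-th percentile (interpolation because
`n_reps · α` need not be integral). The default `α = 0.05`. The submission
score is the ratio `AUC / AUC_α`; per-metric scores are unweighted means
over the `M` networks and the overall score the mean of the two metric
means, so score 1.0 is exactly the random-performance boundary. No density
is fitted to the null — percentiles of the empirical sample are used
directly.

The production default is `n_reps = 100000`; tests, examples and the
acceptance script use 200–1000 replicates with fixed seeds, which locates
the 95th percentile to well within the tolerances they assert. Each
(network, metric) pair gets its own RNG stream derived from the master seed
(`derive_seed`, CRC-based, < 2³¹), so adding a network never perturbs
existing nulls.

## Synthetic study conditions

The generator composes gold standards from motifs with known inferability:
cascades and feed-forward loops (their shortcut is the canonical
non-inferable edge), 2-cycles (fully inferable) and k-cycles with k ≥ 3
(fully non-inferable). Motifs occupy disjoint gene groups so the bounds of
the whole network are analytic in tests; optional Bernoulli extra edges
(default probability 0) break that guarantee and are excluded from oracle
tests. Gene labels are shuffled per seed.

Predictions carry two error channels. A *cascade error* (probability
`cascade_error_rate` per gold edge) puts a non-inferable shortcut at the
gold edge's rank and demotes the edge to just below the gold block — still
above every genuine negative. This reproduces direct-vs-indirect confusion:
classic scores degrade, inferability-aware scores are provably unchanged. A
*flip* (probability `flip_rate`) swaps a gold edge with an edge outside the
closure; both assessments degrade. When the supply of substitute edges runs
out the displacement is skipped, so effective rates saturate on small
networks. The two channels are what make the central claim testable — that
the new assessment forgives exactly the errors the data cannot decide.

What the generator does not emulate: expression-level noise (the bounds
here assume ideal reachability data), signed activation/inhibition,
gene-compensation masking, and realistic scale-free topology. Passing tests
therefore show correctness of the assessment machinery under ideal
conditions, not robustness of any inference method to noise.

### Study sizes

Defaults chosen once for the package's own studies: 10–12-gene networks
with 1–3 motifs for calibration and separation experiments, 100 random
networks for the forgiveness property, 1000-replicate nulls, and
500 random 4-node digraphs alongside the exhaustive 3-node set for the
enumeration oracle. The null-calibration network is a 10-gene composition
with 2 FFLs and 2 two-cycles, giving `P′ = 8`: checking that random
predictions exceed `AUC_0.05` five percent of the time requires a null
distribution with reasonably dense support, and a network whose decidable
positive class has collapsed to one or two edges yields an AUROC null with
a few dozen atoms, where strict exceedance of an interpolated percentile is
dominated by discreteness rather than calibration.

## Published reference sizes

`grnassess.reference.DREAM4_REPORTED_BOUND_SIZES` records the published
gold/lower/upper/non-inferable edge counts for the ten DREAM 4 in silico
networks. The package uses them only for internal-consistency checks
(`|Ē| = |G_U| − |G_L|` row-wise; mean non-inferable gold fraction of the
100-gene networks, 71.2%) and for comparison when a user runs
`grnassess bounds` on gold-standard files downloaded from the DREAM
project; the files themselves are not bundled.

## Known limitations

- The lower bound for cyclic gold standards is an approximation from one
  side only; no claim is made that it is the tightest such bound.
- PR-curve integration is trapezoidal throughout; benchmark pipelines that
  use hyperbolic PR interpolation will produce slightly different AUPR
  values for the same ranking, so cross-pipeline score comparisons are
  qualitative.
- The expected-value tail assumes unlisted edges are exchangeable; a
  submission truncated adversarially (e.g. withholding edges it knows are
  negatives) is scored optimistically.
- `enumerate_closure_class` is exponential in the closure's edge count and
  is capped at 5 nodes; it is an oracle for validation, not a tool for
  real networks.
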