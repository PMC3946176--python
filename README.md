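# grnassess

Inferability-aware benchmarking of gene-regulatory-network (GRN) inference.

## The problem

GRN inference benchmarks (the DREAM in silico challenges being the canonical
example) score a method by comparing its ranked list of predicted regulatory
edges against a gold-standard digraph, via confusion matrices swept along the
ranking and the resulting AUROC/AUPR. But the underlying inference problem is
underdetermined: steady-state expression data from single-gene knock-out and
knock-down (KO/KD) experiments reveal which genes *respond* to a
perturbation — i.e. reachability — and cannot separate direct from indirect
regulation. Penalising a method for edges that no algorithm could decide from
the data conflates the method's weaknesses with the data's.

`grnassess` is for people who build or evaluate network-inference methods and
want scores that charge only decidable errors.

## The model

For a gold standard `G` (no auto-regulation; edge universe of size
`n(n−1)`), the set `D` of digraphs sharing `G`'s transitive closure is
exactly the ensemble a complete single-gene KO/KD design cannot
discriminate. The package computes

- **upper bound** `G_U = closure(G)` — the largest network consistent with
  ideal reachability data;
- **lower bound** `G_L` — edges present in every member of `D`,
  approximated by transitively reducing the condensation of `G` (the DAG of
  its strongly connected components), pruning every condensed edge incident
  to a component of size ≥ 2, and keeping internal edges only for 2-cycles;
- **non-inferable set** `Ē = G_U \ G_L` — edges the data can neither
  confirm nor refute.

The inferability-aware confusion matrix excludes `Ē` from every cell:

```
TP = |pred ∩ G_L|      FP = |pred ∩ (U \ G_U)|
FN = |G_L \ pred|      TN = |(U \ G_U) \ pred|
```

so cells sum to `n(n−1) − |Ē|`. ROC and PR curves are built DREAM-style by
sweeping prefixes of the ranked list (`TPR = TP/P′`, `FPR = FP/N′`,
`precision = TP/(TP+FP)`), integrated trapezoidally. Submissions are scored
against an empirical null: `score = AUC / AUC_α`, where `AUC_α` is the
`100·(1−α)`-th percentile of AUCs over random predictions; a score below 1
is "not better than random". Per-metric scores are averaged over the `M`
networks of a subchallenge, and the overall score is the mean of the two
metric means.

Classic (gold-vs-rest) scoring is available throughout for comparison.

## Worked example

A method that confuses direct and indirect regulation ranks the cascade
shortcut `A->C` first on the gold standard `A->B->C`:

```python
from grnassess import (Digraph, RankedEdgeList, build_confusion,
                       curves_and_auc, ensemble_bounds)

gold = Digraph.from_edges([("A", "B"), ("B", "C")])
bounds = ensemble_bounds(gold)
order = [("A","C"), ("A","B"), ("B","C"), ("B","A"), ("C","A"), ("C","B")]
ranking = RankedEdgeList(tuple((t, h, (6-i)/6) for i, (t, h) in enumerate(order)))

for mode in ("classic", "inferable"):
    cm = build_confusion(ranking.top(2), gold, bounds, mode=mode)
    res = curves_and_auc(ranking, gold, bounds, mode=mode)
    print(f"{mode:>9}: top-2 TP={cm.tp} FP={cm.fp} FN={cm.fn} TN={cm.tn}  "
          f"AUROC={res.auroc:.3f} AUPR={res.aupr:.3f}")
```

prints

```
  classic: top-2 TP=1 FP=1 FN=1 TN=3  AUROC=0.750 AUPR=0.417
inferable: top-2 TP=1 FP=0 FN=1 TN=3  AUROC=1.000 AUPR=1.000
```

Classic scoring charges `A->C` as a false positive; the inferability-aware
assessment recognises it as undecidable (`Ē = {A->C}`) and scores the
submission as perfect. The `examples/` directory walks through ensemble
bounds of the standard motifs, curve assessment, empirical-null scoring of
competing teams, and the decomposition of a method's errors into inferable
and non-inferable parts.

## Command line

```sh
grnassess simulate --n-nodes 10 --cascades 2 --ffls 1 --seed 1 \
    --gold-out gold.tsv --pred-out pred.tsv
grnassess bounds gold.tsv
grnassess evaluate --gold net1=gold.tsv --pred team:net1=pred.tsv \
    --mode inferable --n-reps 1000 --seed 1 --out results/
grnassess compare-rankings ranking_new.txt ranking_old.txt
```

Files are DREAM-dialect TSV: gold standards `regulator TAB target TAB {0,1}`,
predictions `regulator TAB target TAB confidence`. To reproduce the published
ensemble-bound sizes of the DREAM 4 In Silico (10- and 100-gene) gold
standards, download the challenge files from the DREAM project and run
`grnassess bounds` on each; the reported `|G_L|`, `|G_U|` and non-inferable
counts for comparison ship as
`grnassess.reference.DREAM4_REPORTED_BOUND_SIZES`.

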