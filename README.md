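# amfeskit

Small two-class expression studies — a few thousand probes measured on a few
dozen blood samples — pose a brutal feature-selection problem: far more genes
than samples, weak signals, and heavy interference between genes. `amfeskit`
implements an ensemble-SVM methodology for finding small biomarker panels in
exactly this regime and for characterizing the dependency structure among the
selected genes:

- **AMFES** (Adaptive Multiple FEatures Selection): genes are ranked by
  training many linear SVMs on small random gene subsets. A gene's score is
  θ(g) = Σᵢ I(g∈Sᵢ)·wᵢ(g) / Σᵢ I(g∈Sᵢ), where wᵢ(g) is the drop in classifier
  Cᵢ's objective when g is removed from every support vector with the dual
  coefficients held fixed (½w_g² for the linear kernel). The ensemble grows
  until ‖θₘ₋₁−θₘ‖²/‖θₘ₋₁‖² < 0.01, and ranking proceeds in recursive stages
  (all genes, then the top half, … down to 3). *Artificial genes* — permuted
  copies of real genes — are ranked alongside; each real gene's **gene-index**
  is the fraction of probes ranked above it. The panel cutoff p\* is chosen by
  validation accuracy over r = max(5, int(500/n + 0.5)) stratified
  training/validation splits, against an all-genes baseline.
- **KDE mutual information**: pairwise dependence between selected genes by
  the Gaussian-kernel plug-in estimator
  I(X,Y) = (1/M) Σ_w log[ M·Σᵤ k(x_w,x_u)k(y_w,y_u) / (Σᵤ k(x_w,x_u)·Σᵤ k(y_w,y_u)) ]
  (nats), with per-gene marginal kernel sums computed once and reused across
  all N(N−1)/2 pairs.
- **Target networks**: edges are gene pairs whose MI strictly exceeds a
  permutation-null threshold (the largest off-diagonal MI observed over
  repeated within-gene permutations of the data), plus hierarchical
  clustergram ordering of the MI matrix.
- **Evaluation**: cross-validated ROC/AUC of a panel, with the trapezoidal
  curve area identical to the Mann–Whitney pair-counting probability.

The core selector is a scikit-learn estimator (`AmfesSelector`, a
`SelectorMixin`), so it composes with sklearn pipelines and model selection.
A `click` CLI (`amfeskit simulate|select|mi|network|clustergram|evaluate|run`)
wires the stages together. A synthetic-data module generates microarray-shaped
studies with planted ground truth so every stage is testable end to end.

## Worked example

```python
from amfeskit import SyntheticSpec, generate_dataset, select_genes, evaluate_panel

spec = SyntheticSpec(n_genes=1000, n_informative=30,
                     n_samples_per_class=20, effect_size=2.0, seed=11)
ds, truth, _ = generate_dataset(spec)

res = select_genes(ds, seed=11)
print(f"panel {len(res.panel)} genes, p*={res.p_star}, "
      f"recall {len(set(res.panel.gene_ids) & set(truth)) / len(truth):.2f}")
roc = evaluate_panel(ds, res.panel, k_folds=5, seed=11)
print(f"cross-validated AUC = {roc.auc}")
```

prints

```
panel 26 genes, p*=0.0, recall 0.83
cross-validated AUC = 1.0
```

Out of 1000 genes (30 carrying a 2-SD class shift), AMFES keeps a 26-gene
panel — 2.6% of the input — recovering 25 of the 30 planted genes; p\* = 0
means the winning panel is the genes ranked above *every* artificial probe.
The held-out SVM decision values separate the classes perfectly (AUC 1.0).

The same run from the shell:

```sh
amfeskit simulate --seed 11 --out d.tsv --labels-out l.tsv --truth t.txt
amfeskit select --data d.tsv --labels l.tsv --seed 11 --out panel.txt --report report.json
amfeskit run --data d.tsv --labels l.tsv --seed 11 --outdir results/
```

`run` emits the panel, per-class MI matrices, the permutation-thresholded
network (GraphML + edge list), the clustergram leaf order, and a ROC report,
all stamped with the config hash; reruns are byte-identical.

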