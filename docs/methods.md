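# Methods

## The selection model

AMFES treats gene relevance as a property of *subsets*, not individuals: a
weak gene can matter inside the right combination, which is exactly what
single-gene statistics and greedy backward elimination (SVM-RFE) miss. The
unit of evidence is a linear SVM trained on a small random subset of genes.
For classifier Cᵢ with support vectors v₁…v_s and dual coefficients αy, the
contribution of gene g is the change in the objective when g is deleted from
every support vector with the coefficients frozen:

    weightᵢ(g) = objᵢ(v₁…v_s) − objᵢ(v₁⁽ᵍ⁾…v_s⁽ᵍ⁾),

where obj is the regularization quadratic form ½ (αy)ᵀK(αy) = ½‖w‖². The
implementation computes this definition from kernel matrices, so the linear
closed form weightᵢ(g) = ½w_g² remains an independently checkable identity
rather than the definition. (Taking obj as the full dual objective Σα − ½‖w‖²
flips the sign and would rank informative genes last; the quadratic-form
convention is the one under which removing an informative gene produces a
large positive drop.)

A gene's ranking score is the average weight over the subsets containing it.
Subsets of j genes are drawn by chunking random shuffles, which guarantees
every gene is covered before convergence is first tested (the score's
denominator must be positive). The ensemble starts at max(m_min, ⌈k/j⌉)
subsets and grows one at a time until the relative squared change of the
score vector falls below 0.01, capped at m_max.

Ranking is staged: all k genes once, then the top max(3, ⌈k/2⌉) re-ranked
while the bottom keeps its order, recursively until a final 3-gene stage.
Stage scores are comparable only within a stage; the reported ordering score
is the running minimum along the final order (raw stage scores are kept
separately).

### Probes and the gene-index

Each artificial gene is an independent within-gene permutation of a randomly
chosen real gene's values: marginals preserved, label association destroyed.
Ranked together with the real genes, the probes calibrate relevance: a gene's
gene-index is the fraction of probes ranked above it. The default probe count
equals the real gene count, giving index resolution 1/n_genes.

### Choosing p\*

The learning samples are split into r = max(5, int(500/n + 0.5)) stratified
training/validation pairs (validation fraction 0.3). Per pair, the ranking
runs with fresh probes, and each observed gene-index value p defines a
candidate panel (genes with index ≤ p) whose SVM validation accuracy v(p) is
measured; v is a step function of p that changes only at that pair's own
observed index values, so the average accuracy av(p) on the pooled candidate
grid is obtained by step-function lookup without refitting any pair at
another pair's candidates. An empty candidate panel scores 0. p\* is the
smallest pooled candidate whose av strictly beats the all-genes baseline
(averaged over the same pairs); if none beats it, the av-maximizing candidate
wins with ties to the smaller p. The final panel comes from one more ranking
with fresh probes on all learning samples: genes with index ≤ p\*.

### Defaults that matter

| parameter | default | why |
|---|---|---|
| kernel / C | linear / 1.0 | objective-drop weights are exact and cheap for linear kernels; C=1 on standardized features |
| subset size j | max(3, ⌈√k⌉) | keeps per-SVM dimensionality below tiny sample counts while subsets stay diverse |
| m_min / m_max | 10 / 500 | floor for a meaningful average; cap bounds runtime |
| convergence tol | 0.01 | relative squared-change threshold of the score vector |
| validation fraction | 0.3 | stratified; classes of 14 give 4–5 validation samples each |
| probes | one per gene | index resolution 1/n_genes; doubles ranking width |
| standardization | per training split, population (ddof=0) SD | no leakage from validation samples; constant genes zeroed and flagged |
| ties in θ | stable sort, input order | deterministic |

Feature weights, stage order and p\* are deterministic functions of one
master seed (numpy `SeedSequence` spawning per-pair streams).

## Mutual information

The pairwise dependence measure is the Gaussian-kernel plug-in estimator in
nats (natural log makes the bivariate-Gaussian reference value −½ln(1−ρ²)
exact). The production path precomputes each gene's M×M kernel matrix and
its row sums (the marginal factors) once, then forms each pair's joint sums
by an elementwise product — every sample-pair kernel distance is computed
once per gene rather than once per gene pair. A naive per-pair
reimplementation serves as the oracle; the two agree to ~1e-15.

Bandwidth h defaults to 0.25 on per-gene standardized values (standardizing
first is what makes a single default meaningful). The estimator is biased:
at small h the bias is positive everywhere (independent noise at M≈15–30
samples yields uniformly positive estimates), while in the smooth regime
(h on the order of the data SD and larger) small-sample noise produces a mix
of signs, with summary magnitudes (mean ~10⁻²–10⁻³, minima around −0.005 at
h=2) matching what small-sample microarray MI tables report. Negative
estimates are never clamped. Summary counts include the diagonal
(self-information I(X,X) > 0), so positive + negative + zero counts
partition N²; exact zeros (measure-zero) sit in neither sign bucket.

## Target network and clustergram

The permutation threshold reads "permute the MI values" operationally: each
gene's sample values are permuted independently, the full pairwise MI matrix
is recomputed, and the maximum off-diagonal entry recorded; the threshold is
the largest such maximum over n_perm (default 30) repetitions — a null
maximum, which is why edges must exceed it *strictly*. At M≈20–30 samples
this null maximum is large (≈0.8–1.2 nats at h=0.25), so sparse networks on
small studies are expected behavior, not failure. Isolated nodes are kept.

Clustergram ordering is agglomerative clustering of the MI-matrix rows under
Euclidean distance with average linkage (the distance is the stated
convention; the linkage had to be fixed and average linkage is the common
default for expression heatmaps), ties resolved by input order.

## Evaluation

Panels are scored by stratified k-fold (default 5) cross-validation with the
same SVM configuration as selection, features standardized per fold's
training samples; when the smaller class has fewer than k samples the scheme
falls back to leave-one-out. Decision values are pooled into one ROC curve
(standard with tens of samples); per-fold AUCs are reported where a fold
contains both classes. The curve is built from all distinct thresholds and
its trapezoidal area equals the Mann–Whitney probability with ties counted
½ — an identity the tests verify against an independent pair-counting
implementation and sklearn.

## What the synthetic generator does and does not emulate

`SyntheticSpec` draws genes × samples Gaussian noise, shifts a planted set of
informative genes by `effect_size`·SD between classes (alternating shift
signs so panels are sign-mixed), and can add co-expressed blocks via a shared
latent factor (gene = √ρ·factor + √(1−ρ)·noise, giving pairwise correlation ρ
in expectation). It reproduces the *shape* of small PBMC microarray studies —
thousands of genes, tens of samples, a handful of true signals — and provides
exact ground truth. It does not model probe-level artifacts (dye bias,
saturation, intensity-dependent variance) or realistic correlation between
informative genes and the background, so passing tests demonstrate
correctness and statistical behavior of the algorithms under clean planted
signal, not performance guarantees on real chips.

Benchmark problem sizes used by the tests and the acceptance script — chosen
as the smallest sizes at which each property is comfortably identifiable:
selection recovery at 1000 genes / 30 informative / 20+20 samples (five
seeds), the AUC benchmark at 1000 genes / 14+14, probe separation at 100
genes / 10 informative / 40 samples pooled over five seeds, the permutation
threshold on 200 noise genes × 20 samples, and Gaussian MI fixtures at
M = 2000.

## Known limitations

- Objective-drop weights are implemented for the linear kernel's quadratic
  form; nonlinear kernels would need their own weight derivation (out of
  scope).
- The gene-index is granular at 1/n_probes; with few probes p\* is coarse.
- KDE-MI values depend strongly on h and M; absolute values are not
  comparable across studies with different sample counts, which is why
  network thresholds are recomputed per dataset by permutation.
- The per-stratum (e.g. per-sex) mode reports panel overlap; it does not test
  its significance.
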