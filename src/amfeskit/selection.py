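"""AMFES: ensemble-SVM gene ranking and adaptive optimal-subset selection.

The algorithm ranks genes by training many small linear SVMs on random gene
subsets.  A gene's ranking score is the average, over the subsets containing
it, of the drop in the SVM objective when the gene is removed from every
support vector with the dual coefficients held fixed.  The subset ensemble
grows until the score vector stabilizes.  Ranking is staged recursively: all
genes are ranked once, then only the top half is re-ranked (the bottom half
keeps its order), halving until three genes remain.

Relevance is calibrated against *artificial genes* (random probes): each probe
is a within-gene permutation of a real gene's values, preserving its marginal
distribution while destroying any label association.  Probes are ranked
together with real genes, and each real gene receives a *gene-index* — the
proportion of probes ranked above it (0 = above all probes, 1 = below all).
Candidate panels are the genes with index ≤ p for each observed index value p;
the cutoff p* is the smallest candidate whose average validation accuracy over
r random training/validation splits beats the all-genes baseline.

The public surface is the scikit-learn style :class:`AmfesSelector` plus the
free functions it is built from; :func:`select_genes` is a thin wrapper
operating on :class:`~amfeskit.data_io.ExpressionDataset`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .data_io import ExpressionDataset, GenePanel

__all__ = [
    "SvmFit",
    "RankingResult",
    "SelectionResult",
    "AmfesSelector",
    "compute_r",
    "plan_splits",
    "fit_svm",
    "feature_weight",
    "ranking_score",
    "converged",
    "rank_stage",
    "recursive_rank",
    "make_artificial_genes",
    "assign_gene_indices",
    "choose_pstar",
    "select_genes",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SvmFit:
    """A trained linear SVM with everything needed to recompute its objective.

    ``dual_coefficients`` are the signed values alpha_i * y_i at the support
    vectors; ``objective_value`` is the regularization quadratic form
    ½ sum_ij (a y)_i (a y)_j K(v_i, v_j) = ½ ||w||² evaluated at those
    coefficients (the part of the objective that feature removal changes).
    """

    support_vector_indices: np.ndarray
    support_vectors: np.ndarray
    dual_coefficients: np.ndarray
    primal_weights: np.ndarray
    intercept: float
    objective_value: float
    C: float

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.primal_weights + self.intercept


@dataclass
class RankingResult:
    """A total order over (real + probe) features from recursive ranking.

    ``scores`` are ordering scores, monotone non-increasing along the order:
    stage-level θ values are comparable only within a ranking stage, so the
    reported score is the running minimum of each feature's final-stage θ
    along the order.  The raw final-stage θ values are kept in
    ``stage_scores`` (aligned with ``ordered_ids``).
    """

    ordered_ids: list[str]
    scores: np.ndarray
    probe_flags: np.ndarray
    stage_scores: np.ndarray
    gene_indices: dict[str, float] | None = None

    @property
    def original_order(self) -> list[str]:
        """Final ranking restricted to original (non-probe) features."""
        return [g for g, p in zip(self.ordered_ids, self.probe_flags) if not p]


@dataclass
class SelectionResult:
    """Outcome of a full AMFES selection run."""

    p_star: float
    panel: GenePanel
    candidate_values: list[float]
    candidate_accuracies: list[float]
    baseline_accuracy: float
    r: int
    pair_seeds: list[int]
    gene_indices: dict[str, float]
    ranking: RankingResult
    stage_sizes: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations


def compute_r(n: int) -> int:
    """Number of training/validation pairs: r = max(5, int(500/n + 0.5))."""
    if n < 2:
        raise ValueError(f"need at least 2 learning samples, got {n}")
    return max(5, int(500.0 / n + 0.5))


def plan_splits(
    labels: np.ndarray,
    validation_fraction: float = 0.3,
    r: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``r`` class-stratified (train, validation) index partitions.

    ``r`` defaults to the heuristic :func:`compute_r` value for ``len(labels)``.
    """
    labels = np.asarray(labels, dtype=int)
    if not 0.0 < validation_fraction <= 0.5:
        raise ValueError(
            f"validation_fraction must lie in (0, 0.5], got {validation_fraction}"
        )
    rng = np.random.default_rng(rng)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes required to plan splits")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to split")
    if r is None:
        r = compute_r(len(labels))
    pairs = []
    for _ in range(r):
        train_idx, val_idx = [], []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            idx = rng.permutation(idx)
            n_val = max(1, int(validation_fraction * len(idx) + 0.5))
            n_val = min(n_val, len(idx) - 1)  # keep ≥1 training sample per class
            val_idx.append(idx[:n_val])
            train_idx.append(idx[n_val:])
        pairs.append(
            (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx)))
        )
    return pairs


def fit_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SvmFit:
    """Train a linear-kernel SVM and package coefficients and objective."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("fit_svm requires samples from both classes")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    dual = clf.dual_coef_[0]  # alpha_i * y_i at support vectors
    sv = clf.support_vectors_
    w = clf.coef_[0]
    obj = 0.5 * float(dual @ (sv @ sv.T) @ dual)
    return SvmFit(
        support_vector_indices=clf.support_.copy(),
        support_vectors=sv.copy(),
        dual_coefficients=dual.copy(),
        primal_weights=w.copy(),
        intercept=float(clf.intercept_[0]),
        objective_value=obj,
        C=C,
    )


def feature_weight(fit: SvmFit, g: int) -> float:
    """Objective change from dropping feature ``g`` out of every support vector.

    With the dual coefficients frozen, the objective is the quadratic form
    ½ aᵀ K a over the support vectors; removing feature ``g`` from the kernel
    gives the weight obj(v_1..v_s) − obj(v_1^(g)..v_s^(g)).  For the linear
    kernel this equals ½ w_g² algebraically; it is computed here from the
    kernel matrices so that identity stays a checkable property.
    """
    if not 0 <= g < fit.n_features:
        raise KeyError(f"feature {g} not in fit with {fit.n_features} features")
    a = fit.dual_coefficients
    sv = fit.support_vectors
    dropped = np.delete(sv, g, axis=1)
    obj_dropped = 0.5 * float(a @ (dropped @ dropped.T) @ a)
    return fit.objective_value - obj_dropped


def _all_feature_weights(fit: SvmFit) -> np.ndarray:
    """Vectorized per-feature objective changes; equals ½ w² for linear kernels."""
    return 0.5 * fit.primal_weights**2


def ranking_score(
    subsets: list[np.ndarray], weights: list[np.ndarray], g: int, n_features: int
) -> float:
    """θ_m(g): mean weight of ``g`` over the subsets that contain it.

    ``subsets[i]`` holds feature indices of subset S_i, ``weights[i]`` the
    matching per-feature weights from classifier C_i.
    """
    total, count = 0.0, 0
    for s, w in zip(subsets, weights):
        hit = np.flatnonzero(s == g)
        if hit.size:
            total += float(w[hit[0]])
            count += 1
    if count == 0:
        raise ValueError(f"feature {g} appears in no subset")
    return total / count


def converged(
    theta_prev: np.ndarray, theta_curr: np.ndarray, tol: float = 0.01
) -> bool:
    """Score-vector stabilization test: ‖θ_prev − θ_curr‖² / ‖θ_prev‖² < tol."""
    theta_prev = np.asarray(theta_prev, dtype=float)
    theta_curr = np.asarray(theta_curr, dtype=float)
    if theta_prev.shape != theta_curr.shape:
        raise ValueError("score vectors must have equal length")
    denom = float(theta_prev @ theta_prev)
    if denom == 0.0:  # degenerate: report not-converged, keep growing
        return False
    diff = theta_prev - theta_curr
    return float(diff @ diff) / denom < tol


def default_subset_size(k: int) -> int:
    """Genes per random subset: max(3, ⌈√k⌉), capped at k."""
    return min(k, max(3, math.ceil(math.sqrt(k))))


class _SubsetSampler:
    """Round-robin subset sampler guaranteeing coverage of every stage gene.

    Features are consumed in consecutive chunks of a random shuffle; a fresh
    shuffle starts whenever the cycle is exhausted, so every feature appears
    at least once in any ⌈k/j⌉ consecutive subsets.
    """

    def __init__(self, k: int, j: int, rng: np.random.Generator):
        self.k, self.j, self.rng = k, j, rng
        self._cycle = rng.permutation(k)
        self._pos = 0

    def next_subset(self) -> np.ndarray:
        out = []
        while len(out) < self.j:
            if self._pos >= self.k:
                self._cycle = self.rng.permutation(self.k)
                self._pos = 0
            take = min(self.j - len(out), self.k - self._pos)
            out.extend(self._cycle[self._pos : self._pos + take])
            self._pos += take
        return np.array(out, dtype=int)


def rank_stage(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx: np.ndarray,
    rng: np.random.Generator,
    C: float = 1.0,
    subset_size: int | None = None,
    m_min: int = 10,
    m_max: int = 500,
    tol: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank one stage's features by ensemble score, descending.

    Returns ``(ordered feature indices, their θ scores)``.  The ensemble is
    grown one random subset at a time; convergence of the score vector is
    tested only after every feature is covered and at least ``m_min`` subsets
    exist.  Ties in θ are broken by input order (stable sort).
    """
    feature_idx = np.asarray(feature_idx, dtype=int)
    k = len(feature_idx)
    if k < 2:
        return feature_idx.copy(), np.zeros(k)
    j = default_subset_size(k) if subset_size is None else min(subset_size, k)
    sampler = _SubsetSampler(k, j, rng)
    n_cover = math.ceil(k / j)

    sums = np.zeros(k)
    counts = np.zeros(k, dtype=int)
    Xs = X[:, feature_idx]

    def add_subset() -> None:
        local = sampler.next_subset()
        fit = fit_svm(Xs[:, local], y, C=C)
        sums[local] += _all_feature_weights(fit)
        counts[local] += 1

    m0 = max(m_min, n_cover)
    for _ in range(m0):
        add_subset()
    theta = sums / counts
    m = m0
    while m < m_max:
        add_subset()
        m += 1
        theta_new = sums / counts
        stop = converged(theta, theta_new, tol)
        theta = theta_new
        if stop:
            break
    order = np.argsort(-theta, kind="stable")
    return feature_idx[order], theta[order]


def recursive_rank(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx: np.ndarray,
    rng: np.random.Generator,
    C: float = 1.0,
    subset_size: int | None = None,
    m_min: int = 10,
    m_max: int = 500,
    tol: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Staged recursive ranking: re-rank the top half until 3 genes remain.

    Stage sizes follow k, max(3, ⌈k/2⌉), … , 3; the bottom of each stage keeps
    its order.  Returns ``(total order, stage θ values aligned with the order,
    stage sizes)``; θ values are comparable only within a stage.
    """
    feature_idx = np.asarray(feature_idx, dtype=int)
    k = len(feature_idx)
    if k == 0:
        return feature_idx.copy(), np.zeros(0), []
    if k == 1:
        return feature_idx.copy(), np.zeros(1), [1]
    sizes = [k]
    while sizes[-1] > 3:
        sizes.append(max(3, math.ceil(sizes[-1] / 2)))

    order = feature_idx.copy()
    stage_theta = np.zeros(k)
    for s in sizes:
        head, theta = rank_stage(
            X, y, order[:s], rng, C=C, subset_size=subset_size,
            m_min=m_min, m_max=m_max, tol=tol,
        )
        order[:s] = head
        stage_theta[:s] = theta
    return order, stage_theta, sizes


def make_artificial_genes(
    values: np.ndarray, count: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Append ``count`` probe rows: independent permutations of random real rows.

    Each probe keeps some original gene's marginal value distribution but
    loses any association with the sample labels.  Returns the augmented
    (genes+probes) × samples matrix and a boolean probe-flag vector.
    """
    if count < 1:
        raise ValueError("need at least one artificial gene")
    n_genes, n_samples = values.shape
    src = rng.integers(0, n_genes, size=count)
    probes = np.empty((count, n_samples))
    for i, s in enumerate(src):
        probes[i] = values[s, rng.permutation(n_samples)]
    augmented = np.vstack([values, probes])
    flags = np.zeros(n_genes + count, dtype=bool)
    flags[n_genes:] = True
    return augmented, flags


def assign_gene_indices(
    ordered_ids: list[str], probe_flags: np.ndarray
) -> dict[str, float]:
    """Gene-index per original feature: fraction of probes ranked above it."""
    probe_flags = np.asarray(probe_flags, dtype=bool)
    n_probes = int(probe_flags.sum())
    if n_probes == 0:
        raise ValueError("ranking contains no artificial genes")
    indices: dict[str, float] = {}
    probes_above = 0
    for fid, is_probe in zip(ordered_ids, probe_flags):
        if is_probe:
            probes_above += 1
        else:
            indices[fid] = probes_above / n_probes
    return indices


def choose_pstar(
    candidates: list[float], avg_acc: list[float], baseline: float
) -> float:
    """First candidate whose average validation accuracy beats baseline.

    Falls back to the accuracy-maximizing candidate (smaller p on ties) when
    no candidate strictly exceeds the all-genes baseline.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate subset values")
    if list(candidates) != sorted(candidates):
        raise ValueError("candidates must be sorted ascending")
    for p, acc in zip(candidates, avg_acc):
        if acc > baseline:
            return p
    best = int(np.argmax(avg_acc))  # argmax takes the first (smallest p) on ties
    return candidates[best]


# ---------------------------------------------------------------------------
# the estimator


class AmfesSelector(SelectorMixin, BaseEstimator):
    """Adaptive multiple-feature selection by ensemble-SVM ranking.

    A scikit-learn compatible feature selector: ``fit(X, y)`` on an
    (n_samples, n_features) matrix, then ``transform`` keeps the selected
    columns.

    Parameters
    ----------
    C : float
        Linear-SVM regularization for every classifier in the pipeline.
    subset_size : int or None
        Genes per random subset; ``None`` means max(3, ⌈√k⌉) per stage.
    validation_fraction : float
        Class-stratified fraction held out in each of the r splits.
    n_probes : int or None
        Artificial genes per ranking run; ``None`` means one per real gene.
    n_splits : int or None
        Override the r heuristic (``None`` → max(5, int(500/n + 0.5))).
    m_min, m_max : int
        Ensemble-size floor and cap per ranking stage.
    convergence_tol : float
        Relative squared-change threshold for score-vector stabilization.
    random_state : int or None
        Master seed; every stage seed derives from it.

    Attributes
    ----------
    support_ : bool array of shape (n_features,)
        Mask of selected features.
    p_star_ : float
        Chosen gene-index cutoff.
    gene_index_ : float array of shape (n_features,)
        Final-ranking gene-index per feature.
    ranking_ : int array
        Feature indices in final descending-relevance order.
    candidate_values_, candidate_accuracies_, baseline_accuracy_, r_,
    pair_seeds_, stage_sizes_ : selection audit trail.
    """

    def __init__(
        self,
        C: float = 1.0,
        subset_size: int | None = None,
        validation_fraction: float = 0.3,
        n_probes: int | None = None,
        n_splits: int | None = None,
        m_min: int = 10,
        m_max: int = 500,
        convergence_tol: float = 0.01,
        random_state: int | None = None,
    ):
        self.C = C
        self.subset_size = subset_size
        self.validation_fraction = validation_fraction
        self.n_probes = n_probes
        self.n_splits = n_splits
        self.m_min = m_min
        self.m_max = m_max
        self.convergence_tol = convergence_tol
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _rank_with_probes(
        self, X_std: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[dict[int, float], np.ndarray, np.ndarray, np.ndarray, list[int]]:
        """Rank genes + fresh probes.

        Returns ``(gene_index map, full order incl. probes, ordered probe
        flags, ordered stage θ, stage sizes)``.
        """
        n_genes = X_std.shape[1]
        n_probes = self.n_probes if self.n_probes is not None else n_genes
        augmented, flags = make_artificial_genes(X_std.T, n_probes, rng)
        order, theta, sizes = recursive_rank(
            augmented.T,
            y,
            np.arange(n_genes + n_probes),
            rng,
            C=self.C,
            subset_size=self.subset_size,
            m_min=self.m_min,
            m_max=self.m_max,
            tol=self.convergence_tol,
        )
        ordered_flags = flags[order]
        idx_map = assign_gene_indices([str(i) for i in order], ordered_flags)
        gene_index = {int(kk): v for kk, v in idx_map.items()}
        return gene_index, order, ordered_flags, theta, sizes

    @staticmethod
    def _standardize_pair(
        X_tr: np.ndarray, X_va: np.ndarray | None
    ) -> tuple[np.ndarray, np.ndarray | None]:
        mean = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        X_tr = (X_tr - mean) / sd
        if X_va is not None:
            X_va = (X_va - mean) / sd
        return X_tr, X_va

    def _pair_accuracy_profile(
        self,
        X: np.ndarray,
        y: np.ndarray,
        train: np.ndarray,
        val: np.ndarray,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """One training/validation pair: candidate accuracies v(p) and baseline.

        Returns ``(candidate p values, v(p) at those values, baseline)``; v is
        a step function of p changing only at this pair's observed indices.
        """
        X_tr, X_va = self._standardize_pair(X[train], X[val])
        y_tr, y_va = y[train], y[val]
        gene_index, _, _, _, _ = self._rank_with_probes(X_tr, y_tr, rng)
        idx_values = np.array([gene_index[g] for g in range(X.shape[1])])
        candidates = np.unique(np.concatenate([[0.0], idx_values]))
        accs = np.empty(len(candidates))
        for i, p in enumerate(candidates):
            feats = np.flatnonzero(idx_values <= p)
            if feats.size == 0:
                accs[i] = 0.0  # empty panel cannot classify
                continue
            fit = fit_svm(X_tr[:, feats], y_tr, C=self.C)
            pred = (fit.decision_function(X_va[:, feats]) > 0).astype(int)
            accs[i] = float(np.mean(pred == y_va))
        base_fit = fit_svm(X_tr, y_tr, C=self.C)
        base_pred = (base_fit.decision_function(X_va) > 0).astype(int)
        baseline = float(np.mean(base_pred == y_va))
        return candidates, accs, baseline

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AmfesSelector":
        X, y = check_X_y(X, y)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("AMFES requires samples from both classes")
        seed_seq = np.random.SeedSequence(self.random_state)
        n = len(y)
        r = self.n_splits if self.n_splits is not None else compute_r(n)
        split_rng = np.random.default_rng(seed_seq.spawn(1)[0])
        pairs = plan_splits(y, self.validation_fraction, r=r, rng=split_rng)
        pair_seqs = seed_seq.spawn(r + 1)
        pair_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in pair_seqs]

        profiles = []
        for (train, val), ss in zip(pairs, pair_seqs[:-1]):
            rng = np.random.default_rng(ss)
            profiles.append(self._pair_accuracy_profile(X, y, train, val, rng))

        # av(p) on the pooled candidate grid via per-pair step-function lookup
        pooled = np.unique(np.concatenate([c for c, _, _ in profiles]))
        av = np.zeros(len(pooled))
        for cands, accs, _ in profiles:
            pos = np.searchsorted(cands, pooled, side="right") - 1
            av += np.where(pos >= 0, accs[np.clip(pos, 0, None)], 0.0)
        av /= len(profiles)
        baseline = float(np.mean([b for _, _, b in profiles]))
        p_star = choose_pstar(list(pooled), list(av), baseline)

        # final ranking on all learning samples with fresh probes
        final_rng = np.random.default_rng(pair_seqs[-1])
        X_std, _ = self._standardize_pair(X, None)
        gene_index, order, ordered_flags, theta, sizes = self._rank_with_probes(
            X_std, y, final_rng
        )
        idx_values = np.array([gene_index[g] for g in range(X.shape[1])])
        support = idx_values <= p_star

        self.n_features_in_ = X.shape[1]
        self.support_ = support
        self.p_star_ = float(p_star)
        self.gene_index_ = idx_values
        self.ranking_ = order[~ordered_flags]
        self.final_order_ = order
        self.final_probe_flags_ = ordered_flags
        self.final_stage_scores_ = theta
        self.candidate_values_ = list(map(float, pooled))
        self.candidate_accuracies_ = list(map(float, av))
        self.baseline_accuracy_ = baseline
        self.r_ = r
        self.pair_seeds_ = pair_seeds[:-1]
        self.stage_sizes_ = sizes
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def select_genes(
    ds: ExpressionDataset,
    C: float = 1.0,
    subset_size: int | None = None,
    validation_fraction: float = 0.3,
    n_probes: int | None = None,
    m_min: int = 10,
    m_max: int = 500,
    convergence_tol: float = 0.01,
    seed: int | None = None,
) -> SelectionResult:
    """Run the full AMFES pipeline on a labeled expression dataset."""
    ds.require_both_classes()
    sel = AmfesSelector(
        C=C,
        subset_size=subset_size,
        validation_fraction=validation_fraction,
        n_probes=n_probes,
        m_min=m_min,
        m_max=m_max,
        convergence_tol=convergence_tol,
        random_state=seed,
    )
    sel.fit(ds.values.T, ds.labels)
    gene_ids = list(ds.gene_ids)
    n_genes = len(gene_ids)

    def _name(i: int) -> str:
        return gene_ids[i] if i < n_genes else f"probe{i - n_genes:05d}"

    ordered_ids = [_name(i) for i in sel.final_order_]
    ranking = RankingResult(
        ordered_ids=ordered_ids,
        scores=np.minimum.accumulate(sel.final_stage_scores_),
        probe_flags=sel.final_probe_flags_.copy(),
        stage_scores=sel.final_stage_scores_.copy(),
        gene_indices={g: float(sel.gene_index_[i]) for i, g in enumerate(gene_ids)},
    )
    selected_set = {gene_ids[i] for i in np.flatnonzero(sel.support_)}
    panel = GenePanel(
        gene_ids=[g for g in ranking.original_order if g in selected_set],
        provenance=f"AMFES p*={sel.p_star_:.4g}, seed={seed}",
    )
    return SelectionResult(
        p_star=sel.p_star_,
        panel=panel,
        candidate_values=sel.candidate_values_,
        candidate_accuracies=sel.candidate_accuracies_,
        baseline_accuracy=sel.baseline_accuracy_,
        r=sel.r_,
        pair_seeds=sel.pair_seeds_,
        gene_indices=ranking.gene_indices or {},
        ranking=ranking,
        stage_sizes=sel.stage_sizes_,
    )
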