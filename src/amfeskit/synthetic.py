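"""Synthetic labeled expression data with known ground truth.

The generator emulates the shape of small two-class PBMC microarray studies:
thousands of genes, tens of samples, a small planted set of label-informative
genes, optional blocks of co-expressed genes sharing a latent factor, and
i.i.d. Gaussian noise everywhere else.  Ground truth (which genes are
informative, which belong to which block) is returned alongside the dataset so
selection, MI and network stages can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionDataset

__all__ = ["SyntheticSpec", "generate_dataset", "generate_bivariate_gaussian"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic two-class expression study.

    ``effect_size`` is the class-mean shift of informative genes in units of
    the within-class SD; ``block_rho`` the target pairwise correlation inside
    each co-expressed block.  Informative genes are disjoint from blocks
    unless ``allow_overlap`` is set, keeping ground truth unambiguous.
    """

    n_genes: int = 1000
    n_informative: int = 30
    n_samples_per_class: int = 14
    effect_size: float = 2.0
    n_corr_blocks: int = 0
    block_size: int = 0
    block_rho: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples_per_class) <= 0:
            raise ValueError("n_genes and n_samples_per_class must be positive")
        if self.n_informative < 0 or self.n_corr_blocks < 0 or self.block_size < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        needed = self.n_informative + self.n_corr_blocks * self.block_size
        if not self.allow_overlap and needed > self.n_genes:
            raise ValueError(
                f"{needed} structured genes exceed n_genes={self.n_genes}"
            )


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, list[str], dict[str, list[str]]]:
    """Draw one dataset from ``spec``; pure function of the spec (incl. seed).

    Returns ``(dataset, informative_gene_ids, block_memberships)``.  Class 1
    samples have informative-gene means shifted by ``effect_size · noise_sd``;
    block genes are ``sqrt(rho)·factor + sqrt(1−rho)·noise`` around a shared
    per-sample latent factor, giving pairwise correlation ``rho`` in
    expectation.
    """
    rng = np.random.default_rng(spec.seed)
    n_per = spec.n_samples_per_class
    n_samples = 2 * n_per
    labels = np.array([1] * n_per + [0] * n_per)

    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))

    informative = list(range(spec.n_informative))
    shift = spec.effect_size * spec.noise_sd
    # half the genes shift up in cases, half down, so panels are sign-mixed
    signs = np.where(np.arange(spec.n_informative) % 2 == 0, 1.0, -1.0)
    values[np.ix_(informative, np.flatnonzero(labels == 1))] += shift * signs[:, None]

    blocks: dict[str, list[int]] = {}
    next_free = 0 if spec.allow_overlap else spec.n_informative
    rho = spec.block_rho
    for b in range(spec.n_corr_blocks):
        members = list(range(next_free, next_free + spec.block_size))
        next_free += spec.block_size
        factor = rng.normal(0.0, spec.noise_sd, size=n_samples)
        values[members] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * values[members]
        blocks[f"block{b}"] = members

    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    ds = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        labels=labels,
        covariates={"sex": ["F" if i % 2 == 0 else "M" for i in range(n_samples)]},
    )
    truth = [gene_ids[i] for i in informative]
    memberships = {k: [gene_ids[i] for i in v] for k, v in blocks.items()}
    return ds, truth, memberships


def generate_bivariate_gaussian(
    rho: float, M: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two length-``M`` draws from a standard bivariate normal with corr ``rho``."""
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    if M < 2:
        raise ValueError("need M >= 2 samples")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((2, M))
    x = z[0]
    y = rho * z[0] + np.sqrt(1.0 - rho**2) * z[1]
    return x, y
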