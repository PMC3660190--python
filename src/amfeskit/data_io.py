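"""Expression-table I/O and standardization.

On-disk conventions
-------------------
Expression: TSV, UTF-8, ``.`` decimal separator, genes in rows and samples in
columns (the microarray convention); an orientation flag handles transposed
tables.  Labels: two-column TSV ``sample_id<TAB>label`` with a configurable
mapping of label strings onto {1, 0} (default ``AD``→1, ``normal``→0).
Panels: one gene id per line.  MI matrices: TSV with gene ids as both header
row and first column.  Networks: GraphML or a 3-column edge-list TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GenePanel",
    "read_expression_table",
    "read_labels",
    "write_expression_table",
    "write_labels",
    "read_panel",
    "write_panel",
    "read_mi_matrix",
    "write_mi_matrix",
    "standardize",
    "convert_xlsx_to_tsv",
    "DEFAULT_LABEL_MAP",
]

DEFAULT_LABEL_MAP = {"AD": 1, "normal": 0}


@dataclass
class ExpressionDataset:
    """A genes × samples expression matrix with binary sample labels.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Real-valued normalized expression.
    labels : ndarray of shape (n_samples,)
        Binary class per sample (case = 1, control = 0).
    covariates : dict, optional
        Per-sample string covariates, e.g. ``{"sex": ["F", "M", ...]}``.
    constant_genes : list of str
        Genes flagged as zero-variance by :func:`standardize`.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    covariates: dict[str, list[str]] = field(default_factory=dict)
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.labels.shape != (n_samples,):
            raise ValueError("labels must align with samples")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        for name, vals in self.covariates.items():
            if len(vals) != n_samples:
                raise ValueError(f"covariate {name!r} must align with samples")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_both_classes(self) -> None:
        """Raise unless labels contain both classes (supervised use)."""
        present = set(np.unique(self.labels))
        if not {0, 1} <= present:
            raise ValueError(
                f"supervised operation needs both classes; labels contain {sorted(present)}"
            )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionDataset":
        """Restrict to the given genes, preserving the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return replace(
            self,
            gene_ids=list(gene_ids),
            values=self.values[rows].copy(),
            constant_genes=[g for g in self.constant_genes if g in set(gene_ids)],
        )

    def subset_samples(self, idx: np.ndarray) -> "ExpressionDataset":
        """Restrict to the samples at positional indices ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx].copy(),
            labels=self.labels[idx].copy(),
            covariates={k: [v[i] for i in idx] for k, v in self.covariates.items()},
        )

    def filter_by_covariate(self, name: str, value: str) -> "ExpressionDataset":
        if name not in self.covariates:
            raise KeyError(f"unknown covariate {name!r}")
        idx = np.flatnonzero(np.asarray(self.covariates[name]) == value)
        return self.subset_samples(idx)


@dataclass
class GenePanel:
    """An ordered list of selected gene ids with free-text provenance."""

    gene_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "panel gene")

    def __len__(self) -> int:
        return len(self.gene_ids)


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} identifier {x!r}")
        seen.add(x)


def read_expression_table(
    path,
    orientation: str = "genes-in-rows",
    labels_path=None,
    label_map: dict[str, int] | None = None,
    impute_median: bool = False,
) -> ExpressionDataset:
    """Read a delimited expression table (one header row, one id column).

    Missing values are rejected unless ``impute_median`` is set, in which case
    each gene's missing entries are replaced by that gene's median.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples-in-rows":
        df = df.T
    elif orientation != "genes-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    _check_unique(list(df.index.astype(str)), "gene")
    _check_unique(list(df.columns.astype(str)), "sample")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    nan_mask = np.isnan(values)
    raw_nan = df.isna().to_numpy()
    nonnum = nan_mask & ~raw_nan
    if nonnum.any():
        r, c = np.argwhere(nonnum)[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    if nan_mask.any():
        if not impute_median:
            r, c = np.argwhere(nan_mask)[0]
            raise ValueError(
                f"missing value at gene {df.index[r]!r}, sample {df.columns[c]!r} "
                "(set impute_median=True to impute)"
            )
        med = np.nanmedian(values, axis=1, keepdims=True)
        values = np.where(nan_mask, med, values)
    sample_ids = [str(s) for s in df.columns]
    if labels_path is not None:
        labels, covariates = read_labels(labels_path, sample_ids, label_map)
    else:
        labels = np.zeros(len(sample_ids), dtype=int)
        covariates = {}
    return ExpressionDataset(
        gene_ids=[str(g) for g in df.index],
        sample_ids=sample_ids,
        values=values,
        labels=labels,
        covariates=covariates,
    )


def read_labels(
    path, sample_ids: list[str], label_map: dict[str, int] | None = None
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Read a sample_id/label TSV; extra columns become covariates."""
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels file needs at least sample_id and label columns")
    df = df.set_index(df.columns[0])
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    df = df.loc[sample_ids]
    raw = df.iloc[:, 0]
    labels = np.empty(len(sample_ids), dtype=int)
    for i, v in enumerate(raw):
        if v in label_map:
            labels[i] = label_map[v]
        elif v in {"0", "1"}:
            labels[i] = int(v)
        else:
            raise ValueError(f"unmapped label {v!r} for sample {sample_ids[i]!r}")
    covariates = {c: list(df[c]) for c in df.columns[1:]}
    return labels, covariates


def write_expression_table(ds: ExpressionDataset, path) -> None:
    pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids).to_csv(
        path, sep="\t", index_label="gene_id"
    )


def write_labels(ds: ExpressionDataset, path, label_names=("normal", "AD")) -> None:
    df = pd.DataFrame(
        {"sample_id": ds.sample_ids, "label": [label_names[y] for y in ds.labels]}
    )
    for name, vals in ds.covariates.items():
        df[name] = vals
    df.to_csv(path, sep="\t", index=False)


def read_panel(path, provenance: str = "") -> GenePanel:
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return GenePanel(gene_ids=genes, provenance=provenance or f"read from {path}")


def write_panel(panel: GenePanel, path) -> None:
    Path(path).write_text("".join(g + "\n" for g in panel.gene_ids))


def write_mi_matrix(gene_ids: list[str], values: np.ndarray, path) -> None:
    pd.DataFrame(values, index=gene_ids, columns=gene_ids).to_csv(
        path, sep="\t", index_label="gene_id", float_format="%.12g"
    )


def read_mi_matrix(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(g) for g in df.index], df.to_numpy(dtype=float)


def standardize(ds: ExpressionDataset) -> ExpressionDataset:
    """Scale each gene row to mean 0 and population variance 1.

    Constant (zero-variance) genes cannot be scaled; their rows become all
    zeros and the gene ids are recorded in ``constant_genes``.
    """
    mean = ds.values.mean(axis=1, keepdims=True)
    sd = ds.values.std(axis=1, keepdims=True)  # population (ddof=0) convention
    flat = sd[:, 0] == 0.0
    safe = np.where(flat[:, None], 1.0, sd)
    values = (ds.values - mean) / safe
    values[flat] = 0.0
    return replace(
        ds,
        values=values,
        constant_genes=[g for g, f in zip(ds.gene_ids, flat) if f],
    )


def convert_xlsx_to_tsv(xlsx_path, tsv_path, sheet=0) -> None:
    """One-shot spreadsheet → TSV conversion (keeps the core dependency-light)."""
    df = pd.read_excel(xlsx_path, sheet_name=sheet, index_col=0)
    df.to_csv(tsv_path, sep="\t")
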