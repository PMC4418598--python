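"""Count matrix container, normalization and preprocessing.

The raw observable is a :class:`CountStudy`: a gene x sample matrix of
non-negative integer counts from a paired (T0/T3) design with per-sample
metadata.  Preprocessing follows the conventional bulk RNA-seq path:
median-of-ratios size factors, low-count filtering, a variance-stabilizing
log transform of normalized counts, per-gene least-squares adjustment for
technical covariates, and selection of the most variable genes at baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountStudy",
    "ExpressionMatrix",
    "read_counts",
    "write_counts",
    "size_factors",
    "filter_low_expression",
    "vst",
    "adjust_covariates",
    "select_most_variable",
]

METADATA_COLUMNS = ("subject", "time")


@dataclass
class CountStudy:
    """Gene x sample count matrix with per-sample metadata.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, genes in rows (index = gene IDs),
        samples in columns.
    metadata : DataFrame
        One row per sample (index = sample IDs, aligned with the count
        columns).  Must contain ``subject`` and ``time`` (values "T0"/"T3"
        for a paired study); technical covariates such as ``run``, ``rin``
        and ``rna_concentration`` are carried through when present.
    size_factors : Series, optional
        Per-sample positive normalization factors; computed on demand.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    size_factors: pd.Series | None = field(default=None)

    def __post_init__(self):
        if list(self.counts.columns) != list(self.metadata.index):
            missing = set(self.counts.columns) ^ set(self.metadata.index)
            raise ValueError(f"count columns and metadata rows disagree: {sorted(missing)}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicated gene ID: {dup!r}")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None and np.any(self.size_factors.to_numpy() <= 0):
            raise ValueError("size factors must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def with_size_factors(self) -> "CountStudy":
        """Return a copy carrying median-of-ratios size factors."""
        if self.size_factors is not None:
            return self
        return replace(self, size_factors=size_factors(self.counts))

    def mask_time(self, time: str) -> np.ndarray:
        return (self.metadata["time"] == time).to_numpy()


@dataclass
class ExpressionMatrix:
    """Transformed gene x sample expression with provenance."""

    values: pd.DataFrame
    transform: str = "log2(norm+1)"
    adjusted_for: tuple[str, ...] = ()

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def read_counts(counts_path, metadata_path) -> CountStudy:
    """Read a count TSV (gene IDs in the first column) and a metadata TSV
    keyed by sample ID into a :class:`CountStudy`.

    Raises a format error for non-integer or negative counts and names any
    sample present in the counts but absent from the metadata.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    if np.any(vals < 0):
        raise ValueError("count matrix contains negative entries")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("count matrix contains non-integer entries")
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    meta = meta.loc[counts.columns]
    return CountStudy(counts=counts.astype(np.int64), metadata=meta)


def write_counts(study: CountStudy, counts_path, metadata_path) -> None:
    """Write counts and metadata TSVs (inverse of :func:`read_counts`)."""
    study.counts.to_csv(counts_path, sep="\t")
    study.metadata.to_csv(metadata_path, sep="\t")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j the factor is the median over genes of
    ``count_gj / geometric_mean_g``, restricted to genes with nonzero
    counts in every sample (those are the only genes with a finite
    geometric-mean ratio).
    """
    vals = counts.to_numpy(dtype=float)
    all_nonzero = np.all(vals > 0, axis=1)
    if not np.any(all_nonzero):
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "consider adding a pseudo-count before normalization"
        )
    logs = np.log(vals[all_nonzero])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def filter_low_expression(study: CountStudy, min_mean: float = 10.0) -> CountStudy:
    """Remove genes whose mean count is below ``min_mean`` at both times.

    A gene is kept as soon as its mean raw count reaches the threshold at
    either time point (the rule is a strict ``<`` at both).
    """
    t0 = study.mask_time("T0")
    t3 = study.mask_time("T3")
    vals = study.counts.to_numpy(dtype=float)
    mean_t0 = vals[:, t0].mean(axis=1)
    mean_t3 = vals[:, t3].mean(axis=1)
    keep = (mean_t0 >= min_mean) | (mean_t3 >= min_mean)
    n_removed = int((~keep).sum())
    filtered = replace(study, counts=study.counts.loc[keep], size_factors=None)
    filtered.n_removed = n_removed
    return filtered


def vst(study: CountStudy) -> ExpressionMatrix:
    """Variance-stabilizing transform: log2(count / size_factor + 1).

    Monotone in counts within each sample; size factors must have been
    computed (see :meth:`CountStudy.with_size_factors`).
    """
    if study.size_factors is None:
        raise ValueError("size factors must be computed before the VST")
    norm = study.counts.to_numpy(dtype=float) / study.size_factors.to_numpy()[None, :]
    vals = pd.DataFrame(np.log2(norm + 1.0), index=study.genes, columns=study.samples)
    return ExpressionMatrix(values=vals, transform="log2(norm+1)")


def adjust_covariates(
    expr: ExpressionMatrix,
    covariates: pd.DataFrame,
    columns: Sequence[str] = ("run", "rin", "rna_concentration"),
) -> ExpressionMatrix:
    """Regress technical covariates out of each gene.

    Per gene, expression is replaced by the residual of an ordinary
    least-squares fit on the covariates (categoricals one-hot encoded,
    constants/collinear columns dropped with a warning) plus the gene's
    mean.  The output is numerically uncorrelated with every retained
    covariate column.
    """
    cov = covariates.loc[expr.samples, list(columns)]
    parts = []
    for col in cov.columns:
        if cov[col].dtype == object or str(cov[col].dtype) == "category":
            if cov[col].nunique() <= 1:
                warnings.warn(f"covariate {col!r} is constant; dropped")
                continue
            parts.append(pd.get_dummies(cov[col], prefix=col, drop_first=True, dtype=float))
        else:
            parts.append(cov[[col]].astype(float))
    design = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cov.index)

    keep = []
    for col in design.columns:
        if design[col].nunique() <= 1:
            warnings.warn(f"covariate {col!r} is constant; dropped")
        else:
            keep.append(col)
    design = design[keep]
    X = np.column_stack([np.ones(len(design))] + [design[c].to_numpy() for c in design.columns])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("collinear covariates detected; using pseudo-inverse")

    Y = expr.values.to_numpy().T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    adjusted = resid.T + expr.values.to_numpy().mean(axis=1, keepdims=True)
    out = pd.DataFrame(adjusted, index=expr.genes, columns=expr.samples)
    return ExpressionMatrix(values=out, transform=expr.transform, adjusted_for=tuple(columns))


def select_most_variable(
    expr: ExpressionMatrix, k: int, sample_mask: np.ndarray | None = None
) -> ExpressionMatrix:
    """Keep the k genes with the highest variance over the given samples.

    ``sample_mask`` restricts the variance computation (typically the T0
    columns); all columns are retained in the output.  Ties at the cutoff
    are broken by gene-ID order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > expr.values.shape[0]:
        raise ValueError("k exceeds the number of genes")
    sub = expr.values.to_numpy() if sample_mask is None else expr.values.to_numpy()[:, sample_mask]
    variances = sub.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": variances, "gene": expr.genes}).sort_values(
        ["var", "gene"], ascending=[False, True]
    )
    chosen = order["gene"].iloc[:k]
    keep = expr.genes[expr.genes.isin(set(chosen))]
    return ExpressionMatrix(
        values=expr.values.loc[keep],
        transform=expr.transform,
        adjusted_for=expr.adjusted_for,
    )
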