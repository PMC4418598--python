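"""Weighted gene coexpression network construction and module detection.

The network is built from an expression matrix (genes x samples) in the
usual weighted-network fashion: pairwise Pearson correlation raised to a
soft power beta gives the adjacency a_ij = |cor(x_i, x_j)|^beta (unsigned
by default), the topological overlap measure (TOM) converts shared
neighborhoods into a similarity, and average-linkage hierarchical
clustering of 1 - TOM with an adaptive tree cut yields modules.  Module
label 0 ("grey") collects unassigned genes.  Each module is summarized by
its eigengene (first principal component of the standardized member
expression) and each gene by its module membership (MM), the correlation
with a module eigengene.

:class:`CoexpressionNetwork` is the model object; :meth:`fit` runs the
soft-threshold/adjacency/TOM/cut/merge pipeline and returns a
:class:`NetworkResults` carrying labels, eigengenes, MM and connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CoexpressionNetwork",
    "NetworkResults",
    "adjacency",
    "pick_soft_threshold",
    "tom",
    "detect_modules",
    "eigengene",
    "merge_modules",
    "module_membership",
    "hubgenes",
]


def _corr(values: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of a genes x samples matrix."""
    sd = values.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant gene encountered; drop constant genes first")
    c = np.corrcoef(values)
    return np.clip(c, -1.0, 1.0)


def adjacency(values, beta: int = 6, signed: bool = False) -> np.ndarray:
    """Soft-thresholded adjacency |cor|^beta (or ((1+cor)/2)^beta signed).

    ``values`` is genes x samples with at least 4 samples; the diagonal is
    set to 1.
    """
    values = np.asarray(values, dtype=float)
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if values.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    c = _corr(values)
    a = ((1.0 + c) / 2.0) ** beta if signed else np.abs(c) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Per-gene connectivity k_i = sum_{u != i} a_iu (self term excluded)."""
    return adj.sum(axis=1) - np.diag(adj)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index: bin connectivity, regress log10 p(k)
    on log10 mean(k) per bin; returns (-sign(slope) * R^2, slope)."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() > 0:
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_res = np.sum((ys - fitted) ** 2)
    ss_tot = np.sum((ys - ys.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


@dataclass
class SoftThresholdScan:
    """Scale-free-topology scan over candidate soft powers."""

    table: pd.DataFrame  # power, fit_index, slope, mean_k, median_k, max_k
    recommended: int | None  # smallest power reaching the fit-index target


def pick_soft_threshold(
    values, powers=tuple(range(1, 13)), fit_target: float = 0.8, signed: bool = False
) -> SoftThresholdScan:
    """Scan soft powers for approximate scale-free topology.

    For each power the connectivity distribution is binned (10 bins) and
    log10 frequency regressed on log10 mean connectivity; the fit index is
    -sign(slope) * R^2.  Recommends the smallest power whose index reaches
    ``fit_target``; ``recommended`` is None when no power qualifies.
    """
    powers = sorted(set(int(p) for p in powers))
    if any(p < 1 or p > 30 for p in powers):
        raise ValueError("powers must lie in [1, 30]")
    values = np.asarray(values, dtype=float)
    c = _corr(values)
    base = ((1.0 + c) / 2.0) if signed else np.abs(c)
    np.fill_diagonal(base, 0.0)
    rows = []
    for p in powers:
        a = base**p
        k = a.sum(axis=1)
        if np.all(k == 0):
            raise ValueError("all-zero connectivity")
        fit, slope = _scale_free_fit(k)
        rows.append((p, fit, slope, k.mean(), np.median(k), k.max()))
    table = pd.DataFrame(
        rows, columns=["power", "fit_index", "slope", "mean_k", "median_k", "max_k"]
    )
    qual = table[table["fit_index"] >= fit_target]
    recommended = int(qual["power"].iloc[0]) if len(qual) else None
    return SoftThresholdScan(table=table, recommended=recommended)


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k the self-excluded connectivity;
    the diagonal is 1.
    """
    adj = np.asarray(adj, dtype=float)
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # l_ij = sum_u a_iu a_uj with u != i,j since diag(a)=0
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (l + a) / (kmin + 1.0 - a)
    t[~np.isfinite(t)] = 0.0
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def detect_modules(
    tom_matrix: np.ndarray,
    min_size: int = 20,
    cut_height: float = 0.96,
) -> np.ndarray:
    """Tree-variant dynamic cut of the TOM dendrogram.

    Average-linkage clustering of 1 - TOM is cut at an absolute height
    ``cut_height`` on the TOM dissimilarity scale (which lies in [0, 1];
    the default 0.96 trims genes that attach loosely near the top of a
    branch): branches whose members
    cohere below the cut become candidate modules, branches smaller than
    ``min_size`` fall to label 0 (grey).  Structureless data merges near
    the top of the dendrogram (1 - TOM close to 1), so most genes stay
    grey; planted modules merge far below the cut.  Labels are renumbered
    by decreasing module size (1 = largest).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    t = np.asarray(tom_matrix, dtype=float)
    n = t.shape[0]
    if n < 3:
        return np.zeros(n, dtype=int)
    diss = 1.0 - t
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    labels = np.zeros(n, dtype=int)
    kept = []
    for lab in np.unique(raw):
        members = np.flatnonzero(raw == lab)
        if members.size >= min_size:
            kept.append((members.size, lab, members))
    kept.sort(key=lambda x: (-x[0], x[1]))
    for new_label, (_, _, members) in enumerate(kept, start=1):
        labels[members] = new_label
    return labels


def eigengene(values: np.ndarray, member_idx) -> np.ndarray:
    """Module eigengene: unit-norm sample scores of the first principal
    component of the standardized member expression, oriented so the mean
    correlation with member genes is positive.  A single-gene module
    returns the standardized gene itself (unit norm)."""
    member_idx = np.asarray(member_idx)
    if member_idx.size == 0:
        raise ValueError("module is empty")
    sub = np.asarray(values, dtype=float)[member_idx]
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    if member_idx.size == 1:
        e = z[0]
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
    norm = np.linalg.norm(e)
    e = e / norm if norm > 0 else e
    cors = _row_cor_with(z, e)
    if np.nanmean(cors) < 0:
        e = -e
    return e


def _row_cor_with(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, rc @ vc / denom, np.nan)


def _eigengene_frame(values, labels, sample_index) -> pd.DataFrame:
    mods = sorted(m for m in np.unique(labels) if m > 0)
    rows = {m: eigengene(values, np.flatnonzero(labels == m)) for m in mods}
    return pd.DataFrame(rows, index=sample_index).T.rename_axis("module")


def merge_modules(values: np.ndarray, labels: np.ndarray, cut_height: float = 0.25):
    """Merge modules whose eigengenes are highly correlated.

    Average-linkage clustering of eigengenes on 1 - cor; modules joining
    below ``cut_height`` (eigengene correlation above 1 - cut_height) are
    unified, and the procedure iterates until stable.  Labels are
    renumbered by decreasing size."""
    labels = np.asarray(labels).copy()
    while True:
        mods = sorted(m for m in np.unique(labels) if m > 0)
        if len(mods) <= 1:
            break
        eig = np.vstack([eigengene(values, np.flatnonzero(labels == m)) for m in mods])
        d = 1.0 - np.corrcoef(eig)
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, 2.0)
        Z = linkage(squareform(d, checks=False), method="average")
        groups = fcluster(Z, t=cut_height, criterion="distance")
        if len(np.unique(groups)) == len(mods):
            break
        mapping = {m: g for m, g in zip(mods, groups)}
        new = np.zeros_like(labels)
        for m, g in mapping.items():
            new[labels == m] = g
        labels = new
    return _renumber(labels)


def _renumber(labels: np.ndarray) -> np.ndarray:
    mods = [m for m in np.unique(labels) if m > 0]
    sizes = {m: int((labels == m).sum()) for m in mods}
    order = sorted(mods, key=lambda m: (-sizes[m], m))
    out = np.zeros_like(labels)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def module_membership(values: np.ndarray, eigengenes: pd.DataFrame, gene_index) -> pd.DataFrame:
    """Correlation of every gene with every module eigengene (genes x
    modules); constant genes give NaN with a warning."""
    values = np.asarray(values, dtype=float)
    if np.any(values.std(axis=1) == 0):
        warnings.warn("constant gene(s): module membership set to NaN")
    mm = {}
    for m in eigengenes.index:
        mm[m] = _row_cor_with(values, eigengenes.loc[m].to_numpy())
    return pd.DataFrame(mm, index=gene_index).rename_axis(columns="module")


def hubgenes(mm: pd.DataFrame, labels: pd.Series, module: int, top_n: int = 30):
    """Top-n member genes of a module by absolute module membership
    (descending; ties by gene ID).  Returns the ordered gene list."""
    members = labels.index[labels == module]
    if len(members) == 0:
        raise ValueError(f"module {module} does not exist or is empty")
    scores = mm.loc[members, module].abs()
    order = (
        pd.DataFrame({"gene": members, "score": scores.to_numpy()})
        .sort_values(["score", "gene"], ascending=[False, True])
    )
    return list(order["gene"].iloc[:top_n])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class CoexpressionNetwork:
    """Weighted coexpression network model over an expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix or DataFrame
        Genes x samples expression on a variance-stabilized scale.
    signed : bool
        Use the signed adjacency variant (default unsigned, |cor|^beta).
    """

    def __init__(self, expr, signed: bool = False):
        if isinstance(expr, pd.DataFrame):
            values = expr
        elif isinstance(getattr(expr, "values", None), pd.DataFrame):
            values = expr.values
        else:
            raise TypeError("expr must be an ExpressionMatrix or DataFrame")
        sd = values.to_numpy().std(axis=1)
        if np.any(sd == 0):
            warnings.warn(f"dropping {int((sd == 0).sum())} constant gene(s)")
            values = values.loc[sd > 0]
        self.expr = values
        self.signed = signed

    def scan_soft_threshold(self, powers=tuple(range(1, 13)), fit_target=0.8):
        return pick_soft_threshold(
            self.expr.to_numpy(), powers=powers, fit_target=fit_target, signed=self.signed
        )

    def fit(
        self,
        beta: int = 6,
        min_size: int = 20,
        merge_height: float = 0.25,
        cut_height: float = 0.96,
        merge: bool = True,
    ) -> "NetworkResults":
        """Adjacency -> TOM -> tree cut -> (optional) eigengene merge."""
        vals = self.expr.to_numpy()
        adj = adjacency(vals, beta=beta, signed=self.signed)
        t = tom(adj)
        labels = detect_modules(t, min_size=min_size, cut_height=cut_height)
        if merge and labels.max() > 1:
            labels = merge_modules(vals, labels, cut_height=merge_height)
        eig = (
            _eigengene_frame(vals, labels, self.expr.columns)
            if labels.max() > 0
            else pd.DataFrame(columns=self.expr.columns)
        )
        mm = (
            module_membership(vals, eig, self.expr.index)
            if len(eig)
            else pd.DataFrame(index=self.expr.index)
        )
        return NetworkResults(
            model=self,
            beta=beta,
            min_size=min_size,
            merge_height=merge_height,
            cut_height=cut_height,
            adjacency=adj,
            tom=t,
            labels=pd.Series(labels, index=self.expr.index, name="module"),
            eigengenes=eig,
            mm=mm,
            connectivity=pd.Series(connectivity(adj), index=self.expr.index, name="k"),
        )


@dataclass
class NetworkResults:
    """Fitted coexpression network: module labels (0 = grey/unassigned),
    eigengenes (module x sample), module membership and connectivity."""

    model: CoexpressionNetwork
    beta: int
    min_size: int
    merge_height: float
    cut_height: float
    adjacency: np.ndarray
    tom: np.ndarray
    labels: pd.Series
    eigengenes: pd.DataFrame
    mm: pd.DataFrame
    connectivity: pd.Series = field(default=None)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def module_genes(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    def module_sizes(self) -> pd.Series:
        mods = self.labels[self.labels > 0]
        return mods.value_counts().sort_index()

    def hubgenes(self, module: int, top_n: int = 30):
        return hubgenes(self.mm, self.labels, module, top_n=top_n)

    def hub_correlations(self, module: int, top_n: int = 30) -> pd.DataFrame:
        """Pairwise correlation sub-matrix of the hubgenes (for circle-plot
        style displays)."""
        hubs = self.hubgenes(module, top_n=top_n)
        sub = self.model.expr.loc[hubs].to_numpy()
        return pd.DataFrame(np.corrcoef(sub), index=hubs, columns=hubs)

    def summary(self) -> str:
        sizes = self.module_sizes()
        grey = int((self.labels == 0).sum())
        lines = [
            "Weighted coexpression network",
            f"  genes:                 {len(self.labels)}",
            f"  soft power beta:       {self.beta} ({'signed' if self.model.signed else 'unsigned'})",
            f"  modules detected:      {self.n_modules}",
            f"  unassigned (grey):     {grey}",
            "  module sizes:          "
            + ", ".join(f"{m}:{s}" for m, s in sizes.items()),
        ]
        return "\n".join(lines)
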