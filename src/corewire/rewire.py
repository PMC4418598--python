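"""Cross-condition network comparison: module preservation and rewiring.

Given module labels learned in a reference condition (e.g. baseline T0,
or an obese reference cohort), these routines quantify how each module's
internal correlation structure changes in a test condition (e.g. T3 after
the intervention, or a lean cohort):

* fixed-order correlation matrices of a module's members in both
  conditions (the before/after heatmap comparison, gene order frozen by
  reference module membership);
* module membership recomputed in the test condition with the eigengene
  calculated on the *identical* gene set, yielding a per-gene membership
  drop delta_mm and rule-based "disconnected" calls;
* thresholded edge networks keeping only correlations with p below a cut
  and |cor| above a magnitude gate;
* a cross-study wrapper matching gene identifiers between two studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import eigengene, _row_cor_with

__all__ = [
    "RewiringReport",
    "condition_matrices",
    "membership_shift",
    "edge_network",
    "preserve_across_studies",
]


@dataclass
class RewiringReport:
    """Per-gene membership change between a reference and a test condition.

    ``gene_table`` has one row per analyzed module gene: module, mm_ref,
    mm_test, delta_mm = mm_ref - mm_test, and the disconnection flag
    (mm_ref >= high_cut and mm_test <= low_cut).  ``matrices`` maps module
    label -> (reference, test) correlation matrices in frozen gene order.
    """

    gene_table: pd.DataFrame
    matrices: dict = field(default_factory=dict)
    high_cut: float = 0.5
    low_cut: float = 0.2
    skipped_modules: tuple = ()
    unmapped_genes: tuple = ()

    def disconnected(self) -> pd.Index:
        return self.gene_table.index[self.gene_table["disconnected"]]

    def ranking(self) -> pd.DataFrame:
        """Genes ranked by decreasing membership loss (connection-loss
        ranking)."""
        return self.gene_table.sort_values("delta_mm", ascending=False)

    def summary(self) -> str:
        n_disc = int(self.gene_table["disconnected"].sum())
        lines = [
            "Cross-condition module rewiring",
            f"  module genes analyzed: {len(self.gene_table)}",
            f"  disconnected (mm_ref>={self.high_cut}, mm_test<={self.low_cut}): {n_disc}",
        ]
        top = self.ranking().head(5)
        lines.append("  largest membership losses:")
        lines.append(top[["module", "mm_ref", "mm_test", "delta_mm"]].round(3).to_string())
        return "\n".join(lines)


def _module_mm(values: np.ndarray, member_rows: np.ndarray) -> np.ndarray:
    """Module membership of member genes against the eigengene computed on
    exactly those genes (orientation rule applied inside ``eigengene``)."""
    e = eigengene(values, member_rows)
    return _row_cor_with(values[member_rows], e)


def condition_matrices(
    expr_ref: pd.DataFrame, expr_test: pd.DataFrame, labels: pd.Series, module: int
):
    """Pairwise correlation matrices of a module's genes in each condition.

    Gene order is fixed by descending reference module membership, and the
    test matrix uses the identical order, so the two heatmaps are directly
    comparable.
    """
    members = labels.index[labels == module]
    if len(members) == 0:
        raise ValueError(f"module {module} has no members")
    missing = [g for g in members if g not in expr_test.index]
    if missing:
        raise ValueError(f"genes missing in test condition: {missing}")

    ref_vals = expr_ref.loc[members].to_numpy()
    mm_ref = _module_mm(expr_ref.to_numpy(), expr_ref.index.get_indexer(members))
    order = np.argsort(-mm_ref, kind="stable")
    ordered = members[order]

    ref_mat = pd.DataFrame(
        np.corrcoef(expr_ref.loc[ordered].to_numpy()), index=ordered, columns=ordered
    )
    test_mat = pd.DataFrame(
        np.corrcoef(expr_test.loc[ordered].to_numpy()), index=ordered, columns=ordered
    )
    return ref_mat, test_mat


def membership_shift(
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    labels: pd.Series,
    high_cut: float = 0.5,
    low_cut: float = 0.2,
    min_module: int = 3,
    with_matrices: bool = True,
) -> RewiringReport:
    """Membership change of every module gene between two conditions.

    For each module the eigengene is recomputed per condition on the same
    member set (labels come from the reference condition); each member's
    module membership is the correlation with that condition's eigengene.
    A gene is flagged disconnected when mm_ref >= ``high_cut`` and
    mm_test <= ``low_cut``.  Modules with fewer than ``min_module`` genes
    present in either condition are skipped with a warning.
    """
    rows = []
    matrices = {}
    skipped = []
    for module in sorted(m for m in labels.unique() if m > 0):
        members = labels.index[labels == module]
        present = [g for g in members if g in expr_ref.index and g in expr_test.index]
        if len(present) < min_module:
            warnings.warn(f"module {module} has fewer than {min_module} usable genes; skipped")
            skipped.append(module)
            continue
        members = pd.Index(present)
        ref_rows = expr_ref.index.get_indexer(members)
        test_rows = expr_test.index.get_indexer(members)
        mm_ref = _module_mm(expr_ref.to_numpy(), ref_rows)
        mm_test = _module_mm(expr_test.to_numpy(), test_rows)
        for g, a, b in zip(members, mm_ref, mm_test):
            rows.append((g, module, a, b))
        if with_matrices:
            matrices[module] = condition_matrices(expr_ref, expr_test, labels, module)

    table = pd.DataFrame(rows, columns=["gene", "module", "mm_ref", "mm_test"]).set_index("gene")
    table["delta_mm"] = table["mm_ref"] - table["mm_test"]
    table["disconnected"] = (table["mm_ref"] >= high_cut) & (table["mm_test"] <= low_cut)
    return RewiringReport(
        gene_table=table,
        matrices=matrices,
        high_cut=high_cut,
        low_cut=low_cut,
        skipped_modules=tuple(skipped),
    )


def edge_network(expr: pd.DataFrame, p_cut: float = 0.05, cor_cut: float = 0.4) -> pd.DataFrame:
    """Thresholded correlation edge list.

    An edge (i, j) is retained iff the two-sided correlation-test p-value
    is below ``p_cut`` AND |cor| exceeds ``cor_cut``; the weight is the
    signed correlation.  Both orientations of each undirected edge are
    emitted; self-edges never are.  Requires at least 5 samples.
    """
    n = expr.shape[1]
    if n < 5:
        raise ValueError("need at least 5 samples")
    c = np.corrcoef(expr.to_numpy())
    np.fill_diagonal(c, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = c * np.sqrt((n - 2) / np.maximum(1.0 - c**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(c) >= 1.0 - 1e-12] = 0.0
    keep = (p < p_cut) & (np.abs(c) > cor_cut)
    ii, jj = np.nonzero(keep)
    genes = expr.index
    return pd.DataFrame(
        {
            "gene_i": genes[ii],
            "gene_j": genes[jj],
            "cor": c[ii, jj],
            "p": p[ii, jj],
        }
    )


def preserve_across_studies(
    labels_ref: pd.Series,
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    high_cut: float = 0.5,
    low_cut: float = 0.2,
    min_mappable: float = 0.5,
) -> RewiringReport:
    """Module preservation between two independent studies.

    Study A (where the modules were detected) is the reference, study B
    the test; gene identifiers must live in a shared namespace, unmapped
    genes are dropped with a report, and a module with less than
    ``min_mappable`` of its genes mappable is skipped.  The result carries
    the per-gene connection-loss ranking (``.ranking()``).
    """
    shared = expr_ref.index.intersection(expr_test.index)
    unmapped = tuple(g for g in labels_ref.index if g not in shared)
    labels = labels_ref[labels_ref.index.isin(shared)]

    kept_labels = labels.copy()
    skipped = []
    for module in sorted(m for m in labels_ref.unique() if m > 0):
        total = int((labels_ref == module).sum())
        mapped = int((labels == module).sum())
        if total and mapped / total < min_mappable:
            warnings.warn(
                f"module {module}: only {mapped}/{total} genes mappable; skipped"
            )
            skipped.append(module)
            kept_labels = kept_labels[kept_labels != module]

    if kept_labels[kept_labels > 0].empty:
        warnings.warn("no module has enough mappable genes; empty report")
        empty = pd.DataFrame(
            columns=["module", "mm_ref", "mm_test", "delta_mm", "disconnected"]
        )
        return RewiringReport(
            gene_table=empty,
            high_cut=high_cut,
            low_cut=low_cut,
            skipped_modules=tuple(skipped),
            unmapped_genes=unmapped,
        )

    report = membership_shift(
        expr_ref.loc[shared],
        expr_test.loc[shared],
        kept_labels,
        high_cut=high_cut,
        low_cut=low_cut,
    )
    report.skipped_modules = tuple(skipped) + report.skipped_modules
    report.unmapped_genes = unmapped
    return report
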