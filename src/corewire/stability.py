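"""Jackknife stability of coexpression modules.

Module detection is rerun on every leave-one-out subset of the samples
(or subjects), each rerun's modules are matched to the original ones by
maximum Jaccard overlap (or, as a variant, by maximum absolute eigengene
correlation), and per-gene classification counts k_i record how often a
gene landed in its own module's best match.  A gene is "correctly
classified" when k_i reaches ceil(r * n_subsets), with r = 18/22 by
default so the rule reduces to >= 18 of 22 subsets in a 22-sample design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import CoexpressionNetwork, eigengene, _row_cor_with

__all__ = ["jaccard", "best_match", "jackknife_stability", "StabilityReport"]

DEFAULT_THRESHOLD_FRAC = 18.0 / 22.0


def jaccard(set_a, set_b) -> float:
    """Jaccard index |A n B| / |A u B|; 0 when both sets are empty."""
    a, b = frozenset(set_a), frozenset(set_b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def best_match(
    ref_modules: dict,
    test_modules: dict,
    criterion: str = "jaccard",
    ref_eigengenes: pd.DataFrame | None = None,
    test_eigengenes: pd.DataFrame | None = None,
) -> dict:
    """Best-matching test module for each reference module.

    ``ref_modules``/``test_modules`` map module label -> gene set (label 0
    must already be excluded).  With ``criterion='jaccard'`` the score is
    the Jaccard overlap; with ``'eigengene_cor'`` it is the absolute
    correlation between eigengenes (the sign of a principal component is
    arbitrary).  Ties prefer the larger test module, then the lower label.
    Matching is independent per reference module.  An empty test partition
    yields score 0 (matched label None).
    """
    if criterion not in ("jaccard", "eigengene_cor"):
        raise ValueError("criterion must be 'jaccard' or 'eigengene_cor'")
    out = {}
    for ref_lab, ref_genes in ref_modules.items():
        best = (None, 0.0)
        for test_lab in sorted(test_modules, key=lambda t: (-len(test_modules[t]), t)):
            if criterion == "jaccard":
                score = jaccard(ref_genes, test_modules[test_lab])
            else:
                score = abs(
                    float(
                        np.corrcoef(
                            ref_eigengenes.loc[ref_lab].to_numpy(),
                            test_eigengenes.loc[test_lab].to_numpy(),
                        )[0, 1]
                    )
                )
            if score > best[1]:
                best = (test_lab, score)
        out[ref_lab] = best
    return out


@dataclass
class StabilityReport:
    """Per-module and per-gene jackknife stability summaries."""

    module_summary: pd.DataFrame  # mean/sd max-Jaccard, mean |eigengene cor|, prop correct
    gene_table: pd.DataFrame  # gene, module, k_i, stable
    n_subsets: int
    stability_threshold: int
    subset_jaccards: pd.DataFrame | None = None  # module x left-out unit

    def summary(self) -> str:
        lines = [
            f"Jackknife stability over {self.n_subsets} leave-one-out subsets "
            f"(stable if k_i >= {self.stability_threshold})",
            self.module_summary.round(3).to_string(),
        ]
        return "\n".join(lines)


def jackknife_stability(
    expr: pd.DataFrame,
    network_params: dict | None = None,
    reference=None,
    subjects: pd.Series | None = None,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    criterion: str = "jaccard",
) -> StabilityReport:
    """Leave-one-out stability of module detection.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples expression used for the reference detection.
    network_params : dict
        Keyword arguments for :meth:`CoexpressionNetwork.fit`; the
        jackknife reruns use exactly these.
    reference : NetworkResults, optional
        A pre-computed reference fit.  Its parameters must equal
        ``network_params``; a mismatch raises.
    subjects : Series, optional
        Sample -> subject mapping; when given, one *subject* (all of its
        samples) is left out per subset, otherwise one sample.
    threshold_frac : float
        r in the stability rule k_i >= ceil(r * n_subsets).
    criterion : 'jaccard' or 'eigengene_cor'
        Module-matching criterion; k_i counting follows the same matches.
    """
    params = dict(network_params or {})
    if expr.shape[1] < 5:
        raise ValueError("need at least 5 samples for a jackknife")

    if reference is None:
        reference = CoexpressionNetwork(expr).fit(**params)
    else:
        for key, val in params.items():
            if getattr(reference, key, val) != val:
                raise ValueError(
                    f"reference was fitted with {key}={getattr(reference, key)}, "
                    f"jackknife requested {val}; parameters must be identical"
                )

    labels = reference.labels
    ref_modules = {
        int(m): frozenset(labels.index[labels == m]) for m in sorted(labels.unique()) if m > 0
    }
    if not ref_modules:
        warnings.warn("reference detection produced no modules")

    if subjects is not None:
        units = list(dict.fromkeys(subjects.loc[expr.columns]))
        drop_cols = {u: expr.columns[(subjects.loc[expr.columns] == u).to_numpy()] for u in units}
    else:
        units = list(expr.columns)
        drop_cols = {u: pd.Index([u]) for u in units}

    n_subsets = len(units)
    threshold = math.ceil(threshold_frac * n_subsets)
    k_counts = pd.Series(0, index=expr.index)
    jaccards = {m: [] for m in ref_modules}
    eig_cors = {m: [] for m in ref_modules}

    for unit in units:
        keep = expr.columns.difference(drop_cols[unit], sort=False)
        sub = expr[keep]
        sub_fit = CoexpressionNetwork(sub).fit(**params)
        sub_labels = sub_fit.labels
        test_modules = {
            int(m): frozenset(sub_labels.index[sub_labels == m])
            for m in sorted(sub_labels.unique())
            if m > 0
        }
        vals = sub.to_numpy()
        pos = {g: i for i, g in enumerate(sub.index)}
        ref_eig = pd.DataFrame(
            {
                m: eigengene(vals, np.asarray([pos[g] for g in genes]))
                for m, genes in ref_modules.items()
            }
        ).T
        test_eig = (
            pd.DataFrame(
                {
                    m: eigengene(vals, np.asarray([pos[g] for g in genes]))
                    for m, genes in test_modules.items()
                }
            ).T
            if test_modules
            else pd.DataFrame()
        )
        matches = best_match(
            ref_modules,
            test_modules,
            criterion=criterion,
            ref_eigengenes=ref_eig,
            test_eigengenes=test_eig,
        )
        for m, (test_lab, score) in matches.items():
            jaccards[m].append(
                score if criterion == "jaccard" else jaccard(
                    ref_modules[m], test_modules.get(test_lab, frozenset())
                )
            )
            if test_modules and test_lab is not None and len(test_eig):
                eig_cors[m].append(
                    abs(
                        float(
                            np.corrcoef(
                                ref_eig.loc[m].to_numpy(), test_eig.loc[test_lab].to_numpy()
                            )[0, 1]
                        )
                    )
                )
            else:
                eig_cors[m].append(0.0)
            if test_lab is not None:
                hit = ref_modules[m] & test_modules[test_lab]
                k_counts.loc[list(hit)] += 1

    rows = []
    for m, genes in ref_modules.items():
        genes = list(genes)
        ki = k_counts.loc[genes]
        rows.append(
            (
                m,
                len(genes),
                float(np.mean(jaccards[m])),
                float(np.std(jaccards[m], ddof=1)) if n_subsets > 1 else 0.0,
                float(np.mean(eig_cors[m])),
                float((ki >= threshold).mean()),
            )
        )
    module_summary = pd.DataFrame(
        rows,
        columns=["module", "size", "mean_jaccard", "sd_jaccard", "mean_eigengene_cor", "prop_correct"],
    ).set_index("module")

    gene_table = pd.DataFrame(
        {
            "module": labels,
            "k_i": k_counts,
            "stable": (k_counts >= threshold) & (labels > 0),
        }
    )
    return StabilityReport(
        module_summary=module_summary,
        gene_table=gene_table,
        n_subsets=n_subsets,
        stability_threshold=threshold,
        subset_jaccards=pd.DataFrame(jaccards, index=units).T.rename_axis("module"),
    )
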