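"""Eigengene-trait association (correlation-heatmap machinery).

Spearman rank correlations between module eigengenes and phenotypic
traits, with two-sided p-values from the t approximation,
pairwise-complete handling of missing trait values, and BH adjustment
across the full module x trait grid (raw p-values are kept alongside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr

__all__ = ["TraitAssociation", "eigengene_trait_cor"]


@dataclass
class TraitAssociation:
    """Module x trait Spearman association grid."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: pd.DataFrame  # pairwise-complete sample count per cell

    def heatmap_table(self) -> pd.DataFrame:
        """Heatmap-ready layout: rows = traits, columns = modules."""
        return self.rho.T

    def summary(self) -> str:
        cells = self.rho.stack().dropna()
        strongest = cells.abs().sort_values(ascending=False).head(5)
        lines = ["Eigengene-trait Spearman associations", "  strongest correlations:"]
        for (module, trait), _ in strongest.items():
            lines.append(
                f"    module {module} ~ {trait}: rho={self.rho.loc[module, trait]:+.3f} "
                f"(p={self.p.loc[module, trait]:.3g}, q={self.q.loc[module, trait]:.3g})"
            )
        return "\n".join(lines)


def eigengene_trait_cor(
    eigengenes: pd.DataFrame, trait_table: pd.DataFrame, min_n: int = 5
) -> TraitAssociation:
    """Correlate each module eigengene with each trait.

    ``eigengenes`` is module x sample, ``trait_table`` sample x trait;
    samples are aligned on the trait-table index.  Cells with fewer than
    ``min_n`` complete pairs, or with a constant trait, are NaN (with a
    warning for constants).
    """
    common = [s for s in eigengenes.columns if s in trait_table.index]
    if not common:
        raise ValueError("no shared samples between eigengenes and trait table")
    eig = eigengenes[common]
    traits = trait_table.loc[common]

    modules, names = list(eig.index), list(traits.columns)
    rho = pd.DataFrame(np.nan, index=modules, columns=names)
    p = rho.copy()
    n = pd.DataFrame(0, index=modules, columns=names)
    for trait in names:
        tvals = traits[trait].to_numpy(dtype=float)
        ok = ~np.isnan(tvals)
        for m in modules:
            e = eig.loc[m].to_numpy()[ok]
            t = tvals[ok]
            n.loc[m, trait] = int(ok.sum())
            if ok.sum() < min_n:
                continue
            if np.ptp(t) == 0:
                warnings.warn(f"trait {trait!r} is constant; association set to NaN")
                continue
            r, pv = stats.spearmanr(e, t)
            rho.loc[m, trait] = r
            p.loc[m, trait] = pv
    q = pd.DataFrame(
        bh_fdr(p.to_numpy().ravel()).reshape(p.shape), index=modules, columns=names
    )
    return TraitAssociation(rho=rho, p=p, q=q, n=n)
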