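"""Paired differential expression by negative-binomial mixed regression.

Each gene's counts are modelled as

    y_gj ~ NB(mu_gj, phi_g),   log mu_gj = x_j' beta_g + u_g,s(j) + log s_j

with a log link, fixed effects for time (T3 vs T0) and technical/clinical
covariates, a Gaussian per-subject random intercept u ~ N(0, sigma^2)
capturing the repeated measures, and the log size factor as offset.  The
NB variance is mu + phi * mu^2.

Fitting is two-stage: the dispersion phi_g is estimated per gene by
method-of-moments on Pearson residuals of a Poisson fit and then held
fixed; the mixed model is maximized by penalized IRLS over (beta, u)
jointly (the Laplace/PQL working model) with a closed-form update for the
subject variance.  Wald t statistics use residual df = n_obs - n_fixed - 1
and Benjamini-Hochberg control across genes.

The module also provides the BH step-up itself, ranked-list export for
external enrichment tools, and a hypergeometric over-representation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedNBRegression",
    "DEResults",
    "estimate_dispersion",
    "fit_nb_mixed",
    "bh_fdr",
    "de_table",
    "de_fraction",
    "export_ranked",
    "write_rnk",
    "hypergeom_enrich",
    "read_gmt",
]

_MIN_SIGMA2 = 1e-8
_MAX_PHI = 10.0


# ---------------------------------------------------------------------------
# per-gene fitters
# ---------------------------------------------------------------------------

def _poisson_irls(y, X, offset, max_iter=50, tol=1e-8):
    """Poisson GLM (log link) by iteratively reweighted least squares."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 0.5)) - offset.mean()
    eta = X @ beta + offset
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu
        z = eta - offset + (y - mu) / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise ValueError("degenerate design in Poisson fit") from exc
        eta_new = X @ beta_new + offset
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            eta = eta_new
            break
        beta, eta = beta_new, eta_new
    mu = np.exp(np.clip(eta, -30, 30))
    return beta, mu


def estimate_dispersion(y, X, offset):
    """Method-of-moments NB dispersion from a Poisson fit.

    Solves E[(y - mu)^2] = mu + phi mu^2 in aggregate with a residual-df
    correction, clamped at 0 (underdispersion) and at a large ceiling.
    Requires at least 2 residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n - p < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    _, mu = _poisson_irls(y, X, offset)
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    phi = (num / den) * n / (n - p) if den > 0 else 0.0
    return float(np.clip(phi, 0.0, _MAX_PHI))


def _nb_loglik(y, mu, phi):
    if phi <= 1e-12:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    r = 1.0 / phi
    return float(
        np.sum(
            stats.nbinom.logpmf(y, r, r / (r + mu))
        )
    )


def fit_nb_mixed(y, X, subject_idx, offset, phi, max_iter=200, tol=1e-6, fix_sigma2=None):
    """Fit one gene's NB mixed model by penalized IRLS (Laplace/PQL).

    Parameters
    ----------
    y : (n,) counts
    X : (n, p) fixed-effect design (first column intercept)
    subject_idx : (n,) int codes 0..q-1 grouping repeated measures
    offset : (n,) log size factors
    phi : float, NB dispersion (held fixed)
    fix_sigma2 : float, optional
        Hold the subject variance at this value instead of estimating it
        (e.g. 0 to reduce to a plain NB/Poisson GLM).

    Returns
    -------
    dict with ``coef``, ``se``, ``t``, ``p`` arrays over fixed effects,
    ``sigma2`` (subject variance), ``u`` (posterior modes), ``converged``,
    ``loglik`` (Laplace-approximate marginal log-likelihood).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    subject_idx = np.asarray(subject_idx)
    n, p = X.shape
    q = int(subject_idx.max()) + 1

    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 0.5)) - offset.mean()
    u = np.zeros(q)
    sigma2 = 0.1

    def irls(beta, u, sigma2):
        """Penalized IRLS for (beta, u) at fixed sigma2."""
        for _ in range(50):
            eta = X @ beta + u[subject_idx] + offset
            mu = np.exp(np.clip(eta, -30, 30))
            w = mu / (1.0 + phi * mu)
            z = (eta - offset) + (y - mu) / mu  # working response minus offset

            Bq = np.zeros((q, p))
            np.add.at(Bq, subject_idx, X * w[:, None])
            B = Bq.T
            d = np.bincount(subject_idx, weights=w, minlength=q)
            ztw = np.bincount(subject_idx, weights=w * z, minlength=q)

            Dinv = 1.0 / (d + 1.0 / sigma2)
            S = (X.T * w) @ X - (B * Dinv) @ B.T  # Schur complement
            rhs = (X.T * w) @ z - B @ (Dinv * ztw)
            try:
                beta_new = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError as exc:
                raise ValueError("degenerate design in mixed fit") from exc
            u_new = Dinv * (ztw - B.T @ beta_new)
            step = max(np.max(np.abs(beta_new - beta)), np.max(np.abs(u_new - u)))
            beta, u = beta_new, u_new
            if step < tol:
                break
        return beta, u, Dinv

    if fix_sigma2 is not None:
        sigma2 = max(float(fix_sigma2), _MIN_SIGMA2)
        beta, u, _ = irls(beta, u, sigma2)

    sig_hist = []
    n_outer = 0 if fix_sigma2 is not None else max(max_iter // 4, 10)
    converged = fix_sigma2 is not None
    for it in range(n_outer):
        beta, u, Dinv = irls(beta, u, sigma2)
        # variance update: E[u_i^2] under the Laplace posterior
        sigma2_new = max(float(np.mean(u**2 + Dinv)), _MIN_SIGMA2)
        sig_hist.append(sigma2_new)
        # the fixed point contracts geometrically near the boundary;
        # Aitken extrapolation jumps to the limit when the sequence is
        # monotone and contracting
        if len(sig_hist) >= 3:
            s0, s1, s2 = sig_hist[-3:]
            d1, d2 = s1 - s0, s2 - s1
            if d1 * d2 > 0 and abs(d2) < abs(d1):
                accel = s2 - d2**2 / (d2 - d1)
                if np.isfinite(accel):
                    sigma2_new = float(np.clip(accel, _MIN_SIGMA2, 10.0))
                    sig_hist = []
        delta = abs(sigma2_new - sigma2)
        sigma2 = sigma2_new
        if delta < 1e-6 + 1e-3 * sigma2:
            beta, u, Dinv = irls(beta, u, sigma2)
            converged = True
            break

    eta = X @ beta + u[subject_idx] + offset
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + phi * mu)
    Bq = np.zeros((q, p))
    np.add.at(Bq, subject_idx, X * w[:, None])
    B = Bq.T
    d = np.bincount(subject_idx, weights=w, minlength=q)
    Dinv = 1.0 / (d + 1.0 / sigma2)
    S = (X.T * w) @ X - (B * Dinv) @ B.T
    cov = np.linalg.inv(S)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    df = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)

    loglik = (
        _nb_loglik(y, mu, phi)
        - 0.5 * np.sum(u**2) / sigma2
        - 0.5 * q * np.log(2 * np.pi * sigma2)
        - 0.5 * np.sum(np.log(d + 1.0 / sigma2))
        + 0.5 * q * np.log(2 * np.pi)
    )
    return {
        "coef": beta,
        "se": se,
        "t": t,
        "p": pvals,
        "sigma2": sigma2,
        "u": u,
        "converged": converged,
        "df": df,
        "loglik": loglik,
    }


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the m non-missing p-values;
    NaN entries propagate to NaN q-values and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(qv, 1.0)
    q[ok] = out
    return q


def de_fraction(n_de, n_total):
    """Fraction of analyzed genes declared differentially expressed, in
    percent rounded to one decimal (e.g. 1214 of 15972 -> 7.6)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_de / n_total, 1)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

def _build_design(metadata, covariates, interaction):
    """Fixed-effect design: intercept, time dummy, then covariates
    (categoricals one-hot, continuous centered)."""
    n = len(metadata)
    cols = {"Intercept": np.ones(n), "time[T3]": (metadata["time"] == "T3").to_numpy(float)}
    for cov in covariates:
        col = metadata[cov]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.unique())
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (col == lev).to_numpy(float)
        else:
            x = col.to_numpy(float)
            cols[cov] = x - x.mean()
    if interaction:
        proc = metadata["procedure"]
        levels = sorted(proc.unique())
        for lev in levels[1:]:
            cols[f"time[T3]:procedure[{lev}]"] = (
                cols["time[T3]"] * (proc == lev).to_numpy(float)
            )
    X = np.column_stack(list(cols.values()))
    # drop constant non-intercept columns (e.g. single-level categoricals)
    names = list(cols.keys())
    keep = [0] + [i for i in range(1, X.shape[1]) if np.ptp(X[:, i]) > 0]
    return X[:, keep], [names[i] for i in keep]


class PairedNBRegression:
    """Per-gene NB mixed-effects model for a paired count study.

    Parameters
    ----------
    study : CountStudy
        Filtered study; size factors are computed if absent.
    covariates : sequence of str
        Metadata columns used as fixed effects besides time.
    interaction : bool
        Add procedure and time x procedure terms.
    """

    def __init__(self, study, covariates=(), interaction=False):
        self.study = study.with_size_factors()
        meta = self.study.metadata
        self.covariates = tuple(c for c in covariates if c in meta.columns)
        dropped = set(covariates) - set(self.covariates)
        if dropped:
            warnings.warn(f"covariates absent from metadata dropped: {sorted(dropped)}")
        if interaction and "procedure" not in meta.columns:
            raise ValueError("interaction requires a 'procedure' metadata column")
        self.interaction = interaction
        covs = list(self.covariates)
        if interaction and "procedure" not in covs:
            covs.append("procedure")
        self.design, self.design_names = _build_design(meta, covs, interaction)
        subj = meta["subject"]
        self.subject_idx = subj.map({s: i for i, s in enumerate(subj.unique())}).to_numpy()
        self.offset = np.log(self.study.size_factors.to_numpy())

    def fit(self, alpha=0.05) -> "DEResults":
        """Fit every gene; returns a :class:`DEResults`."""
        counts = self.study.counts.to_numpy(dtype=float)
        t0 = self.study.mask_time("T0")
        t3 = self.study.mask_time("T3")
        time_col = self.design_names.index("time[T3]")

        rows = []
        n_failed = 0
        for g in range(counts.shape[0]):
            y = counts[g]
            try:
                phi = estimate_dispersion(y, self.design, self.offset)
                fit = fit_nb_mixed(y, self.design, self.subject_idx, self.offset, phi)
            except (ValueError, FloatingPointError):
                fit = None
            if fit is None or not np.isfinite(fit["se"][time_col]):
                n_failed += 1
                rows.append((np.nan,) * 4 + (y[t0].mean(), y[t3].mean(), np.nan, np.nan, False))
                continue
            conv = bool(fit["converged"])
            if not conv:
                n_failed += 1
            rows.append(
                (
                    fit["coef"][time_col],
                    fit["se"][time_col],
                    fit["t"][time_col] if conv else np.nan,
                    fit["p"][time_col] if conv else np.nan,
                    y[t0].mean(),
                    y[t3].mean(),
                    phi,
                    fit["sigma2"],
                    conv,
                )
            )
        table = pd.DataFrame(
            rows,
            index=self.study.genes,
            columns=[
                "time_coef",
                "se",
                "t_stat",
                "p_value",
                "mean_counts_T0",
                "mean_counts_T3",
                "dispersion",
                "subject_variance",
                "converged",
            ],
        )
        table["fdr"] = bh_fdr(table["p_value"].to_numpy())
        return DEResults(model=self, table=table, alpha=alpha, n_not_converged=n_failed)


@dataclass
class DEResults:
    """Differential-expression results: one row per gene with the time
    coefficient (log scale), its Wald test, BH FDR and per-time raw mean
    counts."""

    model: PairedNBRegression
    table: pd.DataFrame
    alpha: float = 0.05
    n_not_converged: int = 0

    def de_genes(self, alpha=None) -> pd.Index:
        a = self.alpha if alpha is None else alpha
        return self.table.index[self.table["fdr"] < a]

    @property
    def n_tested(self) -> int:
        return int(self.table["p_value"].notna().sum())

    def summary(self) -> str:
        n_de = len(self.de_genes())
        frac = de_fraction(n_de, len(self.table)) if len(self.table) else float("nan")
        lines = [
            "Paired NB mixed-model differential expression",
            f"  genes analyzed:        {len(self.table)}",
            f"  fixed effects:         {', '.join(self.model.design_names)}",
            f"  subjects:              {int(self.model.subject_idx.max()) + 1}",
            f"  non-converged genes:   {self.n_not_converged} (excluded from FDR)",
            f"  DE at FDR<{self.alpha:g}:       {n_de} ({frac}%)",
        ]
        top = self.table.sort_values("p_value").head(10)
        lines.append("  top genes by p-value:")
        lines.append(
            top[["time_coef", "p_value", "fdr", "mean_counts_T0", "mean_counts_T3"]]
            .round(4)
            .to_string()
        )
        return "\n".join(lines)

    def ranked(self, mode="signed") -> pd.DataFrame:
        return export_ranked(self.table, mode=mode)


def de_table(study, covariates=(), interaction=False, alpha=0.05) -> DEResults:
    """One-call orchestration: dispersion -> mixed fit -> BH FDR."""
    return PairedNBRegression(study, covariates=covariates, interaction=interaction).fit(
        alpha=alpha
    )


# ---------------------------------------------------------------------------
# ranked export & over-representation
# ---------------------------------------------------------------------------

def export_ranked(de_table_df: pd.DataFrame, mode="signed") -> pd.DataFrame:
    """Two-column (gene, score) list sorted by descending score, for
    external enrichment tools; ``mode`` is 'signed' or 'absolute' on the
    t statistic.  Genes with missing t are excluded."""
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    t = de_table_df["t_stat"]
    ok = t.notna()
    n_excluded = int((~ok).sum())
    score = t[ok] if mode == "signed" else t[ok].abs()
    out = (
        pd.DataFrame({"gene": score.index, "score": score.to_numpy()})
        .sort_values(["score", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    out.attrs["n_excluded"] = n_excluded
    return out


def write_rnk(ranked: pd.DataFrame, path) -> None:
    """Write a ranked list in the tab-separated RNK format."""
    ranked.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def hypergeom_enrich(gene_sets: dict, selection, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``selection``
    (e.g. a module or the DE set) in each gene set, BH-adjusted across
    sets.  Gene sets are intersected with the universe."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    selection = frozenset(selection) & universe
    M, N = len(universe), len(selection)
    rows = []
    for name, genes in gene_sets.items():
        genes = frozenset(genes) & universe
        k = len(genes & selection)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), N)) if genes else 1.0
        rows.append((name, len(genes), k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"]).set_index("set")
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out
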