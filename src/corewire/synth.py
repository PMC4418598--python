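"""Synthetic paired-design count studies with known ground truth.

Generates gene-level negative-binomial counts for a before/after (T0/T3)
paired design with planted structure mirroring what the downstream analysis
assumes and looks for:

* a log-scale factor model plants coexpression modules — genes in module m
  share a per-sample latent factor f_m(j), entering the log mean with a
  loading lambda in [0, 1];
* a subset of genes carries a time effect delta on the log scale (the
  differential-expression signal);
* "disconnected" genes have their module loading zeroed at T3 only, so
  they lose coexpression after the intervention without necessarily
  changing mean expression;
* per-sample size factors (lognormal), per-subject random intercepts, and
  innocuous technical covariates (run, RIN, RNA concentration) with small
  planted effects complete the observation layer.

The NB observation layer uses the gamma-Poisson mixture, giving
Var = mu + phi * mu^2 with dispersion phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import CountStudy

__all__ = ["SynthConfig", "GroundTruth", "generate_study", "generate_traits"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic paired count study.

    Defaults emulate a 22-subject paired design with 2,000 genes, five
    planted modules of 50-300 genes, moderate loadings and moderate NB
    dispersion.
    """

    n_subjects: int = 22
    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (300, 200, 150, 100, 50)
    module_loading: float = 0.7
    frac_de: float = 0.1
    de_log_fc: float = float(np.log(2.0))
    frac_disconnected: float = 0.0
    dispersion: float = 0.2
    subject_sd: float = 0.2
    libsize_sd: float = 0.2
    base_log_mean_range: tuple[float, float] = (3.0, 7.5)
    factor_scale: float = 1.0  # maps loadings to the log scale
    run_effect: float = 0.05
    rin_effect: float = 0.05
    concentration_effect: float = 0.05
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum exceeds n_genes")
        for name in ("module_loading", "frac_de", "frac_disconnected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_subjects < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 subjects and 1 gene")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic study."""

    module_of_gene: pd.Series  # gene -> module label, 0 = background
    de_genes: frozenset
    disconnected_genes: frozenset
    true_size_factors: pd.Series
    true_subject_effects: pd.Series
    delta: pd.Series  # signed log-scale time effect per gene
    loadings: pd.Series  # per-gene module loading
    factors: pd.DataFrame = field(default=None)  # module x sample latent factors

    def __post_init__(self):
        module_genes = set(self.module_of_gene.index[self.module_of_gene > 0])
        if not set(self.disconnected_genes) <= module_genes:
            raise ValueError("disconnected genes must belong to a module")


def _sample_ids(n_subjects):
    subjects = [f"P{i + 1:02d}" for i in range(n_subjects)]
    ids, meta_subject, meta_time = [], [], []
    for t in ("T0", "T3"):
        for s in subjects:
            ids.append(f"{s}_{t}")
            meta_subject.append(s)
            meta_time.append(t)
    return subjects, ids, meta_subject, meta_time


def generate_study(
    config: SynthConfig, gene_loadings: np.ndarray | None = None
) -> tuple[CountStudy, pd.DataFrame, GroundTruth]:
    """Generate one paired count study, a trait table and its ground truth.

    Counts for gene g in sample j are NB with mean

        s_j * exp(mu_g + u_subj(j) + delta_g * [time=T3]
                  + c * lambda_g * f_m(g)(j) + technical_j)

    where f_m(j) is the module-m latent factor of sample j (drawn
    independently per sample, hence per time point) and disconnected genes
    have lambda replaced by 0 in T3 samples.  Identical config and seed
    give bit-identical output.

    Parameters
    ----------
    config : SynthConfig
    gene_loadings : ndarray, optional
        Per-gene loading overriding the uniform ``config.module_loading``
        (e.g. to plant a hub gene); background genes keep loading 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sub, n_genes = config.n_subjects, config.n_genes
    n_samples = 2 * n_sub

    genes = pd.Index([f"G{i + 1:04d}" for i in range(n_genes)], name="gene")
    subjects, sample_ids, meta_subject, meta_time = _sample_ids(n_sub)
    t3 = np.array([t == "T3" for t in meta_time])

    # module assignment: contiguous blocks, label 0 = background
    labels = np.zeros(n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[pos : pos + size] = m
        pos += size

    loadings = np.where(labels > 0, config.module_loading, 0.0)
    if gene_loadings is not None:
        loadings = np.where(labels > 0, np.asarray(gene_loadings, dtype=float), 0.0)

    mu = rng.uniform(*config.base_log_mean_range, size=n_genes)
    u = rng.normal(0.0, config.subject_sd, size=n_sub)
    log_s = rng.normal(0.0, config.libsize_sd, size=n_samples)
    s = np.exp(log_s)

    n_de = int(round(config.frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    delta = np.zeros(n_genes)
    if n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        delta[de_idx] = signs * config.de_log_fc

    module_gene_idx = np.flatnonzero(labels > 0)
    n_disc = int(round(config.frac_disconnected * module_gene_idx.size))
    disc_idx = (
        rng.choice(module_gene_idx, size=n_disc, replace=False)
        if n_disc
        else np.array([], dtype=int)
    )
    disc_mask = np.zeros(n_genes, dtype=bool)
    disc_mask[disc_idx] = True

    n_mod = config.n_modules
    factors = rng.normal(0.0, 1.0, size=(n_mod, n_samples)) if n_mod else np.empty((0, n_samples))

    # technical covariates with small planted effects; the per-gene
    # coefficient spread (uniform on [0, 2] x effect) matters: a perfectly
    # gene-shared effect would be absorbed by the size factors
    run = np.array(["R1" if i % 2 == 0 else "R2" for i in range(n_samples)])
    rin = rng.normal(8.0, 0.5, size=n_samples)
    conc = rng.normal(100.0, 15.0, size=n_samples)
    tech_cols = np.column_stack(
        [
            (run == "R2").astype(float),
            (rin - rin.mean()) / rin.std(),
            (conc - conc.mean()) / conc.std(),
        ]
    )
    effects = np.array(
        [config.run_effect, config.rin_effect, config.concentration_effect]
    )
    gene_coefs = effects[None, :] * rng.uniform(0.0, 2.0, size=(n_genes, 3))
    tech = gene_coefs @ tech_cols.T  # genes x samples

    subj_of_sample = np.array([subjects.index(s_) for s_ in meta_subject])
    eta = (
        mu[:, None]
        + u[subj_of_sample][None, :]
        + delta[:, None] * t3[None, :]
        + tech
    )
    if n_mod:
        lam = np.repeat(loadings[:, None], n_samples, axis=1)
        lam[np.ix_(disc_mask, t3)] = 0.0
        for m in range(1, n_mod + 1):
            in_m = labels == m
            eta[in_m] += config.factor_scale * lam[in_m] * factors[m - 1][None, :]

    mean = s[None, :] * np.exp(eta)
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam_gp = rng.gamma(shape, mean * config.dispersion)
        counts = rng.poisson(lam_gp)
    else:
        counts = rng.poisson(mean)

    age = rng.normal(42.0, 8.0, size=n_sub)
    ethnicity = rng.choice(["European", "nonEuropean"], size=n_sub, p=[0.8, 0.2])
    procedure = rng.permutation(
        ["RYGB"] * ((2 * n_sub + 1) // 3) + ["AGB"] * (n_sub - (2 * n_sub + 1) // 3)
    )
    metadata = pd.DataFrame(
        {
            "subject": meta_subject,
            "time": meta_time,
            "run": run,
            "rin": rin,
            "rna_concentration": conc,
            "age": age[subj_of_sample],
            "ethnicity": ethnicity[subj_of_sample],
            "procedure": procedure[subj_of_sample],
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    counts_df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=metadata.index)
    study = CountStudy(counts=counts_df, metadata=metadata)

    truth = GroundTruth(
        module_of_gene=pd.Series(labels, index=genes, name="module"),
        de_genes=frozenset(genes[de_idx]),
        disconnected_genes=frozenset(genes[disc_idx]),
        true_size_factors=pd.Series(s, index=metadata.index, name="size_factor"),
        true_subject_effects=pd.Series(u, index=subjects, name="subject_effect"),
        delta=pd.Series(delta, index=genes, name="delta"),
        loadings=pd.Series(loadings, index=genes, name="loading"),
        factors=pd.DataFrame(
            factors, index=range(1, n_mod + 1), columns=metadata.index
        ),
    )
    trait_seed = int(rng.integers(0, 2**31 - 1))
    # traits tied to modules the config does not have fall back to pure noise
    specs = {
        name: (m if m <= n_mod else 0, rho, mean, sd)
        for name, (m, rho, mean, sd) in DEFAULT_TRAIT_SPECS.items()
    }
    traits = generate_traits(truth, truth.factors, trait_specs=specs, seed=trait_seed)
    return study, traits, truth


DEFAULT_TRAIT_SPECS = {
    # trait -> (module label driving it, target correlation, mean, sd)
    "bmi": (1, 0.5, 45.0, 6.0),
    "fat_mass": (1, 0.5, 55.0, 10.0),
    "crp": (2, 0.5, 8.0, 5.0),
    "glucose": (3, 0.4, 5.3, 0.6),
    "insulin": (3, 0.4, 20.0, 8.0),
    "triglycerides": (2, 0.45, 1.5, 0.5),
    "hdl": (2, -0.4, 1.2, 0.25),
    "leptin": (1, 0.5, 50.0, 20.0),
    "adiponectin": (4, 0.4, 6.0, 2.5),
    "sbp": (0, 0.0, 130.0, 12.0),
    "dbp": (0, 0.0, 80.0, 9.0),
}


def generate_traits(
    ground_truth: GroundTruth,
    factors: pd.DataFrame,
    trait_specs: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-sample traits correlated with module latent factors.

    Each trait is ``rho * f_m + sqrt(1 - rho^2) * noise`` rescaled to a
    realistic clinical mean/SD (affine, so the population correlation with
    the factor is exactly the target).  Module label 0 (or a spec with
    rho=0) yields pure noise.  Always includes ``insulin`` and ``glucose``
    so the HOMA-IR index is computable downstream.
    """
    specs = dict(DEFAULT_TRAIT_SPECS if trait_specs is None else trait_specs)
    rng = np.random.default_rng(seed)
    n_samples = factors.shape[1] if len(factors) else len(ground_truth.true_size_factors)
    columns = {}
    avail = set(factors.index)
    for name, (module, rho, mean, sd) in specs.items():
        if module != 0 and module not in avail:
            raise ValueError(f"trait {name!r} references unknown module {module}")
        if not -1.0 < rho < 1.0:
            raise ValueError(f"target correlation for {name!r} must lie in (-1, 1)")
        noise = rng.normal(size=n_samples)
        z = noise if module == 0 or rho == 0 else (
            rho * factors.loc[module].to_numpy() + np.sqrt(1 - rho**2) * noise
        )
        vals = mean + sd * z
        # clinical concentrations cannot go negative; centred test traits can
        columns[name] = np.maximum(vals, 0.01 * abs(mean)) if mean > 0 else vals
    index = factors.columns if len(factors) else ground_truth.true_size_factors.index
    return pd.DataFrame(columns, index=pd.Index(index, name="sample"))
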