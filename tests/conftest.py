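import numpy as np
import pandas as pd
import pytest

from corewire import prep, synth


@pytest.fixture(scope="session")
def small_study():
    """A compact paired study with two planted modules and some DE genes."""
    cfg = synth.SynthConfig(
        n_subjects=22, n_genes=300, module_sizes=(60, 40), frac_de=0.1, seed=7
    )
    study, traits, truth = synth.generate_study(cfg)
    return study, traits, truth


@pytest.fixture(scope="session")
def t0_expression(small_study):
    """VST + covariate-adjusted T0 expression of the small study."""
    study, _, truth = small_study
    study = prep.filter_low_expression(study).with_size_factors()
    expr = prep.adjust_covariates(prep.vst(study), study.metadata)
    return expr.values.loc[:, study.mask_time("T0")], truth


def make_expression(n_genes, n_samples, seed=0, index=None):
    """Plain i.i.d. Gaussian expression frame for structural tests."""
    rng = np.random.default_rng(seed)
    idx = index if index is not None else [f"G{i:04d}" for i in range(n_genes)]
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=pd.Index(idx, name="gene"),
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )
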