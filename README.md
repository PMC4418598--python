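# corewire

Paired RNA-seq differential expression and coexpression-network rewiring
analysis.

`corewire` is for transcriptomics studies with a paired before/after
design — the motivating case is subcutaneous adipose tissue biopsied in
the same obese subjects before and a few months after bariatric surgery —
where two complementary questions are asked of the same count matrix:

1. **Which genes change in mean expression?** Answered per gene by a
   negative-binomial regression on counts, log mu = x'beta + u + log s,
   with fixed effects for time and technical/clinical covariates, a
   Gaussian per-subject random intercept u for the repeated measures, the
   median-of-ratios size factor s as offset, Wald t-tests on the time
   coefficient and Benjamini–Hochberg FDR across genes.
2. **Which genes change in *coexpression*?** Answered at the network
   level: a weighted coexpression network (adjacency |cor|^beta with
   beta = 6, topological overlap, average-linkage clustering with a tree
   cut) yields modules at baseline; each module is summarized by its
   eigengene (PC1 of the member expression) and each gene by its module
   membership MM (correlation with the eigengene). Module credibility is
   quantified by a leave-one-out jackknife (max-Jaccard matching, a gene
   is "correctly classified" when it lands in its module's best match in
   ≥ 18 of 22 subsets), eigengenes are correlated with clinical traits
   by Spearman rank, and *rewiring* is measured by recomputing each
   module's eigengene after the intervention on the identical gene set:
   a gene with high baseline MM and collapsed follow-up MM
   (delta_mm = mm_ref − mm_test) has become disconnected from its module.

Both analyses are exercised end-to-end on a synthetic generator
(`corewire.synth`) that plants known modules, time effects and
disconnected genes in NB counts with subject effects and library-size
variation, so every claim the package makes is tested against ground
truth. Derived clinical phenotypes (HOMA-IR = insulin × glucose / 22.5,
the four-factor metabolic-syndrome rule, the two-occasion diabetes rule)
are included for the trait analyses.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
import numpy as np
from corewire import (
    SynthConfig, generate_study, CoexpressionNetwork, de_table,
    jackknife_stability, membership_shift, eigengene_trait_cor, prep,
)

cfg = SynthConfig(seed=1, n_genes=800, module_sizes=(150, 120, 100),
                  frac_de=0.1, frac_disconnected=0.1)
study, traits, truth = generate_study(cfg)

# 1) per-gene differential expression
res = de_table(study, covariates=("age", "ethnicity", "run", "rin",
                                  "rna_concentration"))
print(res.summary())

# 2) network at baseline (VST -> covariate adjustment -> T0 columns)
filtered = prep.filter_low_expression(study).with_size_factors()
expr = prep.adjust_covariates(prep.vst(filtered), filtered.metadata)
expr_t0 = expr.values.loc[:, filtered.mask_time("T0")]
expr_t3 = expr.values.loc[:, filtered.mask_time("T3")]
net = CoexpressionNetwork(expr_t0).fit(beta=6, min_size=20)
print(net.summary())

# 3) stability, trait association, rewiring
print(jackknife_stability(expr_t0, {"beta": 6, "min_size": 20}).summary())
print(eigengene_trait_cor(net.eigengenes, traits).summary())
print(membership_shift(expr_t0, expr_t3, net.labels,
                       with_matrices=False).summary())
```

Output (abridged):

```
Paired NB mixed-model differential expression
  genes analyzed:        800
  fixed effects:         Intercept, time[T3], age, ethnicity[nonEuropean], run[R2], rin, rna_concentration
  subjects:              22
  non-converged genes:   0 (excluded from FDR)
  DE at FDR<0.05:       68 (8.5%)

Weighted coexpression network
  genes:                 800
  soft power beta:       6 (unsigned)
  modules detected:      3
  unassigned (grey):     403
  module sizes:          1:177, 2:142, 3:78

Jackknife stability over 22 leave-one-out subsets (stable if k_i >= 18)
        size  mean_jaccard  sd_jaccard  mean_eigengene_cor  prop_correct
module
1        177         0.956       0.028               1.000         0.944
2        142         0.951       0.024               1.000         0.979
3         78         0.828       0.081               0.998         0.782

Eigengene-trait Spearman associations
  strongest correlations:
    module 1 ~ bmi: rho=+0.688 (p=0.000398, q=0.0131)
    module 1 ~ leptin: rho=+0.645 (p=0.00118, q=0.0195)

Cross-condition module rewiring
  module genes analyzed: 397
  disconnected (mm_ref>=0.5, mm_test<=0.2): 30
  largest membership losses:
       module  mm_ref  mm_test  delta_mm
gene
G0199       2   0.839   -0.382     1.221
G0074       1   0.902   -0.293     1.195
```

Reading the numbers: 68 of 800 genes (8.5%) pass FDR < 0.05 — close to
the planted 10% DE fraction at the achievable power. The three planted
modules are recovered (177/142/78 members against true sizes
150/120/100; background genes stay grey), are highly reproducible under
the jackknife (mean max-Jaccard 0.83–0.96), and their eigengenes
correlate with the traits that were generated from the same latent
factors. The rewiring table ranks, by membership loss, exactly the genes
whose module loading was zeroed at the second time point.

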