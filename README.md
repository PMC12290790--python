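# hierpet

Hierarchical multivariate analysis of dynamic PET time–activity curves.

## The problem

Quantifying a radioligand like [11C]WAY100635 (serotonin-1A receptor)
from dynamic PET is hard in exactly the places that matter most.  The
binding outcomes of the two-tissue compartment model (2TCM) —
`BP_ND = k3/k4`, `BP_P = K1 k3 / (k2 k4)`, `BP_F = BP_P / f_P` — are
ratios of weakly identified rate constants, the region of greatest
biological interest (the raphe nuclei, where the autoreceptors sit) is
tiny and noisy, and reference-tissue shortcuts (SRTM) lean on a
cerebellar region that violates their assumptions.  Conventional
per-curve nonlinear least squares (NLS) therefore produces noisy, often
catastrophic estimates, and group comparisons built on them have
disagreed across outcome measures for two decades.

`hierpet` implements the hierarchical multivariate alternative: every
time–activity curve (TAC) in a study is fitted *simultaneously*, with
the log kinetic parameters of each curve decomposed as

    theta[t] = mu + beta_age age + beta_sex sex + gamma[group, region]
             + u_region + u_individual + u_TAC

where the group-by-region contrast `gamma` (on log BP only, with a
skeptical Normal(0, 0.2) prior) is the quantity of scientific interest,
and the individual-level deviations are *correlated across all kinetic
parameters*.  That multivariate partial pooling borrows strength across
subjects, regions and parameters, stabilises the directly estimated
binding outcomes without any reference region, and makes group
inferences that are consistent across `BP_ND`, `BP_P` and `BP_F` even
when the plasma-free fraction f_P is confounded by assay drift.  A
companion two-stage analysis applies the same multilevel structure to
conventionally estimated SRTM parameter vectors (log R1, log k2',
log BP_ND).

The package is aimed at PET quantification methodologists: it ships the
forward models, the conventional NLS comparator, the hierarchical
models, group-contrast/power utilities, and a seeded synthetic-cohort
generator that emulates the statistical structure of a three-group
clinical study (healthy volunteers vs. not-recently-medicated vs.
antidepressant-exposed patients; raphe-dominant group effects;
f_P/scan-date confounding; raphe-dominated noise), so every method can
be validated against known ground truth.

## Worked example

Simulate a small cohort with a raphe-dominant binding increase in the
not-recently-medicated (NRM) group, quantify it conventionally, fit the
hierarchical model, and compare:

```python
import numpy as np
from hierpet.cohort import CohortConfig, simulate_cohort
from hierpet.nls import fit_cohort_nls
from hierpet.simba import HierarchicalModelSpec, build_simba_model, fit_simba
from hierpet.inference import InferenceSettings
from hierpet.contrasts import group_contrasts

cfg = CohortConfig(group_sizes={"HV": 6, "NRM": 6, "AE": 6},
                   regions=("DLPFC", "HIP", "RN"), include_reference=False)
study = simulate_cohort(cfg, seed=1)          # truth: RN +16%, others +8%

nls = fit_cohort_nls(study, "2tcm", "bpnd", seed=0)
model = build_simba_model(study, HierarchicalModelSpec(outcome="bpnd"))
fit = fit_simba(model, InferenceSettings(seed=1, draws=500, chains=2))

for c in group_contrasts(fit, comparisons=("NRM-HV",)):
    print(f"{c.region:6s} {c.percent:+6.1f}%  "
          f"95% CrI [{c.lo95:+6.1f}, {c.hi95:+6.1f}]  P(>0)={c.p_positive:.2f}")
```

Output (seed 1):

```
DLPFC    -2.4%  95% CrI [ -13.2,   +9.7]  P(>0)=0.36
HIP      +5.0%  95% CrI [  -5.8,  +17.1]  P(>0)=0.80
RN      +18.5%  95% CrI [  +2.2,  +37.3]  P(>0)=0.99
```

Each line is a regional NRM-vs-HV percent difference in `BP_ND`
(`100 (e^beta - 1)` of the log-scale contrast), its 95% credible
interval, and the posterior probability that the difference is positive.
Even at n = 6 per group the raphe increase (injected truth +16%) is
resolved with `P(beta > 0) = 0.99` — whereas the same contrast computed
from the per-TAC NLS estimates via a univariate mixed model spans
hundreds of percent in the raphe.  The prior-mass helper
reproduces the skepticism of the contrast prior
(`prior_mass(0.2, 0.20)` → 0.64: 64% of prior mass on differences below
20%), and `power_n_per_group(0.32)` → 155 subjects per group shows why
univariate t-tests on single-outcome estimates are underpowered for
effects of this size.

A command-line surface wraps the same pipeline
(`hierpet simulate | fit-nls | fit-simba | fit-pumba | contrast | power |
priors | fp-drift | report`), reading and writing plain TSV/CSV/JSON.

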