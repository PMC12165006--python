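# netspill

Spillover (interference) analysis of a binary treatment on a binary outcome
over an observed risk network — built for studies like a network of people
who inject drugs, where medication for opioid use disorder (MOUD) given to
one person may also reduce the HIV injection-risk behavior of their
untreated contacts.

## What it computes

Under **partial interference**, the network is split into disjoint
communities (the interference sets) and spillover is assumed possible only
within them.  For Bernoulli allocation strategies — counterfactual policies
that treat each community member independently with coverage probability α —
the package estimates four risk differences:

| effect | contrast |
|---|---|
| direct `DE(α)` | treated vs untreated at the same coverage α |
| spillover `SE(α, α′)` | untreated at coverage α vs untreated at α′ |
| total `TE(α, α′)` | treated at α vs untreated at α′ (≡ DE + SE) |
| overall `OE(α, α′)` | everyone at α vs everyone at α′ |

Estimation is inverse probability weighting with **community-level
propensity scores**: `f(A_i|X_i)`, the probability of community *i*'s whole
observed treatment vector from a mixed-effects logit with a community random
intercept integrated out by adaptive Gauss–Hermite quadrature.  Standard
errors are M-estimation sandwiches with communities as independent units and
the propensity score equations stacked in, giving 95% Wald intervals that
account for weight estimation.

Because the interference sets come from modularity-based community
detection (greedy agglomerative and leading-eigenvector detectors, both
implemented here with deterministic tie-breaking), the package also
quantifies how much that structure can be trusted: perturb a fraction γ of
edges, re-detect, and track the normalized **variation of information**
against a degree-matched null network and against reference levels for 10%
and 20% node reassignment.

Rounding out the pipeline: covariate screening (VIF, pairwise chi-square,
convergence checks), random-forest covariate imputation, mixed-logit /
plain-logit / best-worst-case outcome imputation, extreme-weight trimming,
and a synthetic-study generator with exact ground-truth effects for
validation.  See `docs/methods.md` for the full model account.

## Worked example

Generate a synthetic study with known truth (direct log-odds −1, spillover
log-odds −1 per unit coverage), fit the propensity model on the true
communities, and estimate:

```python
import numpy as np
from netspill import estimate_effects, fit_mixed_logit
from netspill.synthetic import SyntheticStudyConfig, generate_study

cfg = SyntheticStudyConfig(
    n_communities=250, size_log_mean=np.log(3.5), size_log_sd=0.2,
    treat_intercept=-0.4, treat_coef_risk=0.5, treat_coef_age=0.3,
    sigma_b=0.4, out_intercept=0.5, outcome_missing_rate=0.0, seed=1)
study = generate_study(cfg)
model = fit_mixed_logit(study.records, study.true_structure, ["risk_base", "age"])
res = estimate_effects(study.network, study.true_structure, model,
                       alphas=[0.5], alpha_pairs=[(0.6, 0.2)])
for e in res.estimates:
    print(e.effect, e.alpha, e.alpha_prime,
          f"{e.estimate:+.3f} ({e.ci_low:+.3f}, {e.ci_high:+.3f})")
```

prints

```
direct 0.5 None -0.221 (-0.292, -0.151)
spillover 0.6 0.2 -0.053 (-0.170, +0.063)
total 0.6 0.2 -0.273 (-0.382, -0.164)
overall 0.6 0.2 -0.151 (-0.230, -0.072)
```

Read: at 50% coverage, being treated yourself lowers the outcome risk by an
estimated 22 per 100 persons; raising community coverage from 20% to 60%
lowers an untreated member's risk by an estimated 5 per 100 (CI crosses 0).
The exact true values under this generating law are DE = −0.225 and
SE = −0.087, both inside their intervals.

The full pipeline (imputation → detection → screening → propensity → effects
→ trimming → significance) runs from a YAML config:

```
netspill simulate --seed 1 --out study/
netspill run --config config.yaml
```

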