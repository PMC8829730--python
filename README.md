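# sparsepoisson

Poisson regression for sparse count data, built around the problem of
*separation*: data configurations (e.g. a covariate group with no events)
under which the maximum-likelihood estimate does not exist. The package
provides

- **`glm_core`** — Poisson GLM with offset: log-likelihood, score, Fisher
  information, hat-matrix leverages, and a Newton/step-halving ML fitter
  that returns its flagged last iterate instead of aborting under
  separation;
- **`separation`** — a linear-program decision of whether the ML estimate
  exists, with a certificate direction when it does not;
- **`firth`** — Firth-penalized likelihood (FL, the Jeffreys-prior penalty
  `l + 0.5 log|X'WX|`, equivalently ML on counts augmented by half the
  leverages) and its prediction-debiased variants FLAC (added covariate)
  and FLIC (intercept correction), which coincide for Poisson models;
- **`intervals`** — Wald, profile likelihood on the fixed h/2-augmented
  data, and profile *penalized* likelihood (PPL) confidence intervals by
  bracketed deviance root-finding, with infinite bounds reported as such;
- **`bda`** — Bayesian data augmentation: symmetric normal priors on
  log-rate-ratios encoded as pseudo-observations (value 1/S, count S²/v,
  offset log count), maximum-posterior fitting, and profile CIs on the
  augmented likelihood;
- **`exact_conditional`** — exact conditional inference for one
  coefficient: enumeration of the conditional distribution of its
  sufficient statistic, maximum conditional likelihood estimate, median
  unbiased estimate at support boundaries, and exact / mid-p intervals;
- **`simulation`** — a sparse-event simulation engine (factorial covariate
  designs with a latent correlated-normal generator, events-per-variable
  scenario sizing, zero-truncated Poisson exposure multipliers, intercept
  calibration to a target incidence) with bias / scaled RMSE / scaled
  RMSPE / one-sided coverage / power summaries;
- **`io` / `cli`** — CSV readers with dummy expansion, result tables with
  JSON run manifests, bundled example fixtures, and a `click` CLI.

## Quick start

```python
import numpy as np
from sparsepoisson import (
    covid_dataset, detect_separation, fit_fl, fit_exact, profile_ci,
)

data = covid_dataset()          # 3-row testing table, offset log(tested)
detect_separation(data)         # separated=True, certificate (-1, 1, 1)

fl = fit_fl(data)
np.exp(fl.beta[1:])             # rate ratios 5.55, 6.75
profile_ci(data, fl, 1, mode="ppl")   # 95% PPL CI for the first ratio

fit_exact(data, 1)              # conditional MUE 3.05, mid-p CI (0.46, inf)
```

## CLI

```sh
sparsepoisson fixtures --outdir examples
sparsepoisson diagnose -i examples/covid_testing.csv \
    --outcome positive --multiplier tested
sparsepoisson fit -i examples/covid_testing.csv \
    --outcome positive --multiplier tested --method fl --ci ppl
sparsepoisson simulate --k 2 --epv 3 --beta1 -1.386 --reps 500 --seed 1
```

`fit` supports `--method {ml,fl,flac,flic,bda,exact}`; BDA takes
`--prior-upper` (per-covariate upper 95% prior limits for the rate ratio)
and `--S`; exact conditional inference takes `--target <column>`.

## Notes

- Counts must be nonnegative integers; exposures enter as a positive
  multiplier column or a log-offset.
- Exact conditional inference requires integer-valued covariates and is
  guarded to small problems (sum(y) <= 60, n <= 250, k <= 5).
- Under separation, ML results carry `separated=True` and Wald intervals
  are flagged unreliable; FL/FLAC/FLIC/BDA remain finite, and the exact
  method falls back from the MCLE to the median unbiased estimate.
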