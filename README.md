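# glocal

Modelling individual differences in **global vs local processing** across two
decision domains that share one stimulus set: compound (Navon-style) number
figures — a large digit drawn out of small digits.

* **Numerical comparison task** (448 trials): which level shows the larger
  digit? Choices and RTs carry congruency effects (better/faster when the
  global digit is larger) and the classic numerical distance effect.
* **Mixed-gamble task** (512 trials): accept or reject a 50/50 gamble whose
  gain is displayed at one hierarchical level and whose loss is displayed at
  the other (GGLL: gain global; GLLG: loss global).

The package is for computational cognitive modellers who want to estimate a
per-subject global-salience trait from each task and ask whether it is stable
across the two. Because trial-level human data for this paradigm are not
publicly distributable, a first-class synthetic-subject generator with known,
correlated traits makes every stage of the pipeline testable end to end.

## Models

**Preference (logit choice with loss aversion and global salience).** For a
gamble with gain `G` and loss `L` (magnitudes),

    p(accept) = 1 / (1 + exp(-β·U)),
    U = G·θ_pref − L·λ        (GGLL: gain shown globally)
    U = G − L·λ·θ_pref        (GLLG: loss shown globally)

with utility sensitivity β, loss aversion λ, and a salience factor `θ_pref`
multiplying whichever amount is displayed globally (θ > 1: global bias;
θ = 1: none; θ < 1: local bias). The value function is linear in money.
Fitted per subject by multistart maximum likelihood; a one-parameter
"accept iff gain > loss" lapse heuristic is the AIC rival.

**Numerical comparison (place-coded network + accumulator).** Three leaky
linear layers per hierarchical level: 15 place-coded input units
`dX_i/dt = −X_i + gain·I_i` (gain = `θ_perc` for the global field, 1 for the
local); a number-line layer `dY_j/dt = −Y_j + Σ_i e^{−|i−j|}·X_i`; and two
response units `dZ_k/dt = −Z_k + Σ_j w_j·Y_j + ε`, `ε ~ N(0, σ²)`, with
concave weights `w_j = 1.1 − 10^{−(j−1)/(n−1)}` spanning [0.1, 1]. A response
is emitted when `|Z_global − Z_local|` crosses a threshold;
`RT = t_nd + time_scale · crossing time`. Fitted per subject by a
Ratcliff-style RT-quantile chi-square with simulated predictions.

**Indices and cross-task analysis.** Model-free per-subject measures
(congruency effects, distance profiles, global-consistent choice fraction,
two loss-aversion readouts) plus Pearson/Spearman correlations across
subjects — in particular fitted `θ_perc` vs fitted `θ_pref`.

## Worked example

```python
from glocal import (PreferenceParams, build_session, fit_preference,
                    fit_heuristic, simulate_preference)

true = PreferenceParams(beta=0.7, lam=1.8, theta_pref=1.4)
trials = simulate_preference(build_session("preference", seed=10), true, seed=11)
fit = fit_preference(trials, n_starts=8, seed=0)
print(fit.params, fit.aic, fit_heuristic(trials).aic)
```

prints (see `examples/02_preference_model.py`):

```
fitted:  beta=0.69  lambda=1.79  theta=1.48   (true 0.70 / 1.80 / 1.40)
log-likelihood -110.6, AIC 227.2, converged=True
rival gain>loss heuristic: eps=0.252, AIC 596.8
```

i.e. the generating parameters are recovered from 512 choices and AIC
correctly prefers the value model. `examples/` contains one short script per
capability (stimulus design, both models, model-free indices, full study);
`examples/05_full_study.py` runs the whole pipeline on 8 synthetic subjects
and prints the cross-task correlation report. The same pipeline is available
from a shell:

```
glocal run-all --seed 5 --outdir run1 --sims-per-cell 40
```

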