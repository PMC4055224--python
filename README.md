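# rtwsim

Prediction of one-year labour-market outcomes for persons on long-term sick
leave, using a six-state multi-state model with transition-specific Cox
hazards combined by discrete event simulation (DES), benchmarked against
per-outcome logistic regression with Brier scores and ROC/AUC.

## The problem and the model

When a worker has been sick-listed for four weeks or more, caseworkers want
to know where that person will be one year later: back at **work** (W),
**unemployed** (U), in **recurrent sickness absence** (SA), still in the
initial **long-term sickness** episode (LTS), **temporarily out** of the
labour market (TO, e.g. maternity or education benefits), or on a
**disability pension** (D, absorbing).  Register data record this history as
dated benefit spells; work is any period without a registered benefit.

Two predictors are built from baseline covariates only (gender, age group,
socio-economic position, job type, chronic-disease insurance, prior sickness
absence, prior unemployment — all known on the first day of sick-listing):

1. **Multi-state Cox + DES.**  Each of the 20 legal transitions `s -> k`
   gets a cause-specific Cox model on the common clock *t* = days since
   sick-listing, with Breslow tie handling and left truncation at sojourn
   entry.  The fitted baseline increments ΔΛ₀ₑ(t) and hazard ratios
   exp(βₑ′x) drive a daily microsimulation: from state *s* at day *t* the
   next state is one categorical draw with stay probability exp(−ΣΔ) and
   exit probability (Δₖ/ΣΔ)(1−exp(−ΣΔ)) for each reachable state.  The
   predicted state-occupation probability at day 365 is the fraction of
   10,000 simulated pathways ending in each state.  An exact oracle — the
   ordered product of the 365 daily one-step transition matrices — verifies
   the simulation to Monte-Carlo accuracy.
2. **Logistic baseline.**  Six separate additive binary logistic models,
   one per outcome state (so the six predicted probabilities need not sum
   to one — by design).

Both are scored on a held-out validation share (default 67.4% training)
against a **null model** that predicts the training prevalence *p* for
everyone: mean Brier *p(1−p)* and AUC exactly 0.5.

Because real register data of this kind cannot be distributed, the package
ships a first-class synthetic generator (`rtwsim.synthetic`): register-like
spell histories from a *known* proportional-hazards ground truth, including
a 365-day look-back buffer year, an initial LTS episode of ≥ 28 days, and
right truncation — so every stage is testable against the generating truth.

## Worked example

```python
import rtwsim as r
from rtwsim.evaluate import format_report

cfg = r.ExperimentConfig(scenarios={"growth": r.TrueModel.default()},
                         n_persons=2000, n_reps=500, seed=1)
res = r.run_scenario("growth", cfg.scenarios["growth"], cfg)
print(format_report(res.report))
```

```
scenario: growth
state method     obs prev  pred prev     AUC    Brier  band
-----------------------------------------------------------
LTS   null           4.5%       5.6%   50.0%   0.0432  fail
LTS   logistic       4.5%       5.5%   59.4%   0.0441  fail
LTS   DES            4.5%       5.1%   63.5%   0.0430  poor
W     null          68.9%      64.8%   50.0%   0.2160  fail
W     logistic      68.9%      65.1%   62.1%   0.2062  poor
W     DES           68.9%      65.0%   62.4%   0.2054  poor
U     null          10.9%       9.2%   50.0%   0.0972  fail
U     logistic      10.9%       9.0%   67.3%   0.0941  poor
U     DES           10.9%       9.2%   69.4%   0.0925  poor
SA    null           8.2%      12.5%   50.0%   0.0771  fail
SA    logistic       8.2%      12.3%   55.5%   0.0783  fail
SA    DES            8.2%      12.6%   53.7%   0.0777  fail
TO    null           7.0%       6.9%   50.0%   0.0653  fail
TO    logistic       7.0%       7.3%   46.3%   0.0671  fail
TO    DES            7.0%       7.1%   49.3%   0.0666  fail
D     null           0.5%       1.0%   50.0%   0.0050  fail
D     logistic       0.5%       0.9%   53.9%   0.0051  fail
D     DES            0.5%       0.9%   58.9%   0.0050  fail
```

Each row gives, for one outcome state and method, the observed validation
prevalence, the mean predicted probability, the tie-corrected AUC, the mean
Brier score over non-censored validation persons, and the discrimination
band (≥0.9 excellent / 0.8 good / 0.7 fair / 0.6 poor / below 0.6 fail).
Both covariate-based predictors beat the null Brier for the work state and
discriminate above chance, with DES and logistic regression closely
comparable — the expected behaviour when a one-year endpoint summarises
many competing pathways.  Leave-one-variable-out importance
(`res.importance`) ranks prior unemployment first for the work outcome
(ΔAUC ≈ 5% here).

The same experiment runs from the shell:

```bash
rtwsim run-all -o out/ --n-persons 2000 --n-reps 500 --seed 1
```

with stage-wise subcommands (`simulate`, `derive`, `fit`, `predict`,
`evaluate`) exchanging plain CSV artifacts.

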