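"""Per-outcome logistic regression — the comparison predictor.

One *binary* additive logistic model per outcome state: the indicator of
being in that state at day 365 is regressed on all seven baseline
covariates (dummy-coded at the conventional reference levels).  Six
separate binary fits, not one multinomial model, so the six predicted
probabilities of a person need not sum to one — that is a feature of the
design being replicated, not a bug.

Censored-before-outcome persons are excluded from fitting (and from all
scoring downstream).  The near-empty "unregistered" socio-economic level is
merged into "without job" when it carries no cases, with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .schema import encode_design
from .states import STATES


class SeparationError(RuntimeError):
    pass


class OutcomeLogit:
    """Binary logistic model for one of the six outcome states.

    Parameters
    ----------
    cohort : DataFrame
        Cohort rows with the seven covariates and an ``outcome`` column.
    outcome_state : str
        One of ``LTS, W, U, SA, TO, D``.
    """

    def __init__(self, cohort: pd.DataFrame, outcome_state: str):
        if outcome_state not in STATES:
            raise ValueError(f"unknown outcome state {outcome_state!r}")
        self.outcome_state = outcome_state
        data = cohort[cohort["outcome"] != "censored"].copy()
        # unidentifiable sparse level: fold into its nearest neighbour
        sep = data["socio_economic_position"]
        y = (data["outcome"] == outcome_state).astype(int)
        unreg = sep == "unregistered"
        if unreg.any() and y[unreg].nunique() < 2:
            warnings.warn(
                "socio-economic level 'unregistered' has no outcome "
                "variation; merged into 'without_job'")
            data.loc[unreg, "socio_economic_position"] = "without_job"
        self.data = data
        self.endog = (data["outcome"] == outcome_state).astype(int).to_numpy()

    def fit(self) -> "OutcomeLogitResults":
        n1 = int(self.endog.sum())
        if n1 == 0 or n1 == len(self.endog):
            raise ValueError(
                f"outcome {self.outcome_state}: need at least one case and "
                f"one non-case among non-censored rows (got {n1} cases of "
                f"{len(self.endog)})")
        X = encode_design(self.data)
        y = self.endog.astype(bool)
        keep, dropped = [], []
        for c in X.columns:
            x = X[c].to_numpy() > 0
            # dummy levels whose carriers are all cases or all non-cases
            # have a divergent MLE (quasi-separation) -> treated as reference
            if x.any() and (~x).any() and y[x].any() and (~y[x]).any():
                keep.append(c)
            else:
                dropped.append(c)
        if dropped:
            warnings.warn(
                f"outcome {self.outcome_state}: level(s) {dropped} carry no "
                f"outcome variation; treated as reference")
        self.dropped = tuple(dropped)
        exog = sm.add_constant(X[keep], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(self.endog, exog).fit(disp=False, maxiter=200)
        if not np.isfinite(res.params).all() or \
                not np.isfinite(res.bse).all() or (res.bse > 50).any():
            bad = [c for c, s in zip(exog.columns, res.bse)
                   if not np.isfinite(s) or s > 50]
            raise SeparationError(
                f"outcome {self.outcome_state}: (quasi-)complete separation "
                f"suspected for {bad}")
        return OutcomeLogitResults(self, res, tuple(keep))


class OutcomeLogitResults:
    """Fitted per-outcome logistic model."""

    def __init__(self, model: OutcomeLogit, res, columns: tuple[str, ...]):
        self.model = model
        self.outcome_state = model.outcome_state
        self._res = res
        self.columns = columns
        self.params = pd.Series(res.params.values,
                                index=["intercept", *columns])
        self.bse = pd.Series(res.bse.values, index=["intercept", *columns])

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        """Inverse-logit of the linear predictor; strictly inside (0, 1)."""
        X = encode_design(covariates)
        lp = np.full(len(covariates), self.params["intercept"])
        for c in self.columns:
            lp += self.params[c] * X[c].to_numpy()
        return 1.0 / (1.0 + np.exp(-lp))

    def summary(self) -> pd.DataFrame:
        """Odds-ratio table: OR, 95% CI, Wald p per non-reference level."""
        coefs = self.params.drop("intercept")
        ses = self.bse.drop("intercept")
        z = coefs / ses
        from scipy import stats
        rows = []
        for c in coefs.index:
            cov, lvl = c[:-1].split("[")
            rows.append({
                "outcome": self.outcome_state, "covariate": cov,
                "level": lvl, "OR": np.exp(coefs[c]),
                "ci_low": np.exp(coefs[c] - 1.96 * ses[c]),
                "ci_high": np.exp(coefs[c] + 1.96 * ses[c]),
                "p_value": 2 * stats.norm.sf(abs(z[c])),
            })
        return pd.DataFrame(rows)


def fit_outcome_logistic(cohort: pd.DataFrame,
                         outcome_state: str) -> OutcomeLogitResults:
    """Convenience: build and fit in one call."""
    return OutcomeLogit(cohort, outcome_state).fit()


def fit_all_outcomes(cohort: pd.DataFrame
                     ) -> dict[str, OutcomeLogitResults]:
    """One binary fit per state (states with no cases are skipped with a
    warning — e.g. disability in a very small cohort)."""
    out = {}
    for s in STATES:
        try:
            out[s] = fit_outcome_logistic(cohort, s)
        except ValueError as err:
            warnings.warn(str(err))
    return out
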