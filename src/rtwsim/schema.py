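"""Baseline covariate schema shared by every model in the package.

Seven categorical predictors, all recorded on the first day of the initial
long-term sick-listing and never updated afterwards.  Reference levels follow
the convention of the logistic-regression reporting (female, 50-59 years,
wage earner, sale/service/care-taking work, no chronic disease, no prior
sickness absence, no prior unemployment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: covariate -> ordered levels, reference level FIRST.
COVARIATES: dict[str, tuple[str, ...]] = {
    "gender": ("female", "male"),
    "age_group": ("50-59", "20-29", "30-39", "40-49"),
    "socio_economic_position": (
        "wage_earner", "self_employed", "without_job", "unregistered",
    ),
    "job_type": (
        "sale_service", "military", "management", "office",
        "farming", "other", "unregistered",
    ),
    "chronic_disease": ("no", "yes"),
    "prior_sa": ("none", "one_or_more"),
    "prior_unemp": ("none", "one", "two_or_more"),
}

#: Covariates sampled directly by the generator; prior_sa / prior_unemp are
#: derived from the 365-day look-back window instead.
BASELINE_SAMPLED = (
    "gender", "age_group", "socio_economic_position", "job_type",
    "chronic_disease",
)
LOOKBACK_DERIVED = ("prior_sa", "prior_unemp")


def dummy_columns(covariates: dict[str, tuple[str, ...]] | None = None) -> list[str]:
    """Ordered non-reference dummy names, ``cov[level]`` style."""
    covariates = covariates or COVARIATES
    cols = []
    for cov, levels in covariates.items():
        cols.extend(f"{cov}[{lvl}]" for lvl in levels[1:])
    return cols


def encode_design(df: pd.DataFrame,
                  covariates: dict[str, tuple[str, ...]] | None = None,
                  ) -> pd.DataFrame:
    """Dummy-code the covariate columns of ``df`` against the schema.

    Returns a float design matrix with one column per non-reference level,
    in schema order.  Unknown levels raise ``ValueError`` naming the
    covariate — predictions must never silently treat a typo as reference.
    """
    covariates = covariates or COVARIATES
    out = {}
    for cov, levels in covariates.items():
        vals = df[cov].to_numpy()
        known = np.isin(vals, levels)
        if not known.all():
            bad = sorted(set(vals[~known]))
            raise ValueError(f"unknown level(s) {bad} for covariate {cov!r}")
        for lvl in levels[1:]:
            out[f"{cov}[{lvl}]"] = (vals == lvl).astype(float)
    return pd.DataFrame(out, index=df.index)


def validate_margins(margins: dict[str, dict[str, float]]) -> None:
    """Check that category probabilities are a distribution per covariate."""
    for cov, probs in margins.items():
        if cov not in COVARIATES:
            raise ValueError(f"margins given for unknown covariate {cov!r}")
        levels = COVARIATES[cov]
        unknown = set(probs) - set(levels)
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} for {cov!r}")
        p = np.array([probs.get(lvl, 0.0) for lvl in levels])
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"margins for covariate {cov!r} must be nonnegative and sum "
                f"to 1 (got sum {p.sum():.6f})"
            )
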