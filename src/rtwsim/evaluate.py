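"""Validation metrics: Brier scores, ROC/AUC, variable importance, report.

Both predictors are scored per outcome state on the non-censored validation
persons.  The benchmark is the null model that assigns every person the
training prevalence: its mean Brier score is ``q(1-p)^2 + (1-q)p^2`` for
training prevalence ``p`` and validation prevalence ``q`` (``p(1-p)``
exactly when the two coincide), and its AUC is 0.5 by construction under
the tie-corrected rank estimator.

AUC uses the rank statistic counting ties as 1/2 — equivalent to the
trapezoidal area under the ROC curve over all thresholds (scikit-learn).
Discrimination bands follow the usual rough guide: >=0.9 excellent,
0.8-0.9 good, 0.7-0.8 fair, 0.6-0.7 poor, below 0.6 fail (left-closed
boundaries).

Variable importance is leave-one-variable-out on the logistic model:
``dAUC% = 100 * (AUC_full - AUC_reduced) / AUC_full`` and
``dBrier% = 100 * (Brier_reduced - Brier_full) / Brier_full`` — positive
values mean accuracy is lost when the variable is removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .logistic import OutcomeLogit
from .schema import COVARIATES
from .states import STATES


def brier_score(predictions, outcomes) -> tuple[np.ndarray, float]:
    """Per-person squared errors ``(y_i - p_i)^2`` and their mean."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predictions must be probabilities in [0, 1]")
    scores = (y - p) ** 2
    return scores, float(scores.mean())


def null_model_brier(training_prevalence: float, validation_outcomes) -> float:
    """Mean Brier of the constant predictor = training prevalence."""
    if not 0 <= training_prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    y = np.asarray(validation_outcomes, dtype=float)
    if y.size == 0:
        return 0.0
    _, mean = brier_score(np.full(y.shape, training_prevalence), y)
    return mean


def roc_auc(predictions, outcomes) -> tuple[float, pd.DataFrame]:
    """Tie-corrected AUC plus the ROC curve points.

    Requires both classes present.  Constant predictions give exactly 0.5
    (the single ROC segment from (0,0) to (1,1)).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present to compute "
                         "a ROC curve")
    auc = float(roc_auc_score(y, p))
    fpr, tpr, thr = roc_curve(y, p, drop_intermediate=False)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve


def classify_auc(auc: float) -> str:
    """Discrimination band, left-closed at the boundaries."""
    if not 0 <= auc <= 1:
        raise ValueError("AUC must be in [0, 1]")
    if auc >= 0.9:
        return "excellent"
    if auc >= 0.8:
        return "good"
    if auc >= 0.7:
        return "fair"
    if auc >= 0.6:
        return "poor"
    return "fail"


def variable_importance(cohort_train: pd.DataFrame,
                        cohort_valid: pd.DataFrame,
                        outcome_state: str,
                        variable: str | None = None) -> pd.DataFrame:
    """Leave-one-variable-out change in logistic AUC and Brier (percent).

    Refits the outcome's logistic model without each variable (or only
    ``variable`` if given) and scores on the validation cohort.
    """
    if variable is not None and variable not in COVARIATES:
        raise ValueError(f"unknown predictor {variable!r}")
    valid = cohort_valid[cohort_valid["outcome"] != "censored"]
    y = (valid["outcome"] == outcome_state).astype(int).to_numpy()

    full = OutcomeLogit(cohort_train, outcome_state).fit()
    p_full = full.predict(valid)
    auc_full, _ = roc_auc(p_full, y)
    _, bs_full = brier_score(p_full, y)

    variables = [variable] if variable else list(COVARIATES)
    rows = []
    for var in variables:
        # refit on the reduced design by overwriting the variable with its
        # reference level (equivalent to removing its dummies)
        train_red = cohort_train.copy()
        train_red[var] = COVARIATES[var][0]
        valid_red = valid.copy()
        valid_red[var] = COVARIATES[var][0]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            red = OutcomeLogit(train_red, outcome_state).fit()
        p_red = red.predict(valid_red)
        auc_red, _ = roc_auc(p_red, y)
        _, bs_red = brier_score(p_red, y)
        rows.append({
            "outcome": outcome_state, "variable": var,
            "auc_full": auc_full, "auc_reduced": auc_red,
            "dAUC_pct": 100.0 * (auc_full - auc_red) / auc_full,
            "brier_full": bs_full, "brier_reduced": bs_red,
            "dBrier_pct": 100.0 * (bs_red - bs_full) / bs_full,
        })
    return pd.DataFrame(rows)


def build_report(cohort_train: pd.DataFrame, cohort_valid: pd.DataFrame,
                 predictions: pd.DataFrame,
                 scenario: str = "default") -> pd.DataFrame:
    """Per (state, method) prevalence / AUC / Brier summary table.

    ``predictions`` is a long frame with columns ``person_id``, ``source``
    (``logistic`` or ``DES``) and ``P_<state>`` probability columns for the
    validation persons.  Null-model rows use the training prevalence as the
    constant prediction.  Censored validation persons are excluded from
    every metric.
    """
    need = {"logistic", "DES"} - set(predictions["source"].unique())
    if need:
        raise ValueError(f"missing prediction source(s): {sorted(need)}")
    train = cohort_train[cohort_train["outcome"] != "censored"]
    valid = cohort_valid[cohort_valid["outcome"] != "censored"]
    rows = []
    for state in STATES:
        y = (valid["outcome"] == state).astype(int).to_numpy()
        obs_prev = float(y.mean())
        p_train = float((train["outcome"] == state).mean())
        both = len(np.unique(y)) == 2
        rows.append({
            "scenario": scenario, "state": state, "method": "null",
            "observed_prevalence": obs_prev,
            "predicted_prevalence": p_train,
            "auc": 0.5 if both else np.nan,
            "brier": null_model_brier(p_train, y),
        })
        for method in ("logistic", "DES"):
            sub = predictions[predictions["source"] == method] \
                .set_index("person_id")
            p = sub.loc[valid["person_id"], f"P_{state}"].to_numpy()
            usable = np.isfinite(p).all()  # e.g. no-case outcome unfitted
            rows.append({
                "scenario": scenario, "state": state, "method": method,
                "observed_prevalence": obs_prev,
                "predicted_prevalence": float(p.mean()) if usable else np.nan,
                "auc": roc_auc(p, y)[0] if usable and both else np.nan,
                "brier": brier_score(p, y)[1] if usable else np.nan,
            })
    return pd.DataFrame(rows)


def roc_points(cohort_valid: pd.DataFrame,
               predictions: pd.DataFrame) -> pd.DataFrame:
    """Long frame of ROC curve points per (state, method) for plotting."""
    valid = cohort_valid[cohort_valid["outcome"] != "censored"]
    frames = []
    for state in STATES:
        y = (valid["outcome"] == state).astype(int).to_numpy()
        if len(np.unique(y)) < 2:
            continue
        for method in ("logistic", "DES"):
            sub = predictions[predictions["source"] == method] \
                .set_index("person_id")
            p = sub.loc[valid["person_id"], f"P_{state}"].to_numpy()
            if not np.isfinite(p).all():
                continue
            _, curve = roc_auc(p, y)
            curve = curve.assign(state=state, method=method)
            frames.append(curve)
    cols = ["state", "method", "fpr", "tpr", "threshold"]
    return pd.concat(frames, ignore_index=True)[cols] if frames else \
        pd.DataFrame(columns=cols)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable table: one block per scenario, rows per state/method."""
    lines = []
    header = (f"{'state':<5} {'method':<9} {'obs prev':>9} {'pred prev':>10} "
              f"{'AUC':>7} {'Brier':>8}  band")
    for scen, grp in report.groupby("scenario", sort=False):
        lines.append(f"scenario: {scen}")
        lines.append(header)
        lines.append("-" * len(header))
        for _, r in grp.iterrows():
            band = classify_auc(r["auc"]) if np.isfinite(r["auc"]) else "-"
            auc = f"{100 * r['auc']:.1f}%" if np.isfinite(r["auc"]) else "  -"
            lines.append(
                f"{r['state']:<5} {r['method']:<9} "
                f"{100 * r['observed_prevalence']:>8.1f}% "
                f"{100 * r['predicted_prevalence']:>9.1f}% "
                f"{auc:>7} {r['brier']:>8.4f}  {band}")
        lines.append("")
    return "\n".join(lines)


def plot_roc(curves: dict[str, pd.DataFrame], title: str, path=None):
    """Basic ROC figure (one line per method plus the chance diagonal)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        ax.plot(curve["fpr"], curve["tpr"], label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="null model")
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.set_title(title)
    ax.legend(loc="lower right")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
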