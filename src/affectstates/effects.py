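"""Mixed-effects effect sizes, the SCR median split, and the set-size experiment.

Observed measures are regressed on predicted measures in a linear mixed
model with subject-wise random slope and intercept (maximum likelihood).
The reported effect size follows two conventions: the Pearson correlation
between the fixed-effect fitted values and the observations (primary), and
the t-to-r conversion ``r = t / sqrt(t^2 + df)`` (alternative); both are
carried in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .lss import BetaSeries
from .mvpa import loocv_classify

__all__ = ["EffectSizeResult", "glmm_effect_size", "median_split_analysis",
           "set_size_experiment"]


@dataclass
class EffectSizeResult:
    """Fixed and random effects of an observed-on-predicted mixed model."""

    slope: float
    slope_se: float
    intercept: float
    r: float                      # Pearson r of fixed-effect fit vs observed
    r_from_t: float               # alternative: t / sqrt(t^2 + df)
    p: float                      # slope test
    random_effects: pd.DataFrame  # per-subject deviations + significance flags
    n_obs: int
    n_subjects: int
    singular: bool = False
    converged: bool = True
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Mixed-effects effect size (observed ~ predicted)",
            f"  n_obs = {self.n_obs}, n_subjects = {self.n_subjects}",
            f"  fixed slope = {self.slope:.4f} (p = {self.p:.4g})",
            f"  fixed intercept = {self.intercept:.4f}",
            f"  Pearson r (fixed-effect fit) = {self.r:.4f}",
            f"  r from t  = {self.r_from_t:.4f}",
        ]
        if self.singular:
            lines.append("  note: random-slope fit singular; "
                         "random-intercept-only fallback used")
        return "\n".join(lines)


def glmm_effect_size(observed: np.ndarray, predicted: np.ndarray,
                     subjects: np.ndarray) -> EffectSizeResult:
    """Fit observed ~ predicted with subject-wise random slope + intercept.

    Singular random-slope fits fall back to a random-intercept-only model
    (flagged in the result, never silently accepted).
    """
    df = pd.DataFrame({"observed": np.asarray(observed, float),
                       "predicted": np.asarray(predicted, float),
                       "subject": np.asarray(subjects)})
    n_sub = df["subject"].nunique()
    if n_sub < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    if df.groupby("subject").size().min() < 3:
        raise ValueError("each subject needs at least 3 observations")

    def _try_fit(re_formula):
        model = smf.mixedlm("observed ~ predicted", df, groups=df["subject"],
                            re_formula=re_formula)
        fit = model.fit(reml=False)
        if not np.all(np.isfinite(np.asarray(fit.cov_re))):
            raise np.linalg.LinAlgError("non-finite random-effect covariance")
        re = fit.random_effects  # raises on a singular covariance structure
        return fit, re

    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit, rand_effects = _try_fit("~predicted")
        except (np.linalg.LinAlgError, ValueError):
            singular = True
            try:
                fit, rand_effects = _try_fit(None)
            except (np.linalg.LinAlgError, ValueError):
                # variance components vanish (e.g. exact identity data):
                # keep the fixed-effect fit, report zero random effects
                model = smf.mixedlm("observed ~ predicted", df,
                                    groups=df["subject"])
                fit = model.fit(reml=False)
                rand_effects = {s: np.zeros(1) for s in df["subject"].unique()}

    slope = float(fit.params["predicted"])
    slope_se = float(fit.bse["predicted"])
    intercept = float(fit.params["Intercept"])
    fitted_fixed = intercept + slope * df["predicted"].to_numpy()
    if np.std(fitted_fixed) > 0 and np.std(df["observed"]) > 0:
        r = float(stats.pearsonr(fitted_fixed, df["observed"])[0])
    else:
        r = 0.0
    tval = float(fit.tvalues["predicted"])
    dof = len(df) - 2
    r_from_t = float(tval / np.sqrt(tval ** 2 + dof))
    p = float(fit.pvalues["predicted"])

    re_rows = []
    re_sd = np.sqrt(np.clip(np.diag(np.asarray(fit.cov_re)), 0, None))
    for subject, re in rand_effects.items():
        re = np.asarray(re, float)
        flags = np.abs(re) > 1.96 * np.where(re_sd[:len(re)] > 0,
                                             re_sd[:len(re)], np.inf)
        re_rows.append([subject, *re, *flags])
    ncols = len(re_rows[0]) - 1 if re_rows else 0
    names = ["intercept_dev", "slope_dev"][:ncols // 2]
    random_effects = pd.DataFrame(
        re_rows, columns=["subject"] + names + [f"{n}_sig" for n in names])

    return EffectSizeResult(slope=slope, slope_se=slope_se, intercept=intercept, r=r,
                            r_from_t=r_from_t, p=p,
                            random_effects=random_effects,
                            n_obs=len(df), n_subjects=n_sub,
                            singular=singular,
                            converged=bool(fit.converged))


def median_split_analysis(observed: np.ndarray, predicted: np.ndarray,
                          subjects: np.ndarray,
                          within_subject: bool = False) -> EffectSizeResult:
    """Effect size on observations strictly above the median.

    Emulates restricting an analysis to trials that actually elicited a
    strong response. The split is pooled across subjects by default;
    ``within_subject=True`` splits against each subject's own median.
    """
    observed = np.asarray(observed, float)
    subjects = np.asarray(subjects)
    if np.ptp(observed) == 0:
        raise ValueError("constant observations: median split undefined")
    if within_subject:
        keep = np.zeros(len(observed), bool)
        for s in np.unique(subjects):
            m = subjects == s
            keep[m] = observed[m] > np.median(observed[m])
    else:
        keep = observed > np.median(observed)
    res = glmm_effect_size(observed[keep], np.asarray(predicted)[keep],
                           subjects[keep])
    res.extras["n_retained"] = int(keep.sum())
    return res


def set_size_experiment(betas_per_subject: dict, labels_per_subject: dict,
                        property_name: str,
                        fractions: np.ndarray | None = None,
                        n_reps: int = 3, seed: int = 0,
                        max_redraws: int = 50) -> tuple[pd.DataFrame, EffectSizeResult]:
    """Classification accuracy as a function of stimulus-set size.

    For each fraction on the 25%-100% grid (5% steps, 16 levels) a uniform
    random stimulus subset is drawn per subject, the full balanced LOOCV
    classification is run on it, and the accuracy recorded. Draws that
    collapse a class below 2 members are redrawn (and counted). A mixed
    model of accuracy on set size with subject-wise random effects gives
    the size effect.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.25, 1.0001, 0.05), 2)
    rng = np.random.default_rng(seed)
    rows = []
    redraws = 0
    for subject, betas in betas_per_subject.items():
        labels = np.asarray(labels_per_subject[subject], int)
        n = betas.n_trials
        for frac in fractions:
            size = max(int(round(frac * n)), 4)
            for attempt in range(max_redraws):
                if frac >= 1.0:
                    idx = np.arange(n)
                else:
                    idx = np.sort(rng.choice(n, size=size, replace=False))
                sub_labels = labels[idx]
                if (sub_labels == 1).sum() >= 2 and (sub_labels == -1).sum() >= 2:
                    break
                redraws += 1
            else:
                raise ValueError("could not draw a subset with both classes")
            sub = BetaSeries(data=betas.data[idx], modality=betas.modality,
                             stimulus_ids=betas.stimulus_ids[idx],
                             subject=subject)
            preds = loocv_classify(sub, sub_labels, property_name,
                                   n_reps=n_reps, seed=seed)
            acc = float((preds["y_pred"] == preds["y_true"]).mean())
            rows.append((subject, float(frac), size, acc))
    table = pd.DataFrame(rows, columns=["subject", "fraction", "set_size",
                                        "accuracy"])
    effect = glmm_effect_size(table["accuracy"].to_numpy(),
                              table["fraction"].to_numpy(),
                              table["subject"].to_numpy())
    effect.extras["n_redraws"] = redraws
    return table, effect
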