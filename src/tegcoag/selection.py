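"""Collinearity screening, stepwise regression and propensity matching.

The multivariate modelling workflow mirrors common clinical-statistics
practice: variance-inflation-factor (VIF) screening removes strongly
collinear coagulation markers; forward stepwise selection with a backward
re-check (likelihood-ratio criterion for logistic outcomes, partial-F for
linear ones) identifies independent influencing factors; optional 1:1
propensity matching balances confounders before group comparisons.

One pipeline rule is encoded explicitly rather than hidden in the stepwise
machinery: when the coagulation index CI is found to be a complete mediator
of a TEG parameter's effect on grade, CI is excluded from the multivariate
model for that grouping (see ``pipeline``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "VifReport",
    "StepwiseResult",
    "vif_screen",
    "stepwise_logistic",
    "stepwise_linear",
    "propensity_match",
    "SeparationWarning",
]

VIF_INFINITE_R2 = 1 - 1e-10  # R^2 above this is treated as exact collinearity


class SeparationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class VifReport:
    vif: dict  # final VIFs of retained variables
    initial_vif: dict  # VIFs on the full input set
    retained: list
    dropped: list  # (name, reason, vif_at_removal)

    def __post_init__(self):
        names = set(self.retained) | {d[0] for d in self.dropped}
        if names != set(self.initial_vif):
            raise ValueError("retained + dropped must partition the input set")


@dataclass(frozen=True)
class StepwiseResult:
    selected: list
    coefficients: dict  # name -> B
    conf_int: dict  # name -> (lo, hi) on the coefficient scale
    odds_ratios: dict  # exp(B) with exp CI (logistic only; empty for linear)
    p_values: dict  # Wald p of the final fit
    step_trace: list  # (step, action, variable, criterion_p)
    family: str = "logistic"
    standardized: dict = field(default_factory=dict)  # linear only
    skipped: dict = field(default_factory=dict)  # name -> reason

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.selected:
            row = {
                "variable": name,
                "B": self.coefficients[name],
                "ci_lo": self.conf_int[name][0],
                "ci_hi": self.conf_int[name][1],
                "p": self.p_values[name],
            }
            if self.family == "logistic":
                row["OR"] = self.odds_ratios[name][0]
                row["OR_lo"] = self.odds_ratios[name][1]
                row["OR_hi"] = self.odds_ratios[name][2]
            else:
                row["standardized_B"] = self.standardized.get(name)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VIF screening
# ---------------------------------------------------------------------------


def _r_squared(target: np.ndarray, others: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(target)), others])
    resid = target - design @ np.linalg.lstsq(design, target, rcond=None)[0]
    ss_tot = np.sum((target - target.mean()) ** 2)
    if ss_tot == 0:
        return 1.0
    return float(1 - np.sum(resid**2) / ss_tot)


def _vifs(df: pd.DataFrame) -> dict:
    out = {}
    for name in df.columns:
        r2 = _r_squared(df[name].to_numpy(dtype=float),
                        df.drop(columns=name).to_numpy(dtype=float))
        out[name] = float("inf") if r2 >= VIF_INFINITE_R2 else 1.0 / (1.0 - r2)
    return out


def vif_screen(design: pd.DataFrame, threshold: float = 10.0) -> VifReport:
    """Iteratively drop the largest-VIF predictor until all VIFs <= threshold.

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the remaining
    predictors (with intercept).  Exactly collinear columns get an infinite
    VIF and are removed first; ties break alphabetically for determinism.
    """
    design = pd.DataFrame(design)
    if design.shape[1] < 2:
        raise ValueError("vif_screen needs >= 2 predictors")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more rows than predictors")
    initial = _vifs(design)
    current = design.copy()
    dropped = []
    while current.shape[1] >= 2:
        vifs = _vifs(current)
        worst = max(sorted(vifs), key=lambda k: (vifs[k],))
        if vifs[worst] <= threshold:
            break
        reason = "exact_collinearity" if np.isinf(vifs[worst]) else "vif_above_threshold"
        dropped.append((worst, reason, vifs[worst]))
        current = current.drop(columns=worst)
    final = _vifs(current) if current.shape[1] >= 2 else {
        c: 1.0 for c in current.columns
    }
    return VifReport(
        vif=final, initial_vif=initial,
        retained=list(current.columns), dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Stepwise selection
# ---------------------------------------------------------------------------


def _fit(design: pd.DataFrame, y: np.ndarray, cols: list, family: str):
    X = sm.add_constant(design[cols].to_numpy(dtype=float)) if cols else \
        np.ones((len(y), 1))
    if family == "logistic":
        model = sm.Logit(y, X)
        return model.fit(disp=0, maxiter=100, method="newton")
    return sm.OLS(y, X).fit()


def _partial_f_p(ssr_base: float, ssr_full: float, df_resid: float) -> float:
    """Partial-F p-value for one added regressor, guarding exact fits."""
    improvement = max(ssr_base - ssr_full, 0.0)
    if ssr_full <= 1e-12 * max(ssr_base, 1.0):
        # full model is an exact fit: decisive only if it actually improved
        return 0.0 if improvement > 1e-12 * max(ssr_base, 1.0) else 1.0
    f = improvement / (ssr_full / df_resid)
    return float(stats.f.sf(f, 1, df_resid))


def _entry_p(design, y, current, candidate, family, base_fit):
    """Likelihood-ratio (logistic) or partial-F (linear) p for adding a variable."""
    try:
        fit = _fit(design, y, current + [candidate], family)
    except (np.linalg.LinAlgError, PerfectSeparationError):
        return None, None
    if family == "logistic":
        if not np.all(np.isfinite(fit.params)) or \
                not fit.mle_retvals.get("converged", True) or \
                np.abs(fit.params).max() > 50:
            return None, fit
        lr = 2 * (fit.llf - base_fit.llf)
        return float(stats.chi2.sf(max(lr, 0.0), df=1)), fit
    return _partial_f_p(base_fit.ssr, fit.ssr, fit.df_resid), fit


def _stepwise(design: pd.DataFrame, y, family: str, p_enter: float,
              p_remove: float, max_steps: int = 100):
    design = pd.DataFrame(design)
    y = np.asarray(y, dtype=float)
    if family == "logistic" and len(np.unique(y)) != 2:
        raise ValueError("outcome must contain both classes")
    current: list = []
    trace = []
    skipped: dict = {}
    step = 0
    while step < max_steps:
        step += 1
        base_fit = _fit(design, y, current, family)
        # forward: best candidate by (p, name)
        best = None
        for cand in sorted(c for c in design.columns if c not in current):
            p, _ = _entry_p(design, y, current, cand, family, base_fit)
            if p is None:
                skipped[cand] = "separation"
                trace.append((step, "skip_separation", cand, None))
                continue
            if best is None or p < best[0] - 1e-15 or (
                abs(p - best[0]) <= 1e-15 and cand < best[1]
            ):
                best = (p, cand)
        entered = False
        if best is not None and best[0] <= p_enter:
            current.append(best[1])
            trace.append((step, "enter", best[1], best[0]))
            entered = True
        # backward re-check
        removed = True
        while removed and len(current) > (1 if entered else 0):
            removed = False
            full_fit = _fit(design, y, current, family)
            worst = None
            for name in sorted(current):
                reduced = [c for c in current if c != name]
                red_fit = _fit(design, y, reduced, family)
                if family == "logistic":
                    lr = 2 * (full_fit.llf - red_fit.llf)
                    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
                else:
                    p = _partial_f_p(red_fit.ssr, full_fit.ssr,
                                     full_fit.df_resid)
                if worst is None or p > worst[0] + 1e-15 or (
                    abs(p - worst[0]) <= 1e-15 and name < worst[1]
                ):
                    worst = (p, name)
            if worst is not None and worst[0] > p_remove and worst[1] != (
                current[-1] if entered else None
            ):
                current.remove(worst[1])
                trace.append((step, "remove", worst[1], worst[0]))
                removed = True
        if not entered:
            break
    return design, y, current, trace, skipped


def stepwise_logistic(design, y, p_enter: float = 0.05,
                      p_remove: float = 0.10) -> StepwiseResult:
    """Forward stepwise logistic selection with backward re-check.

    Entry uses the single-df likelihood-ratio test against the current model;
    removal re-tests each retained variable after every entry.  Ties break by
    smaller p then alphabetical name, so traces are fully deterministic.
    Variables whose candidate fit diverges (separation) are skipped with a
    trace note rather than silently entering.
    """
    design, y, current, trace, skipped = _stepwise(
        design, y, "logistic", p_enter, p_remove
    )
    coefficients, conf, ors, pvals = {}, {}, {}, {}
    if current:
        fit = _fit(design, y, current, "logistic")
        ci = fit.conf_int()
        for i, name in enumerate(current, start=1):
            b = float(fit.params[i])
            lo, hi = float(ci[i][0]), float(ci[i][1])
            coefficients[name] = b
            conf[name] = (lo, hi)
            ors[name] = (float(np.exp(b)), float(np.exp(lo)), float(np.exp(hi)))
            pvals[name] = float(fit.pvalues[i])
    return StepwiseResult(
        selected=current, coefficients=coefficients, conf_int=conf,
        odds_ratios=ors, p_values=pvals, step_trace=trace,
        family="logistic", skipped=skipped,
    )


def stepwise_linear(design, y, p_enter: float = 0.05,
                    p_remove: float = 0.10) -> StepwiseResult:
    """Forward stepwise OLS selection with backward re-check (partial-F tests).

    Reports unstandardized coefficients with 95% CIs plus standardized B
    (B * sd_x / sd_y) for comparability across predictors.
    """
    design, y, current, trace, skipped = _stepwise(
        design, y, "linear", p_enter, p_remove
    )
    coefficients, conf, pvals, std_b = {}, {}, {}, {}
    if current:
        fit = _fit(design, y, current, "linear")
        ci = fit.conf_int()
        sd_y = np.std(y, ddof=1)
        for i, name in enumerate(current, start=1):
            b = float(fit.params[i])
            coefficients[name] = b
            conf[name] = (float(ci[i][0]), float(ci[i][1]))
            pvals[name] = float(fit.pvalues[i])
            std_b[name] = float(
                b * np.std(design[name].to_numpy(dtype=float), ddof=1) / sd_y
            )
    return StepwiseResult(
        selected=current, coefficients=coefficients, conf_int=conf,
        odds_ratios={}, p_values=pvals, step_trace=trace,
        family="linear", standardized=std_b, skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Propensity matching
# ---------------------------------------------------------------------------


def propensity_match(df: pd.DataFrame, treatment_col: str, covariates: list,
                     caliper_sd: float = 0.2) -> pd.DataFrame:
    """1:1 nearest-neighbor matching without replacement on the logit propensity.

    The propensity is a logistic regression of treatment on ``covariates``;
    matching proceeds from the treated unit with the highest propensity
    downward, pairing each with the nearest untreated unit within
    ``caliper_sd`` standard deviations of the logit propensity.  Returns the
    matched rows (equal group sizes); empty with equal columns if no pair
    falls within the caliper.
    """
    data = df.dropna(subset=covariates + [treatment_col]).copy()
    t = data[treatment_col].to_numpy(dtype=float)
    if len(np.unique(t)) != 2:
        raise ValueError("treatment must be binary with both groups present")
    X = data[covariates].to_numpy(dtype=float)
    # ridge-regularized propensity model: stable under near/perfect separation
    fit = LogisticRegression(max_iter=1000).fit(X, t)
    ps = np.clip(fit.predict_proba(X)[:, 1], 1e-10, 1 - 1e-10)
    logit_ps = np.log(ps / (1 - ps))
    caliper = caliper_sd * logit_ps.std(ddof=1)

    treated_idx = np.where(t == 1)[0]
    control_idx = list(np.where(t == 0)[0])
    order = treated_idx[np.argsort(-logit_ps[treated_idx], kind="stable")]
    pairs = []
    for ti in order:
        if not control_idx:
            break
        dists = np.abs(logit_ps[control_idx] - logit_ps[ti])
        j = int(np.argmin(dists))
        if dists[j] <= caliper:
            pairs.append((ti, control_idx.pop(j)))
    if not pairs:
        return data.iloc[[]]
    keep = sorted(i for pair in pairs for i in pair)
    return data.iloc[keep]


def standardized_mean_difference(df: pd.DataFrame, treatment_col: str,
                                 covariate: str) -> float:
    """Absolute standardized mean difference of one covariate between groups."""
    t = df[treatment_col].to_numpy(dtype=float)
    x = df[covariate].to_numpy(dtype=float)
    x1, x0 = x[t == 1], x[t == 0]
    pooled = np.sqrt((x1.var(ddof=1) + x0.var(ddof=1)) / 2)
    if pooled == 0:
        return 0.0
    return float(abs(x1.mean() - x0.mean()) / pooled)
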