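"""Product-of-coefficients mediation with bootstrap confidence intervals.

Tests whether the coagulation index CI mediates the association between a TEG
parameter (R or MA) and binary tumor grade: path a is the OLS slope of the
mediator M on the exposure X; paths b and c' are log-odds coefficients from a
logistic regression of the outcome Y on (X, M); the total effect c comes from
regressing Y on X alone.  The indirect effect is a*b, with percentile
bootstrap confidence intervals over patient resampling.

With a logistic outcome, total = direct + indirect does NOT hold exactly
(non-collapsibility of the log-odds scale); the deviation is reported, not
hidden.  A fully linear analogue (``family="linear"``) restores exact
additivity and serves as the internal consistency oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MediationResult",
    "MediationError",
    "fit_mediation",
    "classify_mediation",
    "effect_proportions",
]


class MediationError(RuntimeError):
    """Raised on non-convergent (e.g. separated) component fits."""


@dataclass(frozen=True)
class MediationResult:
    path_a: float
    path_b: float
    total_c: float
    direct_c_prime: float
    indirect: float
    boot_ci: dict  # {"total"|"direct"|"indirect": (lo, hi)}
    proportions: dict  # {"indirect/total", "direct/total"}
    classification: str  # complete | partial | none
    family: str = "logistic"
    n_boot: int = 0
    n_boot_failed: int = 0
    boot_se: dict = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.indirect - self.path_a * self.path_b) > 1e-10 * max(
            1.0, abs(self.indirect)
        ):
            raise ValueError("indirect effect must equal path_a * path_b")
        for lo, hi in self.boot_ci.values():
            if lo > hi:
                raise ValueError("bootstrap CI bounds out of order")

    def to_dict(self) -> dict:
        return {
            "effects": {
                "total": self.total_c,
                "direct": self.direct_c_prime,
                "indirect": self.indirect,
            },
            "paths": {"a": self.path_a, "b": self.path_b},
            "ci_95": {k: list(v) for k, v in self.boot_ci.items()},
            "effect_percentage": dict(self.proportions),
            "classification": self.classification,
            "additivity_gap": self.total_c
            - (self.direct_c_prime + self.indirect),
            "family": self.family,
            "n_boot": self.n_boot,
            "n_boot_failed": self.n_boot_failed,
        }


# ---------------------------------------------------------------------------
# Fast component fits (vectorized; called thousands of times in the bootstrap)
# ---------------------------------------------------------------------------


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def _ols_coefs(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(design, y, rcond=None)[0]


def _logit_irls(design: np.ndarray, y: np.ndarray, max_iter: int = 50,
                tol: float = 1e-8) -> np.ndarray:
    """Newton-Raphson logistic fit; raises MediationError on separation."""
    beta = np.zeros(design.shape[1])
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1 - mu)
        if w.max() < 1e-10:
            raise MediationError("logistic fit degenerate (separation suspected)")
        grad = design.T @ (y - mu)
        hess = (design * w[:, None]).T @ design
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise MediationError("singular logistic information matrix") from exc
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    else:
        raise MediationError("logistic fit did not converge")
    if np.abs(beta).max() > 50:
        raise MediationError("divergent coefficients (perfect separation)")
    return beta


def _fit_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray, family: str):
    """Return (a, b, c, c_prime) for one dataset."""
    ones = np.ones_like(x)
    a = _ols_slope(x, m)
    d_xm = np.column_stack([ones, x, m])
    d_x = np.column_stack([ones, x])
    if family == "logistic":
        beta_xm = _logit_irls(d_xm, y)
        beta_x = _logit_irls(d_x, y)
    else:
        beta_xm = _ols_coefs(d_xm, y)
        beta_x = _ols_coefs(d_x, y)
    c_prime, b = beta_xm[1], beta_xm[2]
    c = beta_x[1]
    return float(a), float(b), float(c), float(c_prime)


# ---------------------------------------------------------------------------
# Public interface
# ---------------------------------------------------------------------------


def effect_proportions(total: float, direct: float, indirect: float) -> dict:
    """Effect-percentage decomposition: indirect/total and direct/total."""
    return {
        "indirect/total": float(indirect / total),
        "direct/total": float(direct / total),
    }


def fit_mediation(X, M, Y, n_boot: int = 2000, seed: int = 0,
                  family: str = "logistic", alpha: float = 0.05,
                  standardize: bool = False) -> MediationResult:
    """Fit the X -> M -> Y product-of-coefficients mediation model.

    Parameters
    ----------
    X, M : continuous exposure and mediator vectors.
    Y : outcome — binary (0/1) for ``family="logistic"``, continuous for
        ``family="linear"``.
    n_boot : percentile-bootstrap replicates (>= 200) over patient resampling.
    seed : bootstrap RNG seed; results are reproducible given (data, n_boot, seed).
    standardize : if True, X and M (and Y when linear) are z-scored first, so
        effects are on the standardized scale.

    Raises ``MediationError`` on non-convergent (separated) logistic fits of
    the point estimates; bootstrap replicates that fail are dropped and
    counted in ``n_boot_failed``.
    """
    x = np.asarray(X, dtype=float)
    m = np.asarray(M, dtype=float)
    y = np.asarray(Y, dtype=float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("X, M, Y must have equal length")
    if family not in ("logistic", "linear"):
        raise ValueError(f"unknown family {family!r}")
    if family == "logistic" and len(np.unique(y)) != 2:
        raise ValueError("logistic outcome must contain both classes")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
        m = (m - m.mean()) / m.std(ddof=1)
        if family == "linear":
            y = (y - y.mean()) / y.std(ddof=1)

    a, b, c, c_prime = _fit_paths(x, m, y, family)
    indirect = a * b

    rng = np.random.default_rng(seed)
    n = len(x)
    boots = {"total": [], "direct": [], "indirect": []}
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if family == "logistic" and len(np.unique(yb)) != 2:
            failed += 1
            continue
        try:
            ab, bb, cb, cpb = _fit_paths(x[idx], m[idx], yb, family)
        except MediationError:
            failed += 1
            continue
        boots["total"].append(cb)
        boots["direct"].append(cpb)
        boots["indirect"].append(ab * bb)

    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    boot_ci, boot_se = {}, {}
    for key, vals in boots.items():
        vals = np.asarray(vals)
        if len(vals) < n_boot // 2:
            raise MediationError("majority of bootstrap replicates failed")
        boot_ci[key] = (float(np.percentile(vals, lo_q)),
                        float(np.percentile(vals, hi_q)))
        boot_se[key] = float(vals.std(ddof=1))

    result = MediationResult(
        path_a=a, path_b=b, total_c=c, direct_c_prime=c_prime,
        indirect=indirect, boot_ci=boot_ci,
        proportions=effect_proportions(c, c_prime, indirect),
        classification="", family=family, n_boot=n_boot,
        n_boot_failed=failed, boot_se=boot_se,
    )
    return MediationResult(
        **{**result.__dict__, "classification": classify_mediation(result)}
    )


def classify_mediation(result: MediationResult) -> str:
    """Complete / partial / no mediation from the bootstrap intervals.

    ``complete``: the indirect CI excludes 0 while the direct CI covers 0 —
    the exposure acts on the outcome only through the mediator.  ``partial``:
    both exclude 0.  ``none`` otherwise.
    """

    def excludes_zero(ci):
        lo, hi = ci
        return lo > 0 or hi < 0

    ind = excludes_zero(result.boot_ci["indirect"])
    direct = excludes_zero(result.boot_ci["direct"])
    if ind and not direct:
        return "complete"
    if ind and direct:
        return "partial"
    return "none"
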