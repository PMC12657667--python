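"""Matching-adjusted indirect comparison: weights, diagnostics, estimator.

MAIC reweights the IPD so that the weighted covariate means equal the
published means of the ALD trial. The weights are trial-assignment odds
assumed log-linear in the matched covariates, ``w_i = exp(alpha' x_i)``;
combining this form with the mean-balancing constraint

    sum_i w_i x_i / sum_i w_i = xbar_ALD

is equivalent to minimizing the convex objective
``Q(alpha) = sum_i exp(alpha' (x_i - xbar_ALD))``, whose gradient vanishes
exactly at mean balance. The anchored estimate contrasts a weighted
logistic regression of outcome on treatment (A vs C in the reweighted IPD)
with the B-vs-C log odds ratio computed from the ALD event counts, and its
variance is estimated by a nonparametric bootstrap over IPD rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .trial_data import ALDSummary, IPDTrial

__all__ = ["MAICWeights", "estimate_weights", "ess", "maic_point_estimate", "maic_estimate"]


@dataclass
class MAICWeights:
    """Estimated assignment-model coefficients and the induced weights."""

    alpha: np.ndarray
    w: np.ndarray
    w_norm: np.ndarray
    ess: float
    converged: bool
    balance_residual: np.ndarray
    message: str = ""
    matched_cols: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return len(self.w)


def ess(w: np.ndarray) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2``.

    Scale-invariant and bounded by ``1 <= ess <= n`` for non-negative,
    not-all-zero weights.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    wmax = float(w.max(initial=0.0))
    if wmax == 0.0:
        raise ValueError("all weights are zero")
    v = w / wmax  # guard against under/overflow of w**2
    return float(np.sum(v)) ** 2 / float(np.sum(v**2))


def _failed(n: int, K: int, message: str) -> MAICWeights:
    return MAICWeights(
        alpha=np.full(K, np.nan),
        w=np.ones(n),
        w_norm=np.full(n, 1.0 / n),
        ess=float(n),
        converged=False,
        balance_residual=np.full(K, np.nan),
        message=message,
    )


def _newton(Zs: np.ndarray, gtol: float, max_iter: int = 60) -> np.ndarray | None:
    """Damped Newton minimization of ``mean(exp(Zs @ a))``.

    The objective is smooth and convex with gradient ``mean(w z)`` and
    Hessian ``mean(w z z')``; a half-step backtracking line search keeps the
    iteration monotone. Returns ``None`` when the step fails numerically
    (caller falls back to a quasi-Newton line search; an infeasible target,
    whose optimum sits at infinity, surfaces there as a balance-residual
    failure)."""
    n, k = Zs.shape
    a = np.zeros(k)
    w = np.ones(n)
    q = 1.0
    for _ in range(max_iter):
        g = (w @ Zs) / n
        if np.max(np.abs(g)) < gtol:
            return a
        H = (Zs * w[:, None]).T @ Zs / n
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(k), -g)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(40):
            a_new = a + lam * step
            eta = Zs @ a_new
            if np.max(eta) < 700:
                w_new = np.exp(eta)
                q_new = float(w_new.mean())
                if np.isfinite(q_new) and q_new <= q + 1e-14:
                    break
            lam *= 0.5
        else:
            return None
        a, w, q = a_new, w_new, q_new
    return None


def estimate_weights(
    X: np.ndarray,
    target_means: np.ndarray,
    tol: float = 1e-6,
    gtol: float = 1e-10,
) -> MAICWeights:
    """Estimate mean-balancing weights by convex optimization.

    Covariates are centered at the target means and standardized before
    optimization (quasi-Newton from ``alpha = 0`` with analytic gradient);
    balance is declared when every standardized weighted-mean residual is
    below ``tol``. A constant column already equal to its target carries no
    information and is dropped with a warning; an infeasible target (outside
    the convex hull of the data) yields ``converged=False`` rather than an
    exception.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    target = np.atleast_1d(np.asarray(target_means, dtype=float))
    n, K = X.shape
    if target.shape != (K,):
        raise ValueError(f"target_means must have length {K}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(target))):
        raise ValueError("non-finite values in X or target_means")

    Z = X - target
    scale = X.std(axis=0, ddof=1) if n > 1 else np.ones(K)
    keep = []
    for j in range(K):
        if scale[j] == 0.0:
            if abs(Z[0, j]) < 1e-12:
                warnings.warn(
                    f"covariate column {j} is constant and equals its target; dropped",
                    stacklevel=2,
                )
                continue
            return _failed(n, K, f"constant column {j} cannot be matched to a different target")
        keep.append(j)
    keep = np.asarray(keep, dtype=int)
    if keep.size == 0:
        # everything already balanced exactly: uniform weights
        out = _failed(n, K, "no informative columns")
        out.converged = True
        out.alpha = np.zeros(K)
        out.balance_residual = np.zeros(K)
        return out

    Zs = Z[:, keep] / scale[keep]

    def objective(a: np.ndarray) -> tuple[float, np.ndarray]:
        eta = np.clip(Zs @ a, -700, 700)
        w = np.exp(eta)
        return float(w.sum()) / n, (w @ Zs) / n

    alpha_s = _newton(Zs, gtol)
    if alpha_s is None:  # fall back to quasi-Newton line search
        try:
            res = optimize.minimize(
                objective,
                np.zeros(keep.size),
                jac=True,
                method="BFGS",
                options={"gtol": gtol, "maxiter": 500},
            )
            alpha_s = res.x
        except (FloatingPointError, np.linalg.LinAlgError) as err:  # pragma: no cover
            return _failed(n, K, f"optimizer error: {err}")

    alpha = np.zeros(K)
    alpha[keep] = alpha_s / scale[keep]
    eta = np.clip(Z @ alpha, -700, 700)
    w = np.exp(eta)
    if not np.all(np.isfinite(w)) or w.sum() == 0.0:
        return _failed(n, K, "weights overflowed or vanished")
    w_norm = w / w.sum()
    residual = w_norm @ X - target
    resid_std = np.abs(residual[keep]) / scale[keep]
    converged = bool(np.all(resid_std < tol) and np.all(np.isfinite(alpha)))
    return MAICWeights(
        alpha=alpha,
        w=w,
        w_norm=w_norm,
        ess=ess(w),
        converged=converged,
        balance_residual=residual,
        message="" if converged else "balance residual above tolerance (target may be infeasible)",
        matched_cols=keep,
    )


def _weighted_log_or(y: np.ndarray, t: np.ndarray, w: np.ndarray) -> float:
    """MLE of the treatment coefficient in a weighted logistic model of y on
    an intercept and t; closed form via the weighted 2x2 table. Returns NaN
    under weighted separation (an empty weighted cell)."""
    a1 = float(w[(t == 1) & (y == 1)].sum())
    b1 = float(w[(t == 1) & (y == 0)].sum())
    a0 = float(w[(t == 0) & (y == 1)].sum())
    b0 = float(w[(t == 0) & (y == 0)].sum())
    if min(a1, b1, a0, b0) <= 0.0:
        return np.nan
    return float(np.log(a1 / b1) - np.log(a0 / b0))


def maic_point_estimate(trial: IPDTrial, weights: MAICWeights, ald: ALDSummary) -> float:
    """Anchored MAIC point estimate ``d_AB = d_AC(weighted) - d_BC(ALD)``.

    Returns ``NaN`` under weighted separation (all weighted events in one
    arm), signalling an invalid estimate to the caller.
    """
    from .marginalization import ald_log_or

    d_ac = _weighted_log_or(trial.y, trial.t, weights.w_norm)
    d_bc, _ = ald_log_or(ald)
    return d_ac - d_bc


def maic_estimate(
    trial: IPDTrial,
    ald: ALDSummary,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    tol: float = 1e-6,
):
    """Classical MAIC with nonparametric-bootstrap standard error.

    Each bootstrap replicate resamples IPD rows with replacement,
    re-estimates the weights against the fixed ALD means and recomputes the
    anchored contrast. Replicates whose weight estimation fails to converge
    (or that are separated) are dropped and counted; if more than half fail
    the SE is flagged unreliable. The whole estimate is invalid when weight
    estimation fails on the full sample.
    """
    from .marginalization import MarginalEstimate

    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng() if rng is None else rng

    weights = estimate_weights(trial.X, ald.cov_means, tol=tol)
    info = {
        "ess": weights.ess,
        "ess_reduction": 1.0 - weights.ess / trial.n,
        "boot_failures": 0,
        "n_boot": n_boot,
        "weights_converged": weights.converged,
    }
    notes: list[str] = []
    if not weights.converged:
        return MarginalEstimate(
            point=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
            draws=None, method="maic", valid=False,
            notes=[f"full-sample weight estimation failed: {weights.message}"], info=info,
        )
    point = maic_point_estimate(trial, weights, ald)
    if not np.isfinite(point):
        return MarginalEstimate(
            point=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
            draws=None, method="maic", valid=False,
            notes=["weighted separation in the full sample"], info=info,
        )

    replicates = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, trial.n, size=trial.n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w_b = estimate_weights(trial.X[idx], ald.cov_means, tol=tol)
        if not w_b.converged:
            failures += 1
            continue
        est_b = _weighted_log_or(trial.y[idx], trial.t[idx], w_b.w_norm)
        if not np.isfinite(est_b):
            failures += 1
            continue
        replicates.append(est_b)
    info["boot_failures"] = failures
    from .marginalization import ald_log_or

    d_bc, _ = ald_log_or(ald)
    draws = np.asarray(replicates) - d_bc
    if len(draws) < 2:
        return MarginalEstimate(
            point=point, se=np.nan, ci_low=np.nan, ci_high=np.nan,
            draws=None, method="maic", valid=False,
            notes=["fewer than 2 successful bootstrap replicates"], info=info,
        )
    se = float(draws.std(ddof=1))
    if failures > n_boot / 2:
        notes.append("more than half of bootstrap replicates failed; SE unreliable")
    return MarginalEstimate(
        point=point,
        se=se,
        ci_low=point - 1.96 * se,
        ci_high=point + 1.96 * se,
        draws=draws,
        method="maic",
        valid=True,
        notes=notes,
        info=info,
    )
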