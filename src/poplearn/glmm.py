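"""Poisson generalized linear mixed model with one random intercept.

Fits ``count ~ X beta + (1 | subject)`` with a log link and Gaussian
random intercepts by Laplace-approximation maximum likelihood — the same
approximation lme4's ``glmer`` uses by default — and returns Wald
z-statistics for the fixed effects.

The implementation is *batched*: many independent problems (e.g. one per
estimate bin × permutation) sharing a common design matrix are fitted
simultaneously with vectorized inner Newton steps for the per-subject
modes and a damped, finite-difference Newton for the outer parameters
(beta, log tau).  This is what makes permutation tests with a GLMM
statistic tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GlmmFit", "fit_poisson_glmm"]

_LT_MIN, _LT_MAX = -6.0, 4.0  # bounds on log tau
_BETA_CLIP = 20.0


@dataclass
class GlmmFit:
    """Batched GLMM fit: arrays are indexed by problem."""

    beta: np.ndarray  # (B, P)
    se: np.ndarray  # (B, P)
    z: np.ndarray  # (B, P)
    log_tau: np.ndarray  # (B,)
    loglik: np.ndarray  # (B,)
    degenerate: np.ndarray  # (B,) bool: all-zero counts, z forced to 0
    boundary_tau: np.ndarray  # (B,) bool: tau at its lower bound (plain-GLM regime)


def _laplace_ll(theta, y, X, bhat, inner: int, update_bhat: bool):
    """Laplace log-likelihood (constants dropped) for a batch of problems.

    theta: (B, P+1) = (beta, log tau); y: (B, S, J); X: (S, J, P);
    bhat: (B, S) per-subject modes, warm-started and optionally updated.
    """
    P = X.shape[-1]
    beta = theta[:, :P]
    lt = np.clip(theta[:, P], _LT_MIN, _LT_MAX)
    tau2 = np.exp(2.0 * lt)[:, None]
    eta = np.einsum("sjp,bp->bsj", X, beta)
    b = bhat if update_bhat else bhat.copy()
    # Inner Newton for the per-subject posterior modes (1-D, concave).
    for _ in range(inner):
        mu = np.exp(eta + b[..., None])
        g = (y - mu).sum(-1) - b / tau2
        h = mu.sum(-1) + 1.0 / tau2
        np.add(b, np.clip(g / h, -3.0, 3.0), out=b)
        np.clip(b, -30.0, 30.0, out=b)
    mu = np.exp(eta + b[..., None])
    ll = (
        (y * (eta + b[..., None]) - mu).sum((-1, -2))
        - (b**2).sum(-1) / (2.0 * tau2[:, 0])
        - 0.5 * np.log(tau2 * mu.sum(-1) + 1.0).sum(-1)
    )
    return ll


def fit_poisson_glmm(
    y: np.ndarray,
    X: np.ndarray,
    max_outer: int = 40,
    tol: float = 1e-5,
) -> GlmmFit:
    """Fit a batch of Poisson random-intercept GLMMs sharing a design.

    Parameters
    ----------
    y : (B, S, J) or (S, J) int array
        Counts per problem × subject × within-subject observation.
    X : (S, J, P) float array
        Fixed-effects design (first column should be the intercept).

    Returns a :class:`GlmmFit` with Wald z for every fixed effect.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        y = y[None]
    B, S, J = y.shape
    X = np.asarray(X, dtype=float)
    if X.shape[:2] != (S, J):
        raise ValueError(f"design shape {X.shape} incompatible with counts {y.shape}")
    if S < 2:
        raise ValueError("a random intercept needs at least 2 subjects")
    P = X.shape[-1]
    D = P + 1

    degenerate = y.sum(axis=(1, 2)) == 0
    if degenerate.all():
        return GlmmFit(
            beta=np.zeros((B, P)),
            se=np.full((B, P), np.nan),
            z=np.zeros((B, P)),
            log_tau=np.full(B, _LT_MIN),
            loglik=np.zeros(B),
            degenerate=degenerate,
            boundary_tau=np.ones(B, dtype=bool),
        )
    if degenerate.any():
        # all-zero problems carry no information; fit the rest and backfill
        keep = ~degenerate
        sub = fit_poisson_glmm(y[keep], X, max_outer=max_outer, tol=tol)
        beta = np.zeros((B, P))
        se = np.full((B, P), np.nan)
        z = np.zeros((B, P))
        log_tau = np.full(B, _LT_MIN)
        loglik = np.zeros(B)
        boundary = np.ones(B, dtype=bool)
        for arr, val in (
            (beta, sub.beta),
            (se, sub.se),
            (z, sub.z),
            (log_tau, sub.log_tau),
            (loglik, sub.loglik),
            (boundary, sub.boundary_tau),
        ):
            arr[keep] = val
        return GlmmFit(
            beta=beta,
            se=se,
            z=z,
            log_tau=log_tau,
            loglik=loglik,
            degenerate=degenerate,
            boundary_tau=boundary,
        )

    theta = np.zeros((B, D))
    theta[:, 0] = np.log(y.mean(axis=(1, 2)) + 0.1)
    theta[:, P] = np.log(0.3)
    bhat = np.zeros((B, S))

    _laplace_ll(theta, y, X, bhat, inner=25, update_bhat=True)

    steps = np.full(D, 1e-4)

    def f(th):
        return _laplace_ll(th, y, X, bhat, inner=3, update_bhat=False)

    ll = _laplace_ll(theta, y, X, bhat, inner=12, update_bhat=True)
    eye = np.eye(D)

    def grad_hess(ll_now):
        grad = np.zeros((B, D))
        H = np.zeros((B, D, D))
        for k in range(D):
            fpk = f(theta + steps[k] * eye[k])
            fmk = f(theta - steps[k] * eye[k])
            grad[:, k] = (fpk - fmk) / (2 * steps[k])
            H[:, k, k] = (fpk - 2 * ll_now + fmk) / steps[k] ** 2
        for k in range(D):
            for l in range(k + 1, D):
                hk, hl = steps[k] * eye[k], steps[l] * eye[l]
                mixed = (
                    f(theta + hk + hl)
                    - f(theta + hk - hl)
                    - f(theta - hk + hl)
                    + f(theta - hk - hl)
                ) / (4 * steps[k] * steps[l])
                H[:, k, l] = mixed
                H[:, l, k] = mixed
        return grad, H

    for _ in range(max_outer):
        grad, H = grad_hess(ll)
        if np.max(np.abs(grad)) < tol * (1.0 + np.max(np.abs(ll))):
            break
        # damped Newton ascent
        A = -H + 1e-8 * eye[None]
        try:
            step = np.linalg.solve(A, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = grad * 1e-2
        bad = ~np.isfinite(step).all(axis=1)
        if bad.any():
            step[bad] = grad[bad] * 1e-2
        np.clip(step, -5.0, 5.0, out=step)
        new_theta = theta + step
        new_ll = _laplace_ll(new_theta, y, X, bhat, inner=5, update_bhat=False)
        for _ in range(6):
            worse = new_ll < ll - 1e-10
            if not worse.any():
                break
            step[worse] *= 0.5
            new_theta = theta + step
            new_ll = _laplace_ll(new_theta, y, X, bhat, inner=5, update_bhat=False)
        improved = new_ll >= ll - 1e-10
        theta[improved] = new_theta[improved]
        np.clip(theta[:, :P], -_BETA_CLIP, _BETA_CLIP, out=theta[:, :P])
        np.clip(theta[:, P], _LT_MIN, _LT_MAX, out=theta[:, P])
        ll = _laplace_ll(theta, y, X, bhat, inner=10, update_bhat=True)

    # observed information at the final parameters
    _, H = grad_hess(ll)

    # observed-information standard errors for the fixed effects
    cov_ok = np.zeros(B, dtype=bool)
    se = np.full((B, P), np.nan)
    Hbb = -H[:, :P, :P]
    for bidx in range(B):
        try:
            c = np.linalg.inv(Hbb[bidx])
            d = np.diag(c)
            if np.all(d > 0):
                se[bidx] = np.sqrt(d)
                cov_ok[bidx] = True
        except np.linalg.LinAlgError:
            pass
    beta = theta[:, :P]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    z[~cov_ok] = 0.0
    z[degenerate] = 0.0
    return GlmmFit(
        beta=beta,
        se=se,
        z=z,
        log_tau=theta[:, P],
        loglik=ll,
        degenerate=degenerate,
        boundary_tau=theta[:, P] <= _LT_MIN + 1e-9,
    )
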