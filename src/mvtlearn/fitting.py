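"""Hierarchical empirical-Bayes fitting and model comparison.

Subjects' parameters are estimated in an unconstrained space (logit-mapped
learning rates, raw betas) by maximum a posteriori under a Gaussian group
prior; the group prior itself is re-estimated by expectation maximisation:

  E-step  per-subject MAP (multistart L-BFGS with analytic gradients) and a
          Laplace approximation of the subject's posterior,
  M-step  closed-form update of the group mean and (diagonal) variance,
          mean_k = mean_i(theta_ik),
          var_k  = mean_i((theta_ik - mean_k)^2 + inv(H_i)_kk).

Model comparison uses subject-level leave-one-out cross-validation: each
subject is scored by the negative log marginal likelihood (Laplace) under the
group prior fitted to everyone else, and per-subject scores are compared
between models with a paired t-test.  The learning-bias contrast tests
alpha_pos - alpha_neg at the group level with a z-statistic whose standard
error comes from the estimated covariance of the group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from . import _kernels
from .analysis import StatResult
from .model import (
    PARAM_NAMES,
    SubjectParams,
    TrialLog,
    initial_rate,
    log_arrays,
    params_from_transformed,
)

__all__ = [
    "FitError",
    "SubjectFit",
    "GroupPosterior",
    "default_prior",
    "map_fit_subject",
    "em_fit",
    "loocv",
    "compare_models",
    "learning_bias_ztest",
]

_HESS_STEP = 1e-4


class FitError(RuntimeError):
    pass


@dataclass
class SubjectFit:
    """One subject's MAP estimate under a group prior."""

    subject_id: str
    model: str
    theta: np.ndarray  # transformed space
    params: SubjectParams  # natural space
    log_posterior: float  # log lik + log prior at the MAP
    log_lik: float
    hessian: np.ndarray  # of the negative log joint, transformed space
    laplace_logml: float
    converged: bool

    @property
    def posterior_cov(self) -> np.ndarray:
        return _safe_inv(self.hessian)


@dataclass
class GroupPosterior:
    """Group-level Gaussian over transformed parameters."""

    model: str
    mean: np.ndarray
    var: np.ndarray  # diagonal of the group covariance
    mean_cov: np.ndarray | None = None  # covariance of the group-mean estimate
    n_subjects: int = 0
    n_iter: int = 0
    converged: bool = True
    mean_history: list = field(default_factory=list)
    logml_history: list = field(default_factory=list)

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.model]

    def mean_params(self) -> SubjectParams:
        return params_from_transformed(self.model, self.mean)


def default_prior(model: str) -> GroupPosterior:
    """Weakly informative starting prior: slow learning, neutral betas."""
    if model == "symmetric":
        mean = np.array([-3.9, 0.0, 0.05])
        var = np.array([9.0, 9.0, 0.04])
    else:
        mean = np.array([-3.9, -3.9, 0.0, 0.05])
        var = np.array([9.0, 9.0, 9.0, 0.04])
    return GroupPosterior(model, mean, var)


def _safe_inv(h: np.ndarray) -> np.ndarray:
    """Inverse of a Hessian, clipping non-positive curvature."""
    h = 0.5 * (h + h.T)
    w, v = np.linalg.eigh(h)
    w = np.clip(w, 1e-8, None)
    return (v / w) @ v.T


def _safe_logdet(h: np.ndarray) -> float:
    h = 0.5 * (h + h.T)
    w = np.linalg.eigvalsh(h)
    return float(np.sum(np.log(np.clip(w, 1e-8, None))))


def _loglik_and_grad(theta, model, arrays, enc_upd, timeout_upd, rho0, order_code):
    """Log-likelihood and gradient in transformed space."""
    choice, r_opt, t_opt, include = arrays
    if model == "symmetric":
        a = expit(theta[0])
        ll, g_ap, g_am, g_b0, g_b1, _ = _kernels.loglik_grad(
            choice, r_opt, t_opt, include, enc_upd, timeout_upd, True,
            a, a, theta[1], theta[2], rho0, order_code,
        )
        grad = np.array([(g_ap + g_am) * a * (1 - a), g_b0, g_b1])
    else:
        ap, am = expit(theta[0]), expit(theta[1])
        ll, g_ap, g_am, g_b0, g_b1, _ = _kernels.loglik_grad(
            choice, r_opt, t_opt, include, enc_upd, timeout_upd, True,
            ap, am, theta[2], theta[3], rho0, order_code,
        )
        grad = np.array([g_ap * ap * (1 - ap), g_am * am * (1 - am), g_b0, g_b1])
    return ll, grad


def _neg_log_joint(theta, model, arrays, enc_upd, timeout_upd, rho0, order_code, mu, var):
    ll, grad = _loglik_and_grad(theta, model, arrays, enc_upd, timeout_upd, rho0, order_code)
    dev = theta - mu
    f = -ll + 0.5 * float(np.sum(dev**2 / var)) + 0.5 * float(
        np.sum(np.log(2 * np.pi * var))
    )
    g = -grad + dev / var
    return f, g


def map_fit_subject(
    log: TrialLog,
    prior: GroupPosterior,
    model: str | None = None,
    restarts: int = 5,
    seed: int | np.random.Generator | None = 0,
    include_forced: bool = False,
    rho0: float | None = None,
    update_during: str = "all",
    update_order: str = "delay_first",
    x0: np.ndarray | None = None,
) -> SubjectFit:
    """MAP estimate of one subject's parameters under the group prior.

    Best of ``restarts`` multistarts (the prior mean, an optional warm start
    ``x0``, and random prior draws), maximising log-likelihood plus log
    Gaussian prior in transformed space.  The Hessian of the negative log
    joint is computed by central finite differences of the analytic gradient
    and feeds the Laplace marginal-likelihood approximation.
    """
    model = model or prior.model
    if model != prior.model:
        raise FitError("prior and requested model disagree")
    mu = np.asarray(prior.mean, dtype=float)
    var = np.asarray(prior.var, dtype=float)
    if np.any(var <= 0):
        raise FitError("prior covariance is not invertible")
    arrays = log_arrays(log, include_forced)
    enc_upd = log.design.encounter_seconds if update_during == "all" else 0
    timeout_upd = log.design.timeout_seconds if update_during == "all" else 0
    if rho0 is None:
        rho0 = log.rho0 if log.rho0 is not None else initial_rate(log.design)
    order_code = 0 if update_order == "delay_first" else 1
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(0 if seed is None else seed)
    )

    starts = [mu.copy()]
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    while len(starts) < max(restarts, 1):
        starts.append(rng.normal(mu, np.sqrt(var)))

    def fun(theta):
        return _neg_log_joint(
            theta, model, arrays, enc_upd, timeout_upd, rho0, order_code, mu, var
        )

    best = None
    n_ok = 0
    for s in starts[: max(restarts, 1) + (1 if x0 is not None else 0)]:
        try:
            res = optimize.minimize(
                fun, s, jac=True, method="L-BFGS-B", options={"maxiter": 500}
            )
        except (FloatingPointError, OverflowError):  # pragma: no cover
            continue
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(
            f"subject {log.subject_id}: all {len(starts)} restarts failed"
        )

    theta = np.asarray(best.x, dtype=float)
    d = len(theta)
    hess = np.empty((d, d))
    for k in range(d):
        step = np.zeros(d)
        step[k] = _HESS_STEP
        _, g_plus = fun(theta + step)
        _, g_minus = fun(theta - step)
        hess[:, k] = (g_plus - g_minus) / (2 * _HESS_STEP)
    hess = 0.5 * (hess + hess.T)

    ll, _ = _loglik_and_grad(theta, model, arrays, enc_upd, timeout_upd, rho0, order_code)
    # log joint without the Gaussian normaliser constant folded into fun
    log_post = -best.fun
    logml = log_post + 0.5 * d * math.log(2 * math.pi) - 0.5 * _safe_logdet(hess)
    return SubjectFit(
        subject_id=log.subject_id,
        model=model,
        theta=theta,
        params=params_from_transformed(model, theta),
        log_posterior=log_post,
        log_lik=float(ll),
        hessian=hess,
        laplace_logml=float(logml),
        converged=bool(best.success),
    )


def em_fit(
    cohort: list[TrialLog],
    model: str,
    tol: float = 1e-3,
    max_iter: int = 200,
    restarts: int = 5,
    seed: int = 0,
    init: GroupPosterior | None = None,
    init_fits: list[SubjectFit] | None = None,
    include_forced: bool = False,
    min_var: float = 1e-4,
) -> tuple[GroupPosterior, list[SubjectFit]]:
    """Empirical-Bayes EM over a cohort.

    Alternates subject-level MAP + Laplace (E-step) with the closed-form
    group mean/variance update (M-step) until the group mean moves less than
    ``tol``.  After the first iteration each subject's fit is warm-started
    from its previous MAP with a single start.  Non-convergence within
    ``max_iter`` returns the best iterate with ``converged=False``.
    """
    if len(cohort) < 2:
        raise FitError("EM needs at least 2 subjects")
    prior = init or default_prior(model)
    prior = GroupPosterior(model, np.array(prior.mean, float), np.array(prior.var, float))
    rng = np.random.default_rng(seed)
    fits: list[SubjectFit] = list(init_fits) if init_fits else None
    history, logml_hist = [], []
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        new_fits = []
        for i, log in enumerate(cohort):
            x0 = fits[i].theta if fits else None
            n_starts = restarts if (it == 0 and fits is None) else 1
            new_fits.append(
                map_fit_subject(
                    log, prior, model, restarts=n_starts, seed=rng,
                    include_forced=include_forced, x0=x0,
                )
            )
        fits = new_fits
        theta = np.stack([f.theta for f in fits])
        covs = np.stack([f.posterior_cov for f in fits])
        mu = theta.mean(axis=0)
        var = np.mean((theta - mu) ** 2 + np.diagonal(covs, axis1=1, axis2=2), axis=0)
        var = np.maximum(var, min_var)
        history.append(mu.copy())
        logml_hist.append(float(sum(f.laplace_logml for f in fits)))
        delta = np.max(np.abs(mu - prior.mean))
        prior = GroupPosterior(model, mu, var)
        if delta < tol:
            converged = True
            break

    n = len(cohort)
    theta = np.stack([f.theta for f in fits])
    dev = theta - prior.mean
    mean_cov = (
        np.einsum("ij,ik->jk", dev, dev) + sum(f.posterior_cov for f in fits)
    ) / n**2
    post = GroupPosterior(
        model,
        prior.mean,
        prior.var,
        mean_cov=mean_cov,
        n_subjects=n,
        n_iter=n_iter,
        converged=converged,
        mean_history=history,
        logml_history=logml_hist,
    )
    return post, fits


def loocv(
    cohort: list[TrialLog],
    model: str,
    restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 100,
    fold_max_iter: int = 10,
    include_forced: bool = False,
) -> np.ndarray:
    """Per-subject negative log marginal likelihood, leave-one-subject-out.

    For each held-out subject the group prior is refit to the remaining
    subjects (EM warm-started from the full-cohort posterior) and the
    held-out subject is scored by the Laplace marginal likelihood of its
    choices under that prior.  Lower scores are better.
    """
    if len(cohort) < 3:
        raise FitError("LOOcv needs at least 3 subjects")
    full_post, full_fits = em_fit(
        cohort, model, tol=tol, max_iter=max_iter, restarts=restarts, seed=seed,
        include_forced=include_forced,
    )
    scores = np.empty(len(cohort))
    for i, log in enumerate(cohort):
        rest = cohort[:i] + cohort[i + 1 :]
        rest_fits = full_fits[:i] + full_fits[i + 1 :]
        try:
            fold_post, _ = em_fit(
                rest, model, tol=tol, max_iter=fold_max_iter, restarts=1,
                seed=seed + 1 + i, init=full_post, init_fits=rest_fits,
                include_forced=include_forced,
            )
            held = map_fit_subject(
                log, fold_post, model, restarts=restarts, seed=seed + 1000 + i,
                include_forced=include_forced, x0=full_fits[i].theta,
            )
        except FitError as err:
            raise FitError(f"LOOcv fold {i} ({log.subject_id}): {err}") from err
        scores[i] = -held.laplace_logml
    return scores


def compare_models(scores_a: np.ndarray, scores_b: np.ndarray) -> StatResult:
    """Paired two-tailed t-test on per-subject scores (A minus B)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be paired (same subjects)")
    d = a - b
    n = len(d)
    if np.allclose(d.std(ddof=1), 0.0):
        same = bool(np.allclose(d.mean(), 0.0))
        return StatResult(
            "LOOcv A vs B", "t", 0.0 if same else math.inf, n - 1,
            1.0 if same else 0.0, degenerate=True, note="zero variance of differences",
        )
    res = stats.ttest_rel(a, b)
    se = d.std(ddof=1) / math.sqrt(n)
    half = float(stats.t.ppf(0.975, n - 1)) * se
    return StatResult(
        "LOOcv A vs B", "t", float(res.statistic), n - 1, float(res.pvalue),
        ci=(float(d.mean() - half), float(d.mean() + half)),
    )


def learning_bias_ztest(group: GroupPosterior) -> StatResult:
    """Group-level z-test of the learning bias alpha_pos - alpha_neg.

    The contrast is evaluated in the transformed (logit) analysis space,
    where the group distribution is Gaussian; its standard error uses the
    full estimated covariance of the group means.  The sign agrees with the
    natural-space difference because the logit is monotone.
    """
    if group.model != "asymmetric":
        raise FitError("learning-bias contrast requires the asymmetric model")
    if group.mean_cov is None:
        raise FitError("group posterior lacks a mean covariance (run em_fit)")
    c = np.zeros(len(group.mean))
    c[0], c[1] = 1.0, -1.0
    se2 = float(c @ group.mean_cov @ c)
    if not np.isfinite(se2) or se2 <= 0:
        raise FitError("singular covariance for the learning-bias contrast")
    z = float((group.mean[0] - group.mean[1]) / math.sqrt(se2))
    p = 2 * float(stats.norm.sf(abs(z)))
    return StatResult("alpha_pos - alpha_neg", "z", z, math.inf, p)
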