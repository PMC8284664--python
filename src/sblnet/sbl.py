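"""Sequential Bayesian learning over blocks of trials.

Learning is offline: after each block of trials the parameter posterior is
updated by (i) finding the maximum-a-posteriori parameter vector by
gradient ascent on the log joint (Bernoulli block likelihood plus
factorised Gaussian prior), with the step length chosen each iteration by
bounded scalar minimisation and a step-ceiling halving fallback, and
(ii) a fully factorised Laplace approximation in which each parameter's
posterior precision is the prior precision plus the diagonal of the
outer-product (Gauss-Newton) Hessian of the block likelihood.  The
posterior then becomes the prior for the next block or task (elastic
weight consolidation).

MAP optimisation is restarted from fresh prior samples (multistart) until
the average trial likelihood -- exp(log likelihood / n trials), the mean
per-trial probability of the observed feedback -- reaches the threshold
``pc_T``, or the start budget is exhausted, in which case the best
log-joint solution is kept and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .network import (
    NetworkParams,
    NetworkSpec,
    forward,
    layout,
    n_params,
    sensitivities,
    unpack,
)
from .task_env import TrialBlock

__all__ = [
    "FactorisedGaussian",
    "OptimiserConfig",
    "FitResult",
    "init_prior",
    "block_values",
    "block_log_likelihood",
    "avg_trial_likelihood",
    "log_prior",
    "log_prior_grad",
    "log_joint",
    "map_estimate",
    "laplace_precision_update",
    "transfer_prior",
    "linear_gaussian_sbl",
]

_V_EPS = 1e-12  # clamp for values before taking logs


@dataclass
class FactorisedGaussian:
    """Independent Gaussian over each packed parameter (means, precisions)."""

    m: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.m.shape != self.lam.shape:
            raise ValueError("mean and precision vectors must have equal length")
        if np.any(self.lam <= 0):
            raise ValueError("precisions must be strictly positive")

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.m + rng.standard_normal(self.m.size) / np.sqrt(self.lam)

    def copy(self) -> "FactorisedGaussian":
        return FactorisedGaussian(self.m.copy(), self.lam.copy())


@dataclass(frozen=True)
class OptimiserConfig:
    """MAP optimiser settings (defaults are the study's settings)."""

    tol: float = 1e-3          # relative log-joint change declaring convergence
    max_iter: int = 64
    pc_threshold: float = 0.60  # average-trial-likelihood restart criterion
    maxstarts: int = 3
    step_max: float = 1.0       # line-search upper bound on the step length
    max_halvings: int = 3

    def __post_init__(self) -> None:
        if not 0.5 < self.pc_threshold < 1.0:
            raise ValueError("pc_threshold must lie in (0.5, 1)")
        if min(self.tol, self.maxstarts, self.step_max) <= 0:
            raise ValueError("optimiser settings must be positive")
        if self.max_iter < 0:  # 0 = return the prior sample untouched
            raise ValueError("max_iter must be non-negative")


@dataclass
class FitResult:
    theta: np.ndarray
    log_joint: float
    avg_trial_likelihood: float
    n_starts_used: int
    n_iterations: int
    reached_threshold: bool
    trace: list[tuple[int, float, float]] | None = None  # (iteration, J, step)


def init_prior(spec: NetworkSpec) -> FactorisedGaussian:
    """Zero-mean prior; weight precision = fan-in of the destination unit.

    Units with more inputs therefore start with smaller weights
    (std 1/sqrt(fan-in)); biases have unit precision.
    """
    lam = np.ones(n_params(spec))
    fan_in = {"W1": spec.d, "W2": spec.h1, "w_out": spec.h2}
    for seg in layout(spec):
        if seg.name in fan_in:
            lam[seg.start : seg.stop] = fan_in[seg.name]
    return FactorisedGaussian(np.zeros(n_params(spec)), lam)


def block_values(params: NetworkParams, block: TrialBlock) -> np.ndarray:
    """Per-trial value of the chosen action, v_tk (task-aware)."""
    v1 = np.empty(len(block))
    U = block.stimuli
    for task in np.unique(block.task):
        mask = block.task == task
        v1[mask] = forward(params, U[mask], int(task))["v1"]
    return np.where(block.decision == 1, v1, 1.0 - v1)


def block_log_likelihood(params: NetworkParams, block: TrialBlock) -> float:
    """Sum over trials of r log v_k + (1 - r) log(1 - v_k)."""
    vk = block_values(params, block)
    if np.any(vk <= _V_EPS) or np.any(vk >= 1.0 - _V_EPS):
        warnings.warn("saturated trial values clamped before log", RuntimeWarning)
    vk = np.clip(vk, _V_EPS, 1.0 - _V_EPS)
    r = block.reward
    return float(np.sum(r * np.log(vk) + (1 - r) * np.log(1.0 - vk)))


def avg_trial_likelihood(params: NetworkParams, block: TrialBlock) -> float:
    """exp(log likelihood / n): mean per-trial probability of the feedback."""
    return float(np.exp(block_log_likelihood(params, block) / len(block)))


def log_prior(theta: np.ndarray, prior: FactorisedGaussian) -> float:
    d = theta - prior.m
    return float(
        -0.5 * theta.size * np.log(2.0 * np.pi)
        + 0.5 * np.sum(np.log(prior.lam) - prior.lam * d * d)
    )


def log_prior_grad(theta: np.ndarray, prior: FactorisedGaussian) -> np.ndarray:
    return -prior.lam * (theta - prior.m)


def _likelihood_and_grad(
    params: NetworkParams, block: TrialBlock
) -> tuple[float, np.ndarray]:
    U = block.stimuli
    total = 0.0
    grad = np.zeros(n_params(params.spec))
    for task in np.unique(block.task):
        mask = block.task == task
        cache = forward(params, U[mask], int(task))
        v1 = cache["v1"]
        d = block.decision[mask]
        r = block.reward[mask]
        vk = np.where(d == 1, v1, 1.0 - v1)
        vc = np.clip(vk, _V_EPS, 1.0 - _V_EPS)
        total += float(np.sum(r * np.log(vc) + (1 - r) * np.log(1.0 - vc)))
        eta = sensitivities(params, U[mask], int(task), cache)
        coeff = np.where(d == 1, 1.0, -1.0) * (r - vk)
        grad += eta.T @ coeff
    return total, grad


def log_joint(
    theta: np.ndarray, block: TrialBlock, prior: FactorisedGaussian, spec: NetworkSpec
) -> tuple[float, np.ndarray]:
    """Log joint J = block log likelihood + log prior, with its gradient."""
    params = unpack(theta, spec)
    loglik, grad_lik = _likelihood_and_grad(params, block)
    return loglik + log_prior(theta, prior), grad_lik + log_prior_grad(theta, prior)


def _ascend(
    theta0, objective, config: OptimiserConfig, trace: list | None = None
) -> tuple[np.ndarray, float, int]:
    """Gradient ascent with per-iteration bounded line search.

    ``objective(theta)`` returns (J, dJ/dtheta).  Each iteration the step
    length is chosen by bounded scalar minimisation of -J along the
    gradient; if that fails to improve J the step ceiling is halved up to
    ``max_halvings`` times before the iteration loop terminates.
    Convergence is declared when the log-joint improvement falls below
    ``tol`` relative to the log-joint scale, |dJ| / (|J| + 1) < tol.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    J, g = objective(theta)
    for it in range(1, config.max_iter + 1):
        gnorm = np.linalg.norm(g)
        if gnorm == 0.0:
            return theta, J, it - 1
        # search along the unit gradient so the step length (and hence the
        # parameter displacement) is what the (0, step_max] bound limits;
        # this keeps -J close to unimodal on the search interval
        direction = g / gnorm
        step_max = config.step_max
        improved = False
        for _ in range(config.max_halvings + 1):
            res = minimize_scalar(
                lambda a: -objective(theta + a * direction)[0],
                bounds=(0.0, step_max),
                method="bounded",
                options={"xatol": 1e-4},
            )
            if -res.fun > J:
                improved = True
                break
            step_max *= 0.5
        if not improved:
            return theta, J, it - 1
        theta = theta + res.x * direction
        J_new, g = objective(theta)
        delta = abs(J_new - J)
        J = J_new
        if trace is not None:
            trace.append((it, J, float(res.x)))
        if delta / (abs(J) + 1.0) < config.tol:
            return theta, J, it
    return theta, J, config.max_iter


def map_estimate(
    block: TrialBlock,
    prior: FactorisedGaussian,
    config: OptimiserConfig,
    rng: np.random.Generator,
    spec: NetworkSpec,
    keep_trace: bool = False,
) -> FitResult:
    """Multistart MAP estimation of theta for one block of trials.

    Each start samples its initialisation from the prior.  Starts repeat
    until the solution's average trial likelihood reaches ``pc_threshold``
    or ``maxstarts`` is exhausted; the start with the highest average trial
    likelihood -- the same score the restart criterion applies -- is
    returned.  (Selecting on the log joint instead would systematically
    prefer the degenerate prior-mode solution, whose prior density
    outweighs its chance-level fit.)
    """

    def objective(theta):
        return log_joint(theta, block, prior, spec)

    best: FitResult | None = None
    for start in range(1, config.maxstarts + 1):
        theta0 = prior.sample(rng)
        J0, _ = objective(theta0)
        if not np.isfinite(J0):
            continue  # degenerate start counts against the budget
        trace: list | None = [] if keep_trace else None
        theta, J, n_iter = _ascend(theta0, objective, config, trace)
        atl = avg_trial_likelihood(unpack(theta, spec), block)
        result = FitResult(
            theta=theta,
            log_joint=J,
            avg_trial_likelihood=atl,
            n_starts_used=start,
            n_iterations=n_iter,
            reached_threshold=atl >= config.pc_threshold,
            trace=trace,
        )
        if best is None or result.avg_trial_likelihood > best.avg_trial_likelihood:
            best = result
        best.n_starts_used = start
        if atl >= config.pc_threshold:
            break
    if best is None:
        raise RuntimeError("all optimisation starts produced non-finite objectives")
    return best


def trace_to_frame(fit: FitResult):
    """Fit trace as a table (iteration, log_joint, step), CSV-ready."""
    import pandas as pd

    if fit.trace is None:
        raise ValueError("fit was run without keep_trace=True")
    return pd.DataFrame(fit.trace, columns=["iteration", "log_joint", "step"])


def laplace_precision_update(
    prior_lam: np.ndarray, params: NetworkParams, block: TrialBlock | None
) -> np.ndarray:
    """Posterior precisions: prior + sum_t v_tk (1 - v_tk) eta_t^2.

    The increment is the diagonal of the outer-product approximation to the
    negative block-likelihood Hessian, evaluated at the MAP parameters.
    Only the current block's trials contribute; with no trials the
    precisions are unchanged.
    """
    lam = np.asarray(prior_lam, dtype=float).copy()
    if block is None or len(block) == 0:
        return lam
    U = block.stimuli
    for task in np.unique(block.task):
        mask = block.task == task
        cache = forward(params, U[mask], int(task))
        eta = sensitivities(params, U[mask], int(task), cache)
        w = cache["v1"] * (1.0 - cache["v1"])  # v_k(1 - v_k), invariant to k
        lam += (w[:, None] * eta**2).sum(axis=0)
    return lam


def transfer_prior(
    posterior: FactorisedGaussian,
    old_spec: NetworkSpec,
    new_spec: NetworkSpec,
    reduced_precision: bool = False,
) -> FactorisedGaussian:
    """Prior for a grown network: carry the old posterior over shared segments.

    Segments present in ``old_spec`` keep their posterior mean and
    precision (precision reset to the initial prior's value in the
    reduced-precision ablation); segments new to ``new_spec`` receive
    initial-prior statistics.
    """
    fresh = init_prior(new_spec)
    init_old = init_prior(old_spec)
    old_segs = {seg.key: seg for seg in layout(old_spec)}
    m, lam = fresh.m.copy(), fresh.lam.copy()
    for seg in layout(new_spec):
        if seg.key not in old_segs:
            continue
        src = old_segs[seg.key]
        if src.shape != seg.shape:
            raise ValueError(f"segment {seg.key} changed shape during growth")
        m[seg.start : seg.stop] = posterior.m[src.start : src.stop]
        lam[seg.start : seg.stop] = (
            init_old.lam[src.start : src.stop]
            if reduced_precision
            else posterior.lam[src.start : src.stop]
        )
    return FactorisedGaussian(m, lam)


def linear_gaussian_sbl(
    x: np.ndarray,
    y: np.ndarray,
    n_blocks: int,
    prior: FactorisedGaussian,
    noise_precision: float = 1.0,
    config: OptimiserConfig | None = None,
) -> FactorisedGaussian:
    """Block-sequential Bayesian estimation of a 1-D Gaussian regression.

    Runs y = theta * x + noise through the same ascend-then-update cycle as
    the network engine: per block, the MAP of the Gaussian log joint is
    found by the shared line-search ascent and the precision update adds
    the (here exact) likelihood curvature tau * sum x^2.  For this
    conjugate model the result matches single-batch Bayesian regression,
    which is the independent check applied in the test suite.
    """
    config = config or OptimiserConfig(tol=1e-12, max_iter=200)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    post = prior.copy()
    for xb, yb in zip(np.array_split(x, n_blocks), np.array_split(y, n_blocks)):

        def objective(theta, xb=xb, yb=yb, pr=post):
            resid = yb - theta[0] * xb
            J = (
                -0.5 * noise_precision * np.sum(resid**2)
                + log_prior(theta, pr)
            )
            g = noise_precision * np.sum(resid * xb) + log_prior_grad(theta, pr)[0]
            return J, np.array([g])

        theta_map, _, _ = _ascend(post.m.copy(), objective, config)
        lam_new = post.lam + noise_precision * np.sum(xb**2)
        post = FactorisedGaussian(theta_map, lam_new)
    return post
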