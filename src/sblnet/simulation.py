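"""In-silico versions of the two-task transfer experiment.

Two protocols are implemented.  *Over tasks*: each task's 100 trials form
a single block; Task 1 is learnt from the initial prior, the Laplace
posterior becomes the Task 2 prior for the shared parameters of the grown
network, and each task is scored by the average trial likelihood of its
training data at the MAP solution.  *Over blocks*: 250 trials per task
arrive in 25-trial blocks; each block is scored by the current network
before being trained on (test-then-train), and the posterior chains across
blocks and across the task boundary.  Model variants: ``minimal`` (one
shared hidden unit), ``increased`` (two), and ``reduced_precision``
(minimal, but Task-1 posterior precisions are reset to their initial
values before Task 2 -- an ablation of consolidation).

Batches of 40 independent runs per condition mirror the 40 subjects per
experimental Task 1/Task 2 pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkSpec, grow_spec, unpack
from .sbl import (
    FactorisedGaussian,
    OptimiserConfig,
    avg_trial_likelihood,
    init_prior,
    laplace_precision_update,
    map_estimate,
    transfer_prior,
)
from .task_env import (
    Condition,
    RewardMap,
    TrialBlock,
    make_condition,
    reward_map,
    STIMULUS_GRID,
)
from . import network

__all__ = [
    "RunConfig",
    "SimulationResult",
    "sample_decision",
    "make_dataset",
    "run_over_tasks",
    "run_over_blocks",
    "run_batch",
    "maxstarts_sweep",
    "config_text",
]

VARIANTS = ("minimal", "increased", "reduced_precision")
MODES = ("over_tasks", "over_blocks")


@dataclass(frozen=True)
class RunConfig:
    """Protocol settings; defaults reproduce the study's simulations."""

    mode: str = "over_tasks"
    variant: str = "minimal"
    n_trials_per_task: int | None = None  # 100 over tasks, 250 over blocks
    block_size: int = 25
    n_sims: int = 40
    optimiser: OptimiserConfig = field(default_factory=OptimiserConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_trials_per_task is None:
            object.__setattr__(
                self, "n_trials_per_task", 100 if self.mode == "over_tasks" else 250
            )
        if self.mode == "over_blocks" and self.n_trials_per_task % self.block_size:
            raise ValueError("block_size must divide n_trials_per_task")

    @property
    def h1(self) -> int:
        return 2 if self.variant == "increased" else 1

    @property
    def reduced_precision(self) -> bool:
        return self.variant == "reduced_precision"


@dataclass
class SimulationResult:
    task1_accuracy: float
    task2_accuracy: float
    precision_ratio: float      # mean posterior/prior precision of W1 after Task 1
    flagged: bool               # some fit never reached the pc_T threshold
    curve: np.ndarray | None = None  # over-blocks: 10 accuracies per 50 trials
    block_scores: np.ndarray | None = None  # over-blocks: raw 25-trial scores


def sample_decision(values: tuple[float, float], rng: np.random.Generator) -> int:
    """Bernoulli action selection: P(k=1) = v1."""
    v1, v2 = values
    if abs(v1 + v2 - 1.0) > 1e-9:
        raise ValueError("action values must sum to one")
    return 1 if rng.random() < v1 else 2


def make_dataset(
    rmap: RewardMap,
    task_index: int,
    n_trials: int,
    decision_params: network.NetworkParams,
    rng: np.random.Generator,
    block_index: int = 1,
) -> TrialBlock:
    """Sample a block whose decisions come from a value network.

    Cues are uniform over the grid; decisions are Bernoulli draws from the
    network's values; the reward is 1 iff the sampled outcome matches the
    decision.
    """
    idx = rng.integers(0, len(STIMULUS_GRID), size=n_trials)
    cues = STIMULUS_GRID[idx]
    U = np.column_stack([cues, np.full(n_trials, 6.0)])
    v1 = network.forward(decision_params, U, task_index)["v1"]
    decision = np.where(rng.random(n_trials) < v1, 1, 2)
    outcome = rng.random(n_trials) < rmap.probabilities(cues)
    reward = ((decision == 1) == outcome).astype(int)
    return TrialBlock(
        u1=cues[:, 0],
        u2=cues[:, 1],
        task=np.full(n_trials, task_index),
        decision=decision,
        reward=reward,
        block_index=block_index,
    )


def _w1_ratio(lam_post: np.ndarray, lam_prior: np.ndarray, spec: NetworkSpec) -> float:
    seg = next(s for s in network.layout(spec) if s.name == "W1")
    return float(
        np.mean(lam_post[seg.start : seg.stop] / lam_prior[seg.start : seg.stop])
    )


def run_over_tasks(
    condition: Condition, config: RunConfig, rng: np.random.Generator
) -> SimulationResult:
    """One simulated subject under the single-block-per-task protocol."""
    if config.mode != "over_tasks":
        raise ValueError("config.mode must be 'over_tasks'")
    n = config.n_trials_per_task
    spec1 = NetworkSpec(h1=config.h1, n_tasks=1)
    prior1 = init_prior(spec1)

    # Task 1: data from a prior-sampled (untrained, highly stochastic) net
    dec_params1 = unpack(prior1.sample(rng), spec1)
    block1 = make_dataset(condition.task1_map, 1, n, dec_params1, rng)
    fit1 = map_estimate(block1, prior1, config.optimiser, rng, spec1)
    lam_post1 = laplace_precision_update(prior1.lam, unpack(fit1.theta, spec1), block1)
    posterior1 = FactorisedGaussian(fit1.theta, lam_post1)
    ratio = _w1_ratio(lam_post1, prior1.lam, spec1)

    # grow the network and transfer the posterior as the Task 2 prior
    spec2 = grow_spec(spec1)
    prior2 = transfer_prior(
        posterior1, spec1, spec2, reduced_precision=config.reduced_precision
    )
    dec_params2 = unpack(init_prior(spec2).sample(rng), spec2)
    block2 = make_dataset(condition.task2_map, 2, n, dec_params2, rng)
    fit2 = map_estimate(block2, prior2, config.optimiser, rng, spec2)

    return SimulationResult(
        task1_accuracy=fit1.avg_trial_likelihood,
        task2_accuracy=fit2.avg_trial_likelihood,
        precision_ratio=ratio,
        flagged=not (fit1.reached_threshold and fit2.reached_threshold),
    )


def run_over_blocks(
    condition: Condition, config: RunConfig, rng: np.random.Generator
) -> SimulationResult:
    """One simulated subject under the blockwise test-then-train protocol."""
    if config.mode != "over_blocks":
        raise ValueError("config.mode must be 'over_blocks'")
    blocks_per_task = config.n_trials_per_task // config.block_size
    spec = NetworkSpec(h1=config.h1, n_tasks=1)
    prior = init_prior(spec)
    init_lam_w1 = prior.lam.copy()
    params = unpack(prior.m.copy(), spec)  # prior-mean network: at chance
    scores: list[float] = []
    flagged = False
    ratio = np.nan

    for j in range(2 * blocks_per_task):
        task = 1 if j < blocks_per_task else 2
        if j == blocks_per_task:  # task boundary: grow and transfer
            old_spec = spec
            spec = grow_spec(spec)
            prior = transfer_prior(
                prior, old_spec, spec, reduced_precision=config.reduced_precision
            )
            params = unpack(prior.m.copy(), spec)
        rmap = condition.task1_map if task == 1 else condition.task2_map
        block = make_dataset(rmap, task, config.block_size, params, rng, block_index=j + 1)
        scores.append(avg_trial_likelihood(params, block))  # test before train
        fit = map_estimate(block, prior, config.optimiser, rng, spec)
        flagged |= not fit.reached_threshold
        params = unpack(fit.theta, spec)
        lam_post = laplace_precision_update(prior.lam, params, block)
        prior = FactorisedGaussian(fit.theta, lam_post)
        if j == blocks_per_task - 1:
            ratio = _w1_ratio(lam_post, init_lam_w1, spec)

    scores_arr = np.asarray(scores)
    curve = scores_arr.reshape(-1, 2).mean(axis=1)  # neighbouring 25-trial blocks
    return SimulationResult(
        task1_accuracy=float(scores_arr[:blocks_per_task].mean()),
        task2_accuracy=float(scores_arr[blocks_per_task:].mean()),
        precision_ratio=ratio,
        flagged=flagged,
        curve=curve,
        block_scores=scores_arr,
    )


def _run_one(
    condition: Condition, config: RunConfig, rng: np.random.Generator
) -> SimulationResult:
    runner = run_over_tasks if config.mode == "over_tasks" else run_over_blocks
    return runner(condition, config, rng)


def run_batch(
    conditions: list[Condition] | list[int],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """``n_sims`` independent runs per condition.

    Returns a per-run results table and, in over-blocks mode, a long-format
    learning-curve table (one row per run and 50-trial curve point).  Run
    seeds are spawned deterministically from ``config.seed``.
    """
    conditions = [c if isinstance(c, Condition) else make_condition(c) for c in conditions]
    root = np.random.SeedSequence(config.seed)
    rows, curve_rows = [], []
    for cond in conditions:
        # per-condition child streams keyed by the design row, so adding or
        # reordering conditions leaves individual runs unchanged
        cond_seq = np.random.SeedSequence(entropy=root.entropy, spawn_key=(cond.row,))
        for run, child in enumerate(cond_seq.spawn(config.n_sims), start=1):
            rng = np.random.default_rng(child)
            result = _run_one(cond, config, rng)
            rows.append(
                {
                    "run": run,
                    "condition": cond.row,
                    "task1_map": cond.task1_map.map_id,
                    "task2_map": cond.task2_map.map_id,
                    "relation": cond.subspace_relation,
                    "variant": config.variant,
                    "mode": config.mode,
                    "task1_acc": result.task1_accuracy,
                    "task2_acc": result.task2_accuracy,
                    "precision_ratio": result.precision_ratio,
                    "flagged": result.flagged,
                }
            )
            if result.curve is not None:
                for point, acc in enumerate(result.curve, start=1):
                    curve_rows.append(
                        {
                            "run": run,
                            "condition": cond.row,
                            "relation": cond.subspace_relation,
                            "block": point,
                            "accuracy": acc,
                        }
                    )
    results = pd.DataFrame(rows)
    curves = pd.DataFrame(curve_rows) if curve_rows else None
    return results, curves


def maxstarts_sweep(
    maxstarts_values: list[int],
    task1_map_ids: list[str] = ("Sub1",),
    n_sims: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean Task-1 accuracy as a function of the multistart budget.

    Only Task 1 is fitted (the sweep is about escaping local maxima of the
    first fit).  Returns one row per maxstarts value with the mean
    accuracy over ``n_sims`` runs per Task-1 map.
    """
    spec = NetworkSpec(h1=1, n_tasks=1)
    rows = []
    for ms in maxstarts_values:
        config = OptimiserConfig(maxstarts=ms)
        accs = []
        root = np.random.SeedSequence(entropy=seed, spawn_key=(ms,))
        for map_id in task1_map_ids:
            rmap = reward_map(map_id)
            for child in root.spawn(n_sims):
                rng = np.random.default_rng(child)
                prior = init_prior(spec)
                dec = unpack(prior.sample(rng), spec)
                block = make_dataset(rmap, 1, 100, dec, rng)
                fit = map_estimate(block, prior, config, rng, spec)
                accs.append(fit.avg_trial_likelihood)
        rows.append({"maxstarts": ms, "task1_acc_mean": float(np.mean(accs)), "n": len(accs)})
    return pd.DataFrame(rows)


def config_text(config: RunConfig) -> str:
    """key=value echo of every run and optimiser setting."""
    opt = config.optimiser
    pairs = {
        "mode": config.mode,
        "variant": config.variant,
        "n_trials_per_task": config.n_trials_per_task,
        "block_size": config.block_size,
        "n_sims": config.n_sims,
        "seed": config.seed,
        "h1": config.h1,
        "optimiser.tol": opt.tol,
        "optimiser.max_iter": opt.max_iter,
        "optimiser.pc_threshold": opt.pc_threshold,
        "optimiser.maxstarts": opt.maxstarts,
        "optimiser.step_max": opt.step_max,
        "optimiser.max_halvings": opt.max_halvings,
    }
    return "\n".join(f"{k} = {v}" for k, v in pairs.items()) + "\n"
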