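"""Synthetic task environment for two-pie probabilistic category learning.

The stimulus on every trial is a pair of pie charts showing ``u1`` and
``u2`` filled slices (each 1-5 out of a full pie of 6), giving a 5x5 grid
of 25 equiprobable cue configurations.  A binary outcome (sun/rain in the
weather task, heads/tails in the coin task) is drawn from one of four
stimulus-reward maps, and the agent's reward is 1 iff its prediction
matches the realised outcome.

Two maps are *log-quadratic* (``Sub1``, ``Add1``): the log-odds of the
outcome are a quadratic form in the stimulus whose ridge lies along a
linear subspace of the input -- the difference ``u1 - u2`` for Sub1
(outcome most likely when the pies show equal slices) or the sum
``u1 + u2 - 6`` for Add1 (most likely when the slices make a full pie).
Two maps are *log-linear* (``Sub2``, ``Add2``), depending on the same two
subspace features through a linear log-odds with a half-step offset, so
that the approximate rules are strict inequalities ("more slices on the
left", "sum greater than six").  The quadratic maps support a 95% ceiling
accuracy under the argmax policy; the linear maps are calibrated
numerically to a 93% ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "FULL_PIE",
    "STIMULUS_GRID",
    "Stimulus",
    "RewardMap",
    "TrialBlock",
    "Condition",
    "reward_map",
    "reward_probability",
    "best_possible_accuracy",
    "generate_trials",
    "make_condition",
    "map_config_text",
]

FULL_PIE = 6
_SLICES = np.arange(1, 6)

#: all 25 (u1, u2) cue configurations, row-major over the 5x5 grid
STIMULUS_GRID = np.array([(a, b) for a in _SLICES for b in _SLICES], dtype=int)

# quadratic map constants: log-odds = (u - mu)' W (u - mu) + w0 with
# W = 2.4 * [[-0.71, wd], [wd, -0.71]].  The off-diagonal sign selects the
# subspace: wd = +0.71 collapses the form onto (u1 - u2)^2 (Sub), while
# wd = -0.71 collapses it onto (u1 + u2 - 6)^2 (Add).
_QUAD_DIAG = -0.71
_QUAD_SCALE = 2.4
_QUAD_MU = np.array([3.0, 3.0])
_QUAD_W0 = 4.0
_LINEAR_CEILING = 0.93
_LINEAR_OFFSET = 0.5


def augment(u: np.ndarray) -> np.ndarray:
    """Append the constant third input u3 = 6 (slices per full pie).

    Accepts an (n, 2) array of cue configurations and returns (n, 3).
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    return np.column_stack([u, np.full(len(u), float(FULL_PIE))])


@dataclass(frozen=True)
class Stimulus:
    """A single two-pie cue; ``u3`` is the constant pie size."""

    u1: int
    u2: int

    def __post_init__(self) -> None:
        if not (1 <= self.u1 <= 5 and 1 <= self.u2 <= 5):
            raise ValueError(f"slice counts must be in 1..5, got {self}")

    @property
    def u3(self) -> int:
        return FULL_PIE

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.u1, self.u2, self.u3], dtype=float)


@dataclass(frozen=True)
class RewardMap:
    """A stimulus -> outcome-probability function with its subspace label."""

    map_id: str
    family: str            # "log-quadratic" | "log-linear"
    subspace: str          # "Sub" | "Add"
    quad_wd: float | None = None
    lin_beta: float | None = None

    def log_odds(self, u: np.ndarray) -> np.ndarray:
        """Log-odds of outcome 1 for an (n, 2) array of cues."""
        u = np.atleast_2d(np.asarray(u, dtype=float))
        if self.family == "log-quadratic":
            W = _QUAD_SCALE * np.array(
                [[_QUAD_DIAG, self.quad_wd], [self.quad_wd, _QUAD_DIAG]]
            )
            x = u - _QUAD_MU
            return np.einsum("ni,ij,nj->n", x, W, x) + _QUAD_W0
        if self.family == "log-linear":
            feat = u[:, 0] - u[:, 1] if self.subspace == "Sub" else u.sum(axis=1) - FULL_PIE
            return self.lin_beta * (feat - _LINEAR_OFFSET)
        raise ValueError(f"unknown reward-map family {self.family!r}")

    def probabilities(self, u: np.ndarray) -> np.ndarray:
        return expit(self.log_odds(u))

    @property
    def grid_probabilities(self) -> np.ndarray:
        """Outcome probabilities over the 25-configuration grid."""
        return self.probabilities(STIMULUS_GRID)


def _calibrate_linear_beta(subspace: str) -> float:
    """Slope beta such that the argmax-policy ceiling is exactly 93%."""
    grid = STIMULUS_GRID.astype(float)
    feat = grid[:, 0] - grid[:, 1] if subspace == "Sub" else grid.sum(axis=1) - FULL_PIE

    def ceiling(beta: float) -> float:
        p = expit(beta * (feat - _LINEAR_OFFSET))
        return float(np.maximum(p, 1.0 - p).mean())

    return brentq(lambda b: ceiling(b) - _LINEAR_CEILING, 0.05, 20.0, xtol=1e-12)


def _build_maps() -> dict[str, RewardMap]:
    return {
        "Sub1": RewardMap("Sub1", "log-quadratic", "Sub", quad_wd=+0.71),
        "Add1": RewardMap("Add1", "log-quadratic", "Add", quad_wd=-0.71),
        "Sub2": RewardMap("Sub2", "log-linear", "Sub", lin_beta=_calibrate_linear_beta("Sub")),
        "Add2": RewardMap("Add2", "log-linear", "Add", lin_beta=_calibrate_linear_beta("Add")),
    }


_MAPS = _build_maps()


def reward_map(map_id: str) -> RewardMap:
    """Return one of the four calibrated maps: Sub1, Add1, Sub2, Add2."""
    try:
        return _MAPS[map_id]
    except KeyError:
        raise ValueError(f"unknown reward map {map_id!r}; expected one of {sorted(_MAPS)}")


def reward_probability(rmap: RewardMap | str, u: Stimulus | tuple[int, int]) -> float:
    """Probability that outcome 1 (sun / heads) occurs for cue ``u``."""
    if isinstance(rmap, str):
        rmap = reward_map(rmap)
    if not isinstance(u, Stimulus):
        u = Stimulus(*u)
    return float(rmap.probabilities(np.array([[u.u1, u.u2]]))[0])


def best_possible_accuracy(rmap: RewardMap | str) -> float:
    """Ceiling accuracy (percent) of the argmax policy, averaged over the grid."""
    if isinstance(rmap, str):
        rmap = reward_map(rmap)
    p = rmap.grid_probabilities
    return float(100.0 * np.maximum(p, 1.0 - p).mean())


@dataclass
class TrialBlock:
    """A buffer of trials: cues, task labels, decisions and rewards."""

    u1: np.ndarray
    u2: np.ndarray
    task: np.ndarray       # task index n in {1, 2}
    decision: np.ndarray   # decision k in {1, 2}; k=1 predicts outcome 1
    reward: np.ndarray     # 1 iff the prediction was correct
    block_index: int = 1

    def __post_init__(self) -> None:
        for name in ("u1", "u2", "task", "decision", "reward"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        n = len(self.u1)
        if n == 0:
            raise ValueError("a trial block must contain at least one trial")
        if not all(len(getattr(self, f)) == n for f in ("u2", "task", "decision", "reward")):
            raise ValueError("trial-block fields must have equal length")
        if not np.isin(self.decision, (1, 2)).all():
            raise ValueError("decisions must be 1 or 2")
        if not np.isin(self.reward, (0, 1)).all():
            raise ValueError("rewards must be 0 or 1")
        if not np.isin(self.task, (1, 2)).all():
            raise ValueError("task labels must be 1 or 2")

    def __len__(self) -> int:
        return len(self.u1)

    @property
    def stimuli(self) -> np.ndarray:
        """(n, 3) augmented input matrix [u1, u2, 6]."""
        return augment(np.column_stack([self.u1, self.u2]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "block": self.block_index,
                "task": self.task,
                "u1": self.u1,
                "u2": self.u2,
                "decision": self.decision,
                "reward": self.reward,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialBlock":
        block_index = int(frame["block"].iloc[0]) if "block" in frame else 1
        return cls(
            u1=frame["u1"].to_numpy(),
            u2=frame["u2"].to_numpy(),
            task=frame["task"].to_numpy(),
            decision=frame["decision"].to_numpy(),
            reward=frame["reward"].to_numpy(),
            block_index=block_index,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialBlock":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def concatenate(cls, blocks: Sequence["TrialBlock"]) -> "TrialBlock":
        return cls(
            u1=np.concatenate([b.u1 for b in blocks]),
            u2=np.concatenate([b.u2 for b in blocks]),
            task=np.concatenate([b.task for b in blocks]),
            decision=np.concatenate([b.decision for b in blocks]),
            reward=np.concatenate([b.reward for b in blocks]),
            block_index=blocks[0].block_index,
        )


DecisionPolicy = Callable[[np.ndarray, np.random.Generator], np.ndarray]


def _resolve_policy(rmap: RewardMap, policy) -> DecisionPolicy:
    if callable(policy):
        return policy
    if policy == "random":
        return lambda u, rng: rng.integers(1, 3, size=len(u))
    if policy == "argmax":
        # choose decision 1 whenever outcome 1 is the more likely one
        return lambda u, rng: np.where(rmap.probabilities(u) >= 0.5, 1, 2)
    raise ValueError(f"unknown decision policy {policy!r}")


def generate_trials(
    rmap: RewardMap | str,
    task_index: int,
    n_trials: int,
    policy: DecisionPolicy | str = "random",
    rng: np.random.Generator | int | None = None,
    block_index: int = 1,
) -> TrialBlock:
    """Sample a block of trials under ``rmap``.

    Cues are uniform over the 25 configurations.  The binary outcome is
    drawn once per trial from the map's probability; the recorded reward
    is 1 iff the policy's decision predicted the realised outcome.
    """
    if isinstance(rmap, str):
        rmap = reward_map(rmap)
    if task_index not in (1, 2):
        raise ValueError(f"task index must be 1 or 2, got {task_index}")
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, len(STIMULUS_GRID), size=n_trials)
    cues = STIMULUS_GRID[idx]
    p = rmap.probabilities(cues)
    outcome = rng.random(n_trials) < p
    decision = np.asarray(_resolve_policy(rmap, policy)(cues, rng))
    reward = ((decision == 1) == outcome).astype(int)
    return TrialBlock(
        u1=cues[:, 0],
        u2=cues[:, 1],
        task=np.full(n_trials, task_index),
        decision=decision,
        reward=reward,
        block_index=block_index,
    )


@dataclass(frozen=True)
class Condition:
    """One row of the between-subject design: a Task 1 / Task 2 map pairing."""

    row: int
    task1_map: RewardMap
    task2_map: RewardMap

    @property
    def subspace_relation(self) -> str:
        return "same" if self.task1_map.subspace == self.task2_map.subspace else "different"


_CONDITION_ROWS = {
    1: ("Add1", "Add2"),
    2: ("Sub1", "Sub2"),
    3: ("Add1", "Sub2"),
    4: ("Sub1", "Add2"),
}


def make_condition(row: int) -> Condition:
    """Condition rows 1-4: (Add1,Add2), (Sub1,Sub2), (Add1,Sub2), (Sub1,Add2)."""
    if row not in _CONDITION_ROWS:
        raise ValueError(f"condition row must be in 1..4, got {row}")
    t1, t2 = _CONDITION_ROWS[row]
    return Condition(row=row, task1_map=reward_map(t1), task2_map=reward_map(t2))


def map_config_text() -> str:
    """Plain-text key=value echo of the four calibrated map definitions."""
    lines = []
    for rmap in _MAPS.values():
        prefix = f"map.{rmap.map_id}"
        lines.append(f"{prefix}.family = {rmap.family}")
        lines.append(f"{prefix}.subspace = {rmap.subspace}")
        if rmap.family == "log-quadratic":
            lines.append(f"{prefix}.w_diag = {_QUAD_SCALE * _QUAD_DIAG:.4f}")
            lines.append(f"{prefix}.w_offdiag = {_QUAD_SCALE * rmap.quad_wd:.4f}")
            lines.append(f"{prefix}.mu = 3,3")
            lines.append(f"{prefix}.w0 = {_QUAD_W0}")
        else:
            lines.append(f"{prefix}.beta = {rmap.lin_beta:.6f}")
            lines.append(f"{prefix}.offset = {_LINEAR_OFFSET}")
        lines.append(f"{prefix}.ceiling_pct = {best_possible_accuracy(rmap):.2f}")
    return "\n".join(lines) + "\n"
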