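"""Multitask value network with a shared first hidden layer.

The network maps a 3-vector stimulus ``u = [u1, u2, 6]`` through a linear
first hidden layer (the representational bottleneck whose weights define
the learnt subspace), then through a per-task subnetwork of H = 4 second
layer units, to a single pre-sigmoid output ``a``.  The two action values
are ``v1 = sigmoid(a)`` and ``v2 = 1 - v1``: the probability that the
outcome associated with each button is the one that will occur.

Task 1 subnetworks use GELU second-layer activations (the log-quadratic
maps are nonlinear in the subspace feature); task 2 subnetworks are linear.
All parameters live in a flat vector via ``pack``/``unpack`` whose segment
order is: vec(W1), vec(W2) per task, output weights per task, b1, b2 per
task, output bias per task.  Gradients of the pre-sigmoid output with
respect to every parameter (the "output sensitivity" eta) are computed by
reverse accumulation and are the building block of both the likelihood
gradient and the diagonal outer-product Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .task_env import Stimulus, augment

__all__ = [
    "NetworkSpec",
    "NetworkParams",
    "Segment",
    "layout",
    "n_params",
    "pack",
    "unpack",
    "grow_spec",
    "activation",
    "activation_deriv",
    "forward_value",
    "forward",
    "output_sensitivity",
    "sensitivities",
    "sample_loglik_gradient",
    "params_to_frame",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def activation(kind: str, x):
    """Apply a named activation: 'linear' or 'gelu' (x * Phi(x), exact CDF)."""
    x = np.asarray(x, dtype=float)
    if kind == "linear":
        return x
    if kind == "gelu":
        return x * ndtr(x)
    raise ValueError(f"unknown activation {kind!r}")


def activation_deriv(kind: str, x):
    x = np.asarray(x, dtype=float)
    if kind == "linear":
        return np.ones_like(x)
    if kind == "gelu":
        return ndtr(x) + x * np.exp(-0.5 * x * x) / _SQRT_2PI
    raise ValueError(f"unknown activation {kind!r}")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture: input size D=3, H1 shared units, 4 units per subnetwork."""

    h1: int
    n_tasks: int = 1
    d: int = 3
    h2: int = 4

    def __post_init__(self) -> None:
        if self.h1 < 1 or self.n_tasks < 1:
            raise ValueError("h1 and n_tasks must be positive")

    def act2(self, task: int) -> str:
        """Second-layer activation: GELU for task 1, linear thereafter."""
        self._check_task(task)
        return "gelu" if task == 1 else "linear"

    def _check_task(self, task: int) -> None:
        if not 1 <= task <= self.n_tasks:
            raise ValueError(f"task {task} not in 1..{self.n_tasks}")

    @property
    def tasks(self) -> range:
        return range(1, self.n_tasks + 1)


@dataclass(frozen=True)
class Segment:
    """One named slice of the packed parameter vector."""

    name: str          # "W1", "W2", "w_out", "b1", "b2", "b_out"
    task: int | None   # None for shared parameters
    shape: tuple[int, ...]
    start: int
    stop: int

    @property
    def key(self) -> tuple[str, int | None]:
        return (self.name, self.task)

    @property
    def size(self) -> int:
        return self.stop - self.start


def layout(spec: NetworkSpec) -> list[Segment]:
    """Packed-vector segment table: weights first, then biases."""
    entries: list[tuple[str, int | None, tuple[int, ...]]] = [("W1", None, (spec.h1, spec.d))]
    entries += [("W2", n, (spec.h2, spec.h1)) for n in spec.tasks]
    entries += [("w_out", n, (spec.h2,)) for n in spec.tasks]
    entries += [("b1", None, (spec.h1,))]
    entries += [("b2", n, (spec.h2,)) for n in spec.tasks]
    entries += [("b_out", n, ()) for n in spec.tasks]
    segments, start = [], 0
    for name, task, shape in entries:
        size = int(np.prod(shape)) if shape else 1
        segments.append(Segment(name, task, shape, start, start + size))
        start += size
    return segments


def n_params(spec: NetworkSpec) -> int:
    return layout(spec)[-1].stop


def grow_spec(spec: NetworkSpec, n_tasks: int | None = None) -> NetworkSpec:
    """Extend the architecture with an additional output subnetwork."""
    target = spec.n_tasks + 1 if n_tasks is None else n_tasks
    if target < spec.n_tasks:
        raise ValueError("cannot shrink the number of tasks")
    return replace(spec, n_tasks=target)


@dataclass
class NetworkParams:
    """Structured weights and biases; per-task lists are 0-indexed by task-1."""

    spec: NetworkSpec
    W1: np.ndarray
    b1: np.ndarray
    W2: list[np.ndarray]
    b2: list[np.ndarray]
    w_out: list[np.ndarray]
    b_out: list[float]

    @classmethod
    def zeros(cls, spec: NetworkSpec) -> "NetworkParams":
        return cls(
            spec=spec,
            W1=np.zeros((spec.h1, spec.d)),
            b1=np.zeros(spec.h1),
            W2=[np.zeros((spec.h2, spec.h1)) for _ in spec.tasks],
            b2=[np.zeros(spec.h2) for _ in spec.tasks],
            w_out=[np.zeros(spec.h2) for _ in spec.tasks],
            b_out=[0.0 for _ in spec.tasks],
        )

    def _segment_value(self, seg: Segment) -> np.ndarray:
        if seg.name == "W1":
            return self.W1
        if seg.name == "b1":
            return self.b1
        idx = seg.task - 1
        return {"W2": self.W2, "b2": self.b2, "w_out": self.w_out, "b_out": self.b_out}[
            seg.name
        ][idx]

    def check_shapes(self) -> None:
        for seg in layout(self.spec):
            value = np.asarray(self._segment_value(seg), dtype=float)
            if value.shape != seg.shape:
                raise ValueError(
                    f"segment {seg.key} has shape {value.shape}, expected {seg.shape}"
                )


def pack(params: NetworkParams) -> np.ndarray:
    """Flatten structured parameters into the canonical vector (row-major vec)."""
    params.check_shapes()
    theta = np.empty(n_params(params.spec))
    for seg in layout(params.spec):
        theta[seg.start : seg.stop] = np.ravel(params._segment_value(seg))
    return theta


def unpack(theta: np.ndarray, spec: NetworkSpec) -> NetworkParams:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_params(spec),):
        raise ValueError(f"theta has length {theta.size}, expected {n_params(spec)}")
    params = NetworkParams.zeros(spec)
    for seg in layout(spec):
        value = theta[seg.start : seg.stop].reshape(seg.shape)
        if seg.name == "W1":
            params.W1 = value
        elif seg.name == "b1":
            params.b1 = value
        elif seg.name == "b_out":
            params.b_out[seg.task - 1] = float(value)
        else:
            getattr(params, seg.name)[seg.task - 1] = value
    return params


def forward(params: NetworkParams, U: np.ndarray, task: int) -> dict[str, np.ndarray]:
    """Vectorised forward pass over an (n, 3) input matrix.

    Returns the intermediate quantities needed by the backward pass:
    first-layer outputs ``x1``, second-layer pre-activations ``a2`` and
    outputs ``x2``, the pre-sigmoid output ``a`` and value ``v1``.
    """
    spec = params.spec
    spec._check_task(task)
    U = np.atleast_2d(np.asarray(U, dtype=float))
    i = task - 1
    x1 = U @ params.W1.T + params.b1           # linear first layer
    a2 = x1 @ params.W2[i].T + params.b2[i]
    x2 = activation(spec.act2(task), a2)
    a = x2 @ params.w_out[i] + params.b_out[i]
    return {"x1": x1, "a2": a2, "x2": x2, "a": a, "v1": expit(a)}


def forward_value(
    params: NetworkParams, u: Stimulus | np.ndarray, task: int
) -> tuple[float, float]:
    """Value pair (v1, v2) for a single stimulus; v1 + v2 = 1."""
    U = u.vector[None, :] if isinstance(u, Stimulus) else augment(np.asarray(u)[:2][None, :])
    v1 = float(forward(params, U, task)["v1"][0])
    return v1, 1.0 - v1


def sensitivities(
    params: NetworkParams, U: np.ndarray, task: int, cache: dict | None = None
) -> np.ndarray:
    """Output sensitivities eta = d a / d theta, one row per input.

    Entries in segments private to other tasks are zero.
    """
    spec = params.spec
    if cache is None:
        cache = forward(params, U, task)
    U = np.atleast_2d(np.asarray(U, dtype=float))
    n = len(U)
    i = task - 1
    eta = np.zeros((n, n_params(spec)))
    delta2 = activation_deriv(spec.act2(task), cache["a2"]) * params.w_out[i]  # (n, h2)
    delta1 = delta2 @ params.W2[i]                                            # (n, h1)
    for seg in layout(spec):
        if seg.task is not None and seg.task != task:
            continue
        if seg.name == "W1":
            block = delta1[:, :, None] * U[:, None, :]
        elif seg.name == "b1":
            block = delta1
        elif seg.name == "W2":
            block = delta2[:, :, None] * cache["x1"][:, None, :]
        elif seg.name == "b2":
            block = delta2
        elif seg.name == "w_out":
            block = cache["x2"]
        else:  # b_out
            block = np.ones((n, 1))
        eta[:, seg.start : seg.stop] = block.reshape(n, -1)
    return eta


def output_sensitivity(
    params: NetworkParams, u: Stimulus | np.ndarray, task: int
) -> np.ndarray:
    """Sensitivity vector for a single stimulus."""
    U = u.vector[None, :] if isinstance(u, Stimulus) else augment(np.asarray(u)[:2][None, :])
    return sensitivities(params, U, task)[0]


def sample_loglik_gradient(
    params: NetworkParams, u: Stimulus | np.ndarray, task: int, decision: int, reward: int
) -> np.ndarray:
    """Gradient of one trial's Bernoulli log likelihood w.r.t. theta.

    L = r log v_k + (1 - r) log(1 - v_k) with v_1 = sigmoid(a) and
    v_2 = 1 - v_1; differentiating through the sigmoid gives
    g = +/-(r - v_k) * eta, the sign set by which button was pressed.
    """
    if decision not in (1, 2):
        raise ValueError("decision must be 1 or 2")
    U = u.vector[None, :] if isinstance(u, Stimulus) else augment(np.asarray(u)[:2][None, :])
    cache = forward(params, U, task)
    eta = sensitivities(params, U, task, cache)[0]
    v1 = cache["v1"][0]
    vk = v1 if decision == 1 else 1.0 - v1
    sign = 1.0 if decision == 1 else -1.0
    return sign * (reward - vk) * eta


def params_to_frame(params: NetworkParams, values: np.ndarray | None = None) -> pd.DataFrame:
    """One row per packed entry: (segment, task, index, value)."""
    theta = pack(params) if values is None else np.asarray(values, dtype=float)
    rows = []
    for seg in layout(params.spec):
        for j in range(seg.size):
            rows.append(
                {
                    "segment": seg.name,
                    "task": 0 if seg.task is None else seg.task,
                    "index": j,
                    "value": theta[seg.start + j],
                }
            )
    return pd.DataFrame(rows)
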