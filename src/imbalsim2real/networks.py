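"""Small fully connected networks with hand-written backprop.

All function approximators in this package are 5x20 multilayer perceptrons:
generators and the stiffness self-sensing net use ReLU hidden activations
with a linear scalar output; discriminators use LeakyReLU and an *unbounded*
linear output score (least-squares adversarial objective — no sigmoid).

Parameters live in one flat float64 vector (`theta`); weight matrices and
bias vectors are reshaped views into it, so an optimizer step is a handful
of vectorized operations.  Gradients are accumulated into a caller-provided
flat buffer with the same layout, which lets several backward passes through
the same network (e.g. adversarial + cycle terms) share one buffer.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

from . import _kernels

HIDDEN = (20, 20, 20, 20, 20)


class MLP:
    """Fully connected net, flat parameter vector, explicit backprop."""

    def __init__(
        self,
        input_dim: int,
        hidden: Sequence[int] = HIDDEN,
        activation: str = "relu",
        negative_slope: float = 0.01,
        seed: int = 0,
    ):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if activation not in ("relu", "leaky_relu"):
            raise ValueError(f"unknown activation {activation!r}")
        self.input_dim = int(input_dim)
        self.dims = (self.input_dim, *hidden, 1)
        self.activation = activation
        self.negative_slope = float(negative_slope)
        self.seed = int(seed)

        pairs = list(zip(self.dims[:-1], self.dims[1:]))
        self.n_params = sum(i * o + o for i, o in pairs)
        self.theta = np.empty(self.n_params)
        self._w_slices: list[tuple[slice, tuple[int, int]]] = []
        self._b_slices: list[slice] = []
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        off = 0
        for i, o in pairs:
            ws = slice(off, off + i * o)
            off += i * o
            bs = slice(off, off + o)
            off += o
            self._w_slices.append((ws, (i, o)))
            self._b_slices.append(bs)
            self.W.append(self.theta[ws].reshape(i, o))
            self.b.append(self.theta[bs])
        self._dims_arr = np.asarray(self.dims, dtype=np.int64)
        self._act_kind = _kernels.RELU if activation == "relu" else _kernels.LEAKY
        self._dummy_buf = np.zeros(1)
        self._init_params()

    def _init_params(self) -> None:
        # uniform fan-in initialization: U(-1/sqrt(fan_in), 1/sqrt(fan_in))
        rng = np.random.default_rng(self.seed)
        for (ws, (i, o)), bs in zip(self._w_slices, self._b_slices):
            k = 1.0 / np.sqrt(i)
            self.theta[ws] = rng.uniform(-k, k, i * o)
            self.theta[bs] = rng.uniform(-k, k, o)

    # -- forward / backward --------------------------------------------
    def forward(self, X: np.ndarray, need_cache: bool = False):
        """Forward pass on an (n, input_dim) batch; returns (n, 1) output.

        With ``need_cache`` also returns the activation cache needed for
        :meth:`backward`.
        """
        A = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        if A.ndim == 1:
            A = A[None, :]
        acts = np.empty((A.shape[0], sum(self.dims[1:])))
        _kernels.forward(
            self.theta, A, self._dims_arr, self._act_kind, self.negative_slope, acts
        )
        out = acts[:, -1:].copy()
        if need_cache:
            return out, (A, acts)
        return out

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def backward(
        self,
        cache,
        grad_out: np.ndarray,
        grad_buf: np.ndarray | None = None,
    ) -> np.ndarray:
        """Backpropagate ``grad_out`` (dL/doutput, shape (n, 1)).

        Accumulates (+=) parameter gradients into ``grad_buf`` when given
        (flat, same layout as ``theta``) and returns the gradient with
        respect to the input batch.  Stateless: a cache may be replayed.
        """
        X, acts = cache
        g = np.ascontiguousarray(np.asarray(grad_out, dtype=np.float64))
        if g.ndim == 1:
            g = g[:, None]
        want = grad_buf is not None
        buf = grad_buf if want else self._dummy_buf
        return _kernels.backward(
            self.theta, X, acts, g, self._dims_arr, self._act_kind,
            self.negative_slope, buf, want,
        )

    def zero_grad_buffer(self) -> np.ndarray:
        return np.zeros(self.n_params)

    # -- persistence ----------------------------------------------------
    def state_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "hidden": list(self.dims[1:-1]),
            "activation": self.activation,
            "negative_slope": self.negative_slope,
            "seed": self.seed,
            "theta": self.theta.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.state_dict(), fh)

    @classmethod
    def from_state_dict(cls, state: dict) -> "MLP":
        net = cls(
            state["input_dim"],
            hidden=tuple(state["hidden"]),
            activation=state["activation"],
            negative_slope=state["negative_slope"],
            seed=state.get("seed", 0),
        )
        theta = np.asarray(state["theta"], dtype=float)
        if theta.shape != net.theta.shape:
            raise ValueError("checkpoint parameter count mismatch")
        net.theta[:] = theta
        return net

    @classmethod
    def load(cls, path) -> "MLP":
        with open(path, encoding="utf-8") as fh:
            return cls.from_state_dict(json.load(fh))


class Adam:
    """Adam optimizer over one flat parameter vector."""

    def __init__(
        self,
        n_params: int,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        self.m *= b1
        self.m += (1.0 - b1) * grad
        self.v *= b2
        self.v += (1.0 - b2) * grad * grad
        m_hat = self.m / (1.0 - b1**self.t)
        v_hat = self.v / (1.0 - b2**self.t)
        theta -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ----------------------------------------------------------------------
# Builders
# ----------------------------------------------------------------------

def build_generator(input_dim: int, seed: int = 0) -> MLP:
    """Generator: (covariates, response) -> response.  5x20 ReLU, linear out."""
    return MLP(input_dim, HIDDEN, activation="relu", seed=seed)


def build_discriminator(
    input_dim: int, seed: int = 0, negative_slope: float = 0.01
) -> MLP:
    """Least-squares critic: unbounded linear score, LeakyReLU hidden layers."""
    return MLP(
        input_dim, HIDDEN, activation="leaky_relu", negative_slope=negative_slope, seed=seed
    )


def build_self_sensing_net(seed: int = 0) -> MLP:
    """Stiffness self-sensing net: (pressure, angle) -> stiffness."""
    return MLP(2, HIDDEN, activation="relu", seed=seed)
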