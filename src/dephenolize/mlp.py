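"""Three-layer perceptron: tanh hidden layer, linear output.

On the standardized scale the network computes

    f(x) = b_o + sum_k w_ho[k] * tanh(b_h[k] + sum_i w_ih[k, i] * x[i])

The parameter vector layout used by the trainer (pack/unpack) is
[w_ih (row-major), b_h, w_ho, b_o].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MLPParams", "mlp_forward", "mlp_jacobian"]


@dataclass
class MLPParams:
    w_ih: np.ndarray  # (n_hidden, n_in) input -> hidden weights
    b_h: np.ndarray   # (n_hidden,)      hidden biases
    w_ho: np.ndarray  # (n_hidden,)      hidden -> output weights
    b_o: float        # output bias

    def __post_init__(self) -> None:
        self.w_ih = np.asarray(self.w_ih, dtype=float)
        self.b_h = np.asarray(self.b_h, dtype=float)
        self.w_ho = np.asarray(self.w_ho, dtype=float)
        self.b_o = float(self.b_o)
        nh = self.w_ih.shape[0]
        if self.w_ih.ndim != 2 or self.b_h.shape != (nh,) or self.w_ho.shape != (nh,):
            raise ValueError("inconsistent MLP parameter shapes")
        for arr in (self.w_ih, self.b_h, self.w_ho, np.array([self.b_o])):
            if not np.all(np.isfinite(arr)):
                raise ValueError("MLP parameters must be finite")

    @property
    def n_hidden(self) -> int:
        return self.w_ih.shape[0]

    @property
    def n_in(self) -> int:
        return self.w_ih.shape[1]

    @property
    def n_params(self) -> int:
        return self.n_hidden * (self.n_in + 2) + 1

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.w_ih.ravel(), self.b_h, self.w_ho, [self.b_o]]
        )

    @classmethod
    def unpack(cls, theta: np.ndarray, n_hidden: int, n_in: int = 3) -> "MLPParams":
        theta = np.asarray(theta, dtype=float)
        expected = n_hidden * (n_in + 2) + 1
        if theta.shape != (expected,):
            raise ValueError(f"expected {expected} parameters, got {theta.shape}")
        k = n_hidden * n_in
        return cls(
            w_ih=theta[:k].reshape(n_hidden, n_in),
            b_h=theta[k : k + n_hidden],
            w_ho=theta[k + n_hidden : k + 2 * n_hidden],
            b_o=theta[-1],
        )

    @classmethod
    def init_random(
        cls, n_hidden: int, rng: np.random.Generator, n_in: int = 3, span: float = 0.5
    ) -> "MLPParams":
        """Uniform(-span, span) initialization of all weights and biases."""
        n = n_hidden * (n_in + 2) + 1
        return cls.unpack(rng.uniform(-span, span, size=n), n_hidden, n_in)

    def to_dict(self) -> dict:
        return {
            "n_hidden": self.n_hidden,
            "n_in": self.n_in,
            "w_ih": self.w_ih.tolist(),
            "b_h": self.b_h.tolist(),
            "w_ho": self.w_ho.tolist(),
            "b_o": self.b_o,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPParams":
        return cls(w_ih=d["w_ih"], b_h=d["b_h"], w_ho=d["w_ho"], b_o=d["b_o"])


def mlp_forward(params: MLPParams, x: np.ndarray) -> np.ndarray | float:
    """Network output for one standardized input or an (n, n_in) batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != params.n_in:
        raise ValueError(f"expected {params.n_in} inputs, got {x.shape[1]}")
    h = np.tanh(x @ params.w_ih.T + params.b_h)
    y = h @ params.w_ho + params.b_o
    return float(y[0]) if single else y


def mlp_jacobian(params: MLPParams, x: np.ndarray) -> np.ndarray:
    """(n, n_params) Jacobian of the network output w.r.t. the packed parameters.

    Column order matches :meth:`MLPParams.pack`.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n, nh, nin = x.shape[0], params.n_hidden, params.n_in
    a = x @ params.w_ih.T + params.b_h          # (n, nh) pre-activations
    h = np.tanh(a)
    dh = 1.0 - h**2                             # tanh'
    j = np.empty((n, params.n_params))
    # d f / d w_ih[k, i] = w_ho[k] * tanh'(a_k) * x_i
    jw = (params.w_ho * dh)[:, :, None] * x[:, None, :]  # (n, nh, nin)
    j[:, : nh * nin] = jw.reshape(n, nh * nin)
    j[:, nh * nin : nh * nin + nh] = params.w_ho * dh     # d f / d b_h
    j[:, nh * nin + nh : nh * nin + 2 * nh] = h           # d f / d w_ho
    j[:, -1] = 1.0                                        # d f / d b_o
    return j
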