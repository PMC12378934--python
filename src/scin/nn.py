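"""Modality encoders: a two-linear-layer MLP with batch-norm, ReLU and
row-wise L2 output normalization, plus the Adam optimizer that trains it.

Architecture per encoder: ``Linear(input -> hidden) -> BatchNorm -> ReLU ->
Linear(hidden -> latent) -> L2-normalize``.  The nonlinearity sits between the
two linear maps so embeddings can occupy the whole unit sphere — a ReLU after
the last layer would confine them to the nonnegative orthant and cripple
cosine contrast.  Batch-norm uses batch statistics during training and running
averages at evaluation time, so held-out cells are embedded deterministically
and independently of one another.

Forward and backward passes are explicit NumPy; the gradient of each stage is
the textbook expression and is verified against finite differences in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class EncoderSpec:
    """Shape of one encoder. Both encoders share ``latent_dim``."""

    input_dim: int
    hidden_dim: int = 256
    latent_dim: int = 128
    use_batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass
class EmbeddingSet:
    """Unit-norm d-dimensional embeddings for one modality's cells."""

    vectors: np.ndarray
    cell_ids: np.ndarray
    cell_types: np.ndarray
    modality_name: str = "modality"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-5):
            raise ValueError("embedding rows must be unit-norm within 1e-5")

    @property
    def n_cells(self) -> int:
        return self.vectors.shape[0]

    def subset(self, indices) -> "EmbeddingSet":
        indices = np.asarray(indices)
        return EmbeddingSet(self.vectors[indices], self.cell_ids[indices],
                            self.cell_types[indices], self.modality_name)


def _l2_normalize(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    return Z / norms, norms


class Encoder:
    """One modality's encoder with explicit forward/backward passes."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        d_in, d_h, d_out = spec.input_dim, spec.hidden_dim, spec.latent_dim
        # He initialization for the ReLU hidden layer
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_h)),
            "b1": np.zeros(d_h),
            "gamma": np.ones(d_h),
            "beta": np.zeros(d_h),
            "W2": rng.normal(0.0, np.sqrt(2.0 / d_h), size=(d_h, d_out)),
            "b2": np.zeros(d_out),
        }
        self.running_mean = np.zeros(d_h)
        self.running_var = np.ones(d_h)
        self._cache: dict | None = None

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected input of width {self.spec.input_dim}, got {X.shape}")
        p = self.params
        Z1 = X @ p["W1"] + p["b1"]
        if self.spec.use_batch_norm:
            if training:
                if X.shape[0] < 2:
                    raise ValueError(
                        "batch-norm needs a training batch of >= 2 cells; "
                        "use a larger batch or evaluation mode")
                mu = Z1.mean(axis=0)
                var = Z1.var(axis=0)
                self.running_mean = ((1 - _BN_MOMENTUM) * self.running_mean
                                     + _BN_MOMENTUM * mu)
                self.running_var = ((1 - _BN_MOMENTUM) * self.running_var
                                    + _BN_MOMENTUM * var)
            else:
                mu, var = self.running_mean, self.running_var
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            Xhat = (Z1 - mu) * inv_std
            BN = p["gamma"] * Xhat + p["beta"]
        else:
            Xhat, inv_std = Z1, None
            BN = Z1
        H = np.maximum(BN, 0.0)
        Z2 = H @ p["W2"] + p["b2"]
        E, norms = _l2_normalize(Z2)
        if training:
            self._cache = {"X": X, "Xhat": Xhat, "inv_std": inv_std,
                           "BN": BN, "H": H, "E": E, "norms": norms}
        return E

    def backward(self, dE: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of all parameters given dLoss/dEmbedding (training batch)."""
        if self._cache is None:
            raise RuntimeError("backward requires a preceding training forward")
        c, p = self._cache, self.params
        E, norms = c["E"], c["norms"]
        # through row-wise L2 normalization: z = e/||e||
        dZ2 = (dE - E * np.sum(dE * E, axis=1, keepdims=True)) / norms
        grads = {"W2": c["H"].T @ dZ2, "b2": dZ2.sum(axis=0)}
        dH = dZ2 @ p["W2"].T
        dBN = dH * (c["BN"] > 0)
        if self.spec.use_batch_norm:
            m = dBN.shape[0]
            grads["gamma"] = np.sum(dBN * c["Xhat"], axis=0)
            grads["beta"] = dBN.sum(axis=0)
            dXhat = dBN * p["gamma"]
            dZ1 = (c["inv_std"] / m) * (
                m * dXhat - dXhat.sum(axis=0)
                - c["Xhat"] * np.sum(dXhat * c["Xhat"], axis=0))
        else:
            grads["gamma"] = np.zeros_like(p["gamma"])
            grads["beta"] = np.zeros_like(p["beta"])
            dZ1 = dBN
        grads["W1"] = c["X"].T @ dZ1
        grads["b1"] = dZ1.sum(axis=0)
        return grads

    # --- serialization ---------------------------------------------------
    def state_dict(self) -> dict:
        state = {k: v.copy() for k, v in self.params.items()}
        state["running_mean"] = self.running_mean.copy()
        state["running_var"] = self.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64)
        self.running_mean = np.asarray(state["running_mean"], dtype=np.float64)
        self.running_var = np.asarray(state["running_var"], dtype=np.float64)


class Adam:
    """Adaptive-moment estimation over a list of named parameter dicts."""

    def __init__(self, param_dicts: list[dict], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.param_dicts = param_dicts
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in d.items()} for d in param_dicts]
        self.v = [{k: np.zeros_like(v) for k, v in d.items()} for d in param_dicts]

    def step(self, grad_dicts: list[dict]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for params, grads, m, v in zip(self.param_dicts, grad_dicts, self.m, self.v):
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                params[k] -= self.lr * (m[k] / bias1) / (np.sqrt(v[k] / bias2) + self.eps)


def encode(encoder: Encoder, batch_matrix: np.ndarray, *, cell_ids=None,
           cell_types=None, modality_name: str = "modality",
           training: bool = False) -> EmbeddingSet:
    """Run a forward pass and wrap the result as an :class:`EmbeddingSet`."""
    E = encoder.forward(batch_matrix, training=training)
    n = E.shape[0]
    if cell_ids is None:
        cell_ids = np.array([f"cell{i}" for i in range(n)])
    if cell_types is None:
        cell_types = np.array(["unknown"] * n)
    return EmbeddingSet(E, np.asarray(cell_ids), np.asarray(cell_types),
                        modality_name)
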