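"""Synthetic paired two-modality data with a shared cell-type latent structure.

The generator emulates the situation the integration method assumes: matched
cells carry correlated signal across modalities because both measurements are
driven by one latent state.  Each cell draws a type from ``type_proportions``
and a latent vector from that type's isotropic Gaussian; two fixed random
linear maps (one per modality) project the latent vector into
modality-specific feature spaces with independent noise, emulating distinct
feature spaces and distributional discrepancies.  ``separation`` is the
between-type centroid distance in units of the within-type standard
deviation, so nearest-centroid classification in latent space is essentially
perfect at separation 6 and degrades smoothly below.

``count_model="negative_binomial"`` passes the linear output through a
softplus to obtain nonnegative means and emits integer counts, so the full
count-preprocessing chain (normalize -> log1p -> scale -> PCA) is exercised;
the Gaussian option produces continuous values for fast fixtures that skip
the count steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ModalityTable, PairedDataset
from .nn import EmbeddingSet


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic paired dataset."""

    n_cells: int = 2000
    n_types: int = 5
    type_proportions: tuple[float, ...] | None = None
    latent_dim: int = 10
    p: int = 200
    q: int = 200
    separation: float = 6.0
    noise_sd: float = 1.0
    count_model: str = "gaussian"
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("n_types must be >= 2")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if self.p < self.latent_dim or self.q < self.latent_dim:
            raise ValueError("feature counts must be >= latent_dim")
        if self.count_model not in ("gaussian", "negative_binomial"):
            raise ValueError("count_model must be gaussian or negative_binomial")
        props = self.proportions
        if len(props) != self.n_types:
            raise ValueError("type_proportions length must equal n_types")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("type_proportions must sum to 1")
        if any(w <= 0 for w in props):
            raise ValueError("type_proportions must be positive")

    @property
    def proportions(self) -> tuple[float, ...]:
        if self.type_proportions is None:
            return tuple([1.0 / self.n_types] * self.n_types)
        return tuple(self.type_proportions)


@dataclass
class GroundTruth:
    """The latent state behind a generated dataset, for oracle checks."""

    latent: np.ndarray          # (n_cells, latent_dim)
    centroids: np.ndarray       # (n_types, latent_dim)
    type_indices: np.ndarray    # (n_cells,)
    map1: np.ndarray            # (latent_dim, p)
    map2: np.ndarray            # (latent_dim, q)
    type_names: list[str] = field(default_factory=list)


def _centroids(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Type centroids at pairwise distance ``separation`` (within-type sd 1).

    When the latent space can hold them, centroids sit on mutually orthogonal
    directions at radius separation/sqrt(2), making every pairwise distance
    exactly ``separation``; otherwise random Gaussian centroids are rescaled
    to that mean pairwise distance.
    """
    L, T = spec.latent_dim, spec.n_types
    if L >= T:
        G = rng.normal(size=(L, T))
        Q, _ = np.linalg.qr(G)
        return (spec.separation / np.sqrt(2.0)) * Q[:, :T].T
    C = rng.normal(size=(T, L))
    d = np.linalg.norm(C[:, None] - C[None, :], axis=-1)
    mean_d = d[np.triu_indices(T, k=1)].mean()
    return C * (spec.separation / mean_d)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generate_paired(spec: SyntheticSpec) -> tuple[PairedDataset, GroundTruth]:
    """Generate one paired dataset and its ground-truth latent record."""
    rng = np.random.default_rng(spec.seed)
    types = [f"type{i}" for i in range(spec.n_types)]
    t_idx = rng.choice(spec.n_types, size=spec.n_cells, p=spec.proportions)
    centroids = _centroids(spec, rng)
    Z = centroids[t_idx] + rng.normal(size=(spec.n_cells, spec.latent_dim))
    A1 = rng.normal(size=(spec.latent_dim, spec.p)) / np.sqrt(spec.latent_dim)
    A2 = rng.normal(size=(spec.latent_dim, spec.q)) / np.sqrt(spec.latent_dim)
    X1 = Z @ A1 + spec.noise_sd * rng.normal(size=(spec.n_cells, spec.p))
    X2 = Z @ A2 + spec.noise_sd * rng.normal(size=(spec.n_cells, spec.q))
    if spec.count_model == "negative_binomial":
        X1 = _nb_counts(X1, spec.nb_dispersion, rng)
        X2 = _nb_counts(X2, spec.nb_dispersion, rng)
    cell_ids = np.array([f"cell{i:06d}" for i in range(spec.n_cells)])
    labels = np.array([types[i] for i in t_idx])
    ds = PairedDataset(
        ModalityTable(X1, cell_ids, labels,
                      np.array([f"m1_f{j}" for j in range(spec.p)]), "mod1"),
        ModalityTable(X2, cell_ids, labels,
                      np.array([f"m2_f{j}" for j in range(spec.q)]), "mod2"),
    )
    truth = GroundTruth(latent=Z, centroids=centroids, type_indices=t_idx,
                        map1=A1, map2=A2, type_names=types)
    return ds, truth


def _nb_counts(linear: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with mean softplus(linear) and size r."""
    mean = _softplus(linear)
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.float64)


def generate_eval_embeddings(n: int, d: int, n_types: int, noise: float,
                             seed: int) -> tuple[EmbeddingSet, EmbeddingSet]:
    """Matched unit-norm embedding pairs that bypass training entirely.

    Each type gets an orthonormal anchor direction and each cell a small
    jitter shared by both modalities (so distinct cells are distinct points);
    each modality then adds independent spherical noise of scale ``noise``
    and re-normalizes.  At noise 0 the two sets are identical, so every
    retrieval metric is at its optimum; large noise drives them to the
    chance level.
    """
    if d < n_types:
        raise ValueError("d must be >= n_types for orthonormal anchors")
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.normal(size=(d, n_types)))
    anchors = Q[:, :n_types].T
    t_idx = rng.integers(0, n_types, size=n)
    # per-cell identity, small relative to the anchor spacing of sqrt(2)
    base = anchors[t_idx] + 0.2 * rng.normal(size=(n, d)) / np.sqrt(d)

    def one(name: str) -> np.ndarray:
        V = base + noise * rng.normal(size=(n, d))
        return V / np.linalg.norm(V, axis=1, keepdims=True)

    ids = np.array([f"cell{i:05d}" for i in range(n)])
    labels = np.array([f"type{i}" for i in t_idx])
    return (EmbeddingSet(one("mod1"), ids, labels, "mod1"),
            EmbeddingSet(one("mod2"), ids, labels, "mod2"))
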