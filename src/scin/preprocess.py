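"""Preprocessing chain: total-count normalization, log1p, scaling, PCA.

The fixed chain order is ``normalize_total -> log1p -> scale -> pca`` per
modality.  Every statistic (feature means, standard deviations, principal
axes) is fitted on training cells only and then applied, frozen, to held-out
cells — the leakage-free protocol the evaluation depends on.  Inputs that
arrive already normalized (e.g. CITE-seq distributions preprocessed upstream)
can skip the count steps via :class:`PreprocessConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .data import ModalityTable, ValidationError


def normalize_total(table: ModalityTable, target_sum: float = 1e4) -> ModalityTable:
    """Rescale each cell so its total count equals ``target_sum``.

    All-zero cells are left all-zero.  Negative entries are rejected: the
    operation is defined for raw (UMI-like) counts.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    X = table.dense()
    if np.any(X < 0):
        raise ValidationError("normalize_total requires nonnegative values")
    sums = X.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, sums, out=np.zeros_like(sums), where=sums > 0)
    return table.with_values(X * scale)


def log1p_transform(table: ModalityTable) -> ModalityTable:
    """Elementwise natural log of (1 + value); requires nonnegative input."""
    X = table.dense()
    if np.any(X < 0):
        raise ValidationError("log1p_transform requires nonnegative values")
    return table.with_values(np.log1p(X))


@dataclass
class ScaleTransform:
    """Per-feature centering and unit-variance scaling fitted on training cells.

    Population (divide-by-n) variance; zero-variance features are centered and
    left with a unit divisor so they pass through as zeros without NaN.
    """

    mean_: np.ndarray
    scale_: np.ndarray
    fitted_on: int
    kind: str = "scale"

    def apply(self, table: ModalityTable) -> ModalityTable:
        X = table.dense()
        if X.shape[1] != self.mean_.shape[0]:
            raise ValidationError(
                f"feature dimension {X.shape[1]} != fitted {self.mean_.shape[0]}")
        return table.with_values((X - self.mean_) / self.scale_)


def fit_scale(train: ModalityTable) -> ScaleTransform:
    """Fit per-feature mean/standard deviation on training cells only."""
    if train.n_cells < 2:
        raise ValidationError("scaling requires at least 2 training cells")
    scaler = StandardScaler(with_mean=True, with_std=True)
    scaler.fit(train.dense())
    # sklearn already maps zero variance to a unit divisor
    return ScaleTransform(
        mean_=scaler.mean_.copy(),
        scale_=scaler.scale_.copy(),
        fitted_on=train.n_cells,
    )


@dataclass
class PCATransform:
    """Principal-axis projection fitted on training cells.

    ``components_`` rows are orthonormal axes ordered by decreasing explained
    variance.  Signs follow a fixed convention — the largest-magnitude loading
    of each axis is positive — so results are reproducible across platforms.
    """

    components_: np.ndarray  # (n_components, n_features)
    mean_: np.ndarray
    explained_variance_: np.ndarray
    fitted_on: int
    kind: str = "pca"

    def apply(self, table: ModalityTable) -> ModalityTable:
        X = table.dense()
        if X.shape[1] != self.mean_.shape[0]:
            raise ValidationError(
                f"feature dimension {X.shape[1]} != fitted {self.mean_.shape[0]}")
        proj = (X - self.mean_) @ self.components_.T
        pc_ids = np.array([f"PC{i + 1}" for i in range(proj.shape[1])])
        return ModalityTable(
            values=proj,
            cell_ids=table.cell_ids,
            cell_types=table.cell_types,
            feature_ids=pc_ids,
            modality_name=table.modality_name,
        )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


def fit_pca(train: ModalityTable, n_components: int) -> PCATransform:
    """Fit PCA axes on training cells via full SVD (deterministic)."""
    X = train.dense()
    max_comp = min(X.shape)
    if n_components > max_comp:
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_cells, n_features)={max_comp}")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return PCATransform(
        components_=_fix_signs(pca.components_.copy()),
        mean_=pca.mean_.copy(),
        explained_variance_=pca.explained_variance_.copy(),
        fitted_on=train.n_cells,
    )


def apply(transform, table: ModalityTable) -> ModalityTable:
    """Apply a fitted transform to any table without refitting."""
    return transform.apply(table)


@dataclass(frozen=True)
class PreprocessConfig:
    """Which chain steps run for one modality.

    ``n_pcs`` is clipped at fit time to the rank bound
    ``min(n_train_cells, n_features)``.
    """

    normalize: bool = True
    log1p: bool = True
    scale: bool = True
    n_pcs: int = 100
    target_sum: float = 1e4


class PreprocessPipeline:
    """Fit the full chain on training cells; apply it frozen to any cells."""

    def __init__(self, config: PreprocessConfig | None = None):
        self.config = config or PreprocessConfig()
        self.scale_: ScaleTransform | None = None
        self.pca_: PCATransform | None = None
        self.fitted_on: int | None = None

    def _count_steps(self, table: ModalityTable) -> ModalityTable:
        if self.config.normalize:
            table = normalize_total(table, self.config.target_sum)
        if self.config.log1p:
            table = log1p_transform(table)
        return table

    def fit(self, train: ModalityTable) -> "PreprocessPipeline":
        table = self._count_steps(train)
        if self.config.scale:
            self.scale_ = fit_scale(table)
            table = self.scale_.apply(table)
        if self.config.n_pcs:
            n_pcs = min(self.config.n_pcs, train.n_cells, train.n_features)
            self.pca_ = fit_pca(table, n_pcs)
        self.fitted_on = train.n_cells
        return self

    def transform(self, table: ModalityTable) -> ModalityTable:
        if self.fitted_on is None:
            raise RuntimeError("pipeline is not fitted")
        table = self._count_steps(table)
        if self.scale_ is not None:
            table = self.scale_.apply(table)
        if self.pca_ is not None:
            table = self.pca_.apply(table)
        return table

    def fit_transform(self, train: ModalityTable) -> ModalityTable:
        return self.fit(train).transform(train)

    @property
    def output_dim(self) -> int:
        if self.pca_ is not None:
            return self.pca_.components_.shape[0]
        if self.scale_ is not None:
            return self.scale_.mean_.shape[0]
        raise RuntimeError("pipeline is not fitted")

    # --- serialization ---------------------------------------------------
    def state_dict(self) -> dict:
        state: dict = {"config": vars(self.config) | {}, "fitted_on": self.fitted_on}
        if self.scale_ is not None:
            state["scale"] = {
                "mean": self.scale_.mean_, "scale": self.scale_.scale_,
                "fitted_on": self.scale_.fitted_on,
            }
        if self.pca_ is not None:
            state["pca"] = {
                "components": self.pca_.components_, "mean": self.pca_.mean_,
                "explained_variance": self.pca_.explained_variance_,
                "fitted_on": self.pca_.fitted_on,
            }
        return state

    @classmethod
    def from_state_dict(cls, state: dict) -> "PreprocessPipeline":
        cfg_kwargs = {k: v for k, v in dict(state["config"]).items()}
        if "target_sum" in cfg_kwargs:
            cfg_kwargs["target_sum"] = float(cfg_kwargs["target_sum"])
        for key in ("normalize", "log1p", "scale"):
            if key in cfg_kwargs:
                cfg_kwargs[key] = bool(cfg_kwargs[key])
        if "n_pcs" in cfg_kwargs:
            cfg_kwargs["n_pcs"] = int(cfg_kwargs["n_pcs"])
        pipe = cls(PreprocessConfig(**cfg_kwargs))
        pipe.fitted_on = int(state["fitted_on"])
        if "scale" in state:
            s = state["scale"]
            pipe.scale_ = ScaleTransform(
                mean_=np.asarray(s["mean"]), scale_=np.asarray(s["scale"]),
                fitted_on=int(s["fitted_on"]))
        if "pca" in state:
            p = state["pca"]
            pipe.pca_ = PCATransform(
                components_=np.asarray(p["components"]), mean_=np.asarray(p["mean"]),
                explained_variance_=np.asarray(p["explained_variance"]),
                fitted_on=int(p["fitted_on"]))
        return pipe
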