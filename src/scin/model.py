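"""The contrastive integration model and its fitted results.

:class:`SCINModel` is built from a training dataset (paired or unpaired) and
owns the whole leakage-free pipeline: the preprocessing chain is fitted on the
training cells at ``fit()`` time, the two encoders are trained jointly on the
symmetric contrastive loss, and the returned :class:`SCINResults` carries the
frozen transforms and encoder weights as one sealed unit.  Held-out cells are
embedded through :meth:`SCINResults.embed`, which applies only train-fitted
statistics and evaluation-mode batch-norm — it can embed a single cell and
never updates anything.

Usage::

    model = SCINModel(train_paired, preprocess=PreprocessConfig(n_pcs=50))
    results = model.fit(TrainConfig(seed=0))
    emb1, emb2 = results.embed(test_paired)
    print(results.summary())
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .batching import (BatchPlan, EarlyStopper, TrainConfig,
                       plan_paired_epoch, plan_unpaired_epoch)
from .data import ModalityTable, PairedDataset, UnpairedDataset
from .loss import loss_and_grad
from .nn import Adam, Encoder, EncoderSpec, EmbeddingSet
from .preprocess import PreprocessConfig, PreprocessPipeline

_BUNDLE_VERSION = 1


class SCINModel:
    """Contrastive two-modality integration model (unfitted).

    Parameters
    ----------
    dataset
        Training data only.  Hold-out cells must never be passed here; they
        are embedded later through the fitted results object.
    encoder_spec
        Hidden/latent dimensions; ``input_dim`` is filled in automatically
        from the preprocessing output and may be left at 0.
    preprocess
        One :class:`PreprocessConfig` for both modalities, or a
        ``(config_mod1, config_mod2)`` pair.
    """

    def __init__(self, dataset: PairedDataset | UnpairedDataset,
                 encoder_spec: EncoderSpec | None = None,
                 preprocess=None):
        dataset.validate()
        self.dataset = dataset
        self.paired = isinstance(dataset, PairedDataset)
        self._spec = encoder_spec
        if preprocess is None:
            preprocess = PreprocessConfig()
        if isinstance(preprocess, PreprocessConfig):
            preprocess = (preprocess, preprocess)
        self.preprocess_configs = tuple(preprocess)

    @classmethod
    def from_anndata(cls, adata1, adata2, *, paired: bool = True,
                     cell_type_col: str = "cell_type", **kwargs) -> "SCINModel":
        """Build a model from two in-memory AnnData objects."""
        import pandas as pd  # noqa: F401  (anndata obs access)

        tables = []
        for ad, name in ((adata1, "mod1"), (adata2, "mod2")):
            tables.append(ModalityTable(
                values=ad.X,
                cell_ids=np.asarray(ad.obs_names),
                cell_types=np.asarray(ad.obs[cell_type_col].astype(str)),
                feature_ids=np.asarray(ad.var_names),
                modality_name=str(ad.uns.get("modality_name", name)),
            ))
        ds = (PairedDataset(*tables) if paired else UnpairedDataset(*tables))
        return cls(ds, **kwargs)

    def fit(self, config: TrainConfig | None = None,
            verbose: bool = False) -> "SCINResults":
        """Fit preprocessing on the training cells and train both encoders.

        Returns a :class:`SCINResults` bundle with the loss history, the
        early-stop flag, the frozen transforms and the trained weights.
        """
        config = config or TrainConfig()
        rng = np.random.default_rng(config.seed)

        pipes = [PreprocessPipeline(c) for c in self.preprocess_configs]
        X1 = pipes[0].fit_transform(self.dataset.mod1).dense()
        X2 = pipes[1].fit_transform(self.dataset.mod2).dense()

        spec = self._spec or EncoderSpec(input_dim=0)
        spec1 = EncoderSpec(X1.shape[1], spec.hidden_dim, spec.latent_dim,
                            spec.use_batch_norm)
        spec2 = EncoderSpec(X2.shape[1], spec.hidden_dim, spec.latent_dim,
                            spec.use_batch_norm)
        enc1 = Encoder(spec1, rng)
        enc2 = Encoder(spec2, rng)
        optimizer = Adam([enc1.params, enc2.params], lr=config.learning_rate)

        stopper = EarlyStopper(config.patience, config.min_delta)
        history: list[float] = []
        stopped_early = False
        for epoch in range(config.max_epochs):
            plan = self._plan_epoch(config, rng)
            epoch_losses = []
            for batch in plan:
                e1 = enc1.forward(X1[batch.idx1], training=True)
                e2 = enc2.forward(X2[batch.idx2], training=True)
                loss, dS = loss_and_grad(e1 @ e2.T, config.temperature)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        "non-finite contrastive loss; try a smaller "
                        "learning_rate or check input scaling")
                g1 = enc1.backward(dS @ e2)
                g2 = enc2.backward(dS.T @ e1)
                optimizer.step([g1, g2])
                epoch_losses.append(loss)
            mean_loss = float(np.mean(epoch_losses))
            history.append(mean_loss)
            if verbose:
                print(f"epoch {epoch + 1:3d}  mean loss {mean_loss:.6f}")
            if stopper.update(mean_loss):
                stopped_early = True
                break

        return SCINResults(
            encoders=(enc1, enc2), pipelines=tuple(pipes), config=config,
            loss_history=np.asarray(history), stopped_early=stopped_early,
            paired=self.paired,
            modality_names=(self.dataset.mod1.modality_name,
                            self.dataset.mod2.modality_name),
            n_train=(self.dataset.mod1.n_cells, self.dataset.mod2.n_cells),
        )

    def _plan_epoch(self, config: TrainConfig,
                    rng: np.random.Generator) -> BatchPlan:
        if self.paired:
            return plan_paired_epoch(self.dataset, config, rng)
        return plan_unpaired_epoch(self.dataset, config, rng)


class SCINResults:
    """A fitted integration model: frozen transforms plus trained encoders."""

    def __init__(self, encoders, pipelines, config, loss_history,
                 stopped_early, paired, modality_names, n_train):
        self.encoders = encoders
        self.pipelines = pipelines
        self.config = config
        self.loss_history = loss_history
        self.stopped_early = stopped_early
        self.paired = paired
        self.modality_names = modality_names
        self.n_train = n_train

    @property
    def n_epochs(self) -> int:
        return len(self.loss_history)

    @property
    def latent_dim(self) -> int:
        return self.encoders[0].spec.latent_dim

    def embed_table(self, table: ModalityTable, modality: int) -> EmbeddingSet:
        """Embed one modality's cells with frozen statistics (evaluation mode)."""
        if modality not in (1, 2):
            raise ValueError("modality must be 1 or 2")
        pipe = self.pipelines[modality - 1]
        enc = self.encoders[modality - 1]
        proc = pipe.transform(table)
        vectors = enc.forward(proc.dense(), training=False)
        return EmbeddingSet(vectors, table.cell_ids, table.cell_types,
                            table.modality_name)

    def embed(self, dataset: PairedDataset | UnpairedDataset
              ) -> tuple[EmbeddingSet, EmbeddingSet]:
        """Embed both modalities of a hold-out dataset; fully deterministic."""
        return (self.embed_table(dataset.mod1, 1),
                self.embed_table(dataset.mod2, 2))

    def summary(self) -> str:
        lines = [
            "Contrastive integration results",
            "===============================",
            f"mode:            {'paired' if self.paired else 'unpaired'}",
            f"modalities:      {self.modality_names[0]} / {self.modality_names[1]}",
            f"training cells:  {self.n_train[0]} / {self.n_train[1]}",
            f"latent dim:      {self.latent_dim}",
            f"epochs run:      {self.n_epochs} "
            f"({'early stop' if self.stopped_early else 'full schedule'})",
            f"initial loss:    {self.loss_history[0]:.6f}",
            f"final loss:      {self.loss_history[-1]:.6f}",
        ]
        return "\n".join(lines)

    # --- model bundle serialization --------------------------------------
    def save(self, path) -> None:
        """Write the sealed model bundle (weights + transforms) to ``path``."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for m, enc in enumerate(self.encoders, start=1):
            for k, v in enc.state_dict().items():
                arrays[f"enc{m}/{k}"] = v
        for m, pipe in enumerate(self.pipelines, start=1):
            state = pipe.state_dict()
            for group in ("scale", "pca"):
                if group in state:
                    for k, v in state[group].items():
                        if isinstance(v, np.ndarray):
                            arrays[f"pipe{m}/{group}/{k}"] = v
        meta = {
            "version": _BUNDLE_VERSION,
            "paired": self.paired,
            "modality_names": list(self.modality_names),
            "n_train": list(self.n_train),
            "stopped_early": bool(self.stopped_early),
            "config": asdict(self.config),
            "encoder_specs": [asdict(e.spec) for e in self.encoders],
            "pipelines": [
                {"config": {k: (v if not isinstance(v, float) else float(v))
                            for k, v in asdict_cfg(p.config).items()},
                 "fitted_on": p.fitted_on,
                 "scale_fitted_on": p.scale_.fitted_on if p.scale_ else None,
                 "pca_fitted_on": p.pca_.fitted_on if p.pca_ else None}
                for p in self.pipelines],
        }
        arrays["loss_history"] = self.loss_history
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "SCINResults":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            encoders = []
            for m, spec_kwargs in enumerate(meta["encoder_specs"], start=1):
                spec = EncoderSpec(**spec_kwargs)
                enc = Encoder(spec, np.random.default_rng(0))
                enc.load_state_dict(
                    {k.split("/", 1)[1]: data[k] for k in data.files
                     if k.startswith(f"enc{m}/")})
                encoders.append(enc)
            pipelines = []
            for m, pmeta in enumerate(meta["pipelines"], start=1):
                state: dict = {"config": pmeta["config"],
                               "fitted_on": pmeta["fitted_on"]}
                scale_keys = [k for k in data.files
                              if k.startswith(f"pipe{m}/scale/")]
                if scale_keys:
                    state["scale"] = {k.rsplit("/", 1)[1]: data[k]
                                      for k in scale_keys}
                    state["scale"]["fitted_on"] = pmeta["scale_fitted_on"]
                pca_keys = [k for k in data.files
                            if k.startswith(f"pipe{m}/pca/")]
                if pca_keys:
                    state["pca"] = {k.rsplit("/", 1)[1]: data[k]
                                    for k in pca_keys}
                    state["pca"]["fitted_on"] = pmeta["pca_fitted_on"]
                pipelines.append(PreprocessPipeline.from_state_dict(state))
            return cls(
                encoders=tuple(encoders), pipelines=tuple(pipelines),
                config=TrainConfig(**meta["config"]),
                loss_history=np.asarray(data["loss_history"]),
                stopped_early=meta["stopped_early"], paired=meta["paired"],
                modality_names=tuple(meta["modality_names"]),
                n_train=tuple(meta["n_train"]),
            )


def asdict_cfg(cfg: PreprocessConfig) -> dict:
    return {"normalize": cfg.normalize, "log1p": cfg.log1p,
            "scale": cfg.scale, "n_pcs": cfg.n_pcs,
            "target_sum": cfg.target_sum}
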