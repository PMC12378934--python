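"""Cell-type-structured mini-batch construction and the early-stopping rule.

Each mini-batch holds exactly one cell per cell type in each modality, so the
M×M similarity matrix has same-cell (paired) or same-type (unpaired) positives
on its diagonal and different-type negatives everywhere else.  Within an
epoch, each type's cells are consumed in shuffled order without replacement;
once a type runs out it is topped up by sampling with replacement, so every
batch stays full and every training cell appears at least once per epoch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import PairedDataset, UnpairedDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``max_epochs`` 150, ``patience`` 10 and ``min_delta`` 1e-4 are the
    published training schedule; the learning rate is a free choice (adaptive
    moments, 1e-3 default).  ``batch_types`` defaults to the number of shared
    cell types; when that exceeds ``max_batch_types`` the types are subsampled
    per batch.
    """

    max_epochs: int = 150
    patience: int = 10
    min_delta: float = 1e-4
    learning_rate: float = 1e-3
    temperature: float = 1.0
    batch_types: int | None = None
    max_batch_types: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class Batch:
    """Index arrays into each modality plus the batch's cell types."""

    types: np.ndarray
    idx1: np.ndarray
    idx2: np.ndarray


@dataclass
class BatchPlan:
    batches: list[Batch] = field(default_factory=list)

    def __iter__(self):
        return iter(self.batches)

    def __len__(self):
        return len(self.batches)


def _type_queues(labels: np.ndarray, types: list[str],
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {t: rng.permutation(np.flatnonzero(labels == t)) for t in types}


def _draw_columns(queues: dict[str, np.ndarray], types: list[str],
                  n_batches: int, rng: np.random.Generator) -> np.ndarray:
    """(n_batches, n_types) index matrix: without replacement, then top-up."""
    cols = np.empty((n_batches, len(types)), dtype=np.int64)
    for j, t in enumerate(types):
        q = queues[t]
        if len(q) >= n_batches:
            cols[:, j] = q[:n_batches]
        else:
            extra = rng.choice(q, size=n_batches - len(q), replace=True)
            cols[:, j] = np.concatenate([q, extra])
    return cols


def _select_types(all_types: list[str], cap: int, n_batches: int,
                  rng: np.random.Generator) -> list[np.ndarray]:
    """Per-batch type subsets (subsampled if the type count exceeds the cap)."""
    arr = np.array(all_types)
    if len(arr) <= cap:
        return [arr] * n_batches
    warnings.warn(
        f"{len(arr)} cell types exceed max_batch_types={cap}; "
        "subsampling types per batch")
    return [np.sort(rng.choice(arr, size=cap, replace=False))
            for _ in range(n_batches)]


def plan_paired_epoch(dataset: PairedDataset, config: TrainConfig,
                      rng: np.random.Generator) -> BatchPlan:
    """One epoch of paired batches: identical cell indices in both modalities."""
    labels = dataset.cell_types
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("need at least 2 cell types to form negative pairs")
    counts = {t: int(np.sum(labels == t)) for t in types}
    n_batches = max(counts.values())
    queues = _type_queues(labels, types, rng)
    cols = _draw_columns(queues, types, n_batches, rng)
    type_sets = _select_types(types, config.max_batch_types, n_batches, rng)
    type_pos = {t: j for j, t in enumerate(types)}
    plan = BatchPlan()
    for b in range(n_batches):
        sel = np.array([type_pos[t] for t in type_sets[b]])
        idx = cols[b, sel]
        plan.batches.append(Batch(types=type_sets[b], idx1=idx, idx2=idx.copy()))
    return plan


def plan_unpaired_epoch(dataset: UnpairedDataset, config: TrainConfig,
                        rng: np.random.Generator) -> BatchPlan:
    """One epoch of unpaired batches: same-type cells drawn independently
    from each modality form the diagonal positives."""
    l1, l2 = dataset.mod1.cell_types, dataset.mod2.cell_types
    shared = sorted(set(l1) & set(l2))
    excluded = sorted((set(l1) | set(l2)) - set(shared))
    if excluded:
        logger.warning("cell types present in only one modality excluded "
                       "from training batches: %s", excluded)
    if not shared:
        raise ValueError("modalities share no cell types")
    if len(shared) < 2:
        raise ValueError("need at least 2 shared cell types to form negatives")
    counts = [max(int(np.sum(l1 == t)), int(np.sum(l2 == t))) for t in shared]
    n_batches = max(counts)
    cols1 = _draw_columns(_type_queues(l1, shared, rng), shared, n_batches, rng)
    cols2 = _draw_columns(_type_queues(l2, shared, rng), shared, n_batches, rng)
    type_sets = _select_types(shared, config.max_batch_types, n_batches, rng)
    type_pos = {t: j for j, t in enumerate(shared)}
    plan = BatchPlan()
    for b in range(n_batches):
        sel = np.array([type_pos[t] for t in type_sets[b]])
        plan.batches.append(
            Batch(types=type_sets[b], idx1=cols1[b, sel], idx2=cols2[b, sel]))
    return plan


class EarlyStopper:
    """Stop when the monitored loss fails to improve by more than ``min_delta``
    for ``patience`` consecutive epochs.

    Improvement means ``best_so_far - current > min_delta``.  A constant loss
    sequence therefore stops exactly ``patience`` epochs after the first.
    """

    def __init__(self, patience: int = 10, min_delta: float = 1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0
        self.stopped_at: int | None = None
        self._epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; return True if training should stop now."""
        self._epoch += 1
        if self.best - loss > self.min_delta:
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
        if self.stale >= self.patience:
            self.stopped_at = self._epoch
            return True
        return False


def simulate_early_stopping(losses, patience: int = 10,
                            min_delta: float = 1e-4,
                            max_epochs: int = 150) -> int:
    """Number of epochs actually run on a given loss sequence (test utility)."""
    stopper = EarlyStopper(patience, min_delta)
    for e, loss in enumerate(losses[:max_epochs], start=1):
        if stopper.update(loss):
            return e
    return min(len(losses), max_epochs)
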