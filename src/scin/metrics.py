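"""Integration-quality metrics for cross-modal embeddings.

Five metrics, all on Euclidean distance in the shared latent space:

* ``recall_at_k`` — fraction of cells whose matched counterpart in the other
  modality lies among their k nearest neighbors (needs paired hold-out).
* ``cell_type_at_k`` — mean fraction of a cell's k cross-modal neighbors that
  share its cell-type label (works unpaired).
* ``cell_type_accuracy`` — cell_type_at_k at k = 1.
* ``median_rank`` — median, over cells, of the matched counterpart's rank
  among all cross-modal distances; reported raw and normalized by N.
* ``asw_normalized`` — average silhouette width of the joint embedding with
  cell-type labels as clusters, mapped to [0, 1] via (ASW + 1) / 2.

Nearest-neighbor ties are broken by reference index order; in ``median_rank``
the matched pair receives the best rank among equals.  k values exceeding the
reference size are clipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .nn import EmbeddingSet

DEFAULT_K_GRID = (10, 20, 30, 40, 50)


def _vectors(emb) -> np.ndarray:
    return np.asarray(getattr(emb, "vectors", emb), dtype=np.float64)


def _labels(emb) -> np.ndarray:
    labels = getattr(emb, "cell_types", None)
    if labels is None:
        raise ValueError("embedding set carries no cell-type labels")
    return np.asarray(labels)


def _check_paired(query, reference) -> None:
    q_ids = getattr(query, "cell_ids", None)
    r_ids = getattr(reference, "cell_ids", None)
    if q_ids is not None and r_ids is not None:
        if len(q_ids) != len(r_ids) or not np.array_equal(q_ids, r_ids):
            raise ValueError(
                "paired metric requires the same cells in the same order "
                "in both modalities")
    elif _vectors(query).shape[0] != _vectors(reference).shape[0]:
        raise ValueError("paired metric requires equal cell counts")


def _clip_k(k: int, n_ref: int) -> int:
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_ref:
        warnings.warn(f"k={k} exceeds reference size {n_ref}; clipping")
        return n_ref
    return k


def _knn_indices(query: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest reference rows per query row.

    Stable argsort keeps ties deterministic (smaller reference index wins).
    """
    D = cdist(query, reference)
    return np.argsort(D, axis=1, kind="stable")[:, :k]


def recall_at_k(query, reference, k: int) -> float:
    """Fraction of cells whose matched counterpart is in their k-NN set."""
    _check_paired(query, reference)
    Q, R = _vectors(query), _vectors(reference)
    k = _clip_k(k, R.shape[0])
    knn = _knn_indices(Q, R, k)
    hits = (knn == np.arange(Q.shape[0])[:, None]).any(axis=1)
    return float(hits.mean())


def cell_type_at_k(query, reference, k: int) -> float:
    """Mean fraction of k cross-modal neighbors sharing the query's label."""
    Q, R = _vectors(query), _vectors(reference)
    if R.shape[0] == 0:
        raise ValueError("empty reference set")
    ql, rl = _labels(query), _labels(reference)
    k = _clip_k(k, R.shape[0])
    knn = _knn_indices(Q, R, k)
    same = rl[knn] == ql[:, None]
    return float(same.mean())


def cell_type_accuracy(query, reference) -> float:
    """Fraction of cells whose single nearest cross-modal neighbor shares
    their label; identical to ``cell_type_at_k`` with k = 1."""
    return cell_type_at_k(query, reference, k=1)


def median_rank(query, reference) -> tuple[float, float]:
    """Median 1-based rank of the matched counterpart; raw and divided by N.

    The matched pair wins distance ties (best rank among equals), so the rank
    is one plus the number of strictly closer reference cells.
    """
    _check_paired(query, reference)
    Q, R = _vectors(query), _vectors(reference)
    D = cdist(Q, R)
    matched = np.diagonal(D)
    ranks = 1 + (D < matched[:, None]).sum(axis=1)
    raw = float(np.median(ranks))
    return raw, raw / R.shape[0]


def build_joint_embedding(emb1, emb2, matched: bool
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Combine two embedding sets into one labeled matrix.

    Matched cells are concatenated column-wise (N × 2d, one label per cell);
    unmatched cells are stacked row-wise ((n1 + n2) × d, each cell keeping its
    own label).
    """
    V1, V2 = _vectors(emb1), _vectors(emb2)
    if matched:
        _check_paired(emb1, emb2)
        return np.hstack([V1, V2]), _labels(emb1)
    return np.vstack([V1, V2]), np.concatenate([_labels(emb1), _labels(emb2)])


def asw_normalized(joint: np.ndarray, labels) -> float:
    """Normalized average silhouette width of a labeled joint embedding.

    Euclidean distance, cell-type labels as clusters, mapped through
    (ASW + 1) / 2 so 1 is perfect separation and 0.5 is indifference.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("silhouette undefined for a single cell-type label")
    asw = silhouette_score(np.asarray(joint, dtype=np.float64), labels,
                           metric="euclidean")
    return float((asw + 1.0) / 2.0)


@dataclass
class MetricReport:
    """All five metrics for one replicate and one query direction."""

    recall_at_k: dict[int, float]
    cell_type_at_k: dict[int, float]
    cell_type_accuracy: float
    median_rank_raw: float | None
    median_rank_normalized: float | None
    asw_normalized: float
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    replicate_index: int = 0
    direction: str = "mod1_to_mod2"
    paired: bool = True
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "recall_at_k": {str(k): v for k, v in self.recall_at_k.items()},
            "cell_type_at_k": {str(k): v for k, v in self.cell_type_at_k.items()},
            "cell_type_accuracy": self.cell_type_accuracy,
            "median_rank_raw": self.median_rank_raw,
            "median_rank_normalized": self.median_rank_normalized,
            "asw_normalized": self.asw_normalized,
            "k_grid": list(self.k_grid),
            "replicate_index": self.replicate_index,
            "direction": self.direction,
            "paired": self.paired,
            **self.extra,
        }

    def to_rows(self) -> list[dict]:
        """Long-format rows (replicate, direction, metric, k, value)."""
        rows = []
        base = {"replicate": self.replicate_index, "direction": self.direction}
        for k, v in self.recall_at_k.items():
            rows.append(base | {"metric": "recall_at_k", "k": k, "value": v})
        for k, v in self.cell_type_at_k.items():
            rows.append(base | {"metric": "cell_type_at_k", "k": k, "value": v})
        rows.append(base | {"metric": "cell_type_accuracy", "k": None,
                            "value": self.cell_type_accuracy})
        if self.median_rank_raw is not None:
            rows.append(base | {"metric": "median_rank_raw", "k": None,
                                "value": self.median_rank_raw})
            rows.append(base | {"metric": "median_rank_normalized", "k": None,
                                "value": self.median_rank_normalized})
        rows.append(base | {"metric": "asw_normalized", "k": None,
                            "value": self.asw_normalized})
        return rows


def evaluate_embeddings(emb_query: EmbeddingSet, emb_reference: EmbeddingSet,
                        *, paired: bool = True,
                        k_grid=DEFAULT_K_GRID, replicate_index: int = 0,
                        direction: str = "mod1_to_mod2") -> MetricReport:
    """Compute all metrics for one query direction.

    Pairing-dependent metrics (Recall@k, median rank) are reported only when
    the hold-out embeddings are matched cell-for-cell.
    """
    recall = {k: recall_at_k(emb_query, emb_reference, k)
              for k in k_grid} if paired else {}
    ctk = {k: cell_type_at_k(emb_query, emb_reference, k) for k in k_grid}
    acc = cell_type_accuracy(emb_query, emb_reference)
    if paired:
        raw, norm = median_rank(emb_query, emb_reference)
    else:
        raw = norm = None
    joint, labels = build_joint_embedding(emb_query, emb_reference,
                                          matched=paired)
    asw = asw_normalized(joint, labels)
    return MetricReport(
        recall_at_k=recall, cell_type_at_k=ctk, cell_type_accuracy=acc,
        median_rank_raw=raw, median_rank_normalized=norm, asw_normalized=asw,
        k_grid=tuple(k_grid), replicate_index=replicate_index,
        direction=direction, paired=paired,
    )
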