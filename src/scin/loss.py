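"""Symmetric contrastive loss on mini-batch similarity matrices.

A mini-batch pairs M cells of the first modality with M cells of the second,
one cell per cell type.  Their unit-norm embeddings give an M×M matrix of
inner products whose diagonal entries are the positive (matched or same-type)
pairs and whose off-diagonal entries pair cells of different types — genuine
negatives.  Per anchor i the loss averages a row-wise and a column-wise
softmax cross-entropy on the diagonal:

    L(i) = -1/2 ln[ exp(s_ii) / sum_j exp(s_ij) ]
           -1/2 ln[ exp(s_ii) / sum_j exp(s_ji) ]

and the batch loss is the sum of L(i) over the M anchors.  There is no
temperature in this formulation; an optional temperature is exposed for
experimentation and defaults to 1 (off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax


@dataclass
class SimilarityBatch:
    """An M×M matrix of cross-modal inner products plus pairing metadata."""

    matrix: np.ndarray
    row_labels: np.ndarray | None = None
    col_labels: np.ndarray | None = None
    row_ids: np.ndarray | None = None
    col_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("similarity matrix must be 2-D")


def similarity_matrix(emb1, emb2) -> SimilarityBatch:
    """Inner products between two equal-size embedding batches.

    Accepts :class:`~scin.data` embedding sets or plain arrays; rows are
    assumed unit-norm so entries are cosine similarities in [-1, 1].
    """
    v1 = getattr(emb1, "vectors", emb1)
    v2 = getattr(emb2, "vectors", emb2)
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape:
        raise ValueError(f"batch shapes differ: {v1.shape} vs {v2.shape}")
    return SimilarityBatch(
        matrix=v1 @ v2.T,
        row_labels=getattr(emb1, "cell_types", None),
        col_labels=getattr(emb2, "cell_types", None),
        row_ids=getattr(emb1, "cell_ids", None),
        col_ids=getattr(emb2, "cell_ids", None),
    )


def _as_square(sim) -> np.ndarray:
    S = sim.matrix if isinstance(sim, SimilarityBatch) else np.asarray(sim, float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {S.shape}")
    return S


def loss_and_grad(sim, temperature: float = 1.0) -> tuple[float, np.ndarray]:
    """Batch loss and its gradient with respect to the similarity matrix.

    The gradient of the summed loss is ``0.5 (P_row - I) + 0.5 (P_col - I)``
    where ``P_row`` and ``P_col`` are the row- and column-softmax of the
    (temperature-scaled) similarities; the chain-rule factor 1/temperature is
    included.
    """
    S = _as_square(sim) / temperature
    M = S.shape[0]
    diag = np.diagonal(S)
    row_lse = logsumexp(S, axis=1)
    col_lse = logsumexp(S, axis=0)
    loss = float(np.sum(0.5 * (row_lse - diag) + 0.5 * (col_lse - diag)))
    eye = np.eye(M)
    grad = 0.5 * (softmax(S, axis=1) - eye) + 0.5 * (softmax(S, axis=0) - eye)
    return loss, grad / temperature


def contrastive_loss(sim, temperature: float = 1.0) -> float:
    """Total contrastive loss of a batch, summed over its M anchors."""
    return loss_and_grad(sim, temperature)[0]


def loss_symmetry_check(sim, tol: float = 1e-8) -> bool:
    """True iff swapping the two modalities leaves the total loss unchanged."""
    S = _as_square(sim)
    return abs(contrastive_loss(S) - contrastive_loss(S.T)) < tol
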