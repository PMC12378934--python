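"""Core data containers: per-modality tables, paired/unpaired datasets, splits.

A :class:`ModalityTable` holds one modality's cells-by-features matrix together
with cell identifiers, cell-type labels and feature identifiers.  Two tables
combine into a :class:`PairedDataset` (same physical cells, same order in both
modalities) or an :class:`UnpairedDataset` (disjoint cells that only share a
cell-type vocabulary).  Train/test splitting is driven by a :class:`SplitSpec`
and is fully deterministic given its seed and replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when a data container violates one of its invariants."""


def _as_str_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=object)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr.astype(str)


@dataclass
class ModalityTable:
    """One modality's cells × features matrix with annotations.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix, shape ``(n_cells, n_features)``.
    cell_ids
        Unique string identifiers, one per cell.
    cell_types
        Cell-type labels, one per cell.
    feature_ids
        Unique string identifiers, one per feature.
    modality_name
        Free-form tag, e.g. ``"rna"``, ``"atac"`` or ``"adt"``.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    cell_types: np.ndarray
    feature_ids: np.ndarray
    modality_name: str = "modality"

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=np.float64)
            if self.values.ndim != 2:
                raise ValidationError("values must be a 2-D matrix")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        self.cell_types = _as_str_array(self.cell_types, "cell_types")
        self.feature_ids = _as_str_array(self.feature_ids, "feature_ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Return values as a dense float64 array."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return self.values

    def subset(self, indices) -> "ModalityTable":
        indices = _check_indices(indices, self.n_cells)
        return ModalityTable(
            values=self.values[indices],
            cell_ids=self.cell_ids[indices],
            cell_types=self.cell_types[indices],
            feature_ids=self.feature_ids,
            modality_name=self.modality_name,
        )

    def with_values(self, values) -> "ModalityTable":
        return replace(self, values=values)

    def to_anndata(self):
        import anndata
        import pandas as pd

        ad = anndata.AnnData(
            X=self.values if sp.issparse(self.values) else self.values.copy(),
            obs=pd.DataFrame({"cell_type": self.cell_types},
                             index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.feature_ids, name="feature_id")),
        )
        ad.uns["modality_name"] = self.modality_name
        return ad


def validate(table: ModalityTable) -> ModalityTable:
    """Check all :class:`ModalityTable` invariants; return the table unchanged.

    Raises
    ------
    ValidationError
        On duplicate cell/feature ids, annotation length mismatch, or
        non-finite matrix entries.
    """
    n, p = table.values.shape
    if len(table.cell_ids) != n:
        raise ValidationError(
            f"cell_ids length {len(table.cell_ids)} != row count {n}")
    if len(table.cell_types) != n:
        raise ValidationError(
            f"cell_types length {len(table.cell_types)} != row count {n}")
    if len(table.feature_ids) != p:
        raise ValidationError(
            f"feature_ids length {len(table.feature_ids)} != column count {p}")
    if len(set(table.cell_ids)) != n:
        raise ValidationError("duplicate cell_ids")
    if len(set(table.feature_ids)) != p:
        raise ValidationError("duplicate feature_ids")
    data = table.values.data if sp.issparse(table.values) else table.values
    if not np.all(np.isfinite(data)):
        raise ValidationError("values contain NaN or Inf")
    return table


@dataclass
class PairedDataset:
    """Two modalities measured in the same cells, row-aligned."""

    mod1: ModalityTable
    mod2: ModalityTable

    def __post_init__(self) -> None:
        if self.mod1.n_cells != self.mod2.n_cells:
            raise ValidationError("paired modalities must have equal cell counts")
        if not np.array_equal(self.mod1.cell_ids, self.mod2.cell_ids):
            raise ValidationError("paired modalities must share cell_ids in order")
        if not np.array_equal(self.mod1.cell_types, self.mod2.cell_types):
            raise ValidationError("paired modalities must share cell_types")

    @property
    def n_cells(self) -> int:
        return self.mod1.n_cells

    @property
    def cell_types(self) -> np.ndarray:
        return self.mod1.cell_types

    @property
    def cell_ids(self) -> np.ndarray:
        return self.mod1.cell_ids

    def subset(self, indices) -> "PairedDataset":
        indices = _check_indices(indices, self.n_cells)
        return PairedDataset(self.mod1.subset(indices), self.mod2.subset(indices))

    def validate(self) -> "PairedDataset":
        validate(self.mod1)
        validate(self.mod2)
        return self


@dataclass
class UnpairedDataset:
    """Two modalities measured in disjoint cells sharing a type vocabulary."""

    mod1: ModalityTable
    mod2: ModalityTable

    def __post_init__(self) -> None:
        overlap = set(self.mod1.cell_ids) & set(self.mod2.cell_ids)
        if overlap:
            raise ValidationError(
                f"unpaired modalities share {len(overlap)} cell ids")
        if not self.shared_types():
            raise ValidationError("unpaired modalities share no cell types")

    def shared_types(self) -> list[str]:
        return sorted(set(self.mod1.cell_types) & set(self.mod2.cell_types))

    def validate(self) -> "UnpairedDataset":
        validate(self.mod1)
        validate(self.mod2)
        return self


@dataclass(frozen=True)
class SplitSpec:
    """Deterministic description of one train/test split replicate.

    The effective RNG seed is ``seed + replicate_index``, so a run of 10
    replicates uses 10 consecutive, reproducible seeds.
    """

    test_fraction: float = 0.3
    seed: int = 0
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.replicate_index < 0:
            raise ValueError("replicate_index must be >= 0")


def make_split(n_cells: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return disjoint ``(train_indices, test_indices)`` covering ``0..n-1``.

    The test set has ``round(test_fraction * n_cells)`` cells.  Identical
    specs always produce identical index sets.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells to split")
    n_test = int(round(spec.test_fraction * n_cells))
    n_test = min(max(n_test, 1), n_cells - 1)
    rng = np.random.default_rng(spec.seed + spec.replicate_index)
    perm = rng.permutation(n_cells)
    test = np.sort(perm[:n_test])
    train = np.sort(perm[n_test:])
    return train, test


def subset(dataset: PairedDataset, indices) -> PairedDataset:
    """Subset both modalities of a paired dataset by the same row indices."""
    return dataset.subset(indices)


def _check_indices(indices, n: int) -> np.ndarray:
    indices = np.asarray(indices, dtype=np.int64)
    if indices.size == 0:
        raise ValidationError("empty index set would produce a degenerate dataset")
    if indices.min() < 0 or indices.max() >= n:
        raise ValidationError(f"index out of range for {n} cells")
    return indices


def write_split_manifest(path, train: np.ndarray, test: np.ndarray) -> None:
    """Write a plain-text audit record of one split (one index per line)."""
    path = Path(path)
    lines = ["# train"] + [str(i) for i in train] + ["# test"] + [str(i) for i in test]
    path.write_text("\n".join(lines) + "\n")


def read_modality(path, cell_type_col: str = "cell_type",
                  modality_name: str | None = None) -> ModalityTable:
    """Load a :class:`ModalityTable` from an h5ad file.

    The matrix is taken from the main layer (``X``); cell types come from the
    observation column ``cell_type_col``.  Missing labels are a hard error:
    the method is supervised by type in both training and evaluation.
    """
    import anndata

    ad = anndata.read_h5ad(path)
    if cell_type_col not in ad.obs.columns:
        raise ValidationError(
            f"observation column {cell_type_col!r} not found in {path}")
    name = modality_name or ad.uns.get("modality_name", Path(path).stem)
    table = ModalityTable(
        values=ad.X,
        cell_ids=np.asarray(ad.obs_names),
        cell_types=np.asarray(ad.obs[cell_type_col].astype(str)),
        feature_ids=np.asarray(ad.var_names),
        modality_name=str(name),
    )
    return validate(table)


def write_modality(table: ModalityTable, path) -> None:
    """Write a :class:`ModalityTable` to an h5ad file."""
    table.to_anndata().write_h5ad(Path(path))
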