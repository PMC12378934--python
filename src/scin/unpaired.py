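"""Simulating unpaired data from a paired dataset, plus the random baseline.

A paired assay gives ground-truth cross-modal correspondence; dropping one
modality for a random subset of cells and the other modality for the rest
yields two disjoint cell sets that share only a cell-type vocabulary — the
unpaired regime.  The ``proportion`` controls the minor modality's share of
cells; the published study sweeps 1%, 5%, 10%, 20% and 50%.  The random
baseline permutes cell-type labels, destroying the type signal while keeping
its marginal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import ModalityTable, PairedDataset, UnpairedDataset

PAPER_PROPORTIONS = (0.01, 0.05, 0.10, 0.20, 0.50)


@dataclass(frozen=True)
class UnpairingSpec:
    """How to partition a paired dataset into disjoint unpaired modalities.

    ``proportion`` is the fraction of cells whose *minor* modality profile is
    retained (modality 2 by default — ATAC/ADT in the published datasets);
    all remaining cells keep only the other modality.  ``stratified`` samples
    the subset per cell type so every type survives in both modalities at
    very small proportions.
    """

    proportion: float
    seed: int = 0
    which_modality_minor: int = 2
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError("proportion must lie in (0, 1]")
        if self.which_modality_minor not in (1, 2):
            raise ValueError("which_modality_minor must be 1 or 2")


def _choose_subset(labels: np.ndarray, n_minor: int,
                   spec: UnpairingSpec, rng: np.random.Generator) -> np.ndarray:
    n = len(labels)
    if not spec.stratified:
        return np.sort(rng.choice(n, size=n_minor, replace=False))
    picks = []
    types = sorted(set(labels))
    # one cell per type first, remainder proportional
    for t in types:
        idx = np.flatnonzero(labels == t)
        n_t = max(1, int(round(spec.proportion * len(idx))))
        n_t = min(n_t, len(idx) - 1) if len(idx) > 1 else 1
        picks.append(rng.choice(idx, size=n_t, replace=False))
    return np.sort(np.concatenate(picks))


def simulate_unpaired(paired: PairedDataset,
                      spec: UnpairingSpec) -> UnpairedDataset:
    """Partition a paired dataset into two disjoint single-modality cell sets.

    A random subset of ``round(proportion * N)`` cells keeps only the minor
    modality; the complement keeps only the other.  Deterministic given the
    seed.  Raises if either side would be empty.
    """
    paired.validate()
    n = paired.n_cells
    n_minor = int(round(spec.proportion * n))
    if n_minor == 0 or n_minor == n:
        raise ValueError(
            f"proportion {spec.proportion} leaves one modality empty "
            f"(N={n}); choose a proportion with 0 < round(p*N) < N")
    rng = np.random.default_rng(spec.seed)
    minor_idx = _choose_subset(paired.cell_types, n_minor, spec, rng)
    major_idx = np.setdiff1d(np.arange(n), minor_idx)
    minor_table = (paired.mod2 if spec.which_modality_minor == 2
                   else paired.mod1).subset(minor_idx)
    major_table = (paired.mod1 if spec.which_modality_minor == 2
                   else paired.mod2).subset(major_idx)
    if spec.which_modality_minor == 2:
        return UnpairedDataset(mod1=major_table, mod2=minor_table)
    return UnpairedDataset(mod1=minor_table, mod2=major_table)


def permute_labels(table: ModalityTable, seed: int) -> ModalityTable:
    """Replace cell types by a uniform random permutation of themselves.

    Marginal type counts are preserved exactly; values are untouched.  This
    is the random baseline: any type-driven structure in downstream metrics
    collapses to the label-collision chance level.
    """
    rng = np.random.default_rng(seed)
    permuted = table.cell_types[rng.permutation(table.n_cells)]
    return replace(table, cell_types=permuted)


def permute_dataset_labels(paired: PairedDataset, seed: int) -> PairedDataset:
    """Permute labels consistently across both modalities of a paired set."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(paired.n_cells)
    labels = paired.cell_types[perm]
    return PairedDataset(
        replace(paired.mod1, cell_types=labels),
        replace(paired.mod2, cell_types=labels),
    )
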