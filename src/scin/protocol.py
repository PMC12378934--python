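"""Replicate orchestration: the leakage-free 10-split evaluation protocol.

For each replicate: split the paired data, fit preprocessing and encoders on
the training portion only, embed the paired hold-out, and score both query
directions with all metrics.  In unpaired mode the training portion is first
partitioned into disjoint single-modality cell sets (the hold-out stays
paired, so Recall@k remains computable).  The manifest records effective
configuration, per-replicate seeds and output paths so a completed run can be
re-executed bit-compatibly on the same platform.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .batching import TrainConfig
from .data import PairedDataset, SplitSpec, make_split, write_split_manifest
from .metrics import DEFAULT_K_GRID, MetricReport, evaluate_embeddings
from .model import SCINModel
from .nn import EncoderSpec
from .preprocess import PreprocessConfig
from .unpaired import UnpairingSpec, permute_dataset_labels, simulate_unpaired

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Everything needed to re-execute a replicate run."""

    config: dict
    replicate_seeds: list[int] = field(default_factory=list)
    split_files: list[str] = field(default_factory=list)
    model_bundles: list[str] = field(default_factory=list)
    report_files: list[str] = field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def run_replicates(paired: PairedDataset, *,
                   n_replicates: int = 10,
                   test_fraction: float = 0.3,
                   base_seed: int = 0,
                   train_config: TrainConfig | None = None,
                   encoder_spec: EncoderSpec | None = None,
                   preprocess: PreprocessConfig | tuple | None = None,
                   unpairing: UnpairingSpec | None = None,
                   permute_baseline: bool = False,
                   k_grid=DEFAULT_K_GRID,
                   out_dir=None) -> pd.DataFrame:
    """Run the full split/train/evaluate protocol and return long-format rows.

    Parameters
    ----------
    paired
        The full paired dataset; splitting happens inside, and the training
        stage physically receives only training rows.
    unpairing
        When given, the training portion is converted to disjoint unpaired
        modalities at this proportion before training; evaluation still uses
        the paired hold-out.
    permute_baseline
        Randomly permute cell-type labels first (the random baseline).
    out_dir
        When given, split manifests, model bundles, per-replicate reports and
        the run manifest are written there.

    Returns
    -------
    DataFrame with columns (replicate, direction, metric, k, value).
    """
    train_config = train_config or TrainConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={
        "n_replicates": n_replicates, "test_fraction": test_fraction,
        "base_seed": base_seed, "train_config": asdict(train_config),
        "unpairing": asdict(unpairing) if unpairing else None,
        "permute_baseline": permute_baseline, "k_grid": list(k_grid),
    }, started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    if permute_baseline:
        paired = permute_dataset_labels(paired, seed=base_seed)

    all_rows: list[dict] = []
    for r in range(n_replicates):
        seed_r = base_seed + r
        manifest.replicate_seeds.append(seed_r)
        spec = SplitSpec(test_fraction=test_fraction, seed=base_seed,
                         replicate_index=r)
        train_idx, test_idx = make_split(paired.n_cells, spec)
        train_set = paired.subset(train_idx)
        test_set = paired.subset(test_idx)
        if out_dir is not None:
            split_file = out_dir / f"split_r{r}.txt"
            write_split_manifest(split_file, train_idx, test_idx)
            manifest.split_files.append(str(split_file))

        if unpairing is not None:
            train_data = simulate_unpaired(
                train_set, UnpairingSpec(
                    proportion=unpairing.proportion, seed=seed_r,
                    which_modality_minor=unpairing.which_modality_minor,
                    stratified=unpairing.stratified))
        else:
            train_data = train_set

        cfg_r = TrainConfig(**{**asdict(train_config), "seed": seed_r})
        model = SCINModel(train_data, encoder_spec=encoder_spec,
                          preprocess=preprocess)
        results = model.fit(cfg_r)
        logger.info("replicate %d: %d epochs, final loss %.5f", r,
                    results.n_epochs, results.loss_history[-1])
        if out_dir is not None:
            bundle = out_dir / f"model_r{r}.npz"
            results.save(bundle)
            manifest.model_bundles.append(str(bundle))

        emb1, emb2 = results.embed(test_set)
        reports = [
            evaluate_embeddings(emb1, emb2, paired=True, k_grid=k_grid,
                                replicate_index=r, direction="mod1_to_mod2"),
            evaluate_embeddings(emb2, emb1, paired=True, k_grid=k_grid,
                                replicate_index=r, direction="mod2_to_mod1"),
        ]
        if out_dir is not None:
            report_file = out_dir / f"report_r{r}.json"
            report_file.write_text(json.dumps(
                [rep.to_dict() for rep in reports], indent=2) + "\n")
            manifest.report_files.append(str(report_file))
        for rep in reports:
            all_rows.extend(rep.to_rows())

    table = pd.DataFrame(all_rows)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    if out_dir is not None:
        manifest.save(out_dir / "manifest.json")
        table.to_csv(out_dir / "metrics_long.csv", index=False)
    return table


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd per (direction, metric, k) across replicates."""
    grouped = table.groupby(["direction", "metric", "k"], dropna=False)["value"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    return out


def aggregate_reports(report_paths) -> pd.DataFrame:
    """Combine per-replicate JSON reports into one long-format table."""
    paths = list(report_paths)
    if not paths:
        raise ValueError("no report files given")
    rows: list[dict] = []
    for path in paths:
        try:
            payload = json.loads(Path(path).read_text())
            if not isinstance(payload, list):
                payload = [payload]
            for entry in payload:
                rows.extend(_report_from_dict(entry).to_rows())
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise ValueError(f"malformed report file {path}: {exc}") from exc
    return pd.DataFrame(rows)


def _report_from_dict(d: dict) -> MetricReport:
    return MetricReport(
        recall_at_k={int(k): v for k, v in d["recall_at_k"].items()},
        cell_type_at_k={int(k): v for k, v in d["cell_type_at_k"].items()},
        cell_type_accuracy=d["cell_type_accuracy"],
        median_rank_raw=d.get("median_rank_raw"),
        median_rank_normalized=d.get("median_rank_normalized"),
        asw_normalized=d["asw_normalized"],
        k_grid=tuple(d.get("k_grid", DEFAULT_K_GRID)),
        replicate_index=d.get("replicate_index", 0),
        direction=d.get("direction", "mod1_to_mod2"),
        paired=d.get("paired", True),
    )


def export_tsne_plot(joint: np.ndarray, labels, out_path, *,
                     seed: int = 0, perplexity: float | None = None) -> None:
    """Write a 2-D t-SNE scatter of a joint embedding, colored by cell type.

    A visual aid only — there is no numerical contract on the layout.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.manifold import TSNE

    joint = np.asarray(joint, dtype=np.float64)
    labels = np.asarray(labels)
    n = joint.shape[0]
    if perplexity is None:
        perplexity = max(2.0, min(30.0, (n - 1) / 3.0))
    try:
        coords = TSNE(n_components=2, random_state=seed,
                      perplexity=perplexity, init="pca").fit_transform(joint)
        fig, ax = plt.subplots(figsize=(6, 5))
        for t in sorted(set(labels.tolist())):
            mask = labels == t
            ax.scatter(coords[mask, 0], coords[mask, 1], s=8, label=t)
        ax.legend(markerscale=2, fontsize=8, title="cell type")
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    except Exception:  # plotting must never take down a run
        logger.exception("t-SNE export failed for %s", out_path)
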