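import numpy as np
import pytest

from scin.data import ModalityTable, PairedDataset
from scin.preprocess import PreprocessConfig
from scin.synthetic import SyntheticSpec, generate_paired


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, labels=None, name="rna", prefix="c"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if labels is None:
        labels = ["A"] * n
    return ModalityTable(
        values=values,
        cell_ids=np.array([f"{prefix}{i}" for i in range(n)]),
        cell_types=np.asarray(labels),
        feature_ids=np.array([f"f{j}" for j in range(p)]),
        modality_name=name,
    )


@pytest.fixture
def tiny_paired(rng):
    """30 cells, 3 well-separated types, 8/6 features."""
    labels = np.repeat(["A", "B", "C"], 10)
    shift = {"A": 0.0, "B": 5.0, "C": 10.0}
    base = np.array([shift[t] for t in labels])[:, None]
    m1 = make_table(base + rng.normal(size=(30, 8)), labels, "rna")
    m2 = make_table(base + rng.normal(size=(30, 6)), labels, "atac",
                    prefix="c")
    return PairedDataset(m1, m2)


@pytest.fixture(scope="session")
def separable_dataset():
    """A small but cleanly separable paired dataset for training tests."""
    spec = SyntheticSpec(n_cells=400, n_types=5, p=60, q=60, latent_dim=8,
                         separation=6.0, noise_sd=1.0, seed=7)
    dataset, truth = generate_paired(spec)
    return dataset, truth


@pytest.fixture(scope="session")
def gaussian_preprocess():
    """Chain config for continuous (non-count) synthetic values."""
    return PreprocessConfig(normalize=False, log1p=False, scale=True, n_pcs=40)
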