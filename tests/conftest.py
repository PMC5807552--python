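import numpy as np
import pandas as pd
import pytest

import fluxscreen as fs


@pytest.fixture
def small_library() -> fs.LibraryDesign:
    """12 genes × 4 shRNAs with 4 barcoded samples."""
    return fs.simulate_library(
        n_ubiquitin=10, n_autophagy=2, total_shrnas=48, guide_length=20, seed=11
    )


@pytest.fixture
def tiny_library() -> fs.LibraryDesign:
    return fs.simulate_library(
        n_ubiquitin=2, n_autophagy=1, total_shrnas=6, guide_length=12, seed=3
    )


def make_counts(values: dict[str, list[int]], shrna_ids: list[str]) -> fs.CountMatrix:
    """Build a CountMatrix from per-sample count lists."""
    df = pd.DataFrame(values, index=pd.Index(shrna_ids, name="shrna_id"), dtype=np.int64)
    return fs.CountMatrix(counts=df)


# The nine published hit-table records used as a ranking worked example:
# (gene, number of scoring hairpins, average geomean of scoring hairpins).
PUBLISHED_HITS = [
    ("Atg7", 5, 21.60),
    ("Atg16l1", 4, 7.59),
    ("Birc6", 4, 3.18),
    ("Rb1cc1", 3, 14.33),
    ("Tsg101", 3, 7.15),
    ("Atg12", 3, 4.91),
    ("Sqstm1", 3, 3.77),
    ("Nedd8", 3, 3.05),
    ("Atg9a", 3, 3.03),
]


def published_hit_frame(shuffle_seed: int | None = None) -> pd.DataFrame:
    df = pd.DataFrame(PUBLISHED_HITS, columns=["gene", "n_scoring", "avg_geomean"])
    if shuffle_seed is not None:
        df = df.sample(frac=1.0, random_state=shuffle_seed).reset_index(drop=True)
    return df
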