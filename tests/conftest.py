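import numpy as np
import pandas as pd
import pytest

from blockcca import MultiblockDataset, SyntheticSpec, generate_multiblock


@pytest.fixture(scope="session")
def signal_dataset() -> MultiblockDataset:
    """Mid-size sequential-chain dataset with planted supports."""
    return generate_multiblock(SyntheticSpec(n_case=60, n_control=60, seed=123))


@pytest.fixture()
def toy_dataset() -> MultiblockDataset:
    """Tiny hand-checkable dataset: 8 subjects, 2 + 2 variables."""
    rng = np.random.default_rng(5)
    ids = pd.Index([f"S{i}" for i in range(8)], name="subject_id")
    pheno = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=ids, name="diagnosis")
    cov = pd.DataFrame({
        "age": [30, 41, 52, 38, 29, 44, 51, 36],
        "sex": [0, 1, 0, 1, 0, 1, 0, 1],
        "smoking": [1, 0, 1, 1, 0, 0, 1, 0],
    }, index=ids, dtype=float)
    blocks = {
        "rna": pd.DataFrame(rng.standard_normal((8, 2)), index=ids,
                            columns=["g1", "g2"]),
        "imaging": pd.DataFrame(rng.standard_normal((8, 2)), index=ids,
                                columns=["r1", "r2"]),
    }
    return MultiblockDataset(blocks=blocks, covariates=cov, phenotype=pheno)


def standardized_blocks(rng: np.random.Generator, n: int, widths) -> list:
    """Column-centered/scaled random blocks for engine-level tests."""
    out = []
    for p in widths:
        X = rng.standard_normal((n, p))
        X -= X.mean(axis=0)
        X /= X.std(axis=0, ddof=1)
        out.append(X)
    return out
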