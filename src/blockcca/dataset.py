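"""Aligned multiblock dataset: named data blocks, covariates and a binary phenotype.

Every stage of the pipeline consumes a :class:`MultiblockDataset` — a set of
subject-by-variable matrices (e.g. candidate-gene expression and ROI mean beta
values) measured on the same subjects, together with nuisance covariates
(age, sex, smoking) and a 0/1 diagnosis vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

COVARIATE_COLUMNS = ("age", "sex", "smoking")


@dataclass
class MultiblockDataset:
    """Subject-aligned data blocks plus phenotype and covariates.

    Parameters
    ----------
    blocks : dict of str -> pandas.DataFrame
        Named blocks, each ``n_subjects x p_j`` with unique column names and a
        shared index of subject identifiers.
    covariates : pandas.DataFrame
        ``n_subjects x q`` table; by convention columns ``age`` (years),
        ``sex`` (0/1) and ``smoking`` (0/1).
    phenotype : pandas.Series
        Binary diagnosis, 1 = patient, 0 = control, aligned to the blocks.
    """

    blocks: Dict[str, pd.DataFrame]
    covariates: pd.DataFrame
    phenotype: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.blocks) < 1:
            raise ValueError("at least one data block is required")
        index = self.phenotype.index
        for name, block in self.blocks.items():
            if not block.index.equals(index):
                raise ValueError(
                    f"block {name!r} subject index does not match phenotype index"
                )
            if block.columns.duplicated().any():
                dups = block.columns[block.columns.duplicated()].tolist()
                raise ValueError(f"duplicate variable names in block {name!r}: {dups}")
            if block.isna().any().any():
                raise ValueError(f"missing values in block {name!r}; reject, don't impute")
        if not self.covariates.index.equals(index):
            raise ValueError("covariate subject index does not match phenotype index")
        if self.covariates.isna().any().any():
            raise ValueError("missing values in covariates")
        if index.duplicated().any():
            raise ValueError("duplicate subject ids")
        values = set(pd.unique(self.phenotype))
        if not values <= {0, 1}:
            raise ValueError(f"phenotype must be coded 0/1, found {sorted(values)}")

    @property
    def n_subjects(self) -> int:
        return len(self.phenotype)

    @property
    def subject_ids(self) -> List[str]:
        return list(self.phenotype.index)

    @property
    def block_names(self) -> List[str]:
        return list(self.blocks)

    def block_matrix(self, name: str) -> np.ndarray:
        return self.blocks[name].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return self.phenotype.to_numpy(dtype=int)

    def subset(self, positions: np.ndarray) -> "MultiblockDataset":
        """Row-subset by integer positions (e.g. CV fold indices)."""
        return MultiblockDataset(
            blocks={k: v.iloc[positions] for k, v in self.blocks.items()},
            covariates=self.covariates.iloc[positions],
            phenotype=self.phenotype.iloc[positions],
            meta=dict(self.meta),
        )
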