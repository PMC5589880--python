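"""Univariate differential screening and per-block MANCOVA.

The screening fits, for every variable in every block, an ordinary linear
model ``variable ~ group + age + sex + smoking`` and reports the two-sided
p-value of the group coefficient, with Benjamini–Hochberg step-up adjustment
over an explicit family size (the published screening adjusted 47 printed
tests within a family of 52).  MANCOVA assesses each whole block at once:
a multivariate linear model of the block on group and covariates, summarized
by Pillai's trace (default) or Wilks' lambda with an F approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.multitest import multipletests

from .dataset import MultiblockDataset


class MancovaInfeasibleError(ValueError):
    """Raised when the block is too wide for a valid MANCOVA fit."""


@dataclass
class DifferentialTable:
    """Per-variable screening results (raw and optionally adjusted p-values)."""

    table: pd.DataFrame  # columns: variable, block, coef, raw_p [, adj_p]
    family_size: int
    method: str = "ols_group_t"

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class MancovaResult:
    """Per-factor multivariate test: statistic value, approximate F, p-value."""

    table: pd.DataFrame  # index: factor; columns: statistic, value, F, p
    statistic: str

    def p_value(self, factor: str = "group") -> float:
        return float(self.table.loc[factor, "p"])


def fit_group_models(dataset: MultiblockDataset) -> DifferentialTable:
    """OLS of each variable on [intercept, group, age, sex, smoking]; raw p only.

    The group coefficient's two-sided t-test p-value is reported per variable;
    no variance pooling across variables.
    """
    y = dataset.y()
    if len(np.unique(y)) < 2:
        raise ValueError("both diagnostic groups must be present")
    n = dataset.n_subjects
    if n <= 5:
        raise ValueError(f"need n > 5 subjects, got {n}")
    exog = sm.add_constant(
        np.column_stack([y.astype(float), dataset.covariates.to_numpy(dtype=float)])
    )
    rows = []
    for block_name, block in dataset.blocks.items():
        for var in block.columns:
            fit = sm.OLS(block[var].to_numpy(dtype=float), exog).fit()
            rows.append((var, block_name, fit.params[1], fit.pvalues[1]))
    table = pd.DataFrame(rows, columns=["variable", "block", "coef", "raw_p"])
    return DifferentialTable(table=table, family_size=len(table))


def adjust_bh(raw_p, m: Optional[int] = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with explicit family size ``m``.

    When ``m`` exceeds the number of supplied p-values, the missing family
    members are assumed to occupy the largest ranks (implemented by padding
    with p = 1 before the step-up pass).
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1:
        raise ValueError("raw_p must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of tests ({k})")
    padded = np.concatenate([p, np.ones(m - k)])
    adjusted = multipletests(padded, method="fdr_bh")[1]
    return adjusted[:k]


def differential_table(dataset: MultiblockDataset,
                       m: Optional[int] = None) -> DifferentialTable:
    """Screening plus BH adjustment, sorted ascending by raw p-value."""
    result = fit_group_models(dataset)
    k = len(result.table)
    family = m if m is not None else k
    table = result.table.copy()
    table["adj_p"] = adjust_bh(table["raw_p"].to_numpy(), m=family)
    table = table.sort_values("raw_p", kind="mergesort").reset_index(drop=True)
    return DifferentialTable(table=table, family_size=family, method=result.method)


_MANOVA_ROW = {"pillai": "Pillai's trace", "wilks": "Wilks' lambda"}


def mancova(block, covariates, phenotype, statistic: str = "pillai") -> MancovaResult:
    """Multivariate linear model of a block on group + age/sex/smoking.

    Raises :class:`MancovaInfeasibleError` when the number of response
    variables approaches the sample size, rather than returning a silently
    degenerate fit.
    """
    if statistic not in _MANOVA_ROW:
        raise ValueError(f"statistic must be one of {sorted(_MANOVA_ROW)}")
    Y = np.asarray(block, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, p = Y.shape
    q = cov.shape[1]
    if n <= p + q + 1:
        raise MancovaInfeasibleError(
            f"MANCOVA infeasible: n={n} must exceed p + q + 1 = {p + q + 1} "
            f"(block width {p}, {q} covariates)"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("both diagnostic groups must be present")
    exog = sm.add_constant(np.column_stack([y, cov]))
    cov_names = (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
                 else [f"cov_{j}" for j in range(q)])
    factors = ["group"] + cov_names
    mv = MANOVA(endog=Y, exog=exog)
    rows = []
    for i, factor in enumerate(factors):
        L = np.zeros((1, exog.shape[1]))
        L[0, i + 1] = 1.0
        res = mv.mv_test(hypotheses=[(factor, L, None)])
        stat = res.results[factor]["stat"]
        row = stat.loc[_MANOVA_ROW[statistic]]
        rows.append((factor, statistic, float(row["Value"]),
                     float(row["F Value"]), float(row["Pr > F"])))
    table = pd.DataFrame(rows, columns=["factor", "statistic", "value", "F", "p"])
    table = table.set_index("factor")
    return MancovaResult(table=table, statistic=statistic)
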