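"""TSV readers and writers for the pipeline's tables.

Three subject-indexed TSVs feed the pipeline: expression (subjects x genes),
imaging (subjects x ROIs) and a phenotype table carrying ``diagnosis`` plus
the ``age``/``sex``/``smoking`` covariates.  Subjects are aligned by id, so
row order across the files is irrelevant; misaligned subject sets are an
error naming the asymmetric ids.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import COVARIATE_COLUMNS, MultiblockDataset


def _read_table(path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate subject ids in {what} table: {dups}")
    if df.isna().any().any():
        raise ValueError(f"missing values in {what} table; reject, don't impute")
    return df


def read_dataset(expression_path, imaging_path, phenotype_path) -> MultiblockDataset:
    """Load and id-align the three tables into a :class:`MultiblockDataset`.

    The canonical subject order is sorted ids, so shuffled input rows yield
    an identical dataset.
    """
    expr = _read_table(expression_path, "expression")
    img = _read_table(imaging_path, "imaging")
    pheno = _read_table(phenotype_path, "phenotype")

    sets = {"expression": set(expr.index), "imaging": set(img.index),
            "phenotype": set(pheno.index)}
    common = sets["expression"] & sets["imaging"] & sets["phenotype"]
    problems = {name: sorted(ids - common) for name, ids in sets.items()
                if ids - common}
    if problems:
        raise ValueError(f"subject ids not shared by all tables: {problems}")

    order = sorted(common)
    expr, img, pheno = expr.loc[order], img.loc[order], pheno.loc[order]

    needed = ["diagnosis", *COVARIATE_COLUMNS]
    missing = [c for c in needed if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    diagnosis = pheno["diagnosis"]
    if not set(pd.unique(diagnosis)) <= {0, 1}:
        raise ValueError(
            f"diagnosis must be coded 0/1, found {sorted(pd.unique(diagnosis))}")

    return MultiblockDataset(
        blocks={"rna": expr, "imaging": img},
        covariates=pheno[list(COVARIATE_COLUMNS)].astype(float),
        phenotype=diagnosis.astype(int),
    )


def write_dataset(dataset: MultiblockDataset, outdir,
                  truth_sidecar: bool = True) -> dict:
    """Write expression/imaging/phenotype TSVs (+ JSON truth sidecar if present).

    Returns the mapping of table name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    names = dataset.block_names
    mapping = {"expression": names[0], "imaging": names[1] if len(names) > 1 else None}
    for fname, block in mapping.items():
        if block is None:
            continue
        path = outdir / f"{fname}.tsv"
        dataset.blocks[block].to_csv(path, sep="\t")
        paths[fname] = path
    pheno = dataset.covariates.copy()
    pheno.insert(0, "diagnosis", dataset.phenotype)
    paths["phenotype"] = outdir / "phenotype.tsv"
    pheno.to_csv(paths["phenotype"], sep="\t")

    truth = dataset.meta.get("truth")
    if truth_sidecar and truth is not None:
        payload = {
            "support_rna": list(truth["support_rna"]),
            "support_img": list(truth["support_img"]),
            "latent_rna": np.asarray(truth["latent_rna"]).tolist(),
            "latent_img": np.asarray(truth["latent_img"]).tolist(),
            "dx": np.asarray(truth["dx"]).tolist(),
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in vars(truth["spec"]).items()},
        }
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


def read_ct_table(path) -> pd.DataFrame:
    """Long-format Ct table (sample, gene, role, replicate, ct) from TSV."""
    df = pd.read_csv(path, sep="\t")
    needed = ["sample", "gene", "role", "replicate", "ct"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return df
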