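"""Relative quantification of qPCR Ct data: windowed reference selection and 2^-ddCt.

Targets are normalized against a reference gene of comparable expression
intensity: the Ct axis is partitioned into fixed windows (as published:
Ct < 22; 22–24; 24–25.5; 25.5–28.5; Ct > 30) and each target gene is paired
with the reference whose window contains the target's cross-sample mean Ct.
Relative quantity is then 2^-ddCt against a calibrator defined as the mean
of the control samples.  Note the printed window list leaves a 28.5–30 gap;
a target landing there is reported as unassigned rather than silently
snapped to a neighbor.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: half-open [low, high) expression-intensity windows on the Ct axis
DEFAULT_WINDOWS: Tuple[Tuple[Optional[float], Optional[float]], ...] = (
    (None, 22.0),
    (22.0, 24.0),
    (24.0, 25.5),
    (25.5, 28.5),
    (30.0, None),
)

REQUIRED_COLUMNS = ("sample", "gene", "role", "replicate", "ct")

ReferenceMap = Dict[str, Union[str, Tuple[str, str]]]


class WindowAssignmentError(ValueError):
    """Target mean Ct falls outside every configured window."""


def _validate_ct_table(ct: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (ct["ct"] <= 0).any() or ct["ct"].isna().any():
        raise ValueError("Ct values must be positive and non-missing")
    roles = set(ct["role"].unique())
    if not roles <= {"target", "reference"}:
        raise ValueError(f"unknown roles {sorted(roles - {'target', 'reference'})}")


def aggregate_triplicates(ct: pd.DataFrame, outlier_ct: float = 0.5) -> pd.DataFrame:
    """Mean Ct per (sample, gene) after dropping at most one outlying replicate.

    A replicate deviating more than ``outlier_ct`` cycles from the replicate
    median is discarded (the single worst one only); at least two replicates
    must remain.
    """
    _validate_ct_table(ct)

    def agg(values: pd.Series) -> float:
        v = values.to_numpy(dtype=float)
        dev = np.abs(v - np.median(v))
        if dev.max() > outlier_ct and len(v) >= 3:
            v = np.delete(v, int(np.argmax(dev)))
        if len(v) < 2:
            raise ValueError("fewer than 2 replicates after outlier drop")
        return float(v.mean())

    out = (ct.groupby(["sample", "gene", "role"], sort=False)["ct"]
             .apply(agg).reset_index())
    return out.rename(columns={"ct": "mean_ct"})


def _window_of(mean_ct: float,
               windows: Sequence[Tuple[Optional[float], Optional[float]]]) -> Optional[int]:
    for i, (lo, hi) in enumerate(windows):
        lo_ok = lo is None or mean_ct >= lo
        hi_ok = hi is None or mean_ct < hi
        if lo_ok and hi_ok:
            return i
    return None


def assign_reference(ct: pd.DataFrame,
                     windows: Sequence[Tuple[Optional[float], Optional[float]]] = DEFAULT_WINDOWS,
                     ) -> Dict[str, str]:
    """Map each target gene to the reference gene of its intensity window.

    Both targets and references are placed by their cross-sample mean Ct.
    When several references share a window the closest one (by mean Ct) is
    used.  A proximity warning is logged when the target-to-reference mean
    distance is >= 2 Ct.
    """
    agg = aggregate_triplicates(ct)
    gene_means = agg.groupby(["gene", "role"], sort=False)["mean_ct"].mean().reset_index()
    refs = gene_means[gene_means["role"] == "reference"]
    targets = gene_means[gene_means["role"] == "target"]
    if refs.empty:
        raise ValueError("no reference genes in the Ct table")

    ref_windows: Dict[int, List[Tuple[str, float]]] = {}
    for _, row in refs.iterrows():
        w = _window_of(row["mean_ct"], windows)
        if w is not None:
            ref_windows.setdefault(w, []).append((row["gene"], row["mean_ct"]))

    mapping: Dict[str, str] = {}
    for _, row in targets.iterrows():
        gene, mean_ct = row["gene"], row["mean_ct"]
        w = _window_of(mean_ct, windows)
        if w is None:
            raise WindowAssignmentError(
                f"target {gene!r} mean Ct {mean_ct:.2f} falls in a gap between "
                f"the configured windows; assign a reference explicitly"
            )
        if w not in ref_windows:
            raise ValueError(
                f"no reference gene available in window {windows[w]} "
                f"needed by target {gene!r}"
            )
        ref_gene, ref_ct = min(ref_windows[w], key=lambda rc: abs(rc[1] - mean_ct))
        if abs(mean_ct - ref_ct) >= 2.0:
            logger.warning(
                "target %s (mean Ct %.2f) is >= 2 Ct from its reference %s (%.2f)",
                gene, mean_ct, ref_gene, ref_ct)
        mapping[gene] = ref_gene
    return mapping


def relative_quantity(ct: pd.DataFrame, reference_map: ReferenceMap,
                      calibrator_samples: Iterable[str]) -> pd.DataFrame:
    """Samples x genes table of RQ = 2^-ddCt fold changes.

    dCt = mean target Ct - mean reference Ct per sample (averaged over the
    two references when a pair is configured); ddCt subtracts the mean dCt
    over the calibrator samples (the control group), so the calibrator's
    geometric-mean RQ is 1 per gene.
    """
    calibrators = list(calibrator_samples)
    if not calibrators:
        raise ValueError("calibrator sample set must be non-empty")
    agg = aggregate_triplicates(ct)
    mean_ct = agg.set_index(["sample", "gene"])["mean_ct"]
    samples = list(dict.fromkeys(agg["sample"]))
    missing_cal = [s for s in calibrators if s not in set(samples)]
    if missing_cal:
        raise ValueError(f"calibrator samples absent from the Ct table: {missing_cal}")

    rq = pd.DataFrame(index=pd.Index(samples, name="sample"),
                      columns=sorted(reference_map), dtype=float)
    for gene, refs in reference_map.items():
        ref_genes = (refs,) if isinstance(refs, str) else tuple(refs)
        dct = []
        for sample in samples:
            try:
                target_ct = mean_ct[(sample, gene)]
                ref_cts = [mean_ct[(sample, r)] for r in ref_genes]
            except KeyError as exc:
                raise ValueError(
                    f"missing Ct for sample {sample!r}, gene {exc.args[0][1]!r}"
                ) from None
            dct.append(float(np.mean([target_ct - rc for rc in ref_cts])))
        dct = pd.Series(dct, index=samples)
        ddct = dct - dct.loc[calibrators].mean()
        rq[gene] = np.exp2(-ddct)
    return rq
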