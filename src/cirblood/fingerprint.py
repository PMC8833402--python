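"""Per-patient stable-gene fingerprints and sample correlation clustering.

A patient's "fingerprint" is the set of genes that are simultaneously
highly abundant (within-patient median above its 97.5% quantile) and
nearly invariant over the serial samples (within-patient raw MAD below its
2.5% quantile).  Quantiles are linear-interpolation (type 7) and the
inequalities are strict, so degenerate all-equal distributions select
nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import AnalysisConfig
from .io import ExpressionMatrix, ValidationError
from .preprocess import gene_median_mad

log = logging.getLogger(__name__)


@dataclass
class FingerprintSet:
    patient_id: str
    genes: list[str]
    q_mad: float
    q_med: float
    n_timepoints: int


def select_stable_genes(x: ExpressionMatrix, meta: pd.DataFrame,
                        patient_id: str,
                        cfg: AnalysisConfig) -> FingerprintSet:
    """Stable highly-expressed genes for one patient's serial samples."""
    samples = meta.loc[meta["patient_id"] == patient_id, "sample_id"]
    samples = [s for s in samples if s in set(x.sample_ids)]
    if len(samples) < 2:
        raise ValidationError(
            f"patient {patient_id!r} has fewer than 2 samples")
    vals = x.data[samples].to_numpy()
    med, mad = gene_median_mad(vals)
    q_mad = float(np.quantile(mad, cfg.mad_quantile))
    q_med = float(np.quantile(med, cfg.median_quantile))
    sel = (mad < q_mad) & (med > q_med)
    genes = [g for g, s in zip(x.gene_ids, sel) if s]
    return FingerprintSet(patient_id=patient_id, genes=genes,
                          q_mad=q_mad, q_med=q_med,
                          n_timepoints=len(samples))


def fingerprint_union(sets: list[FingerprintSet]) -> pd.DataFrame:
    """Sorted union of per-patient selections with contribution counts."""
    if not sets:
        raise ValueError("need at least one fingerprint set")
    counts: dict[str, int] = {}
    for fs in sets:
        for g in fs.genes:
            counts[g] = counts.get(g, 0) + 1
    return pd.DataFrame(
        {"gene_id": sorted(counts), "n_patients": [counts[g] for g in sorted(counts)]})


@dataclass
class CorrelationClustering:
    correlation: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series
    excluded: list[str]


def correlation_cluster(x: ExpressionMatrix,
                        cfg: AnalysisConfig) -> CorrelationClustering:
    """Pearson sample-sample correlation + hierarchical clustering on 1-r.

    Zero-variance sample columns are excluded with a warning.  Leaf order
    is made deterministic by clustering samples in sorted-ID order.
    """
    if x.n_samples < 2 or x.n_genes < 2:
        raise ValidationError("need at least 2 samples and 2 genes")
    order = sorted(x.sample_ids)
    vals = x.data[order].to_numpy()
    sds = vals.std(axis=0)
    excluded = [s for s, sd in zip(order, sds) if sd == 0]
    if excluded:
        log.warning("excluding zero-variance sample(s): %s", excluded)
        keep = sds > 0
        order = [s for s, k in zip(order, keep) if k]
        vals = vals[:, keep]
    if len(order) < 2:
        raise ValidationError("fewer than 2 samples with nonzero variance")
    r = np.corrcoef(vals.T)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=order, columns=order)
    dist = squareform(1.0 - r, checks=False)
    Z = hierarchy.linkage(dist, method=cfg.linkage_method)
    labels = pd.Series(hierarchy.fcluster(Z, t=cfg.cluster_k,
                                          criterion="maxclust"),
                       index=order, name="cluster")
    return CorrelationClustering(correlation=corr, linkage=Z,
                                 labels=labels, excluded=excluded)
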