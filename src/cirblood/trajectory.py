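"""Longitudinal trajectory analysis.

Each patient's longitudinal change is summarized as the concatenated
vector of consecutive-timepoint expression differences over the
most-variant gene set (shift-invariant, uses every longitudinal segment).
Patients with complete series are Pearson-correlated and hierarchically
clustered into two groups; incomplete-series patients are assigned to the
cluster with the highest mean correlation over shared delta segments.
Baseline marker genes separating the two groups are then screened with
Welch t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import AnalysisConfig
from .io import ExpressionMatrix, ValidationError
from .preprocess import top_variant_genes
from .stats import screen_frame

log = logging.getLogger(__name__)


@dataclass
class DeltaProfiles:
    """Per-patient concatenated consecutive-timepoint difference vectors.

    ``segments[p]`` maps a patient to the list of (t, t+1) pairs used;
    ``vectors[p]`` is the concatenated difference vector (one block of
    ``len(genes)`` per segment, in timepoint order).
    """

    genes: list[str]
    vectors: dict[str, np.ndarray]
    segments: dict[str, list[tuple[int, int]]]
    excluded: list[str]


def delta_profiles(x: ExpressionMatrix, meta: pd.DataFrame,
                   cfg: AnalysisConfig,
                   genes: list[str] | None = None) -> DeltaProfiles:
    """Consecutive-timepoint differences over the top-variant gene set."""
    if genes is None:
        genes = top_variant_genes(x, cfg.top_variant_fraction)
    sub = x.data.loc[genes]
    vectors: dict[str, np.ndarray] = {}
    segments: dict[str, list[tuple[int, int]]] = {}
    excluded: list[str] = []
    for pid, grp in meta.groupby("patient_id", sort=True):
        tp_to_sample = dict(zip(grp["timepoint"], grp["sample_id"]))
        segs = [(t, t + 1) for t in range(3)
                if t in tp_to_sample and t + 1 in tp_to_sample]
        if not segs:
            excluded.append(pid)
            log.info("patient %s excluded: no consecutive timepoint pair", pid)
            continue
        blocks = [sub[tp_to_sample[t2]].to_numpy()
                  - sub[tp_to_sample[t1]].to_numpy() for t1, t2 in segs]
        vectors[pid] = np.concatenate(blocks)
        segments[pid] = segs
    if not vectors:
        raise ValidationError("no patient has two consecutive timepoints")
    return DeltaProfiles(genes=list(genes), vectors=vectors,
                         segments=segments, excluded=excluded)


@dataclass
class TrajectoryResult:
    correlation: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series                # 'A'/'B' per patient
    assignment: pd.Series            # 'core' or 'nearest-centroid'
    markers: pd.DataFrame | None = None


def _segment_corr(d: DeltaProfiles, p1: str, p2: str) -> float:
    """Pearson correlation of two patients over their shared segments."""
    shared = [s for s in d.segments[p1] if s in d.segments[p2]]
    if not shared:
        return np.nan
    G = len(d.genes)

    def pick(p):
        segs = d.segments[p]
        idx = np.concatenate([np.arange(G) + segs.index(s) * G
                              for s in shared])
        return d.vectors[p][idx]

    a, b = pick(p1), pick(p2)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def cluster_trajectories(d: DeltaProfiles,
                         cfg: AnalysisConfig) -> TrajectoryResult:
    """Correlation clustering of complete-series patients into k groups.

    Incomplete-series patients are assigned post hoc to the cluster whose
    core members correlate best with them on shared segments.  Cluster
    names A/B are fixed by sorted order of the lowest patient ID in each
    cluster, so labels are invariant to input order.
    """
    complete = sorted(p for p, segs in d.segments.items() if len(segs) == 3)
    partial = sorted(p for p in d.vectors if p not in complete)
    if len(complete) < cfg.cluster_k:
        raise ValidationError(
            f"{len(complete)} complete-series patients < cluster_k "
            f"{cfg.cluster_k}")
    mat = np.stack([d.vectors[p] for p in complete])
    sds = mat.std(axis=1)
    if np.any(sds == 0):
        raise ValidationError(
            "zero-variance delta vector(s): clustering degenerate for "
            f"{[p for p, s in zip(complete, sds) if s == 0]}")
    r = np.corrcoef(mat)
    r = np.clip((r + r.T) / 2, -1, 1)
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=complete, columns=complete)
    Z = hierarchy.linkage(squareform(1 - r, checks=False),
                          method=cfg.linkage_method)
    raw = hierarchy.fcluster(Z, t=cfg.cluster_k, criterion="maxclust")
    # stable names: cluster containing the smallest patient ID is 'A'
    name_of: dict[int, str] = {}
    for lab in raw[np.argsort(complete)]:
        if lab not in name_of:
            name_of[lab] = chr(ord("A") + len(name_of))
    labels = {p: name_of[lab] for p, lab in zip(complete, raw)}
    assignment = {p: "core" for p in complete}
    for p in partial:
        means = {}
        for cname in sorted(set(labels.values())):
            cors = [c for q in complete if labels[q] == cname
                    if not np.isnan(c := _segment_corr(d, p, q))]
            means[cname] = np.mean(cors) if cors else -np.inf
        labels[p] = max(sorted(means), key=lambda c: means[c])
        assignment[p] = "nearest-centroid"
    pats = sorted(labels)
    return TrajectoryResult(
        correlation=corr, linkage=Z,
        labels=pd.Series([labels[p] for p in pats], index=pats, name="group"),
        assignment=pd.Series([assignment[p] for p in pats], index=pats,
                             name="assignment"))


def trajectory_marker_screen(x: ExpressionMatrix, meta: pd.DataFrame,
                             labels: pd.Series,
                             cfg: AnalysisConfig) -> pd.DataFrame:
    """Baseline (pre-treatment) Welch t-screen between trajectory groups.

    Markers are ranked by adjusted p, then by absolute effect size.
    """
    base = meta.loc[meta["timepoint"] == 0].copy()
    base["group"] = base["patient_id"].map(labels)
    groups = sorted(base["group"].dropna().unique())
    if len(groups) < 2:
        raise ValidationError("both trajectory clusters need baseline samples")
    ga = base.loc[base["group"] == groups[0], "sample_id"]
    gb = base.loc[base["group"] == groups[1], "sample_id"]
    if len(ga) == 0 or len(gb) == 0:
        raise ValidationError("a cluster has no baseline sample")
    A = x.data[list(ga)].to_numpy()
    B = x.data[list(gb)].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=1, equal_var=False)
    est = A.mean(axis=1) - B.mean(axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    out = screen_frame(x.gene_ids, est, p, "BH", cfg.fdr_strict)
    out["test_name"] = "welch_baseline_groups"
    out = out.sort_values(["adj_p", "estimate"],
                          key=lambda s: -s.abs() if s.name == "estimate" else s,
                          kind="mergesort").reset_index(drop=True)
    return out
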