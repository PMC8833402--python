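"""Dose-dependent screens.

Three stages mirror the analysis design:

1. ``interaction_screen`` - per gene, a rank-based Wald-type test of the
   dose x time interaction between baseline and one post-treatment
   timepoint (dose categorical at 30/33/36 GyRBE), BH-adjusted.
2. ``equivalence_prescreen`` - per gene, pairwise TOST equivalence of
   baseline expression between dose arms; the margin is expressed in
   pooled-SD units since no absolute margin is reported.  A gene passes
   when all three pairs are equivalent at the TOST alpha (no multiplicity
   adjustment, per the printed rule).
3. ``post_only_interaction`` - for prescreen passers only, a linear mixed
   model on post-treatment samples with a numeric time x standardized
   dose interaction, ranked by unadjusted p with a p < 0.001 highlight
   tier and a full BH column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import ExpressionMatrix, ValidationError
from .simulate import DOSE_Z
from .stats import (DesignError, bh_adjust, tost_equivalence,
                    wts_rank_interaction, mixed_model_wald, screen_frame)

log = logging.getLogger(__name__)

DOSE_PAIRS = ((30, 33), (30, 36), (33, 36))


def equivalence_prescreen(x: ExpressionMatrix, meta: pd.DataFrame,
                          cfg: AnalysisConfig) -> pd.DataFrame:
    """Pairwise TOST equivalence of baseline expression across dose arms.

    Returns one row per gene with the three pairwise TOST p-values and a
    ``passes`` flag (all three p < tost_alpha).  The per-gene margin is
    ``tost_margin_sd`` times the pooled baseline SD of that gene.
    """
    base = meta.loc[meta["timepoint"] == 0]
    arms = {d: list(base.loc[base["dose_total"] == d, "sample_id"])
            for d in (30, 33, 36)}
    for d, ids in arms.items():
        if len(ids) < 2:
            raise DesignError(
                f"dose arm {d} GyRBE has {len(ids)} baseline samples (<2)")
    vals = {d: x.data[ids].to_numpy() for d, ids in arms.items()}
    all_base = np.concatenate(list(vals.values()), axis=1)
    pooled_sd = all_base.std(axis=1, ddof=1)
    margins = cfg.tost_margin_sd * pooled_sd

    rows = []
    for i, g in enumerate(x.gene_ids):
        ps = {}
        degenerate = margins[i] <= 0
        for d1, d2 in DOSE_PAIRS:
            if degenerate:
                ps[f"tost_p_{d1}v{d2}"] = np.nan
                continue
            r = tost_equivalence(vals[d1][i], vals[d2][i],
                                 margin=float(margins[i]),
                                 alpha=cfg.tost_alpha)
            ps[f"tost_p_{d1}v{d2}"] = r.p
        passes = (not degenerate
                  and all(p < cfg.tost_alpha for p in ps.values()))
        rows.append({"gene_id": g, **ps, "passes": passes})
    return pd.DataFrame(rows)


def interaction_screen(x: ExpressionMatrix, meta: pd.DataFrame,
                       cfg: AnalysisConfig, comparison: int) -> pd.DataFrame:
    """Rank WTS of the dose x time interaction, baseline vs post ``comparison``."""
    if comparison not in (1, 2, 3):
        raise ValueError("comparison must be 1, 2 or 3")
    m = meta.loc[meta["timepoint"].isin([0, comparison])]
    dose = m["dose_total"].to_numpy()
    tp = m["timepoint"].to_numpy()
    vals = x.data[list(m["sample_id"])].to_numpy()
    raw = np.full(x.n_genes, np.nan)
    est = np.full(x.n_genes, np.nan)
    for i in range(x.n_genes):
        try:
            r = wts_rank_interaction(vals[i], dose, tp)
        except DesignError as exc:
            log.info("gene %s skipped in 0v%d interaction screen: %s",
                     x.gene_ids[i], comparison, exc)
            continue
        raw[i] = r.p
        # signed summary: high-dose post shift minus low-dose post shift
        re = r.relative_effects
        est[i] = (re[-1, -1] - re[-1, 0]) - (re[0, -1] - re[0, 0])
    ok = ~np.isnan(raw)
    out = screen_frame(np.asarray(x.gene_ids)[ok], est[ok], raw[ok],
                       "BH", cfg.fdr_strict)
    out["test_name"] = f"wts_dose_x_time_0v{comparison}"
    return out


def post_only_interaction(x: ExpressionMatrix, meta: pd.DataFrame,
                          prescreened: list[str],
                          cfg: AnalysisConfig,
                          highlight_p: float = 1e-3) -> pd.DataFrame:
    """Mixed-model time x dose interaction on post-treatment samples only.

    Restricted to prescreen passers; dose enters numerically (z-coded
    -1/0/+1), time numerically (1-3), with a patient random intercept.
    Output is ranked by unadjusted interaction p and carries a
    ``highlight`` tier (p < 0.001) plus a BH column.
    """
    if not prescreened:
        log.warning("no prescreen passers; post-only interaction is empty")
        return pd.DataFrame(columns=["gene_id", "estimate", "raw_p", "adj_p",
                                     "adjustment", "significant", "highlight",
                                     "test_name"])
    post = meta.loc[meta["timepoint"] > 0]
    if post["timepoint"].nunique() < 2:
        raise DesignError("need at least 2 post-treatment timepoints")
    t = post["timepoint"].to_numpy(float)
    z = post["dose_total"].map(DOSE_Z).to_numpy(float)
    fixed = pd.DataFrame({"time": t, "dose_z": z, "time_x_dose": t * z})
    groups = post["patient_id"].to_numpy()
    genes = [g for g in x.gene_ids if g in set(prescreened)]
    vals = x.data.loc[genes, list(post["sample_id"])].to_numpy()
    est = np.empty(len(genes))
    raw = np.empty(len(genes))
    for i in range(len(genes)):
        r = mixed_model_wald(vals[i], fixed, groups)
        est[i] = r.params["time_x_dose"]
        raw[i] = r.pvalues["time_x_dose"]
    out = screen_frame(genes, est, raw, "BH", cfg.fdr_strict)
    out["highlight"] = out["raw_p"] < highlight_p
    out["test_name"] = "mixed_post_only_time_x_dose"
    return out.sort_values("raw_p", kind="mergesort").reset_index(drop=True)


def dose_call_table(prescreen: pd.DataFrame,
                    interactions: dict[int, pd.DataFrame],
                    post_only: pd.DataFrame) -> pd.DataFrame:
    """Pure join of the three stages on gene_id (one row per gene)."""
    out = prescreen.copy()
    for t, scr in sorted(interactions.items()):
        cols = scr[["gene_id", "raw_p", "adj_p"]].rename(
            columns={"raw_p": f"int_raw_p_0v{t}", "adj_p": f"int_adj_p_0v{t}"})
        out = out.merge(cols, on="gene_id", how="left")
    if len(post_only):
        cols = post_only[["gene_id", "raw_p"]].rename(
            columns={"raw_p": "post_only_p"})
        out = out.merge(cols, on="gene_id", how="left")
    else:
        out["post_only_p"] = np.nan
    return out
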