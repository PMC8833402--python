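"""Pre/post-treatment time-effect screens and dynamics classification.

Global screens test for any difference across the four timepoints with
the rank-based ANOVA-type statistic; pairwise screens restrict to the
baseline and one post-treatment timepoint.  BH adjustment is applied
within each screen family.  Genes passing a screen are assigned to one of
four temporal response classes by thresholded baseline contrasts on their
mean z-profiles:

1. sustained decrease, 2. decrease then return/overshoot,
3. steady or late decrease, 4. early sustained increase.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import ExpressionMatrix, ValidationError
from .preprocess import top_variant_genes, z_transform_genes, residualize_covariates
from .stats import ats_test, screen_frame, DesignError

log = logging.getLogger(__name__)

ADJUST_COVARIATES = ["sex", "age", "grade_initial"]


def time_effect_screen(x: ExpressionMatrix, meta: pd.DataFrame,
                       cfg: AnalysisConfig, mode: str = "global",
                       gene_set: str = "top-variant",
                       post_timepoint: int | None = None) -> pd.DataFrame:
    """Rank-based time-effect screen.

    ``mode='global'`` tests all four timepoints per gene; ``'pairwise'``
    tests baseline against ``post_timepoint``.  The strict tier (FDR <
    fdr_strict) applies to the top-variant set, the liberal tier (FDR <
    fdr_liberal) to all genes.  Genes whose design is untestable (e.g.
    observed only pre-treatment) are excluded with a logged reason.
    """
    if mode not in ("global", "pairwise"):
        raise ValueError("mode must be 'global' or 'pairwise'")
    if mode == "pairwise":
        if post_timepoint not in (1, 2, 3):
            raise ValueError("pairwise mode needs post_timepoint in {1,2,3}")
        keep = meta["timepoint"].isin([0, post_timepoint]).to_numpy()
    else:
        keep = np.ones(len(meta), bool)
    m = meta.loc[keep]
    sub = ExpressionMatrix(x.data[list(m["sample_id"])])

    if gene_set == "top-variant":
        genes = top_variant_genes(x, cfg.top_variant_fraction)
        threshold = cfg.fdr_strict
    elif gene_set == "all":
        genes = list(x.gene_ids)
        threshold = cfg.fdr_liberal
    else:
        raise ValueError("gene_set must be 'top-variant' or 'all'")
    if not genes:
        raise ValidationError("no genes to screen")

    n_base = (m.groupby("patient_id")["timepoint"]
              .agg(lambda t: (t == 0).any() and (t > 0).any()).sum())
    if n_base < 3:
        raise DesignError("need >=3 patients with baseline plus a post sample")

    subj = m["patient_id"].to_numpy()
    tp = m["timepoint"].to_numpy()
    vals = sub.data.loc[genes].to_numpy()
    raw = np.full(len(genes), np.nan)
    est = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        try:
            r = ats_test(vals[i], subj, tp)
        except DesignError as exc:
            log.info("gene %s excluded from %s screen: %s",
                     genes[i], mode, exc)
            continue
        raw[i] = r.p
        est[i] = r.relative_effects[-1] - r.relative_effects[0]
    ok = ~np.isnan(raw)
    out = screen_frame(np.asarray(genes)[ok], est[ok], raw[ok], "BH", threshold)
    out["test_name"] = f"ats_{mode}" + (
        f"_0v{post_timepoint}" if mode == "pairwise" else "")
    return out


def classify_dynamics(profile, tau: float) -> str:
    """Assign a mean z-profile (m0..m3) to a dynamics class.

    With e1 = m1-m0 and e3 = m3-m0: class 1 when both drop below -tau;
    class 2 when the early drop recovers; class 3 when the change is late;
    class 4 when both rise above tau; otherwise 'unclassified'.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size != 4 or np.any(~np.isfinite(profile)):
        return "unclassified"
    e1 = profile[1] - profile[0]
    e3 = profile[3] - profile[0]
    if e1 <= -tau and e3 <= -tau:
        return "1"
    if e1 <= -tau and e3 > -tau:
        return "2"
    if abs(e1) < tau and e3 <= -tau:
        return "3"
    if e1 >= tau and e3 >= tau:
        return "4"
    return "unclassified"


def mean_z_profiles(x: ExpressionMatrix, meta: pd.DataFrame,
                    genes: list[str], adjust: bool = True) -> pd.DataFrame:
    """Mean z-profile per gene and timepoint on covariate-adjusted data.

    Expression is residualized on sex, age and initial grade, then
    z-transformed gene-wise; means are taken over samples per timepoint.
    """
    work = residualize_covariates(x, meta, ADJUST_COVARIATES) if adjust else x
    z, _ = z_transform_genes(work)
    prof = np.full((len(genes), 4), np.nan)
    vals = z.data.loc[genes]
    tp = meta["timepoint"].to_numpy()
    for t in range(4):
        sel = tp == t
        if sel.any():
            prof[:, t] = vals.to_numpy()[:, sel].mean(axis=1)
    return pd.DataFrame(prof, index=genes, columns=[f"m{t}" for t in range(4)])


def dynamics_calls(x: ExpressionMatrix, meta: pd.DataFrame,
                   cfg: AnalysisConfig,
                   screen: pd.DataFrame) -> pd.DataFrame:
    """Classify screen-passing genes into the four dynamics classes."""
    hits = list(screen.loc[screen["significant"], "gene_id"])
    prof = mean_z_profiles(x, meta, hits) if hits else pd.DataFrame(
        columns=["m0", "m1", "m2", "m3"])
    cls = [classify_dynamics(prof.loc[g].to_numpy(), cfg.dynamics_tau)
           for g in hits]
    out = prof.reset_index(names="gene_id")
    out["dynamics_class"] = cls
    return out


def pairwise_overlap(screens: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Venn-style overlap of significant genes across pairwise screens."""
    sets = {t: set(s.loc[s["significant"], "gene_id"])
            for t, s in screens.items()}
    tps = sorted(sets)
    rows = []
    for t in tps:
        rows.append((f"0v{t}", len(sets[t])))
    for i, t1 in enumerate(tps):
        for t2 in tps[i + 1:]:
            rows.append((f"0v{t1}&0v{t2}", len(sets[t1] & sets[t2])))
    if len(tps) >= 3:
        inter = set.intersection(*sets.values())
        rows.append(("&".join(f"0v{t}" for t in tps), len(inter)))
    return pd.DataFrame(rows, columns=["comparison", "n_genes"])
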