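"""Covariate, seed-gene and signature association screens.

Covariate screens run gene-wise random-intercept mixed models on the
most-variant genes with BH adjustment.  Seed-gene screens regress every
other gene on a chosen seed gene by plain OLS with Bonferroni adjustment
(matching the source analyses' "linear models"); a mixed-model variant is
available behind a flag.  Signature scores are per-sample means of
z-transformed member genes.  Grade separability of a 2-D embedding is
quantified by the AIC of a logistic model with both coordinates and their
interaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import AnalysisConfig
from .io import ExpressionMatrix, ValidationError
from .preprocess import top_variant_genes, z_transform_genes, GRADE_NUMERIC
from .stats import mixed_model_wald, screen_frame, DesignError

log = logging.getLogger(__name__)

COVARIATES = ("sex", "age", "grade_initial", "grade_rert")


def _covariate_vector(meta: pd.DataFrame, covariate: str) -> np.ndarray:
    if covariate == "sex":
        return (meta["sex"] == "female").to_numpy(float)
    if covariate == "age":
        return meta["age"].to_numpy(float)
    if covariate == "grade_initial":
        return meta["grade_initial"].map(GRADE_NUMERIC).to_numpy(float)
    if covariate == "grade_rert":
        return (meta["grade_rert"] == "IV").to_numpy(float)
    raise ValueError(f"unknown covariate {covariate!r}")


def covariate_screen(x: ExpressionMatrix, meta: pd.DataFrame,
                     covariate: str, cfg: AnalysisConfig) -> pd.DataFrame:
    """Mixed-model association of each top-variant gene with one covariate."""
    if covariate not in COVARIATES:
        raise ValueError(f"covariate must be one of {COVARIATES}")
    v = _covariate_vector(meta, covariate)
    if np.unique(v).size < 2:
        raise ValidationError(f"covariate {covariate!r} is constant")
    genes = top_variant_genes(x, cfg.top_variant_fraction)
    if not genes:
        raise ValidationError("no genes selected for screening")
    fixed = pd.DataFrame({covariate: v})
    groups = meta["patient_id"].to_numpy()
    est = np.empty(len(genes))
    raw = np.empty(len(genes))
    sub = x.data.loc[genes].to_numpy()
    for i in range(len(genes)):
        r = mixed_model_wald(sub[i], fixed, groups)
        est[i] = r.params[covariate]
        raw[i] = r.pvalues[covariate]
    out = screen_frame(genes, est, raw, "BH", cfg.fdr_strict)
    out["test_name"] = "mixed_model_wald"
    return out


def seed_gene_screen(x: ExpressionMatrix, seed_gene: str,
                     cfg: AnalysisConfig, mixed: bool = False,
                     meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Regress every other gene on the seed gene's expression.

    OLS across all samples by default; ``mixed=True`` adds a patient
    random intercept (requires ``meta``) and logs where the two disagree.
    """
    if seed_gene not in set(x.gene_ids):
        raise ValidationError(f"seed gene {seed_gene!r} not in matrix")
    s = x.data.loc[seed_gene].to_numpy(float)
    if s.std() == 0:
        raise ValidationError(f"seed gene {seed_gene!r} is constant")
    others = [g for g in x.gene_ids if g != seed_gene]
    Y = x.data.loc[others].to_numpy()
    if mixed:
        if meta is None:
            raise ValueError("mixed seed-gene screen needs metadata")
        fixed = pd.DataFrame({"seed": s})
        groups = meta["patient_id"].to_numpy()
        est = np.empty(len(others))
        raw = np.empty(len(others))
        for i in range(len(others)):
            r = mixed_model_wald(Y[i], fixed, groups)
            est[i] = r.params["seed"]
            raw[i] = r.pvalues["seed"]
    else:
        # vectorized simple OLS: slope, t, two-sided p
        n = s.size
        sc = s - s.mean()
        ssx = float(sc @ sc)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        slope = (Yc @ sc) / ssx
        resid = Yc - np.outer(slope, sc)
        sigma2 = (resid ** 2).sum(axis=1) / (n - 2)
        se = np.sqrt(sigma2 / ssx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
        from scipy import stats as sps
        raw = 2 * sps.t.sf(np.abs(t), n - 2)
        est = slope
    out = screen_frame(others, est, raw, "Bonferroni", cfg.bonferroni_alpha)
    out["test_name"] = "mixed_model_wald" if mixed else "ols"
    return out


@dataclass
class SignatureResult:
    scores: pd.DataFrame          # signature x sample score matrix
    trend_tests: pd.DataFrame     # per-signature grade-trend Wald test
    linkage: np.ndarray | None
    skipped: list[str]


def signature_score(x: ExpressionMatrix, signatures: dict[str, list[str]],
                    meta: pd.DataFrame | None = None) -> SignatureResult:
    """Per-sample signature scores (mean of z-transformed member genes).

    Genes absent from the matrix are dropped and counted; signatures with
    no present genes are flagged and excluded.  When metadata is given,
    each signature score is tested for a numeric initial-grade trend with
    a patient random-intercept model, and signatures are hierarchically
    clustered on score correlation.
    """
    if not signatures:
        raise ValueError("no signatures given")
    z, _ = z_transform_genes(x)
    rows, names, used, skipped = [], [], [], []
    for name, genes in signatures.items():
        if not genes:
            raise ValueError(f"signature {name!r} is empty")
        present = [g for g in genes if g in set(x.gene_ids)]
        if not present:
            skipped.append(name)
            log.warning("signature %r has no genes in the matrix", name)
            continue
        rows.append(z.data.loc[present].to_numpy().mean(axis=0))
        names.append(name)
        used.append(len(present))
    if not rows:
        raise ValidationError("no signature has genes in the matrix")
    scores = pd.DataFrame(rows, index=names, columns=x.sample_ids)
    scores.insert(0, "n_genes_used", used)

    trend = pd.DataFrame()
    Z = None
    if meta is not None:
        grade = pd.DataFrame(
            {"grade": meta["grade_initial"].map(GRADE_NUMERIC).to_numpy(float)})
        groups = meta["patient_id"].to_numpy()
        recs = []
        for name in names:
            r = mixed_model_wald(
                scores.loc[name, x.sample_ids].to_numpy(float), grade, groups)
            recs.append((name, r.params["grade"], r.pvalues["grade"]))
        trend = pd.DataFrame(recs, columns=["signature", "estimate", "raw_p"])
    if len(names) >= 3:
        m = scores[x.sample_ids].to_numpy(float)
        r = np.corrcoef(m)
        Z = hierarchy.linkage(squareform(1 - np.clip(r, -1, 1), checks=False),
                              method="complete")
    return SignatureResult(scores=scores, trend_tests=trend,
                           linkage=Z, skipped=skipped)


@dataclass
class EmbeddingAic:
    aic: float
    timepoint: int
    n: int
    separation: bool
    flagged: bool
    reason: str = ""


def compute_embedding(x: ExpressionMatrix, method: str = "tsne",
                      seed: int = 0) -> pd.DataFrame:
    """2-D sample embedding (t-SNE via scikit-learn, or UMAP)."""
    vals = x.values.T
    if method == "tsne":
        from sklearn.manifold import TSNE
        perp = min(30.0, max(2.0, (vals.shape[0] - 1) / 3))
        emb = TSNE(n_components=2, perplexity=perp, random_state=seed,
                   init="pca").fit_transform(vals)
    elif method == "umap":
        import umap
        emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(vals)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(emb, index=x.sample_ids, columns=["d1", "d2"])


def embedding_aic(coords: pd.DataFrame, meta: pd.DataFrame,
                  grade_definition: str, timepoint: int) -> EmbeddingAic:
    """AIC of logistic grade-IV separation on a 2-D embedding, per timepoint.

    Model: I(grade IV) ~ d1 + d2 + d1*d2 (4 parameters); AIC = -2 loglik + 8.
    Perfect separation is reported with a flag (AIC approaches 8).
    """
    if grade_definition not in ("initial", "reRT"):
        raise ValueError("grade_definition must be 'initial' or 'reRT'")
    sel = meta["timepoint"] == timepoint
    m = meta.loc[sel]
    col = "grade_initial" if grade_definition == "initial" else "grade_rert"
    y = (m[col] == "IV").to_numpy(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        return EmbeddingAic(np.nan, timepoint, len(m), False, True,
                            "fewer than 2 samples in a class")
    c = coords.loc[m["sample_id"]].to_numpy(float)
    X = np.column_stack([np.ones(len(c)), c[:, 0], c[:, 1], c[:, 0] * c[:, 1]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return EmbeddingAic(np.nan, timepoint, len(m), False, True,
                            "degenerate embedding coordinates")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception as exc:  # noqa: BLE001 - flagged, not raised
            return EmbeddingAic(np.nan, timepoint, len(m), False, True,
                                f"fit failed: {exc}")
    mu = fit.predict(X)
    separated = bool(np.all(np.abs(mu - y) < 1e-4))
    aic = float(-2 * fit.llf + 2 * X.shape[1])
    return EmbeddingAic(aic, timepoint, len(m), separated, False)
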