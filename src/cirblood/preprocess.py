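"""Normalization, scaling and covariate residualization.

Virtual-pool normalization centers every sample against a virtual
reference built from the per-gene median across samples: with reference
r_g = median_s(x_gs), each sample is shifted by the median over genes of
(x_gs - r_g).  This removes any per-sample additive offset exactly and is
idempotent.

The MAD used throughout is the raw median absolute deviation without the
1.4826 Gaussian consistency constant: quantile-threshold gene selections
are invariant to the constant, so the simpler definition is used.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)

GRADE_NUMERIC = {"II": 2, "III": 3, "IV": 4}


def gene_median_mad(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise median and raw MAD (no consistency constant)."""
    med = np.median(values, axis=1)
    mad = np.median(np.abs(values - med[:, None]), axis=1)
    return med, mad


def virtual_pool_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Center each sample on the virtual-pool (per-gene median) reference."""
    x.require_finite()
    if x.n_samples < 2:
        log.warning("single-sample matrix: virtual pool normalization is a no-op")
        return x.copy_with(x.values.copy())
    vals = x.values
    ref = np.median(vals, axis=1)
    offsets = np.median(vals - ref[:, None], axis=0)
    return x.copy_with(vals - offsets[None, :])


def z_transform_genes(x: ExpressionMatrix
                      ) -> tuple[ExpressionMatrix, list[str]]:
    """Gene-wise z-scores (n-1 denominator).

    Constant genes are set to 0 and returned as a flag list.
    """
    vals = x.values.astype(float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    z = (vals - mean[:, None]) / safe_sd[:, None]
    z[constant] = 0.0
    flagged = [g for g, c in zip(x.gene_ids, constant) if c]
    return x.copy_with(z), flagged


def top_variant_genes(x: ExpressionMatrix, fraction: float) -> list[str]:
    """Genes ranked by raw MAD across all samples, top ceil(fraction*G).

    Ties at the cutoff break lexicographically by gene ID so the
    selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0,1], got {fraction}")
    if x.n_genes == 0:
        raise ValidationError("empty expression matrix")
    _, mad = gene_median_mad(x.values)
    n_top = int(np.ceil(fraction * x.n_genes))
    order = sorted(range(x.n_genes),
                   key=lambda i: (-mad[i], x.gene_ids[i]))
    return [x.gene_ids[i] for i in order[:n_top]]


def _design_matrix(meta: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Numeric design with intercept; grade coded 2/3/4, sex as indicator."""
    cols = [np.ones(len(meta))]
    for c in covariates:
        if c not in meta.columns:
            raise ValidationError(f"covariate {c!r} absent from metadata")
        s = meta[c]
        if c == "sex":
            cols.append((s == "female").to_numpy(float))
        elif c in ("grade_initial",):
            cols.append(s.map(GRADE_NUMERIC).to_numpy(float))
        elif c in ("grade_rert",):
            cols.append((s == "IV").to_numpy(float))
        else:
            cols.append(pd.to_numeric(s).to_numpy(float))
    return np.column_stack(cols)


def residualize_covariates(x: ExpressionMatrix, meta: pd.DataFrame,
                           covariates: list[str]) -> ExpressionMatrix:
    """Per-gene OLS on the named covariates; returns residuals + gene mean.

    Metadata rows must be aligned with (one per) matrix sample column.
    """
    if not covariates:
        return x.copy_with(x.values.copy())
    if list(meta["sample_id"]) != x.sample_ids:
        raise ValidationError("metadata rows must align with matrix samples")
    X = _design_matrix(meta, covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not increase the rank
        names = ["intercept", *covariates]
        collinear = []
        r = 0
        for j in range(X.shape[1]):
            new = np.linalg.matrix_rank(X[:, :j + 1])
            if new == r:
                collinear.append(names[j])
            r = new
        raise ValidationError(f"rank-deficient design; collinear: {collinear}")
    Y = x.values.T                              # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T + x.values.mean(axis=1)[:, None]
    return x.copy_with(out)
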