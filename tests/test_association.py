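"""Covariate, seed-gene, signature and embedding-AIC screens."""

import numpy as np
import pandas as pd
import pytest

from cirblood.association import (covariate_screen, embedding_aic,
                                  seed_gene_screen, signature_score)
from cirblood.io import ExpressionMatrix, ValidationError
from cirblood.preprocess import z_transform_genes
from conftest import make_matrix


class TestCovariateScreen:
    def test_recovers_planted_sex_genes(self, cohort, cfg):
        x, meta, truth = cohort
        scr = covariate_screen(x, meta, "sex", cfg)
        sex = set(truth.gene_ids("sex"))
        hits = set(scr.loc[scr["significant"], "gene_id"])
        assert len(hits & sex) >= 9
        assert len(hits - sex) <= 3

    def test_permuted_covariate_negative_control(self, cohort, cfg):
        """Permuting sex across patients breaks the association: planted
        genes are then recovered at about the false-positive rate."""
        x, meta, truth = cohort
        rng = np.random.default_rng(0)
        pats = sorted(meta["patient_id"].unique())
        perm = dict(zip(pats, rng.permutation(
            [meta.loc[meta["patient_id"] == p, "sex"].iloc[0] for p in pats])))
        meta2 = meta.copy()
        meta2["sex"] = meta2["patient_id"].map(perm)
        scr = covariate_screen(x, meta2, "sex", cfg)
        hits = set(scr.loc[scr["significant"], "gene_id"])
        # permuted labels still split patients, so a handful of spurious
        # flags can survive, but not systematic recovery
        assert len(hits & set(truth.gene_ids("sex"))) <= 3

    def test_constant_covariate_rejected(self, cohort, cfg):
        x, meta, _ = cohort
        meta2 = meta.copy()
        meta2["sex"] = "male"
        with pytest.raises(ValidationError):
            covariate_screen(x, meta2, "sex", cfg)


class TestSeedGeneScreen:
    def test_satellites_recovered_from_hub(self, cohort, cfg):
        """Seeding on a hub gene recovers the large majority of its planted
        satellites at Bonferroni-adjusted p < 0.05, with slope signs
        matching the planted coefficients."""
        x, _, truth = cohort
        for hub in truth.genes.loc[truth.genes["category"] == "hub",
                                   "gene_id"]:
            sat = truth.genes.loc[
                truth.genes["detail"] == f"satellite-of-{hub}",
                ["gene_id", "effect"]].set_index("gene_id")
            scr = seed_gene_screen(x, hub, cfg).set_index("gene_id")
            assert scr.loc[sat.index, "significant"].mean() >= 0.8
            hits = sat.index[scr.loc[sat.index, "significant"]]
            assert (np.sign(scr.loc[hits, "estimate"])
                    == np.sign(sat.loc[hits, "effect"])).all()

    def test_duplicated_seed_perfect_collinearity(self, cfg):
        rng = np.random.default_rng(1)
        v = rng.normal(size=30)
        x = make_matrix(np.vstack([v, v, rng.normal(size=30)]),
                        genes=["seed", "twin", "other"])
        scr = seed_gene_screen(x, "seed", cfg).set_index("gene_id")
        assert scr.loc["twin", "estimate"] == pytest.approx(1.0)
        assert scr.loc["twin", "adj_p"] < 1e-20
        assert "seed" not in scr.index

    def test_sign_symmetry_exact(self, cfg):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(10, 20))
        x = make_matrix(vals)
        neg = vals.copy()
        neg[0] = -neg[0]
        xn = make_matrix(neg)
        s1 = seed_gene_screen(x, "g0", cfg)
        s2 = seed_gene_screen(xn, "g0", cfg)
        np.testing.assert_allclose(s1["estimate"], -s2["estimate"], atol=1e-12)

    def test_constant_seed_rejected(self, cfg):
        x = make_matrix(np.vstack([np.ones(5),
                                   np.random.default_rng(0).normal(size=5)]))
        with pytest.raises(ValidationError):
            seed_gene_screen(x, "g0", cfg)


class TestSignatureScore:
    def test_single_gene_signature_equals_z_row(self):
        rng = np.random.default_rng(3)
        x = make_matrix(rng.normal(size=(6, 8)))
        z, _ = z_transform_genes(x)
        res = signature_score(x, {"sig": ["g2"]})
        np.testing.assert_allclose(
            res.scores.loc["sig", x.sample_ids].to_numpy(float),
            z.data.loc["g2"].to_numpy())

    def test_all_gene_signature_near_zero(self):
        rng = np.random.default_rng(4)
        x = make_matrix(rng.normal(size=(40, 6)))
        res = signature_score(x, {"all": list(x.gene_ids)})
        # mean of z-rows: each row has mean 0, so column means vanish
        # only up to the row-count scaling; exact zero mean across samples
        s = res.scores.loc["all", x.sample_ids].to_numpy(float)
        assert abs(s.mean()) < 1e-12
        assert np.abs(s).max() < 0.5

    def test_grade_signature_trend_detected(self, cohort):
        x, meta, truth = cohort
        up = truth.genes.loc[(truth.genes["category"] == "grade")
                             & (truth.genes["effect"] > 0), "gene_id"]
        res = signature_score(x, {"grade_up": list(up)}, meta=meta)
        row = res.trend_tests.set_index("signature").loc["grade_up"]
        assert row["estimate"] > 0
        assert row["raw_p"] < 0.01

    def test_absent_signature_flagged(self):
        x = make_matrix(np.random.default_rng(5).normal(size=(4, 5)))
        res = signature_score(x, {"ok": ["g0"], "ghost": ["nope"]})
        assert res.skipped == ["ghost"]


class TestEmbeddingAic:
    def _meta(self, n=16, grades=None):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "patient_id": [f"P{i}" for i in range(n)],
            "timepoint": 0,
            "grade_initial": grades if grades is not None
            else ["IV"] * (n // 2) + ["II"] * (n // 2),
            "grade_rert": ["IV"] * (n // 2) + ["III"] * (n // 2),
        })

    def test_separable_beats_random_labels(self):
        rng = np.random.default_rng(6)
        n = 16
        meta = self._meta(n)
        sep = np.column_stack([np.r_[np.ones(n // 2), -np.ones(n // 2)]
                               + rng.normal(0, 0.05, n),
                               rng.normal(size=n)])
        coords = pd.DataFrame(sep, index=meta["sample_id"],
                              columns=["d1", "d2"])
        good = embedding_aic(coords, meta, "initial", 0)
        shuffled = meta.copy()
        shuffled["grade_initial"] = rng.permutation(
            meta["grade_initial"].to_numpy())
        bad = embedding_aic(coords, shuffled, "initial", 0)
        assert good.separation
        assert good.aic == pytest.approx(8.0, abs=0.5)
        assert bad.aic > good.aic

    def test_random_coords_aic_near_null_deviance(self):
        rng = np.random.default_rng(7)
        n = 14
        meta = self._meta(n, grades=["IV"] * 7 + ["II"] * 7)
        coords = pd.DataFrame(rng.normal(size=(n, 2)),
                              index=meta["sample_id"], columns=["d1", "d2"])
        r = embedding_aic(coords, meta, "initial", 0)
        null_dev = -2 * n * np.log(0.5)
        assert r.aic > 8.0
        assert r.aic < null_dev + 8 + 1e-9

    def test_identical_coordinates_flagged(self):
        meta = self._meta(8)
        coords = pd.DataFrame(np.ones((8, 2)), index=meta["sample_id"],
                              columns=["d1", "d2"])
        r = embedding_aic(coords, meta, "initial", 0)
        assert r.flagged

    def test_single_class_flagged(self):
        meta = self._meta(8, grades=["IV"] * 8)
        coords = pd.DataFrame(np.random.default_rng(8).normal(size=(8, 2)),
                              index=meta["sample_id"], columns=["d1", "d2"])
        r = embedding_aic(coords, meta, "initial", 0)
        assert r.flagged and np.isnan(r.aic)
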