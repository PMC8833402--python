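#!/usr/bin/env python
"""Dose-dependent screens.

Rank-based dose x time interaction tests for baseline vs each
post-treatment timepoint (with the three-way overlap), the baseline TOST
equivalence prescreen across dose arms, and the post-treatment-only mixed
model interaction on the prescreen passers.
"""

from pathlib import Path

import pandas as pd

from cirblood import AnalysisConfig
from cirblood.dose import (dose_call_table, equivalence_prescreen,
                           interaction_screen, post_only_interaction)
from cirblood.io import (read_expression_matrix, read_sample_metadata,
                         write_result_table)
from cirblood.preprocess import virtual_pool_normalize

ROOT = Path(__file__).resolve().parents[1]


def main():
    cfg = AnalysisConfig()
    data = ROOT / "results" / "data"
    out = ROOT / "results"
    x = virtual_pool_normalize(read_expression_matrix(data / "expression.tsv"))
    meta = read_sample_metadata(data / "metadata.tsv")
    truth = pd.read_csv(data / "truth_genes.tsv", sep="\t")
    dose_genes = set(truth.loc[truth["category"] == "dose", "gene_id"])

    screens = {}
    for t in (1, 2, 3):
        scr = interaction_screen(x, meta, cfg, t)
        screens[t] = scr
        write_result_table(scr, out / f"dose_interaction_0v{t}.tsv", cfg, None)
        hits = set(scr.loc[scr["significant"], "gene_id"])
        print(f"0v{t} interaction: {len(hits)} genes at FDR<{cfg.fdr_strict} "
              f"({len(hits & dose_genes)}/{len(dose_genes)} planted)")

    pres = equivalence_prescreen(x, meta, cfg)
    write_result_table(pres, out / "dose_prescreen.tsv", cfg, None)
    passers = list(pres.loc[pres["passes"], "gene_id"])
    print(f"TOST prescreen (margin {cfg.tost_margin_sd} pooled SD): "
          f"{len(passers)} of {len(pres)} genes equivalent at baseline")

    post = post_only_interaction(x, meta, passers, cfg)
    write_result_table(post, out / "dose_post_only.tsv", cfg, None)
    if len(post):
        n_hi = int(post["highlight"].sum())
        print(f"post-only interaction: {n_hi} candidates at p<0.001 "
              f"of {len(post)} prescreened genes")
    else:
        print("post-only interaction: no prescreen passers at the default "
              "margin (the prescreen is highly selective at n=5/6/3)")

    calls = dose_call_table(pres, screens, post)
    write_result_table(calls, out / "dose_calls.tsv", cfg, None)


if __name__ == "__main__":
    main()
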