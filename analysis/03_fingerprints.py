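#!/usr/bin/env python
"""Per-patient stable-gene fingerprints and sample correlation clustering.

Selects each patient's highly-abundant, time-stable genes (median above its
97.5% quantile, MAD below its 2.5% quantile over the serial samples), forms
the cross-patient union, and clusters all samples on the union gene set's
Pearson correlation.  Reports how many planted housekeeping genes the union
recovers.
"""

from pathlib import Path

import pandas as pd

from cirblood import AnalysisConfig
from cirblood.fingerprint import (correlation_cluster, fingerprint_union,
                                  select_stable_genes)
from cirblood.io import (ExpressionMatrix, read_expression_matrix,
                         read_sample_metadata, write_result_table)
from cirblood.preprocess import virtual_pool_normalize

ROOT = Path(__file__).resolve().parents[1]


def main():
    cfg = AnalysisConfig()
    data = ROOT / "results" / "data"
    out = ROOT / "results"
    x = virtual_pool_normalize(read_expression_matrix(data / "expression.tsv"))
    meta = read_sample_metadata(data / "metadata.tsv")
    truth = pd.read_csv(data / "truth_genes.tsv", sep="\t")

    sets = [select_stable_genes(x, meta, p, cfg)
            for p in sorted(meta["patient_id"].unique())]
    per_pat = pd.DataFrame(
        [(s.patient_id, len(s.genes), ";".join(s.genes)) for s in sets],
        columns=["patient_id", "n_genes", "genes"])
    write_result_table(per_pat, out / "fingerprint_per_patient.tsv", cfg, None)
    union = fingerprint_union(sets)
    write_result_table(union, out / "fingerprint_union.tsv", cfg, None)

    hk = set(truth.loc[truth["category"] == "housekeeping", "gene_id"])
    got = hk & set(union["gene_id"])
    print(f"stable genes per patient: median {per_pat['n_genes'].median():.0f} "
          f"(range {per_pat['n_genes'].min()}-{per_pat['n_genes'].max()}); "
          f"union of {len(union)} genes")
    print(f"planted housekeeping genes recovered in union: "
          f"{len(got)}/{len(hk)}")

    cl = correlation_cluster(ExpressionMatrix(x.data.loc[union['gene_id']]),
                             cfg)
    write_result_table(cl.correlation.reset_index(names="sample_id"),
                       out / "fingerprint_correlation.tsv", cfg, None)
    pat = meta.set_index("sample_id")["patient_id"]
    r = cl.correlation
    same, cross = [], []
    ids = list(r.index)
    for i, s1 in enumerate(ids):
        for s2 in ids[i + 1:]:
            (same if pat[s1] == pat[s2] else cross).append(r.loc[s1, s2])
    print(f"mean within-patient sample correlation {sum(same)/len(same):.3f} "
          f"vs cross-patient {sum(cross)/len(cross):.3f}")


if __name__ == "__main__":
    main()
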