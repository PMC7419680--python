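"""Contrast GSEA between the activated-like (HH) and HL ERK clusters.

Median-centers the gated cohort, then runs two-phenotype permutation GSEA
over all stand-in gene sets. Sets enriched at FDR < 0.25 are reported.
"""

from pathlib import Path

import pandas as pd

from tnbcstrat.enrichment import EnrichmentParams, gsea
from tnbcstrat.genesets import read_gmt
from tnbcstrat.matrix import median_center, read_expression

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    matrix = read_expression(ROOT / "cohort" / "expression.tsv")
    sets = read_gmt(ROOT / "cohort" / "gene_sets.gmt")
    clusters = pd.read_csv(ROOT / "clusters.tsv", sep="\t", index_col=0)

    contrast = clusters.index[clusters["erk_cluster"].isin(["HH", "HL"])]
    sub = median_center(matrix.with_values(matrix.values[contrast]))
    table = gsea(sub, clusters.loc[contrast, "erk_cluster"], sets,
                 EnrichmentParams(n_perm=500, seed=SEED))
    table.to_csv(ROOT / "gsea_hh_vs_hl.tsv", sep="\t", index=False)

    sig = table[table["fdr"] < 0.25]
    print(f"compared {len(contrast)} samples (HH vs HL on the ERK axis)")
    print(f"{len(sig)} of {len(table)} sets enriched at FDR < 0.25:")
    print(sig.round(4).to_string(index=False))
    print(f"wrote {ROOT / 'gsea_hh_vs_hl.tsv'}")


if __name__ == "__main__":
    main()
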