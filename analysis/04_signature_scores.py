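"""Score cytolytic activity, the anti-CTLA-4 immune signature, and the
proliferation signature per sample; compare clusters against HH.

Wilcoxon rank-sum tests take the HH (CTLA-4 high / pathway high) cluster
as the reference, with BH adjustment across the compared clusters.
"""

from pathlib import Path

import pandas as pd

from tnbcstrat.genesets import read_gmt
from tnbcstrat.immune_scores import compare_groups, cytolytic_score, mean_signature_score
from tnbcstrat.matrix import read_expression

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    matrix = read_expression(ROOT / "cohort" / "expression.tsv")
    sets = read_gmt(ROOT / "cohort" / "gene_sets.gmt")
    clusters = pd.read_csv(ROOT / "clusters.tsv", sep="\t", index_col=0)

    gated = matrix.with_values(matrix.values[clusters.index])
    scores = pd.DataFrame({
        "cytolytic": cytolytic_score(gated),
        "immune_score_anti_ctla4": mean_signature_score(gated, sets["IS_ANTI_CTLA4"]),
        "proliferation": mean_signature_score(gated, sets["PROLIFERATION"]),
    })
    scores.to_csv(ROOT / "signature_scores.tsv", sep="\t", index_label="sample")

    for name in scores.columns:
        table = compare_groups(scores[name], clusters, axis="erk", reference="HH")
        medians = scores.groupby(clusters["erk_cluster"])[name].median().round(3)
        print(f"\n{name}: median by erk cluster {medians.to_dict()}")
        print(table.round(4).to_string(index=False))
    print(f"\nwrote {ROOT / 'signature_scores.tsv'}")


if __name__ == "__main__":
    main()
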