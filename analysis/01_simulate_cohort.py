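"""Generate the ground-truth synthetic TNBC cohort all later steps analyze.

Writes the expression matrix, planted truth, stand-in gene sets, the
cell-type signature matrix, a responder training table, and a clinical
table to results/cohort/.
"""

from pathlib import Path

from tnbcstrat.cohort import (
    SimulationConfig,
    simulate_clinical_table,
    simulate_cohort,
    simulate_responder_training,
)
from tnbcstrat.genesets import write_gmt
from tnbcstrat.matrix import write_expression

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(n_samples=400, seed=SEED)
    matrix, truth, sets, ref = simulate_cohort(cfg)
    write_expression(matrix, OUT / "expression.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t")
    write_gmt(sets, OUT / "gene_sets.gmt")
    ref.to_csv(OUT / "signature_matrix.tsv", sep="\t", index_label="gene")

    feats, labels = simulate_responder_training(cfg, n=148, seed=SEED + 1)
    train = feats.assign(label=labels)
    train.to_csv(OUT / "responder_training.tsv", sep="\t", index_label="sample")

    clin = simulate_clinical_table(50, seed=SEED)
    clin.to_csv(OUT / "clinical.csv")

    print(f"cohort: {matrix.shape[1]} samples x {matrix.shape[0]} genes (seed {SEED})")
    print(f"planted erk clusters: {truth['erk_cluster'].value_counts().to_dict()}")
    print(f"purity range: {truth['purity'].min():.2f}-{truth['purity'].max():.2f}")
    print(f"responder training set: {len(train)} samples")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
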