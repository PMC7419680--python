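"""Train the anti-CTLA-4 responder SVM and test enrichment across clusters.

Trains on the labeled immune-score table from step 01, predicts responder
status for the gated cohort, and tests whether predicted responders are
enriched in the activated-like (HH) versus the HL ERK cluster.
"""

from pathlib import Path

import pandas as pd

from tnbcstrat.genesets import read_gmt
from tnbcstrat.immune_scores import cytolytic_score, mean_signature_score
from tnbcstrat.matrix import read_expression
from tnbcstrat.responder import predict_responders, responder_enrichment, train_responder

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    matrix = read_expression(ROOT / "cohort" / "expression.tsv")
    sets = read_gmt(ROOT / "cohort" / "gene_sets.gmt")
    clusters = pd.read_csv(ROOT / "clusters.tsv", sep="\t", index_col=0)
    train = pd.read_csv(ROOT / "cohort" / "responder_training.tsv", sep="\t", index_col=0)

    model = train_responder(train.drop(columns=["label"]), train["label"], seed=SEED)
    print(f"trained linear SVM on {model.n_train} samples; "
          f"5-fold CV accuracy {model.cv_accuracy:.3f}")

    gated = matrix.with_values(matrix.values[clusters.index])
    features = pd.DataFrame({
        "immune_score_anti_ctla4": mean_signature_score(gated, sets["IS_ANTI_CTLA4"]),
        "cytolytic_score": cytolytic_score(gated),
    })
    predicted = predict_responders(model, features)
    predicted.to_frame().to_csv(ROOT / "predicted_responders.tsv", sep="\t",
                                index_label="sample")

    enrich = responder_enrichment(predicted, clusters, axis="erk",
                                  positive_class="responder")
    print(enrich.round(4).to_string(index=False))
    print(f"wrote {ROOT / 'predicted_responders.tsv'}")


if __name__ == "__main__":
    main()
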