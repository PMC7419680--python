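"""Formula-defined signature scores and cluster-wise comparisons.

Two scoring modes coexist, assigned signature-by-signature: plain mean
expression over a gene list (cytolytic activity, tumor inflammation,
proliferation, tissue-resident memory, anti-CTLA-4 immune score) and
ssGSEA (immune cell-type panels). The cytolytic activity score (CYT) is
the mean of normalized GZMA and PRF1 expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats as st
from .enrichment import EnrichmentParams, ssgsea_panel
from .genesets import GeneSet, GeneSetCollection
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

CYT_GENES = ("GZMA", "PRF1")


def mean_signature_score(m: ExpressionMatrix, s: GeneSet) -> pd.Series:
    """Per-sample mean expression over the signature genes present.

    Missing signature genes are tolerated (their count is logged); a
    signature with no measured gene is an error.
    """
    present = [g for g in sorted(s.genes) if g in m.gene_ids]
    if not present:
        raise ValueError(f"no genes of signature {s.name!r} in the matrix")
    missing = len(s.genes) - len(present)
    if missing:
        logger.warning("signature %r: %d of %d genes not measured", s.name, missing, len(s.genes))
    return m.values.loc[present].mean(axis=0).rename(s.name)


def cytolytic_score(m: ExpressionMatrix) -> pd.Series:
    """Cytolytic activity (CYT): mean of GZMA and PRF1 per sample."""
    for g in CYT_GENES:
        if g not in m.gene_ids:
            raise ValueError(f"cytolytic score requires gene {g}")
    return mean_signature_score(m, GeneSet("CYT", frozenset(CYT_GENES), role="signature"))


def celltype_enrichment_panel(
    m: ExpressionMatrix,
    collection: GeneSetCollection,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """ssGSEA score of each immune cell-type set per sample (sets x samples)."""
    if len(collection) == 0:
        raise ValueError("empty cell-type collection")
    return ssgsea_panel(m, collection, params)


def compare_groups(
    scores: pd.Series,
    clusters: pd.DataFrame,
    axis: str = "erk",
    reference: str = "HH",
) -> pd.DataFrame:
    """Wilcoxon rank-sum of each cluster against the reference cluster.

    ``clusters`` is the output of :func:`tnbcstrat.stratify.assign_clusters`;
    ``axis`` selects the ``erk_cluster`` or ``akt_cluster`` labels. Returns
    one row per non-reference cluster with group medians, the two-sided p,
    and BH-adjusted q across the compared clusters.
    """
    if axis not in {"erk", "akt"}:
        raise ValueError("axis must be 'erk' or 'akt'")
    labels = clusters[f"{axis}_cluster"].reindex(scores.index)
    ref_vals = scores[labels == reference]
    if len(ref_vals) == 0:
        raise ValueError(f"reference cluster {reference!r} is empty")
    rows = []
    for grp in ("HH", "HL", "LH", "LL"):
        if grp == reference:
            continue
        vals = scores[labels == grp]
        if len(vals) == 0:
            logger.warning("cluster %s empty; comparison skipped", grp)
            continue
        p = st.wilcoxon_rank_sum(vals.to_numpy(), ref_vals.to_numpy())
        rows.append({
            "cluster": grp,
            "n": len(vals),
            "median": float(vals.median()),
            "reference_median": float(ref_vals.median()),
            "p": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = st.bh_adjust(out["p"].to_numpy())
    return out


def marker_cooccurrence(m: ExpressionMatrix, anchor: str, partners) -> pd.DataFrame:
    """Median-split co-occurrence of partner genes within anchor strata.

    Every gene is dichotomized at its cohort median (strictly above =
    High). Returns, per partner, the proportion of partner-High samples
    within the anchor-High and anchor-Low strata.
    """
    genes = [anchor, *partners]
    for g in genes:
        if g not in m.gene_ids:
            raise ValueError(f"gene {g} not in matrix")
    high = {g: m.values.loc[g] > m.values.loc[g].median() for g in genes}
    anchor_high = high[anchor]
    rows = []
    for g in partners:
        rows.append({
            "partner": g,
            "prop_high_in_anchor_high": float(high[g][anchor_high].mean()),
            "prop_high_in_anchor_low": float(high[g][~anchor_high].mean()),
            "n_anchor_high": int(anchor_high.sum()),
            "n_anchor_low": int((~anchor_high).sum()),
        })
    return pd.DataFrame(rows)
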