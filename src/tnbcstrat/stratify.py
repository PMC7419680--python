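"""Immune-adjusted CTLA-4 stratification into HH/HL/LH/LL clusters.

The core procedure of the pipeline: (1) regress CTLA-4 expression on the
ESTIMATE score and CD4/CD8 lymphocyte-infiltration scores and keep the
residual as the tumor-intrinsic ("adjusted") CTLA-4 level; (2) dichotomize
adjusted CTLA-4 at the cohort median (strictly above = High); (3) combine
and dichotomize the ssGSEA scores of the ERK1/2 and AKT pathway axes the
same way; (4) cross the two labels into four clusters per axis.

The "activated-like" phenotype is asymmetric by design: on the ERK axis it
is the HH cluster (CTLA-4 high, ERK1/2 enrichment high), while on the AKT
axis it is HL (CTLA-4 high, AKT program down-modulated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import EnrichmentParams, combine_axis_scores, ssgsea_score
from .genesets import GeneSet
from .matrix import ExpressionMatrix

CONDITION_NUMBER_BOUND = 1e10


def lymphocyte_scores(
    m: ExpressionMatrix,
    cd4_set: GeneSet,
    cd8_set: GeneSet,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Per-sample CD4/CD8 ssGSEA scores plus their combined (standardized
    and averaged) lymphocyte-infiltration score."""
    cd4 = ssgsea_score(m, cd4_set, params)
    cd8 = ssgsea_score(m, cd8_set, params)
    combined = combine_axis_scores(pd.DataFrame([cd4, cd8]))
    return pd.DataFrame({"cd4_score": cd4, "cd8_score": cd8, "lymphocyte_score": combined})


@dataclass(frozen=True)
class AdjustmentModel:
    """OLS fit of CTLA-4 on purity and lymphocyte covariates."""

    coefficients: pd.Series
    residuals: pd.Series  # the adjusted CTLA-4 values
    covariate_mode: str


def adjust_ctla4(
    ctla4_expr: pd.Series,
    purity: pd.DataFrame,
    infil: pd.DataFrame,
    mode: str = "interaction_expansion",
) -> AdjustmentModel:
    """Remove immune/purity contributions from CTLA-4 expression by OLS.

    ``mode="interaction_expansion"`` uses intercept + ESTIMATE score + CD4 +
    CD8 + CD4*CD8 (the usual reading of a ``CD4*CD8`` model formula);
    ``mode="product"`` uses intercept + ESTIMATE score + the CD4*CD8
    product only. The adjusted value is the residual.
    """
    samples = ctla4_expr.index
    if not (samples.equals(purity.index) and samples.equals(infil.index)):
        purity = purity.reindex(samples)
        infil = infil.reindex(samples)
        if purity["estimate_score"].isna().any() or infil["cd4_score"].isna().any():
            raise ValueError("purity/infiltration records must cover all samples")
    est = purity["estimate_score"].to_numpy(dtype=float)
    cd4 = infil["cd4_score"].to_numpy(dtype=float)
    cd8 = infil["cd8_score"].to_numpy(dtype=float)
    if mode == "interaction_expansion":
        cols = {"intercept": np.ones(len(samples)), "est": est,
                "cd4": cd4, "cd8": cd8, "cd4_x_cd8": cd4 * cd8}
    elif mode == "product":
        cols = {"intercept": np.ones(len(samples)), "est": est, "cd4_x_cd8": cd4 * cd8}
    else:
        raise ValueError(f"unknown covariate mode {mode!r}")
    # constant covariates are absorbed by the intercept
    for name in [k for k in cols if k != "intercept"]:
        if np.ptp(cols[name]) == 0:
            del cols[name]
    design = np.column_stack(list(cols.values()))
    if len(samples) < design.shape[1] + 2:
        raise ValueError("too few samples for the adjustment model")
    # scale-invariant collinearity check on the non-constant columns
    scaled = design / np.maximum(np.abs(design).max(axis=0), 1e-300)
    cond = np.linalg.cond(scaled)
    if cond > CONDITION_NUMBER_BOUND:
        raise ValueError(
            f"collinear adjustment design (cond {cond:.2e}) over covariates {list(cols)}"
        )
    y = ctla4_expr.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return AdjustmentModel(
        coefficients=pd.Series(beta, index=list(cols)),
        residuals=pd.Series(resid, index=samples, name="adjusted_ctla4"),
        covariate_mode=mode,
    )


def dichotomize(values: pd.Series) -> pd.Series:
    """Median split: strictly above the median is High, at-or-below Low."""
    if len(values) < 2:
        raise ValueError("need at least two samples to dichotomize")
    if values.nunique() == 1:
        raise ValueError("all values identical; no median split exists")
    med = values.median()
    return pd.Series(np.where(values > med, "High", "Low"), index=values.index)


def assign_clusters(
    ctla4_labels: pd.Series,
    erk_combined_score: pd.Series,
    akt_combined_score: pd.Series,
) -> pd.DataFrame:
    """Cross CTLA-4 status with per-axis pathway status into HH/HL/LH/LL.

    Pathway axis scores are dichotomized at their cohort median. Cluster
    codes read (CTLA-4 status, pathway status); the activated-like flag is
    HH on the ERK axis and HL on the AKT axis.
    """
    samples = ctla4_labels.index
    if not (samples.equals(erk_combined_score.index) and samples.equals(akt_combined_score.index)):
        raise ValueError("cluster inputs must cover the same samples")
    erk_status = dichotomize(erk_combined_score)
    akt_status = dichotomize(akt_combined_score)
    erk_cluster = ctla4_labels.str[0] + erk_status.str[0]
    akt_cluster = ctla4_labels.str[0] + akt_status.str[0]
    return pd.DataFrame(
        {
            "ctla4_status": ctla4_labels,
            "erk_status": erk_status,
            "akt_status": akt_status,
            "erk_cluster": erk_cluster,
            "akt_cluster": akt_cluster,
            "activated_like_erk": erk_cluster == "HH",
            "activated_like_akt": akt_cluster == "HL",
        }
    )
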