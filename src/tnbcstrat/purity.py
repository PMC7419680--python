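"""Tumor purity from stromal/immune enrichment (ESTIMATE-style).

A bulk tumor transcriptome mixes malignant cells with stromal and immune
cells. Following the ESTIMATE approach, stromal and immune content are
quantified as ssGSEA scores of dedicated signatures; their sum maps to a
tumor-purity fraction through the published cosine calibration

    purity = cos(0.6049872018 + 0.0001467884 * estimate_score)

Samples below a purity threshold (default: strictly greater than 60% is
kept) are excluded from downstream stratification so that tumor-cell
CTLA-4 signal is not swamped by infiltrate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .enrichment import EnrichmentParams, ssgsea_score
from .genesets import GeneSet
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

COS_INTERCEPT = 0.6049872018
COS_SLOPE = 0.0001467884


def estimate_scores(
    m: ExpressionMatrix,
    stromal_set: GeneSet,
    immune_set: GeneSet,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Per-sample stromal/immune ssGSEA scores and their ESTIMATE sum.

    Returns a DataFrame indexed by sample with columns ``stromal_score``,
    ``immune_score``, ``estimate_score``, ``purity`` and ``purity_flag``.
    """
    stromal = ssgsea_score(m, stromal_set, params)
    immune = ssgsea_score(m, immune_set, params)
    est = stromal + immune
    purity, flags = purity_from_estimate(est.to_numpy())
    return pd.DataFrame(
        {
            "stromal_score": stromal,
            "immune_score": immune,
            "estimate_score": est,
            "purity": purity,
            "purity_flag": flags,
        }
    )


def purity_from_estimate(estimate_score) -> tuple[np.ndarray, np.ndarray]:
    """Map ESTIMATE score(s) to purity fractions via the cosine calibration.

    Returns ``(purity, flags)``. Cosine arguments beyond pi leave the
    calibrated domain: purity is undefined (NaN, flag ``"undefined"``).
    Values outside [0, 1] are clamped to the boundary and flagged
    ``"clamped"``; in-range values carry ``"ok"``.
    """
    est = np.atleast_1d(np.asarray(estimate_score, dtype=float))
    arg = COS_INTERCEPT + COS_SLOPE * est
    purity = np.cos(arg)
    flags = np.full(est.shape, "ok", dtype=object)
    undefined = arg > np.pi
    clamped = ~undefined & ((purity < 0) | (purity > 1))
    purity = np.clip(purity, 0.0, 1.0)
    purity[undefined] = np.nan
    flags[clamped] = "clamped"
    flags[undefined] = "undefined"
    return purity, flags


def filter_by_purity(records: pd.DataFrame, threshold: float = 0.60) -> pd.Index:
    """Sample ids with purity strictly above ``threshold``.

    ``records`` is the output of :func:`estimate_scores`. Samples with
    undefined purity are excluded; retained/excluded counts are logged.
    """
    purity = records["purity"]
    keep = purity.notna() & (purity > threshold)
    logger.info(
        "purity gate >%s: retained %d of %d samples (%d undefined)",
        threshold, int(keep.sum()), len(records), int(purity.isna().sum()),
    )
    return records.index[keep]
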