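"""Packaged clinicopathological count tables and their association tests.

The package ships the published CTLA-4 membrane-staining score counts of a
50-patient TNBC cohort (TC0 = negative, TC1-TC3 = increasing membrane
positivity) cross-tabulated against tumor stage, smoking history and
chemotherapy setting. Association with CTLA-4 positivity collapses the
expressing scores (TC1-TC3) against TC0; stage (three levels) is tested
with chi-square, the binary covariates with Fisher's exact test.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import stats as st

SCORE_COLUMNS = ["TC0", "TC1", "TC2", "TC3"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("tnbcstrat.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, index_col=0)


def score_counts() -> pd.Series:
    """Cohort counts per CTLA-4 membrane staining score (TC0..TC3)."""
    return _read("table1_ctla4_scores.csv")["count"]


def membrane_positive_fraction() -> float:
    """Fraction of tumors with any membrane CTLA-4 staining (TC1-TC3)."""
    counts = score_counts()
    return float(counts[["TC1", "TC2", "TC3"]].sum() / counts.sum())


def association_table(covariate: str) -> pd.DataFrame:
    """Covariate-by-score count table (covariate in stage/smoking/chemotherapy)."""
    if covariate not in {"stage", "smoking", "chemotherapy"}:
        raise ValueError(f"no packaged table for {covariate!r}")
    return _read(f"table2_{covariate}.csv")


def collapse_positivity(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse score columns to CTLA-4-negative (TC0) vs expressing (TC1-TC3)."""
    out = pd.DataFrame(
        {
            "TC0": table["TC0"],
            "TC1_TC3": table[["TC1", "TC2", "TC3"]].sum(axis=1),
        }
    )
    return out


def association_pvalues() -> dict:
    """Association of CTLA-4 positivity with the three packaged covariates.

    Stage uses Pearson chi-square on the collapsed 3x2 table; smoking and
    chemotherapy use Fisher's exact test on their collapsed 2x2 tables.
    """
    stage = collapse_positivity(association_table("stage"))
    smoking = collapse_positivity(association_table("smoking"))
    chemo = collapse_positivity(association_table("chemotherapy"))
    return {
        "stage": st.chi_square(stage)[1],
        "smoking": st.fisher_exact(smoking),
        "chemotherapy": st.fisher_exact(chemo),
    }
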