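"""Expression-matrix ingestion and normalization.

Bulk transcriptomes enter the pipeline as gene-by-sample tables (plain TSV
or GCT 1.2). Before any scoring, cohorts are harmonized the way
cross-platform meta-cohorts usually are: probes collapsed to one row per
gene symbol (keeping the probe with the largest interquartile range),
per-sample median/MAD scaling, restriction to the common gene universe,
and per-gene median centering for contrast analyses. RNA-seq counts are
brought onto a comparable log scale with a log-CPM transform.

All operations are pure: they return a new :class:`ExpressionMatrix` and
record what was done in its ``provenance`` set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: scale factor that makes the MAD a consistent estimator of the normal sd
MAD_CONSISTENCY = 1.4826


@dataclass(frozen=True)
class ExpressionMatrix:
    """A gene-by-sample expression table with normalization provenance.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. No missing values are permitted.
    provenance
        Flags recording normalization steps already applied, drawn from
        ``{"collapsed", "mad_scaled", "median_centered", "logcpm"}``.
    """

    values: pd.DataFrame
    provenance: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates and "collapsed" in self.provenance:
            raise ValueError("duplicate gene ids in a collapsed matrix")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.isna().any().any():
            raise ValueError("ExpressionMatrix must not contain missing values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, *extra_flags: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.provenance | frozenset(extra_flags))


def _clean_gene_index(index: pd.Index) -> pd.Index:
    return pd.Index([str(g).strip().upper() for g in index], name="gene")


def _from_frame(frame: pd.DataFrame) -> ExpressionMatrix:
    frame = frame.apply(pd.to_numeric, errors="coerce")
    frame.index = _clean_gene_index(frame.index)
    n_before = len(frame)
    frame = frame.dropna(axis=0, how="any")
    n_dropped = n_before - len(frame)
    if n_dropped:
        logger.warning("dropped %d gene rows containing missing values", n_dropped)
    return ExpressionMatrix(frame)


def read_expression(path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from ``path``.

    ``format="tsv"`` expects a header row of sample ids and gene ids in the
    first column. ``format="gct"`` expects GCT 1.2: a ``#1.2`` line, a
    dimensions line, then a header with ``Name``/``Description`` columns.
    Rows containing any missing value are dropped (and counted in the log);
    duplicate sample ids are a hard error.
    """
    if format == "tsv":
        with open(path) as fh:
            _check_unique_samples(fh.readline().rstrip("\n").split("\t")[1:])
        frame = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"malformed GCT header {version!r}; expected '#1.2'")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ValueError("malformed GCT dimensions line")
            header = fh.readline().rstrip("\n").split("\t")
            _check_unique_samples(header[2:])
            frame = pd.read_csv(fh, sep="\t", header=None, names=header, index_col=0)
        frame = frame.drop(columns=[header[1]])
    else:
        raise ValueError(f"unknown format {format!r}")
    return _from_frame(frame)


def _check_unique_samples(sample_ids) -> None:
    seen = set()
    dups = [s for s in sample_ids if s in seen or seen.add(s)]
    if dups:
        raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")


def write_expression(m: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write ``m`` in the same dialects :func:`read_expression` reads."""
    if format == "tsv":
        m.values.to_csv(path, sep="\t", index_label="gene")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
            out = m.values.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown format {format!r}")


def collapse_probes(m: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    For symbols measured by several probes the probe with the largest
    across-sample interquartile range is kept; ties go to the probe that
    appears first in the file. Probes absent from ``probe_map`` are dropped
    with a logged count.
    """
    symbols = {str(k).strip().upper(): str(v).strip().upper() for k, v in probe_map.items()}
    if any(not s for s in symbols.values()):
        raise ValueError("probe map contains empty gene symbols")
    mapped = [p for p in m.gene_ids if p in symbols]
    n_unmapped = m.shape[0] - len(mapped)
    if n_unmapped:
        logger.warning("dropped %d probes absent from the probe map", n_unmapped)
    values = m.values.loc[mapped]
    q3 = values.quantile(0.75, axis=1)
    q1 = values.quantile(0.25, axis=1)
    iqr = (q3 - q1).to_numpy()
    best: dict[str, int] = {}
    order: list[str] = []
    for pos, probe in enumerate(mapped):
        sym = symbols[probe]
        if sym not in best:
            best[sym] = pos
            order.append(sym)
        elif iqr[pos] > iqr[best[sym]]:  # strict: first probe wins ties
            best[sym] = pos
    collapsed = values.iloc[[best[s] for s in order]]
    collapsed.index = pd.Index(order, name=m.values.index.name)
    return m.with_values(collapsed, "collapsed")


def mad_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Robustly scale each sample: ``(x - median) / (MAD * 1.4826)``.

    A sample whose MAD is zero cannot be scaled and raises an error naming
    the sample.
    """
    med = m.values.median(axis=0)
    mad = (m.values - med).abs().median(axis=0)
    zero = mad[mad == 0]
    if len(zero):
        raise ValueError(f"zero MAD for sample(s): {zero.index.tolist()}")
    scaled = (m.values - med) / (mad * MAD_CONSISTENCY)
    return m.with_values(scaled, "mad_scaled")


def intersect_genes(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the sorted common gene set."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common: set | None = None
    for m in matrices:
        genes = set(m.gene_ids)
        common = genes if common is None else common & genes
    if not common:
        raise ValueError("empty gene intersection across matrices")
    ordered = sorted(common)
    return [m.with_values(m.values.loc[ordered]) for m in matrices]


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene row's median (used ahead of contrast GSEA)."""
    centered = m.values.sub(m.values.median(axis=1), axis=0)
    return m.with_values(centered, "median_centered")


def counts_to_logcpm(counts: ExpressionMatrix, prior: float = 0.5) -> ExpressionMatrix:
    """Transform non-negative counts to log2 counts-per-million.

    ``log2((count + prior) / (library_size + 2 * prior) * 1e6)`` with a
    pseudo-count ``prior`` (default 0.5, the usual voom-style offset).
    """
    vals = counts.values
    if (vals.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = vals.sum(axis=0)
    logcpm = np.log2((vals + prior) / (lib + 2.0 * prior) * 1e6)
    return counts.with_values(logcpm, "logcpm")
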