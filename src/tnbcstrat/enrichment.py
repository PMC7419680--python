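"""Single-sample and two-phenotype gene set enrichment.

Two estimators live here, both implemented from first principles because
they are the scoring backbone of the whole stratification:

* :func:`ssgsea_score` — the per-sample running-sum enrichment score of
  Barbie-style ssGSEA. Genes are ranked by expression within a sample
  (descending, gene-id tie-break); the score integrates the gap between
  the rank-weighted empirical CDF of set members (weights ``|rank|^alpha``)
  and the uniform ECDF of non-members. Because only ranks enter, the score
  is invariant under any strictly monotone transform of a sample's values.

* :func:`gsea` — classical two-phenotype GSEA: a signal-to-noise gene
  ranking, a weighted Kolmogorov-Smirnov running sum per set (weight
  ``|metric|^p``), and a phenotype-permutation null. The null is exhaustive
  whenever the number of distinct group assignments fits in ``n_perm``,
  otherwise it is sampled with the configured seed. NES normalizes the
  enrichment score by the mean magnitude of same-sign null scores; the FDR
  is the standard same-sign normalized-null ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSet, GeneSetCollection
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentParams:
    """Knobs shared by the enrichment estimators.

    alpha : rank-weight exponent for ssGSEA (0.25 by convention).
    n_perm : phenotype permutations for the GSEA null.
    ranking_metric : "signal_to_noise" or "t_like".
    weight_p : GSEA running-sum weight exponent (1 = classic weighted KS).
    seed : seed for sampled permutation nulls.
    """

    alpha: float = 0.25
    n_perm: int = 1000
    ranking_metric: str = "signal_to_noise"
    weight_p: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.ranking_metric not in {"signal_to_noise", "t_like"}:
            raise ValueError(f"unknown ranking metric {self.ranking_metric!r}")


def _ordered_positions(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting genes by descending value, gene id breaking ties."""
    # lexsort: last key is primary
    return np.lexsort((gene_ids, -values))


def _ssgsea_one(values: np.ndarray, gene_ids: np.ndarray, member: np.ndarray, alpha: float) -> float:
    n = len(values)
    order = _ordered_positions(values, gene_ids)
    in_set = member[order]
    n_in = int(in_set.sum())
    rank_values = np.arange(n, 0, -1, dtype=float)  # N..1 down the ranking
    w = np.where(in_set, rank_values ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_set) / float(n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    m: ExpressionMatrix,
    s: GeneSet,
    params: EnrichmentParams | None = None,
) -> pd.Series:
    """Per-sample ssGSEA enrichment score of set ``s``.

    Raises if no set gene is measured, or if the set swallows the whole
    matrix (no non-members to compare against).
    """
    params = params or EnrichmentParams()
    gene_ids = m.gene_ids.to_numpy(dtype=object)
    member = np.array([g in s.genes for g in gene_ids], dtype=bool)
    n_in = int(member.sum())
    if n_in == 0:
        raise ValueError(f"no genes of set {s.name!r} present in the matrix")
    if n_in == len(gene_ids):
        raise ValueError(f"set {s.name!r} covers every measured gene")
    vals = m.values.to_numpy(dtype=float)
    scores = np.array([
        _ssgsea_one(vals[:, j], gene_ids, member, params.alpha)
        for j in range(vals.shape[1])
    ])
    return pd.Series(scores, index=m.sample_ids, name=s.name)


def ssgsea_panel(
    m: ExpressionMatrix,
    collection: GeneSetCollection,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """ssGSEA scores for every set in ``collection`` (sets x samples)."""
    if len(collection) == 0:
        raise ValueError("empty gene set collection")
    rows = [ssgsea_score(m, s, params) for s in collection]
    return pd.DataFrame(rows)


def combine_axis_scores(scores: pd.DataFrame) -> pd.Series:
    """Average the standardized per-set scores of one pathway axis.

    ``scores`` holds one row per gene set and one column per sample. Each
    row is standardized to zero mean and unit variance across samples, then
    rows are averaged; zero-variance rows are excluded with a warning.
    """
    if scores.shape[0] < 1:
        raise ValueError("need at least one set score to combine")
    sd = scores.std(axis=1, ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        logger.warning("excluding zero-variance axis set score(s): %s", degenerate)
        scores = scores.drop(index=degenerate)
        sd = sd.drop(index=degenerate)
    if scores.shape[0] == 0:
        raise ValueError("all axis set scores have zero variance")
    z = scores.sub(scores.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0)


# ---------------------------------------------------------------------------
# two-phenotype GSEA


def _ranking_metric(x1: np.ndarray, x0: np.ndarray, kind: str) -> np.ndarray:
    """Per-gene contrast of group 1 vs group 0 (positive = up in group 1)."""
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    s1, s0 = x1.std(axis=1, ddof=1), x0.std(axis=1, ddof=1)
    if kind == "signal_to_noise":
        # Broad-style floors: sd at least 20% of |mean|, never exactly zero
        s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 1e-8))
        s0 = np.maximum(s0, np.maximum(0.2 * np.abs(m0), 1e-8))
        return (m1 - m0) / (s1 + s0)
    n1, n0 = x1.shape[1], x0.shape[1]
    pooled = np.sqrt(s1**2 / n1 + s0**2 / n0)
    pooled = np.maximum(pooled, 1e-8)
    return (m1 - m0) / pooled


def _es_weighted_ks(metric_sorted: np.ndarray, in_set_sorted: np.ndarray, weight_p: float) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    hit_w = np.where(in_set_sorted, np.abs(metric_sorted) ** weight_p, 0.0)
    total_hit = hit_w.sum()
    n = len(metric_sorted)
    n_miss = n - int(in_set_sorted.sum())
    if total_hit == 0:  # all set-gene metrics exactly zero: no signal
        total_hit = 1.0
    running = np.cumsum(hit_w / total_hit - (~in_set_sorted) / float(n_miss))
    k = int(np.argmax(np.abs(running)))
    return float(running[k])


def _label_assignments(n: int, n1: int, n_perm: int, seed: int):
    """Group-1 index sets for the permutation null (exhaustive if feasible)."""
    total = math.comb(n, n1)
    if total <= n_perm:
        return [np.array(c) for c in combinations(range(n), n1)], True
    rng = np.random.default_rng(seed)
    return [rng.permutation(n)[:n1] for _ in range(n_perm)], False


def gsea(
    m: ExpressionMatrix,
    labels: Sequence[str] | pd.Series,
    collection: GeneSetCollection,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Two-phenotype permutation GSEA over a gene set collection.

    ``labels`` assigns each sample (in matrix column order, or by sample id
    when a Series) to one of exactly two groups; the first group in sorted
    label order is the reference (group 0), and positive scores mean
    enrichment in the other group. Returns one row per set with ``es``,
    ``nes``, ``p`` (two-sided nominal, from the permutation null) and
    ``fdr``, sorted by NES.
    """
    params = params or EnrichmentParams()
    if isinstance(labels, pd.Series):
        labels = labels.reindex(m.sample_ids)
        if labels.isna().any():
            raise ValueError("labels missing for some samples")
        labels = labels.to_numpy()
    labels = np.asarray(labels)
    if len(labels) != m.shape[1]:
        raise ValueError("one label per sample required")
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    grp1 = labels == uniq[1]
    n1, n0 = int(grp1.sum()), int((~grp1).sum())
    if min(n1, n0) < 2:
        raise ValueError("both groups need >= 2 samples")

    vals = m.values.to_numpy(dtype=float)
    gene_ids = m.gene_ids.to_numpy(dtype=object)
    memberships = []
    names = []
    for s in collection:
        member = np.array([g in s.genes for g in gene_ids], dtype=bool)
        if member.sum() == 0 or member.sum() == len(gene_ids):
            raise ValueError(f"set {s.name!r} has no usable genes in the matrix")
        memberships.append(member)
        names.append(s.name)

    def es_for(group1_mask: np.ndarray) -> np.ndarray:
        metric = _ranking_metric(vals[:, group1_mask], vals[:, ~group1_mask], params.ranking_metric)
        order = _ordered_positions(metric, gene_ids)
        ms = metric[order]
        return np.array([
            _es_weighted_ks(ms, member[order], params.weight_p) for member in memberships
        ])

    obs = es_for(grp1)

    assignments, exhaustive = _label_assignments(len(labels), n1, params.n_perm, params.seed)
    null = np.empty((len(assignments), len(names)))
    for b, idx in enumerate(assignments):
        mask = np.zeros(len(labels), dtype=bool)
        mask[idx] = True
        null[b] = es_for(mask)

    p = (np.abs(null) >= np.abs(obs)[None, :]).mean(axis=0)
    if not exhaustive:  # add-one so sampled p never reports exactly zero
        p = (p * len(assignments) + 1) / (len(assignments) + 1)

    # NES: normalize by the mean |null ES| of the same sign, per set
    nes = np.full(len(names), np.nan)
    null_nes = np.full_like(null, np.nan)
    for j in range(len(names)):
        for sign in (1.0, -1.0):
            same = null[:, j] * sign > 0
            if not same.any():
                continue
            denom = np.abs(null[same, j]).mean()
            null_nes[same, j] = null[same, j] / denom
            if obs[j] * sign > 0:
                nes[j] = obs[j] / denom

    flat_null = null_nes[~np.isnan(null_nes)]
    fdr = np.full(len(names), np.nan)
    finite = ~np.isnan(nes)
    for j in np.flatnonzero(finite):
        if nes[j] >= 0:
            num = (flat_null >= nes[j]).mean() if len(flat_null) else np.nan
            den = (nes[finite] >= nes[j]).mean()
        else:
            num = (flat_null <= nes[j]).mean() if len(flat_null) else np.nan
            den = (nes[finite] <= nes[j]).mean()
        fdr[j] = min(1.0, num / den) if den > 0 else np.nan

    out = pd.DataFrame(
        {"set": names, "es": obs, "nes": nes, "p": p, "fdr": fdr}
    ).sort_values("nes", ascending=False, ignore_index=True)
    return out
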