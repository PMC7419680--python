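"""Synthetic TNBC cohorts with known ground truth.

The generator emulates the statistical structure every pipeline stage
assumes, so the whole analysis is testable without downloads:

* bulk expression is a purity-weighted mixture of one tumor profile and
  several immune cell-type profiles (Dirichlet fractions), plus Gaussian
  noise on the log scale;
* CTLA-4 carries a planted tumor-intrinsic High/Low bimodal shift on top
  of its immune-lineage contribution — the ground-truth CTLA-4 status is
  the median side of the *realized* tumor-intrinsic level, which is
  exactly the quantity the immune-adjustment step is meant to isolate;
* ERK and AKT pathway gene blocks are shifted up/down per planted label;
* stromal/immune signature genes are elevated by a per-sample intensity
  calibrated so that, noiselessly, the ssGSEA-based ESTIMATE score inverts
  to the planted purity through the published cosine transform (mirroring
  how that transform was calibrated to real cohorts);
* cell-type marker blocks scale with the planted infiltrate fractions, and
  an anti-CTLA-4 immune-score block separates planted responders.

Everything is reproducible from the config seed, and the generator returns
matching stand-in gene sets and a signature matrix so downstream modules
run unmodified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentParams
from .genesets import GeneSet, GeneSetCollection
from .matrix import ExpressionMatrix
from .purity import COS_INTERCEPT, COS_SLOPE

ERK_SET_NAMES = ("ERK_CASCADE_UP", "ERK_TARGETS", "ERK_CASCADE")
AKT_SET_NAMES = ("AKT_PI3K_MTOR", "AKT_TARGETS_CYTOSOL", "AKT_TARGETS_NUCLEUS")
NAMED_GENES = ("CTLA4", "CD80", "CD86", "GZMA", "PRF1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Shifts are absolute on the log-expression scale; with the default
    noise sd of 1 they read directly in noise-sd units. The CTLA-4 shift
    moves each High/Low cluster's tumor-intrinsic mean by +/- the stated
    amount around the cohort center; pathway shifts move every gene of an
    axis set up (High) or down (Low) by the stated amount.
    """

    n_samples: int = 400
    n_genes: int = 6000
    purity_low: float = 0.30
    purity_high: float = 0.95
    celltypes: tuple = ("T_CD4", "T_CD8", "NK", "B_CELL", "MONOCYTE")
    dirichlet_alpha: float = 1.0
    ctla4_shift: float = 1.5
    pathway_shift: float = 1.0
    noise_sd: float = 1.0
    marker_genes_per_set: int = 30
    estimate_set_size: int = 150
    marker_strength: float = 5.0
    coligand_shift: float = 1.0
    proliferation_shift: float = 0.5
    responder_shift: float = 2.0
    responder_rate: float = 0.5
    ssgsea_alpha: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ctla4_shift", "pathway_shift", "noise_sd", "marker_strength"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_samples < 8:
            raise ValueError("need n_samples >= 8 (>= 2 per cluster)")
        if not 0 < self.purity_low <= self.purity_high <= 1:
            raise ValueError("purity bounds must satisfy 0 < low <= high <= 1")
        needed = (
            len(NAMED_GENES)
            + (6 + 2 + len(self.celltypes) + 2) * self.marker_genes_per_set
            + 2 * self.estimate_set_size
        )
        if self.n_genes < needed + 100:
            raise ValueError(f"n_genes too small; need at least {needed + 100}")


def _gene_names(n: int) -> list[str]:
    body = [f"G{i:05d}" for i in range(n - len(NAMED_GENES))]
    return list(NAMED_GENES) + body


def _block_layout(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Assign disjoint index blocks (after the named genes) to each set."""
    cursor = len(NAMED_GENES)
    layout: dict[str, np.ndarray] = {}

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        idx = np.arange(cursor, cursor + k)
        cursor += k
        return idx

    for name in ERK_SET_NAMES + AKT_SET_NAMES:
        layout[name] = take(cfg.marker_genes_per_set)
    layout["STROMAL_SIGNATURE"] = take(cfg.estimate_set_size)
    layout["IMMUNE_SIGNATURE"] = take(cfg.estimate_set_size)
    layout["CD4_LYMPHOCYTE"] = take(cfg.marker_genes_per_set)
    layout["CD8_LYMPHOCYTE"] = take(cfg.marker_genes_per_set)
    for ct in cfg.celltypes:
        layout[f"{ct}_MARKERS"] = take(cfg.marker_genes_per_set)
    layout["IS_ANTI_CTLA4"] = take(cfg.marker_genes_per_set)
    layout["PROLIFERATION"] = take(cfg.marker_genes_per_set)
    return layout


def _gene_set_collection(layout: Mapping[str, np.ndarray], genes: Sequence[str],
                         celltypes: Sequence[str]) -> GeneSetCollection:
    def role_of(name: str) -> str:
        if name in ERK_SET_NAMES:
            return "erk_axis"
        if name in AKT_SET_NAMES:
            return "akt_axis"
        if name.endswith("_MARKERS"):
            return "immune_celltype"
        if name in {"CD4_LYMPHOCYTE", "CD8_LYMPHOCYTE", "IS_ANTI_CTLA4", "PROLIFERATION"}:
            return "signature"
        return "generic"

    collection = GeneSetCollection()
    for name, idx in layout.items():
        collection.add(GeneSet(name, frozenset(genes[i] for i in idx), role=role_of(name)))
    return collection


def _ssgsea_pair(values: np.ndarray, gene_ids: np.ndarray,
                 member_a: np.ndarray, member_b: np.ndarray, alpha: float) -> float:
    """Sum of two set scores sharing one ranking (calibration hot path)."""
    n = len(values)
    order = np.lexsort((gene_ids, -values))
    rank_w = np.arange(n, 0, -1, dtype=float) ** alpha
    total = 0.0
    for member in (member_a, member_b):
        in_set = member[order]
        w = np.where(in_set, rank_w, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_set) / float(n - in_set.sum())
        total += float(np.sum(p_in - p_out))
    return total


def _calibrate_signature_intensity(
    base: np.ndarray,
    gene_ids: np.ndarray,
    sig_idx: np.ndarray,
    stromal_member: np.ndarray,
    immune_member: np.ndarray,
    target_scores: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Per-sample signature-gene elevation hitting the target ESTIMATE score.

    For each sample the noiseless ESTIMATE score is evaluated on a small
    grid of elevations (the score is monotone increasing in the elevation)
    and the required intensity is found by interpolation.
    """
    grid = np.linspace(-10.0, 16.0, 14)
    n_samples = base.shape[1]
    out = np.empty(n_samples)
    for i in range(n_samples):
        v = base[:, i]
        scores = np.empty(len(grid))
        for j, lam in enumerate(grid):
            w = v.copy()
            w[sig_idx] = w[sig_idx] + lam
            scores[j] = _ssgsea_pair(w, gene_ids, stromal_member, immune_member, alpha)
        out[i] = np.interp(target_scores[i], scores, grid)
    return out


def simulate_cohort(cfg: SimulationConfig):
    """Generate a ground-truth cohort.

    Returns ``(matrix, truth, gene_sets, signature_matrix)`` where ``truth``
    is a per-sample DataFrame with planted purity, immune fractions, cluster
    labels and responder status, and ``signature_matrix`` is a gene-by-
    celltype reference usable by :func:`tnbcstrat.deconvolution.deconvolve`.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    gene_arr = np.array(genes, dtype=object)
    layout = _block_layout(cfg)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    n, G, K = cfg.n_samples, cfg.n_genes, len(cfg.celltypes)
    named = {g: i for i, g in enumerate(NAMED_GENES)}

    # fixed cohort-level profiles
    tumor = rng.normal(0.0, 1.0, G)
    immune_base = rng.normal(0.0, 1.0, G)
    profiles = np.tile(immune_base[:, None], (1, K))
    for k, ct in enumerate(cfg.celltypes):
        profiles[layout[f"{ct}_MARKERS"], k] += cfg.marker_strength
    lineage = {
        "T_CD4": ["CD4_LYMPHOCYTE"],
        "T_CD8": ["CD8_LYMPHOCYTE"],
    }
    for ct, sigs in lineage.items():
        if ct in cfg.celltypes:
            k = cfg.celltypes.index(ct)
            for sig in sigs:
                profiles[layout[sig], k] += cfg.marker_strength
    for ct, extra in (("T_CD4", ("CTLA4",)), ("T_CD8", ("CTLA4", "GZMA", "PRF1")),
                      ("NK", ("GZMA", "PRF1")), ("B_CELL", ("CD80", "CD86")),
                      ("MONOCYTE", ("CD80", "CD86"))):
        if ct in cfg.celltypes:
            k = cfg.celltypes.index(ct)
            for g in extra:
                profiles[named[g], k] += cfg.marker_strength

    # planted per-sample truth
    purity = rng.uniform(cfg.purity_low, cfg.purity_high, n)
    fractions = rng.dirichlet(np.full(K, cfg.dirichlet_alpha), size=n)  # n x K
    order = rng.permutation(n)
    ctla4_group = np.empty(n, dtype=object)
    erk_group = np.empty(n, dtype=object)
    akt_group = np.empty(n, dtype=object)
    # balanced assignment over the 8 (ctla4, erk, akt) combinations
    combos = [(c, e, a) for c in "HL" for e in "HL" for a in "HL"]
    for pos, i in enumerate(order):
        c, e, a = combos[pos % 8]
        ctla4_group[i], erk_group[i], akt_group[i] = c, e, a
    responder = rng.random(n) < cfg.responder_rate

    # noiseless per-sample base profile (mixture + planted blocks)
    mix = purity[None, :] * tumor[:, None] + (1.0 - purity)[None, :] * (profiles @ fractions.T)
    base = mix.copy()
    sgn = {"H": 1.0, "L": -1.0}
    for name, group in (
        *[(nm, erk_group) for nm in ERK_SET_NAMES],
        *[(nm, akt_group) for nm in AKT_SET_NAMES],
    ):
        shift = cfg.pathway_shift * np.array([sgn[g] for g in group])
        base[np.ix_(layout[name], np.arange(n))] += shift[None, :]
    base[layout["IS_ANTI_CTLA4"][:, None], responder] += cfg.responder_shift
    base[layout["PROLIFERATION"][:, None], np.array([g == "H" for g in erk_group])] -= (
        cfg.proliferation_shift
    )

    # CTLA-4: tumor-intrinsic bimodal level; its realized value (incl. the
    # gene's own noise draw) is the ground truth the adjustment recovers
    ctla4_latent = (
        cfg.ctla4_shift * np.array([sgn[g] for g in ctla4_group])
        + rng.normal(0.0, cfg.noise_sd, n)
    )
    ctla4_status = np.where(ctla4_latent > np.median(ctla4_latent), "High", "Low")
    high_mask = ctla4_status == "High"
    base[named["CD80"], high_mask] += cfg.coligand_shift
    base[named["CD86"], high_mask] += cfg.coligand_shift

    # stromal/immune signature genes: override the mixture with a calibrated
    # elevation over the tumor background so the ESTIMATE inversion returns
    # the planted purity on the noiseless profile
    sig_idx = np.concatenate([layout["STROMAL_SIGNATURE"], layout["IMMUNE_SIGNATURE"]])
    base[sig_idx, :] = purity[None, :] * tumor[sig_idx, None].reshape(len(sig_idx), 1)
    stromal_member = np.zeros(G, dtype=bool)
    stromal_member[layout["STROMAL_SIGNATURE"]] = True
    immune_member = np.zeros(G, dtype=bool)
    immune_member[layout["IMMUNE_SIGNATURE"]] = True
    targets = (np.arccos(purity) - COS_INTERCEPT) / COS_SLOPE
    lam = _calibrate_signature_intensity(
        base, gene_arr, sig_idx, stromal_member, immune_member, targets, cfg.ssgsea_alpha
    )
    base[sig_idx, :] += lam[None, :]

    # measurement noise (CTLA-4's own draw already sits in the latent level)
    noise = rng.normal(0.0, cfg.noise_sd, (G, n))
    noise[named["CTLA4"], :] = 0.0
    values = base + noise
    values[named["CTLA4"], :] += ctla4_latent

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    truth = pd.DataFrame(
        {
            "purity": purity,
            "immune_fraction": 1.0 - purity,
            "ctla4_latent": ctla4_latent,
            "ctla4_status": ctla4_status,
            "erk_status": ["High" if g == "H" else "Low" for g in erk_group],
            "akt_status": ["High" if g == "H" else "Low" for g in akt_group],
            "responder": np.where(responder, "responder", "non_responder"),
        },
        index=pd.Index(samples, name="sample"),
    )
    truth["erk_cluster"] = truth["ctla4_status"].str[0] + truth["erk_status"].str[0]
    truth["akt_cluster"] = truth["ctla4_status"].str[0] + truth["akt_status"].str[0]
    for k, ct in enumerate(cfg.celltypes):
        truth[f"frac_{ct}"] = fractions[:, k]

    gene_sets = _gene_set_collection(layout, genes, cfg.celltypes)
    marker_union = np.concatenate([layout[f"{ct}_MARKERS"] for ct in cfg.celltypes])
    signature_matrix = pd.DataFrame(
        profiles[marker_union, :],
        index=[genes[i] for i in marker_union],
        columns=list(cfg.celltypes),
    )
    return matrix, truth, gene_sets, signature_matrix


def simulate_mixture(
    ref: pd.DataFrame,
    fractions: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Noisy linear mixtures of reference profiles (deconvolution fixtures).

    ``fractions`` is samples x celltypes, each row summing to one. Noise sd
    may be given as an absolute value; pass e.g. ``0.1 * ref.values.std()``
    for "10% of signal" noise.
    """
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    if fractions.shape[1] != ref.shape[1]:
        raise ValueError("fractions must have one column per cell type")
    if not np.allclose(fractions.sum(axis=1), 1.0):
        raise ValueError("fraction rows must sum to 1")
    rng = np.random.default_rng(seed)
    vals = ref.to_numpy(dtype=float) @ fractions.T
    if noise_sd:
        vals = vals + rng.normal(0.0, noise_sd, vals.shape)
    cols = [f"MIX{i:03d}" for i in range(fractions.shape[0])]
    return ExpressionMatrix(pd.DataFrame(vals, index=ref.index, columns=cols))


def simulate_responder_training(
    cfg: SimulationConfig,
    n: int = 148,
    seed: int = 1,
):
    """A labeled immune-score table emulating external training data.

    A small cohort with the same gene structure is generated and the two
    responder features (anti-CTLA-4 immune score and cytolytic activity)
    are computed from its expression, so feature scales match what the
    pipeline derives for any cohort from the same generator family.
    """
    from .immune_scores import cytolytic_score, mean_signature_score

    train_cfg = SimulationConfig(
        **{**cfg.__dict__, "n_samples": max(n, 8), "seed": seed}
    )
    m, truth, sets, _ = simulate_cohort(train_cfg)
    features = pd.DataFrame(
        {
            "immune_score_anti_ctla4": mean_signature_score(m, sets["IS_ANTI_CTLA4"]),
            "cytolytic_score": cytolytic_score(m),
        }
    )
    return features, truth["responder"]


def simulate_clinical_table(
    n: int,
    score_probs: Sequence[float] = (0.30, 0.14, 0.42, 0.14),
    covariates: Mapping[str, Mapping[str, float]] | None = None,
    stage_probs: Sequence[float] = (0.35, 0.50, 0.15),
    seed: int = 0,
) -> pd.DataFrame:
    """Categorical clinical table with planted covariate odds ratios.

    ``score_probs`` are the marginal frequencies of the TC0..TC3 membrane
    staining scores. Each binary covariate spec has ``p_base`` (probability
    of the positive level among TC0 samples) and ``odds_ratio`` (odds
    multiplier among CTLA-4-expressing, i.e. TC1-TC3, samples). A tumor
    stage column with fixed marginal probabilities is included.
    """
    score_probs = np.asarray(score_probs, dtype=float)
    stage_probs = np.asarray(stage_probs, dtype=float)
    if not np.isclose(score_probs.sum(), 1.0):
        raise ValueError("score_probs must sum to 1")
    if not np.isclose(stage_probs.sum(), 1.0):
        raise ValueError("stage_probs must sum to 1")
    covariates = covariates or {
        "smoking": {"p_base": 0.4, "odds_ratio": 1.0},
        "chemotherapy": {"p_base": 0.5, "odds_ratio": 1.0},
    }
    rng = np.random.default_rng(seed)
    score = rng.choice(["TC0", "TC1", "TC2", "TC3"], size=n, p=score_probs)
    expressing = score != "TC0"
    table = pd.DataFrame({"score": score}, index=[f"P{i:03d}" for i in range(n)])
    table["stage"] = rng.choice(["early", "locally_advanced", "metastatic"], size=n, p=stage_probs)
    for name, spec in covariates.items():
        p0 = float(spec["p_base"])
        orr = float(spec["odds_ratio"])
        if not 0 < p0 < 1 or orr <= 0:
            raise ValueError(f"invalid covariate spec for {name!r}")
        odds = p0 / (1 - p0)
        p1 = (odds * orr) / (1 + odds * orr)
        p = np.where(expressing, p1, p0)
        table[name] = np.where(rng.random(n) < p, "yes", "no")
    return table
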