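"""End-to-end orchestration: purity gate -> adjustment -> stratification ->
signature scores -> enrichment -> deconvolution -> responder -> statistics.

A single config (YAML-friendly dict) drives the run. Inputs come either
from files (expression TSV/GCT, gene sets GMT, signature matrix TSV,
clinical CSV, responder training TSV) or from the synthetic generator.
Stage outputs are written as TSVs plus one machine-readable JSON summary;
every stochastic stage derives its seed from the run seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import stats as st
from .cohort import SimulationConfig, simulate_cohort, simulate_responder_training
from .deconvolution import deconvolve, read_signature_matrix
from .enrichment import EnrichmentParams, combine_axis_scores, gsea, ssgsea_panel
from .genesets import GeneSetCollection, read_gmt, restrict_to_universe
from .immune_scores import compare_groups, cytolytic_score, mean_signature_score
from .matrix import ExpressionMatrix, mad_scale, median_center, read_expression
from .purity import estimate_scores, filter_by_purity
from .responder import predict_responders, responder_enrichment, train_responder
from .stratify import adjust_ctla4, assign_clusters, dichotomize, lymphocyte_scores

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": True,
    "simulation": {},          # SimulationConfig overrides
    "inputs": {},              # expression/gene_sets/signature_matrix/... paths
    "normalize": {"mad_scale": False, "median_center_for_gsea": True},
    "purity_threshold": 0.60,
    "covariate_mode": "interaction_expansion",
    "ctla4_gene": "CTLA4",
    "enrichment": {"alpha": 0.25, "n_perm": 200, "weight_p": 1.0},
    "deconvolution": {"n_perm": 100},
    "axes": {"erk": None, "akt": None},   # set names; None = by role tag
    "sets": {                              # signature names in the GMT input
        "stromal": "STROMAL_SIGNATURE",
        "immune": "IMMUNE_SIGNATURE",
        "cd4": "CD4_LYMPHOCYTE",
        "cd8": "CD8_LYMPHOCYTE",
    },
    "run_gsea": True,
    "run_deconvolution": True,
    "run_responder": True,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def validate_config(cfg: dict) -> None:
    if not cfg.get("synthetic"):
        inputs = cfg.get("inputs", {})
        for key in ("expression", "gene_sets"):
            if key not in inputs:
                raise ValueError(f"config missing required input {key!r}")
        for key, path in inputs.items():
            if key == "expression_format":
                continue
            if not Path(path).exists():
                raise ValueError(f"input {key!r} not found: {path}")


def _load_inputs(cfg: dict):
    if cfg.get("synthetic"):
        sim = SimulationConfig(**{"seed": cfg["seed"], **cfg.get("simulation", {})})
        matrix, truth, sets, ref = simulate_cohort(sim)
        train_feat, train_labels = simulate_responder_training(sim, seed=sim.seed + 1)
        return matrix, sets, ref, truth, (train_feat, train_labels)
    inputs = cfg["inputs"]
    matrix = read_expression(inputs["expression"], inputs.get("expression_format", "tsv"))
    sets = read_gmt(inputs["gene_sets"])
    ref = read_signature_matrix(inputs["signature_matrix"]) if "signature_matrix" in inputs else None
    training = None
    if "responder_training" in inputs:
        table = pd.read_csv(inputs["responder_training"], sep="\t", index_col=0)
        training = (table.drop(columns=["label"]), table["label"])
    return matrix, sets, ref, None, training


def _axis_sets(cfg: dict, sets: GeneSetCollection, axis: str) -> GeneSetCollection:
    names = cfg["axes"].get(axis)
    if names:
        return GeneSetCollection(sets[n] for n in names)
    collection = sets.with_role(f"{axis}_axis")
    if len(collection) == 0:
        raise ValueError(f"no gene sets found for the {axis} axis")
    return collection


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Run every stage and write stage TSVs plus ``summary.json``."""
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    params = EnrichmentParams(
        alpha=cfg["enrichment"]["alpha"],
        n_perm=cfg["enrichment"]["n_perm"],
        weight_p=cfg["enrichment"]["weight_p"],
        seed=seed,
    )
    summary: dict = {"version": __version__, "seed": seed, "stages": {}}

    matrix, sets, ref, truth, training = _load_inputs(cfg)
    if cfg["normalize"].get("mad_scale"):
        matrix = mad_scale(matrix)
    sets = restrict_to_universe(sets, matrix.gene_ids)
    summary["stages"]["input"] = {"n_genes": matrix.shape[0], "n_samples": matrix.shape[1]}

    # purity gate
    stromal = sets[cfg["sets"]["stromal"]]
    immune = sets[cfg["sets"]["immune"]]
    purity_table = estimate_scores(matrix, stromal, immune, params)
    purity_table.to_csv(out / "purity.tsv", sep="\t", index_label="sample")
    retained = filter_by_purity(purity_table, cfg["purity_threshold"])
    if len(retained) < 8:
        raise RuntimeError(f"purity stage: only {len(retained)} samples retained")
    summary["stages"]["purity"] = {
        "threshold": cfg["purity_threshold"],
        "n_retained": int(len(retained)),
        "n_total": int(matrix.shape[1]),
    }
    gated = matrix.with_values(matrix.values[retained])

    # immune adjustment and stratification (post-gate cohort)
    infil = lymphocyte_scores(gated, sets[cfg["sets"]["cd4"]], sets[cfg["sets"]["cd8"]], params)
    ctla4 = gated.values.loc[cfg["ctla4_gene"]]
    model = adjust_ctla4(ctla4, purity_table.loc[retained], infil, cfg["covariate_mode"])
    erk_scores = ssgsea_panel(gated, _axis_sets(cfg, sets, "erk"), params)
    akt_scores = ssgsea_panel(gated, _axis_sets(cfg, sets, "akt"), params)
    clusters = assign_clusters(
        dichotomize(model.residuals),
        combine_axis_scores(erk_scores),
        combine_axis_scores(akt_scores),
    )
    cluster_table = clusters.copy()
    cluster_table.insert(0, "adjusted_ctla4", model.residuals)
    cluster_table.to_csv(out / "clusters.tsv", sep="\t", index_label="sample")
    summary["stages"]["stratify"] = {
        "erk_cluster_sizes": clusters["erk_cluster"].value_counts().to_dict(),
        "akt_cluster_sizes": clusters["akt_cluster"].value_counts().to_dict(),
        "adjustment_mode": model.covariate_mode,
    }

    # signature scores and group comparisons
    scores = pd.DataFrame({"cytolytic": cytolytic_score(gated)})
    for name in ("IS_ANTI_CTLA4", "PROLIFERATION"):
        if name in sets:
            scores[name.lower()] = mean_signature_score(gated, sets[name])
    scores.to_csv(out / "signature_scores.tsv", sep="\t", index_label="sample")
    comparisons = {}
    for col in scores.columns:
        table = compare_groups(scores[col], clusters, axis="erk", reference="HH")
        comparisons[col] = table.set_index("cluster")["p"].to_dict() if len(table) else {}
    summary["stages"]["scores"] = {
        "median_by_erk_cluster": {
            col: scores.groupby(clusters["erk_cluster"])[col].median().round(6).to_dict()
            for col in scores.columns
        },
        "wilcoxon_p_vs_HH": comparisons,
    }

    # contrast GSEA: activated-like vs CTLA-4-high/pathway-low
    if cfg.get("run_gsea"):
        hh_hl = clusters.index[clusters["erk_cluster"].isin(["HH", "HL"])]
        sub = gated.with_values(gated.values[hh_hl])
        if cfg["normalize"].get("median_center_for_gsea", True):
            sub = median_center(sub)
        gsea_table = gsea(sub, clusters.loc[hh_hl, "erk_cluster"], sets, params)
        gsea_table.to_csv(out / "gsea_hh_vs_hl.tsv", sep="\t", index=False)
        sig = gsea_table[gsea_table["fdr"] < 0.25]
        summary["stages"]["gsea"] = {
            "contrast": "erk HH vs HL",
            "n_sets": int(len(gsea_table)),
            "n_fdr_lt_0.25": int(len(sig)),
            "top_set": gsea_table.iloc[0]["set"] if len(gsea_table) else None,
        }

    # immune deconvolution
    if cfg.get("run_deconvolution") and ref is not None:
        frac = deconvolve(gated, ref, n_perm=cfg["deconvolution"]["n_perm"], seed=seed)
        frac.to_csv(out / "deconvolution.tsv", sep="\t", index_label="sample")
        celltypes = list(ref.columns)
        summary["stages"]["deconvolution"] = {
            "mean_fraction": frac[celltypes].mean().round(4).to_dict(),
            "median_p": float(frac["p"].median()),
        }

    # responder model
    if cfg.get("run_responder") and training is not None:
        feats, labels = training
        model_r = train_responder(feats, labels, seed=seed)
        cohort_feats = pd.DataFrame(
            {
                "immune_score_anti_ctla4": mean_signature_score(gated, sets["IS_ANTI_CTLA4"]),
                "cytolytic_score": cytolytic_score(gated),
            }
        )
        predicted = predict_responders(model_r, cohort_feats)
        predicted.to_frame().to_csv(out / "predicted_responders.tsv", sep="\t", index_label="sample")
        enrich = responder_enrichment(predicted, clusters, axis="erk", positive_class="responder")
        summary["stages"]["responder"] = {
            "cv_accuracy": round(model_r.cv_accuracy, 4),
            "enrichment": enrich.round(6).to_dict(orient="records"),
        }

    # clinical contingency statistics
    clinical_path = cfg.get("inputs", {}).get("clinical")
    if clinical_path:
        clin = pd.read_csv(clinical_path, index_col=0)
        summary["stages"]["clinical"] = clinical_association_tests(clin)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


def clinical_association_tests(clin: pd.DataFrame) -> dict:
    """Association of CTLA-4 positivity (TC1-3 vs TC0) with clinical columns.

    Multi-level covariates (e.g. stage) are tested with chi-square on the
    level-by-positivity table; binary covariates with Fisher's exact test.
    """
    expressing = clin["score"] != "TC0"
    out = {}
    for col in clin.columns:
        if col == "score":
            continue
        tab = pd.crosstab(clin[col], expressing)
        if tab.shape[0] > 2:
            stat, p, df, _ = st.chi_square(tab)
            out[col] = {"test": "chi_square", "statistic": round(stat, 6), "df": df, "p": round(p, 6)}
        else:
            out[col] = {"test": "fisher_exact", "p": round(st.fisher_exact(tab), 6)}
    return out
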