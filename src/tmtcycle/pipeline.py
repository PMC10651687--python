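"""End-to-end orchestration: simulate/load → normalize → test → classify →
rhythm → concordance → enrichment, with per-stage TSV outputs and a single
JSON summary."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import TmtCycleError
from . import classify as cls
from . import concord as cc
from . import diffabund as da
from . import enrich as en
from . import normalize as nm
from . import rhythm as rh
from . import syndata as sd
from .io import (
    FLOAT_FMT,
    RAW,
    read_abundance,
    read_design,
    read_expression,
    read_gmt,
    read_id_list,
    write_abundance,
    write_design,
    write_expression,
    write_json,
)

logger = logging.getLogger(__name__)

DEFAULTS = {
    "alpha": 0.05,
    "alpha_relaxed": 0.1,
    "rescue_mode": cls.RESCUE_DICHOTOMY,
    "k_outlier": 3.0,
    "drop_outliers": False,
    "welch": False,
    "period": 24.0,
    "bicw_threshold": rh.DEFAULT_BICW_THRESHOLD,
    "window": [14.0, 22.0],
    "reference_group": "WT",
    "enrich_alpha": en.DEFAULT_ALPHA,
}


class StageError(TmtCycleError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except TmtCycleError as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages and write results under ``out_dir``.

    ``config`` either names input paths under ``inputs`` or carries a
    ``simulate`` section of :class:`~tmtcycle.syndata.SimParams` overrides.
    ``seed`` overrides the configured simulation seed. Returns the summary
    dict (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {**DEFAULTS, **config}
    alpha = float(cfg["alpha"])
    summary: dict = {
        "version": __version__,
        "parameters": {
            k: cfg[k]
            for k in DEFAULTS
        },
    }

    # --- acquire data -------------------------------------------------
    expression = None
    id_map = None
    secreted_ids = None
    if "simulate" in cfg:
        params = sd.SimParams(**{**cfg["simulate"],
                                 **({"seed": seed} if seed is not None else {})})
        summary["seed"] = params.seed
        logger.info("simulating with seed %d", params.seed)
        bundle = _stage("simulate")(sd.simulate_all)(params)
        design = bundle["design"]
        matrix = bundle["matrix"]
        expression = bundle["expression"]
        write_design(design, out / "design.tsv")
        write_abundance(matrix, out / "abundance_raw.tsv")
        write_expression(expression, out / "expression.tsv")
        bundle["protein_truth"].to_csv(out / "ground_truth_proteins.tsv", sep="\t")
        bundle["gene_truth"].to_csv(
            out / "ground_truth_genes.tsv", sep="\t", float_format=FLOAT_FMT
        )
        id_map = pd.DataFrame(
            {"protein_id": matrix.feature_ids, "gene": matrix.meta["gene"]}
        ).reset_index(drop=True)
        secreted_ids = set(matrix.feature_ids[matrix.meta["secreted"]])
    else:
        inputs = cfg["inputs"]
        design = read_design(inputs["design"])
        matrix = read_abundance(inputs["abundance"], design, scale=RAW)
        summary["seed"] = seed
        if "expression" in inputs:
            expression = read_expression(inputs["expression"])
        if "id_map" in inputs:
            id_map = pd.read_csv(inputs["id_map"], sep="\t")
        if "secreted" in inputs:
            secreted_ids = set(read_id_list(inputs["secreted"]))

    # --- normalize ----------------------------------------------------
    filtered = _stage("normalize")(nm.filter_features)(matrix)
    normalized = _stage("normalize")(nm.reference_normalize)(filtered, design)
    pca_result = _stage("normalize")(nm.pca)(normalized)
    outliers = _stage("normalize")(nm.flag_outliers)(
        pca_result, design, k=float(cfg["k_outlier"])
    )
    qc = pca_result.scores.iloc[:, :5].copy()
    qc["outlier_flag"] = [s in set(outliers) for s in qc.index]
    qc.to_csv(out / "qc_pca.tsv", sep="\t", float_format=FLOAT_FMT)
    if cfg["drop_outliers"] and outliers:
        logger.info("dropping flagged outliers: %s", outliers)
        normalized, design = nm.drop_samples(normalized, design, outliers)
    write_abundance(normalized, out / "abundance_normalized.tsv")
    summary["n_features_raw"] = int(len(matrix.feature_ids))
    summary["n_features_filtered"] = int(len(filtered.feature_ids))
    summary["outlier_flags"] = outliers
    summary["thresholds"] = {"alpha": alpha,
                             "alpha_relaxed": float(cfg["alpha_relaxed"]),
                             "k_outlier": float(cfg["k_outlier"]),
                             "enrich_alpha": float(cfg["enrich_alpha"])}

    # --- differential abundance --------------------------------------
    welch = bool(cfg["welch"])
    ttest = _stage("diffabund")(da.pairwise_ttest)
    c_wt_ko = ttest(normalized, design, "WT_AL", "KO_AL", welch=welch)
    c_re_ko = ttest(normalized, design, "RE_AL", "KO_AL", welch=welch)
    c_wt_re = ttest(normalized, design, "WT_AL", "RE_AL", welch=welch)
    contrast_tables = []
    for c in (c_wt_ko, c_re_ko, c_wt_re):
        tab = c.table.copy()
        tab.insert(0, "contrast", c.label)
        contrast_tables.append(tab)

    # --- classification ----------------------------------------------
    dep = _stage("classify")(cls.call_dependent)(c_wt_ko, alpha=alpha)
    labels = _stage("classify")(cls.classify_rescue)(
        dep, c_re_ko, c_wt_re, alpha=alpha, mode=cfg["rescue_mode"]
    )
    feeding_counts = {}
    for genotype in ("WT", "KO", "RE"):
        feed = _stage("classify")(cls.call_feeding_responsive)(
            normalized, design, genotype,
            alpha=alpha, alpha_relaxed=float(cfg["alpha_relaxed"]), welch=welch,
        )
        labels[f"feeding_responsive_{genotype}"] = feed["responsive"]
        labels[f"feeding_responsive_relaxed_{genotype}"] = feed["responsive_relaxed"]
        feeding_counts[genotype] = {
            "strict": int(feed["responsive"].sum()),
            "relaxed": int(feed["responsive_relaxed"].sum()),
        }
    labels.to_csv(out / "class_labels.tsv", sep="\t")
    pd.concat(contrast_tables, ignore_index=True).to_csv(
        out / "contrasts.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    n_detected = int(len(normalized.feature_ids))
    n_dep = int(labels["dependent"].sum())
    counts = {
        "detected": n_detected,
        "dependent": n_dep,
        "dependent_up": int((labels["direction"] == "up").sum()),
        "dependent_down": int((labels["direction"] == "down").sum()),
        "rescued": int((labels["rescue"] == "rescued").sum()),
        "nonrescued": int((labels["rescue"] == "nonrescued").sum()),
        "partial": int((labels["rescue"] == "partial").sum()),
        "feeding_responsive": feeding_counts,
    }
    summary["counts"] = counts
    summary["percent_dependent"] = cls.summarize_percent(n_dep, n_detected)

    if secreted_ids is not None:
        universe = set(normalized.feature_ids)
        sec = _stage("classify")(cls.secreted_fraction_test)(
            set(labels.index[labels["dependent"]]),
            secreted_ids & universe,
            universe,
        )
        summary["secreted"] = {
            "pct_affected_secreted": sec.pct_affected_secreted,
            "pct_affected_nonsecreted": sec.pct_affected_nonsecreted,
            "pct_affected_overall": sec.pct_affected_overall,
            "odds_ratio": sec.odds_ratio,
            "p": sec.p,
        }

    # --- rhythm + concordance ----------------------------------------
    if expression is not None:
        fits = _stage("rhythm")(rh.fit_gene_table)(
            expression,
            reference=cfg["reference_group"],
            period=float(cfg["period"]),
            bicw_threshold=float(cfg["bicw_threshold"]),
        )
        fits.to_csv(out / "rhythm_fits.tsv", sep="\t", float_format=FLOAT_FMT)
        window = tuple(float(v) for v in cfg["window"])
        window_genes = rh.peak_phase_filter(fits, window=window)
        summary["rhythm"] = {
            "n_genes": int(len(fits)),
            "n_rhythmic_in_reference": int(fits["rhythmic_in_reference"].sum()),
            "n_peak_window": len(window_genes),
            "window": list(window),
        }
        if id_map is not None and n_dep > 0:
            try:
                records = _stage("concord")(cc.join_omes)(labels, fits, id_map)
                records.to_csv(out / "concordance.tsv", sep="\t")
                summary["concordance"] = cc.concordance_fractions(records)
                summary["reverse_lookup"] = cc.reverse_lookup(
                    window_genes,
                    set(labels.index[labels["dependent"]]),
                    id_map,
                )
            except TmtCycleError as exc:
                logger.warning("concordance skipped: %s", exc)
                summary["concordance"] = None

    # --- enrichment ---------------------------------------------------
    if cfg.get("gmt"):
        gene_sets = read_gmt(cfg["gmt"])
        universe = set(normalized.meta["gene"])
        query = set(
            normalized.meta.loc[labels.index[labels["dependent"]], "gene"]
        ) & universe
        if query:
            table = _stage("enrich")(en.ora)(
                query, gene_sets, universe, alpha=float(cfg["enrich_alpha"])
            )
            table.to_csv(
                out / "enrichment.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT,
            )
            summary["enrichment"] = {
                "n_sets_tested": int(len(table)),
                "n_significant": int(table["significant"].sum()) if len(table) else 0,
            }

    write_json(summary, out / "summary.json")
    return summary
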