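"""Proteome–transcriptome concordance: join dependence calls with mRNA fits."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import DataError
from .classify import summarize_percent

logger = logging.getLogger(__name__)

CATEGORIES = (
    "transcriptional",
    "post_transcriptional",
    "rhythmic_source",
    "nonrhythmic_source",
)


def join_omes(
    labels: pd.DataFrame,
    fits: pd.DataFrame,
    id_map: pd.DataFrame,
    require_sign_match: bool = False,
) -> pd.DataFrame:
    """One concordance record per mappable dependent protein.

    ``labels`` is the classification frame indexed by protein id (needs a
    ``dependent`` column and, for sign matching, ``direction``); ``fits``
    the per-gene rhythm/mean-model frame; ``id_map`` a two-column
    (protein_id, gene) frame. When several proteins map to one gene each
    still yields a record; when a protein id appears several times in the
    map the first row by sorted gene id wins (logged). Unmapped dependent
    proteins are counted and logged, not errors.

    Category assignment partitions the records: no mean change →
    ``post_transcriptional``; mean change with a rhythmic mRNA source →
    ``rhythmic_source``; mean change from a nonrhythmic gene →
    ``transcriptional``.
    """
    dep_ids = labels.index[labels["dependent"].astype(bool)]
    id_map = id_map.sort_values(["protein_id", "gene"], kind="stable")
    dupes = id_map["protein_id"].duplicated()
    if dupes.any():
        logger.info("join_omes: %d duplicate protein map rows dropped", dupes.sum())
        id_map = id_map[~dupes]
    gene_of = id_map.set_index("protein_id")["gene"]

    rows = []
    unmapped = 0
    for pid in dep_ids:
        gene = gene_of.get(pid)
        if gene is None or gene not in fits.index:
            unmapped += 1
            continue
        fit = fits.loc[gene]
        mean_changed = fit["mean_model"] == "distinct"
        if mean_changed and require_sign_match:
            protein_dir = labels.loc[pid].get("direction", "")
            mrna_dir = "up" if fit["mean_diff"] < 0 else "down"
            # mean_diff is reference - other group; protein direction is KO vs WT
            mean_changed = protein_dir == mrna_dir
        rhythmic = bool(fit["rhythmic_in_reference"])
        if not mean_changed:
            category = "post_transcriptional"
        elif rhythmic:
            category = "rhythmic_source"
        else:
            category = "transcriptional"
        rows.append(
            {
                "protein_id": pid,
                "gene": gene,
                "dependent": True,
                "mRNA_mean_changed": bool(mean_changed),
                "mRNA_rhythmic_in_WT": rhythmic,
                "peaks_in_window": bool(
                    rhythmic and 14.0 <= fit["phase_g2"] <= 22.0
                ),
                "category": category,
            }
        )
    if unmapped:
        logger.info("join_omes: %d dependent proteins without mRNA data", unmapped)
    if not rows:
        raise DataError("empty proteome-transcriptome join")
    return pd.DataFrame(rows).set_index("protein_id")


def concordance_fractions(records: pd.DataFrame, decimals: int = 2) -> dict:
    """Percentages of dependent proteins with mRNA-level support."""
    if len(records) == 0:
        raise DataError("no concordance records")
    n = len(records)
    n_changed = int(records["mRNA_mean_changed"].sum())
    n_rhythmic = int(records["mRNA_rhythmic_in_WT"].sum())
    return {
        "n_records": n,
        "pct_mean_changed": summarize_percent(n_changed, n, decimals),
        "pct_rhythmic_source": summarize_percent(n_rhythmic, n, decimals),
        "pct_nonrhythmic_source": summarize_percent(n - n_rhythmic, n, decimals),
    }


def reverse_lookup(
    window_genes: list[str] | set[str],
    dependent_proteins: set[str],
    id_map: pd.DataFrame,
    decimals: int = 2,
) -> dict:
    """Of rhythmic dark-phase genes with protein data, what share has an altered protein?"""
    id_map = id_map.sort_values(["protein_id", "gene"], kind="stable")
    id_map = id_map[~id_map["protein_id"].duplicated()]
    proteins_of_gene: dict[str, set] = {}
    for pid, gene in zip(id_map["protein_id"], id_map["gene"]):
        proteins_of_gene.setdefault(gene, set()).add(pid)
    mapped = [g for g in sorted(set(window_genes)) if g in proteins_of_gene]
    if not mapped:
        raise DataError("no window genes with mapped protein data")
    n_altered = sum(
        1 for g in mapped if proteins_of_gene[g] & dependent_proteins
    )
    return {
        "n_window_genes_with_protein": len(mapped),
        "n_altered": n_altered,
        "pct_altered": summarize_percent(n_altered, len(mapped), decimals),
    }
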