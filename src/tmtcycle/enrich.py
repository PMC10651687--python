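"""Hypergeometric overrepresentation analysis against GMT gene sets."""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .diffabund import bh_adjust
from .io import GeneSet

DEFAULT_ALPHA = 0.01


def ora(
    query: set[str],
    gene_sets: list[GeneSet],
    universe: set[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """One-sided hypergeometric upper-tail test of ``query`` against each set.

    Sets are intersected with the universe before testing; sets that become
    empty are skipped. ``p = P[X >= hits]`` for X hypergeometric with the
    universe/set/query margins; BH adjustment across tested sets. Rows are
    sorted by (p, set name); ``significant`` flags unadjusted p < alpha.
    """
    if not universe:
        raise ParameterError("universe is empty")
    offenders = query - universe
    if offenders:
        raise ParameterError(
            f"query ids outside the universe: {sorted(offenders)[:10]}"
        )
    m = len(universe)
    n_query = len(query)
    rows = []
    for gs in gene_sets:
        members = set(gs.members) & universe
        if not members:
            continue
        hits = len(query & members)
        k = len(members)
        p = float(stats.hypergeom.sf(hits - 1, m, k, n_query))
        fold = (
            (hits / n_query) / (k / m) if n_query > 0 else float("nan")
        )
        rows.append(
            {
                "set_name": gs.name,
                "hits": hits,
                "set_size": k,
                "query_size": n_query,
                "universe_size": m,
                "p": min(p, 1.0),
                "fold_enrichment": fold,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_name", "hits", "set_size", "query_size",
            "universe_size", "p", "fold_enrichment",
        ],
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["p"] < alpha
        result = result.sort_values(
            ["p", "set_name"], kind="stable", ignore_index=True
        )
    else:
        result["q"] = []
        result["significant"] = []
    return result
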