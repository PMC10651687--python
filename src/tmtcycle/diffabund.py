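"""Pairwise differential abundance with BH FDR, plus per-feature two-way ANOVA.

The t-test route is fully vectorized over features; the ANOVA route is
per-feature (it is used on hand-picked proteins, not the whole matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, ParameterError
from .io import LOG2, AbundanceMatrix, validate_design

logger = logging.getLogger(__name__)


def parse_group_spec(spec: str) -> dict[str, str]:
    """``"WT_AL"`` → ``{"genotype": "WT", "feeding": "AL"}``; a bare
    genotype or feeding label selects on that factor alone."""
    parts = spec.split("_")
    if len(parts) == 2:
        return {"genotype": parts[0], "feeding": parts[1]}
    if len(parts) == 1:
        key = "feeding" if parts[0] in ("AL", "TRF") else "genotype"
        return {key: parts[0]}
    raise ParameterError(f"cannot parse group spec {spec!r}")


def select_samples(design: pd.DataFrame, spec: str | dict) -> list[str]:
    if isinstance(spec, str):
        spec = parse_group_spec(spec)
    mask = ~design["is_reference"]
    for key, value in spec.items():
        mask &= design[key] == value
    return design.loc[mask, "sample"].tolist()


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` on the ascending order
    statistics, capped at 1 and mapped back to the input order. Stable
    under ties. Raises :class:`ParameterError` for p outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ContrastResult:
    """Per-feature statistics for one named two-group comparison."""

    label: str
    table: pd.DataFrame  # feature_id, log2fc, t, p, q, n_a, n_b, zero_variance


def pairwise_ttest(
    matrix: AbundanceMatrix,
    design: pd.DataFrame,
    group_a: str | dict,
    group_b: str | dict,
    welch: bool = False,
    label: str | None = None,
) -> ContrastResult:
    """Two-sample t-test per feature on log2 values, BH-adjusted across features.

    ``log2fc`` is mean(A) − mean(B). Pooled-variance Student's t by default;
    ``welch=True`` switches to unequal-variance with Welch–Satterthwaite df.
    Features with zero pooled variance get p=0 (p=1 when the means are also
    equal) and are flagged in the ``zero_variance`` column with a warning.
    """
    if matrix.scale != LOG2:
        raise ParameterError("pairwise_ttest expects a log2-normalized matrix")
    validate_design(design)
    samples_a = select_samples(design, group_a)
    samples_b = select_samples(design, group_b)
    if set(samples_a) & set(samples_b):
        raise DesignError("contrast groups overlap")
    n_a, n_b = len(samples_a), len(samples_b)
    if n_a < 2 or n_b < 2:
        raise DesignError(
            f"each group needs >=2 samples (got {n_a} vs {n_b})"
        )
    a = matrix.values[samples_a].to_numpy(dtype=float)
    b = matrix.values[samples_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    diff = mean_a - mean_b

    if welch:
        se2 = var_a / n_a + var_b / n_b
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            )
    else:
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        se2 = sp2 * (1.0 / n_a + 1.0 / n_b)
        df = np.full_like(se2, n_a + n_b - 2, dtype=float)

    zero_var = se2 == 0
    if zero_var.any():
        logger.warning(
            "pairwise_ttest: %d features with zero pooled variance", zero_var.sum()
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t = np.where(zero_var & (diff == 0), 0.0, t)
    p = np.where(
        zero_var,
        np.where(diff == 0, 1.0, 0.0),
        2.0 * stats.t.sf(np.abs(np.where(zero_var, 0.0, t)), df),
    )
    q = bh_adjust(p)
    if label is None:
        label = f"{group_a}:{group_b}"
    table = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2fc": diff,
            "t": t,
            "p": p,
            "q": q,
            "n_a": n_a,
            "n_b": n_b,
            "zero_variance": zero_var,
        }
    ).reset_index(drop=True)
    return ContrastResult(label=label, table=table)


@dataclass
class AnovaResult:
    """Two-way (genotype × feeding) ANOVA with Tukey–Kramer cell comparisons."""

    feature_id: str
    effects: pd.DataFrame  # index: genotype, feeding, interaction; cols F, p
    tukey: pd.DataFrame  # cell_a, cell_b, diff, p_adj


def _type2_ss(y: np.ndarray, geno: np.ndarray, feed: np.ndarray):
    """Type-II sums of squares for a two-factor layout via model comparison."""

    def design_matrix(*factor_sets):
        cols = [np.ones_like(y)]
        for levels, codes in factor_sets:
            for lv in levels[1:]:
                cols.append((codes == lv).astype(float))
        return np.column_stack(cols)

    g_levels = np.unique(geno)
    f_levels = np.unique(feed)
    cell = np.char.add(np.char.add(geno.astype(str), "|"), feed.astype(str))

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return float(resid @ resid)

    x_g = design_matrix((g_levels, geno))
    x_f = design_matrix((f_levels, feed))
    x_gf = design_matrix((g_levels, geno), (f_levels, feed))
    # full model with interaction == cell-means model
    c_levels = np.unique(cell)
    x_full = np.column_stack([(cell == lv).astype(float) for lv in c_levels])

    rss_gf = rss(x_gf)
    rss_full = rss(x_full)
    ss_geno = rss(x_f) - rss_gf
    ss_feed = rss(x_g) - rss_gf
    ss_inter = rss_gf - rss_full
    df_geno = len(g_levels) - 1
    df_feed = len(f_levels) - 1
    df_inter = df_geno * df_feed
    df_resid = len(y) - len(c_levels)
    return (
        (max(ss_geno, 0.0), df_geno),
        (max(ss_feed, 0.0), df_feed),
        (max(ss_inter, 0.0), df_inter),
        (max(rss_full, 0.0), df_resid),
    )


def two_way_anova_tukey(
    values: pd.Series, design: pd.DataFrame
) -> AnovaResult:
    """Type-II two-way ANOVA on one feature plus Tukey–Kramer cell contrasts.

    ``values`` is indexed by sample id. Requires ≥2 levels per factor and
    ≥2 replicates per (genotype, feeding) cell; an understaffed cell raises
    :class:`DesignError` naming it. Degenerate zero-variance layouts return
    F=0, p=1 for null effects (and p=0 for nonzero effects over zero
    residual), rather than NaN.
    """
    validate_design(design)
    nonref = design[~design["is_reference"]]
    nonref = nonref[nonref["sample"].isin(values.index)]
    y = values.loc[nonref["sample"]].to_numpy(dtype=float)
    geno = nonref["genotype"].to_numpy()
    feed = nonref["feeding"].to_numpy()
    if len(np.unique(geno)) < 2 or len(np.unique(feed)) < 2:
        raise DesignError("two_way_anova_tukey needs >=2 levels per factor")
    counts = nonref.groupby(["genotype", "feeding"]).size()
    for g in np.unique(geno):
        for f in np.unique(feed):
            n_cell = counts.get((g, f), 0)
            if n_cell < 2:
                raise DesignError(
                    f"cell ({g}, {f}) has {n_cell} replicates; >=2 required"
                )

    (ss_g, df_g), (ss_f, df_f), (ss_i, df_i), (ss_r, df_r) = _type2_ss(
        y, geno, feed
    )
    mse = ss_r / df_r if df_r > 0 else 0.0
    eps = 1e-12 * max(float(np.var(y)), 1.0)

    def f_and_p(ss, df):
        ms = ss / df
        if mse <= eps:
            return (0.0, 1.0) if ss <= eps else (np.inf, 0.0)
        f_stat = ms / mse
        return f_stat, float(stats.f.sf(f_stat, df, df_r))

    effects = pd.DataFrame(
        [f_and_p(ss_g, df_g), f_and_p(ss_f, df_f), f_and_p(ss_i, df_i)],
        index=["genotype", "feeding", "interaction"],
        columns=["F", "p"],
    )

    # Tukey-Kramer over the genotype x feeding cells
    cells = sorted(counts.index)
    k = len(cells)
    cell_mean = {
        c: float(np.mean(y[(geno == c[0]) & (feed == c[1])])) for c in cells
    }
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ca, cb = cells[i], cells[j]
            na, nb = counts[ca], counts[cb]
            diff = cell_mean[ca] - cell_mean[cb]
            if mse <= eps:
                p_adj = 1.0 if abs(diff) <= np.sqrt(eps) else 0.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
                q_stat = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q_stat, k, df_r))
            rows.append(
                {
                    "cell_a": "_".join(ca),
                    "cell_b": "_".join(cb),
                    "diff": diff,
                    "p_adj": min(p_adj, 1.0),
                }
            )
    return AnovaResult(
        feature_id=str(values.name),
        effects=effects,
        tukey=pd.DataFrame(rows),
    )
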