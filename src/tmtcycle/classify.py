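"""Decision rules: genotype dependence, rescue status, feeding response,
cross-tissue overlap, secreted-fraction testing and summary arithmetic.

Thresholding convention: a feature is significant iff q < alpha (strict),
and the "not significant" arm of the rescue rule uses q >= alpha; ties at
exactly alpha are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .exceptions import DataError, DesignError, ParameterError
from .diffabund import ContrastResult, pairwise_ttest
from .io import AbundanceMatrix

logger = logging.getLogger(__name__)

RESCUE_DICHOTOMY = "dichotomy"
RESCUE_THREEWAY = "threeway"


def _q_series(contrast: ContrastResult) -> pd.Series:
    return contrast.table.set_index("feature_id")["q"]


def _log_alpha_ties(q: pd.Series, alpha: float, label: str) -> None:
    ties = int((q == alpha).sum())
    if ties:
        logger.info("%s: %d features with q exactly at alpha=%g", label, ties, alpha)


def call_dependent(
    contrast_wt_ko: ContrastResult, alpha: float = 0.05
) -> pd.DataFrame:
    """Call genotype-dependent features from the WT-vs-KO contrast.

    Dependent iff q < alpha; ``direction`` is the sign of the KO−WT change
    (the contrast is computed as WT−KO, so direction = −sign(log2fc)).
    Returns a frame indexed by feature id with ``dependent`` and
    ``direction`` ∈ {"up", "down", ""} columns.
    """
    tab = contrast_wt_ko.table.set_index("feature_id")
    _log_alpha_ties(tab["q"], alpha, "call_dependent")
    # alpha >= 1 disables filtering entirely (q is capped at exactly 1)
    dependent = tab["q"] < alpha if alpha < 1.0 else tab["q"] <= 1.0
    direction = np.where(
        dependent, np.where(tab["log2fc"] < 0, "up", "down"), ""
    )
    return pd.DataFrame({"dependent": dependent, "direction": direction})


def classify_rescue(
    dependent: pd.DataFrame,
    contrast_re_ko: ContrastResult,
    contrast_wt_re: ContrastResult,
    alpha: float = 0.05,
    mode: str = RESCUE_DICHOTOMY,
) -> pd.DataFrame:
    """Label dependent features as rescued / nonrescued (/ partial).

    Rescued iff the rescue genotype differs from KO (q < alpha) and is
    indistinguishable from WT (q >= alpha). In dichotomy mode everything
    dependent-but-not-rescued is nonrescued, so rescued + nonrescued
    partition the dependent set. Three-way mode labels features significant
    in both arms as ``partial``. Non-dependent features get
    ``not_applicable``.
    """
    if mode not in (RESCUE_DICHOTOMY, RESCUE_THREEWAY):
        raise ParameterError(f"unknown rescue mode {mode!r}")
    q_re_ko = _q_series(contrast_re_ko)
    q_wt_re = _q_series(contrast_wt_re)
    dep_ids = dependent.index[dependent["dependent"]]
    missing = [
        fid
        for fid in dep_ids
        if fid not in q_re_ko.index or fid not in q_wt_re.index
    ]
    if missing:
        raise DataError(
            f"features missing a rescue contrast: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    _log_alpha_ties(q_re_ko.loc[dep_ids], alpha, "classify_rescue[RE vs KO]")
    _log_alpha_ties(q_wt_re.loc[dep_ids], alpha, "classify_rescue[WT vs RE]")

    labels = pd.Series("not_applicable", index=dependent.index, dtype=object)
    for fid in dep_ids:
        sig_re_ko = q_re_ko[fid] < alpha
        sig_wt_re = q_wt_re[fid] < alpha
        if sig_re_ko and not sig_wt_re:
            labels[fid] = "rescued"
        elif mode == RESCUE_THREEWAY and sig_re_ko and sig_wt_re:
            labels[fid] = "partial"
        else:
            labels[fid] = "nonrescued"
    out = dependent.copy()
    out["rescue"] = labels
    return out


def call_feeding_responsive(
    matrix: AbundanceMatrix,
    design: pd.DataFrame,
    genotype: str,
    alpha: float = 0.05,
    alpha_relaxed: float = 0.1,
    welch: bool = False,
) -> pd.DataFrame:
    """Test AL vs TRF within one genotype; report both thresholds.

    Returns a frame indexed by feature id with ``responsive`` (q < alpha)
    and ``responsive_relaxed`` (q < alpha_relaxed) plus the underlying q.
    """
    nonref = design[~design["is_reference"]]
    present = set(nonref.loc[nonref["genotype"] == genotype, "feeding"])
    missing = {"AL", "TRF"} - present
    if missing:
        raise DesignError(
            f"genotype {genotype!r} lacks feeding arm(s): {sorted(missing)}"
        )
    contrast = pairwise_ttest(
        matrix,
        design,
        {"genotype": genotype, "feeding": "AL"},
        {"genotype": genotype, "feeding": "TRF"},
        welch=welch,
        label=f"{genotype}-AL:{genotype}-TRF",
    )
    tab = contrast.table.set_index("feature_id")
    return pd.DataFrame(
        {
            "q": tab["q"],
            "responsive": tab["q"] < alpha,
            "responsive_relaxed": tab["q"] < alpha_relaxed,
        }
    )


def cross_tissue_overlap(
    dep_a: set[str], dep_b: set[str], detected_both: set[str]
) -> dict[str, int]:
    """Overlap of two dependent sets restricted to features detected in both tissues."""
    a = dep_a & detected_both
    b = dep_b & detected_both
    return {
        "overlap": len(a & b),
        "a_only": len(a - b),
        "b_only": len(b - a),
        "detected_both": len(detected_both),
    }


@dataclass
class SecretedFractionResult:
    pct_affected_secreted: float
    pct_affected_nonsecreted: float
    pct_affected_overall: float
    odds_ratio: float
    p: float
    table: np.ndarray  # 2x2: [secreted, non-secreted] x [affected, unaffected]


def secreted_fraction_test(
    affected: set[str], secreted: set[str], universe: set[str]
) -> SecretedFractionResult:
    """Are secreted features over-represented among affected features?

    Builds the 2×2 (secreted × affected) table over the detection universe,
    computes the two-sided Fisher exact p and conditional-MLE odds ratio,
    and the affected percentage within each annotation class.
    """
    if not universe:
        raise ParameterError("universe is empty")
    if not secreted <= universe:
        raise ParameterError("secreted annotation must be a subset of the universe")
    affected = affected & universe
    sec = secreted
    nonsec = universe - secreted
    a = len(affected & sec)
    b = len(sec) - a
    c = len(affected & nonsec)
    d = len(nonsec) - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        or_mle = np.nan
    else:
        or_mle = float(_odds_ratio(table, kind="conditional").statistic)
    pct_sec = summarize_percent(a, len(sec)) if sec else 0.0
    pct_non = summarize_percent(c, len(nonsec)) if nonsec else 0.0
    return SecretedFractionResult(
        pct_affected_secreted=pct_sec,
        pct_affected_nonsecreted=pct_non,
        pct_affected_overall=summarize_percent(len(affected), len(universe)),
        odds_ratio=or_mle,
        p=float(p),
        table=table,
    )


def subunit_set_average(
    matrix: AbundanceMatrix, members: list[str] | set[str]
) -> pd.Series:
    """Per-sample arithmetic mean of normalized abundances over a feature set."""
    members = sorted(set(members))
    if not members:
        raise ParameterError("subunit set is empty")
    missing = [m for m in members if m not in matrix.feature_ids]
    if missing:
        raise DataError(f"subunit set members not in matrix: {missing}")
    return matrix.values.loc[members].mean(axis=0)


def summarize_percent(part: int, whole: int, decimals: int = 2) -> float:
    """``100 * part / whole`` rounded half-up to ``decimals`` places."""
    if whole <= 0:
        raise ParameterError(f"whole must be > 0, got {whole}")
    if not (0 <= part <= whole):
        raise ParameterError(f"part must be within [0, {whole}], got {part}")
    exact = Decimal(100) * Decimal(part) / Decimal(whole)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))
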