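"""Two-group cosinor model enumeration with BIC-weight selection.

Five rhythmicity hypotheses are compared per gene, all with group-specific
intercepts and first-harmonic cos/sin regressors at a fixed period:

1. no rhythm in either group
2. rhythmic in group 1 only
3. rhythmic in group 2 only
4. both rhythmic, shared cosine coefficients
5. both rhythmic, group-specific coefficients

Model weights are ``softmax(-BIC/2)``; the selected model is the argmax,
demoted to "unclassified" when its weight falls below a confidence
threshold. By convention the *reference* group (e.g. the wild type) is
group 2, so "rhythmic in reference" means the selected model is 3, 4 or 5.
A separate shared-vs-distinct mean-model comparison, keeping the selected
rhythmic structure as covariates, detects differences in daily average
expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import IdentifiabilityError, ParameterError

DEFAULT_BICW_THRESHOLD = 0.4
RHYTHMIC_IN_G2 = (3, 4, 5)
_RSS_FLOOR_VAR = 1e-24  # residual-variance floor; ties broken by BIC penalty


def _check_groups(t, group, groups):
    if len(groups) != 2:
        raise ParameterError("exactly two group labels required")
    for g in groups:
        tg = t[group == g]
        if len(np.unique(tg)) < 4:
            raise IdentifiabilityError(
                f"group {g!r} has {len(np.unique(tg))} distinct timepoints; "
                ">=4 required for a 3-parameter cosinor"
            )


def _model_design(t, group, groups, period, model):
    """Design matrix columns beyond the two group intercepts."""
    omega = 2.0 * np.pi / period
    cos_t, sin_t = np.cos(omega * t), np.sin(omega * t)
    g1 = (group == groups[0]).astype(float)
    g2 = (group == groups[1]).astype(float)
    cols = [g1, g2]
    if model == 2:
        cols += [cos_t * g1, sin_t * g1]
    elif model == 3:
        cols += [cos_t * g2, sin_t * g2]
    elif model == 4:
        cols += [cos_t, sin_t]
    elif model == 5:
        cols += [cos_t * g1, sin_t * g1, cos_t * g2, sin_t * g2]
    return np.column_stack(cols)


def _ols(x, y):
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise IdentifiabilityError("rank-deficient cosinor design matrix")
    resid = y - x @ beta
    return beta, float(resid @ resid)


def _bic(rss, n, n_params):
    var = max(rss / n, _RSS_FLOOR_VAR)
    return n * np.log(var) + (n_params + 1) * np.log(n)


def bic_weights(bics: np.ndarray) -> np.ndarray:
    """``softmax(-BIC/2)``; invariant to adding a constant to all BICs."""
    delta = np.asarray(bics, dtype=float)
    delta = delta - delta.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def _amp_phase(a: float, b: float, period: float) -> tuple[float, float]:
    amp = float(np.hypot(a, b))
    phase = float((np.arctan2(b, a) * period / (2.0 * np.pi)) % period)
    return amp, phase


@dataclass
class RhythmFit:
    """Selected rhythmic + mean model for one gene across two groups."""

    gene: str
    groups: tuple[str, str]
    selected_model: int
    bicw: np.ndarray
    confident: bool
    mesor: dict[str, float]
    amplitude: dict[str, float]
    phase: dict[str, float]  # NaN when the group is arrhythmic
    rhythmic_in_reference: bool
    mean_model: str = "shared"
    mean_diff: float = 0.0
    mean_bicw_distinct: float = 0.0


def fit_harmonic_models(
    t: np.ndarray,
    y: np.ndarray,
    group: np.ndarray,
    groups: tuple[str, str],
    period: float = 24.0,
    bicw_threshold: float = DEFAULT_BICW_THRESHOLD,
    gene: str = "",
) -> RhythmFit:
    """Enumerate the five cosinor models for one gene and select by BIC weight.

    ``groups[1]`` is the reference group (group 2). Amplitude is
    ``sqrt(a^2 + b^2)`` and phase the peak time ``atan2(b, a)/omega``
    wrapped into ``[0, period)``.
    """
    if period <= 0:
        raise ParameterError(f"period must be > 0, got {period}")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    _check_groups(t, group, groups)
    n = len(y)

    fits = {}
    bics = np.empty(5)
    for model in range(1, 6):
        x = _model_design(t, group, groups, period, model)
        beta, rss = _ols(x, y)
        fits[model] = beta
        bics[model - 1] = _bic(rss, n, x.shape[1])
    bicw = bic_weights(bics)
    selected = int(np.argmax(bicw)) + 1
    confident = bool(bicw[selected - 1] >= bicw_threshold)

    beta = fits[selected]
    g1, g2 = groups
    mesor = {g1: float(beta[0]), g2: float(beta[1])}
    amplitude = {g1: 0.0, g2: 0.0}
    phase = {g1: float("nan"), g2: float("nan")}
    if selected == 2:
        amplitude[g1], phase[g1] = _amp_phase(beta[2], beta[3], period)
    elif selected == 3:
        amplitude[g2], phase[g2] = _amp_phase(beta[2], beta[3], period)
    elif selected == 4:
        amp, ph = _amp_phase(beta[2], beta[3], period)
        amplitude = {g1: amp, g2: amp}
        phase = {g1: ph, g2: ph}
    elif selected == 5:
        amplitude[g1], phase[g1] = _amp_phase(beta[2], beta[3], period)
        amplitude[g2], phase[g2] = _amp_phase(beta[4], beta[5], period)

    return RhythmFit(
        gene=gene,
        groups=(g1, g2),
        selected_model=selected,
        bicw=bicw,
        confident=confident,
        mesor=mesor,
        amplitude=amplitude,
        phase=phase,
        rhythmic_in_reference=confident and selected in RHYTHMIC_IN_G2,
    )


def fit_mean_models(
    t: np.ndarray,
    y: np.ndarray,
    group: np.ndarray,
    groups: tuple[str, str],
    rhythmic_model: int = 1,
    period: float = 24.0,
) -> tuple[str, float, float]:
    """Compare shared-mean vs group-specific-mean models by BIC weight.

    The rhythmic regressors of ``rhythmic_model`` are retained as
    covariates so a rhythm cannot masquerade as a mean shift. Returns
    ``(selection, mean_diff, bicw_distinct)`` where ``mean_diff`` is the
    group2 − group1 intercept difference from the distinct-means fit.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    for g in groups:
        if not np.any(group == g):
            raise ParameterError(f"group {g!r} has no samples")
    n = len(y)
    x_distinct = _model_design(t, group, groups, period, rhythmic_model)
    # shared model: collapse the two intercept columns into one
    x_shared = np.column_stack([np.ones(n), x_distinct[:, 2:]]) \
        if x_distinct.shape[1] > 2 else np.ones((n, 1))
    beta_d, rss_d = _ols(x_distinct, y)
    _, rss_s = _ols(x_shared, y)
    bics = np.array(
        [
            _bic(rss_s, n, x_shared.shape[1]),
            _bic(rss_d, n, x_distinct.shape[1]),
        ]
    )
    w = bic_weights(bics)
    selection = "distinct" if w[1] > w[0] else "shared"
    mean_diff = float(beta_d[1] - beta_d[0])
    return selection, mean_diff, float(w[1])


def fit_gene_table(
    expression: pd.DataFrame,
    reference: str = "WT",
    period: float = 24.0,
    bicw_threshold: float = DEFAULT_BICW_THRESHOLD,
) -> pd.DataFrame:
    """Fit rhythmic and mean models for every gene of a long-format table.

    ``expression`` needs columns gene, genotype, zt, value. The reference
    genotype is mapped to group 2; the other genotype becomes group 1.
    Returns one row per gene with the selection results.
    """
    genotypes = sorted(expression["genotype"].unique())
    if reference not in genotypes:
        raise ParameterError(f"reference group {reference!r} not in table")
    others = [g for g in genotypes if g != reference]
    if len(others) != 1:
        raise ParameterError(
            f"need exactly two genotypes, got {genotypes}"
        )
    groups = (others[0], reference)
    rows = []
    for gene, sub in expression.groupby("gene", sort=True):
        t = sub["zt"].to_numpy(dtype=float)
        y = sub["value"].to_numpy(dtype=float)
        grp = sub["genotype"].to_numpy()
        fit = fit_harmonic_models(
            t, y, grp, groups, period=period,
            bicw_threshold=bicw_threshold, gene=gene,
        )
        mean_sel, mean_diff, mean_w = fit_mean_models(
            t, y, grp, groups, rhythmic_model=fit.selected_model, period=period
        )
        fit.mean_model = mean_sel
        fit.mean_diff = mean_diff
        fit.mean_bicw_distinct = mean_w
        rows.append(
            {
                "gene": gene,
                "selected_model": fit.selected_model,
                **{f"bicw_{i + 1}": fit.bicw[i] for i in range(5)},
                "confident": fit.confident,
                "mesor_g1": fit.mesor[groups[0]],
                "mesor_g2": fit.mesor[groups[1]],
                "amplitude_g1": fit.amplitude[groups[0]],
                "amplitude_g2": fit.amplitude[groups[1]],
                "phase_g1": fit.phase[groups[0]],
                "phase_g2": fit.phase[groups[1]],
                "rhythmic_in_reference": fit.rhythmic_in_reference,
                "mean_model": fit.mean_model,
                "mean_diff": fit.mean_diff,
                "mean_bicw_distinct": fit.mean_bicw_distinct,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def peak_phase_filter(
    fits: pd.DataFrame, window: tuple[float, float] = (14.0, 22.0)
) -> list[str]:
    """Genes rhythmic in the reference group peaking within ``window`` (inclusive).

    ``fits`` is the output of :func:`fit_gene_table`; the reference-group
    phase (``phase_g2``) is tested against the closed interval.
    """
    lo, hi = window
    mask = (
        fits["rhythmic_in_reference"]
        & (fits["phase_g2"] >= lo)
        & (fits["phase_g2"] <= hi)
    )
    return sorted(fits.index[mask.fillna(False)])
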