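"""Feature filtering, pooled-reference normalization, PCA QC and outlier flags."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, DesignError, ParameterError
from .io import LOG2, RAW, AbundanceMatrix, validate_design

logger = logging.getLogger(__name__)

FLAG_COLUMNS = ("flag_contaminant", "flag_decoy", "flag_single_oxidized")


def filter_features(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Drop decoy, contaminant and single-oxidized-peptide features.

    Survivor order is preserved; the number removed is logged. Filtering
    is idempotent and may return an empty matrix (with a warning).
    """
    flags = np.zeros(len(matrix.feature_ids), dtype=bool)
    for col in FLAG_COLUMNS:
        if col in matrix.meta.columns:
            flags |= matrix.meta[col].to_numpy(dtype=bool)
    keep = matrix.feature_ids[~flags]
    removed = int(flags.sum())
    logger.info("filter_features: removed %d of %d features", removed, len(flags))
    if len(keep) == 0:
        logger.warning("filter_features: no features survive filtering")
    return matrix.subset_features(keep)


def reference_normalize(
    matrix: AbundanceMatrix, design: pd.DataFrame
) -> AbundanceMatrix:
    """Log2-ratio each sample to its plex's pooled reference, then median-center.

    ``value(p, s) = log2 I(p, s) - log2 I(p, ref(plex(s)))`` followed by
    per-sample median subtraction. Reference samples are dropped from the
    output, which is tagged log2-normalized. Multiplicative per-plex batch
    factors cancel exactly in the ratio.
    """
    validate_design(design)
    if matrix.scale != RAW:
        raise ParameterError("reference_normalize expects a raw-intensity matrix")
    vals = matrix.values
    bad = (vals <= 0) | ~np.isfinite(vals)
    if bad.to_numpy().any():
        p_idx, s_idx = np.argwhere(bad.to_numpy())[0]
        raise ParameterError(
            "nonpositive intensity at protein "
            f"{vals.index[p_idx]!r}, sample {vals.columns[s_idx]!r}"
        )
    log2_vals = np.log2(vals)
    ref_of_plex = (
        design.loc[design["is_reference"]].set_index("plex")["sample"].to_dict()
    )
    nonref = design[~design["is_reference"]]
    out = {}
    for row in nonref.itertuples(index=False):
        ref = ref_of_plex[row.plex]
        ratio = log2_vals[row.sample] - log2_vals[ref]
        out[row.sample] = ratio - ratio.median()
    normalized = pd.DataFrame(out, index=vals.index)
    return AbundanceMatrix(normalized, matrix.meta.copy(), scale=LOG2)


@dataclass
class PcaResult:
    """Sample scores (samples × components) and explained-variance fractions."""

    scores: pd.DataFrame
    explained: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained) > 1e-12):
            raise DegenerateInputError("explained variance fractions must be non-increasing")


def pca(matrix: AbundanceMatrix) -> PcaResult:
    """PCA of samples on centered, unscaled log2 values (via SVD).

    Features with any missing value are dropped (complete-case, logged).
    Scores reproduce the centered data when projected back; a constant
    matrix raises :class:`DegenerateInputError`.
    """
    if matrix.scale != LOG2:
        raise ParameterError("pca expects a log2-normalized matrix")
    vals = matrix.values
    complete = vals.dropna(axis=0)
    if len(complete) < len(vals):
        logger.info("pca: dropped %d incomplete features", len(vals) - len(complete))
    x = complete.to_numpy(dtype=float).T  # samples x features
    if x.shape[0] < 2:
        raise DesignError("pca needs at least 2 samples")
    xc = x - x.mean(axis=0, keepdims=True)
    total_var = float((xc**2).sum())
    if total_var == 0.0:
        raise DegenerateInputError("constant matrix has no principal components")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    # sign convention: largest-magnitude loading of each score column positive
    signs = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    scores = u * s * signs
    explained = s**2 / (s**2).sum()
    score_df = pd.DataFrame(
        scores,
        index=vals.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return PcaResult(score_df, explained)


def flag_outliers(
    pca_result: PcaResult, design: pd.DataFrame, k: float = 3.0
) -> list[str]:
    """Flag samples far from their (genotype, feeding) centroid in PC1/PC2.

    A sample is flagged iff its Euclidean distance to its (genotype,
    feeding) centroid in the first two components exceeds ``k`` times the
    median within-group distance. The centroid of each sample is the
    component-wise median of the *other* group members (a plain mean
    centroid is dragged toward the very outlier being tested) and the
    median distance is taken over all samples of all usable groups (a
    per-group median would let a single gross outlier inflate its own
    group's scale). Groups with fewer than 3 samples are skipped with a
    warning. Flags are returned (and logged), never silently applied.
    """
    validate_design(design)
    pcs = pca_result.scores.iloc[:, :2]
    nonref = design[~design["is_reference"]]
    nonref = nonref[nonref["sample"].isin(pcs.index)]
    dists: dict[str, float] = {}
    for (genotype, feeding), grp in nonref.groupby(["genotype", "feeding"]):
        if len(grp) < 3:
            logger.warning(
                "flag_outliers: group (%s, %s) has %d samples, skipped",
                genotype, feeding, len(grp),
            )
            continue
        coords = pcs.loc[grp["sample"]].to_numpy()
        for i, sample in enumerate(grp["sample"]):
            peers = np.delete(coords, i, axis=0)
            centroid = np.median(peers, axis=0)
            dists[sample] = float(np.linalg.norm(coords[i] - centroid))
    if not dists:
        return []
    # floor the median at a sliver of the overall score scale so that
    # numerically-zero within-group spread (noiseless data) never flags
    scale = float(np.sqrt(np.mean(pcs.loc[list(dists)].to_numpy() ** 2)))
    cutoff = k * max(float(np.median(list(dists.values()))), 1e-9 * scale)
    flagged = []
    for sample, d in dists.items():
        if d > cutoff:
            flagged.append(sample)
            logger.info(
                "flag_outliers: %s distance %.3g > cutoff %.3g (k=%g)",
                sample, d, cutoff, k,
            )
    return sorted(flagged)


def drop_samples(
    matrix: AbundanceMatrix, design: pd.DataFrame, samples: list[str]
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Explicit exclusion step: remove the given samples from matrix + design."""
    keep_cols = [s for s in matrix.sample_ids if s not in set(samples)]
    new_design = design[~design["sample"].isin(set(samples))].reset_index(drop=True)
    return matrix.subset_samples(keep_cols), new_design
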