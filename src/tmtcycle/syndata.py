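"""Synthetic multi-plex proteome and diurnal transcriptome generator.

Datasets are generated on log2 scale and exponentiated, with planted
ground-truth labels (genotype dependence, rescue status, feeding
response, rhythmicity, mean shifts, secretion annotation) so that every
downstream decision rule can be scored against a known truth.

Randomness: one :class:`numpy.random.Generator` seeded from the single
integer seed drives each operation, spawned through
``default_rng([stream, seed])`` with a fixed stream id per operation
(0 = design, 1 = proteome, 2 = transcriptome), so adding draws to one
operation never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import IdentifiabilityError, ParameterError, SizingError
from .io import (
    FEEDINGS,
    GENOTYPES,
    POOL,
    RAW,
    AbundanceMatrix,
    validate_design,
)

_DESIGN_STREAM = 0
_PROTEOME_STREAM = 1
_TRANSCRIPTOME_STREAM = 2


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic generator; all effects in log2 units."""

    n_proteins: int = 5000
    n_genes: int = 2000
    n_per_group: int = 4
    genotypes: tuple[str, ...] = GENOTYPES
    feedings: tuple[str, ...] = FEEDINGS
    n_plexes: int = 3
    channels_per_plex: int = 10
    frac_dependent: float = 0.12
    frac_rescued_given_dependent: float = 0.5
    frac_feeding_responsive: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.0, "KO": 0.0, "RE": 0.1}
    )
    effect_log2: float = 1.0
    sigma: float = 0.25
    plex_sd: float = 0.3
    frac_flagged: float = 0.02
    frac_secreted: float = 0.10
    secreted_enrichment: float = 4.0
    corrupt_outlier: bool = False
    # transcriptome
    frac_rhythmic: float = 0.3
    amp_range: tuple[float, float] = (0.5, 2.0)
    frac_rhythm_lost_in_ko: float = 0.6
    frac_mean_shift: float = 0.15
    mean_shift_log2: float = 1.0
    frac_mapped: float = 0.7
    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    reps_per_time: int = 3
    sigma_expr: float = 0.25
    tissue: str = "liver"
    seed: int = 0

    def __post_init__(self) -> None:
        props = {
            "frac_dependent": self.frac_dependent,
            "frac_rescued_given_dependent": self.frac_rescued_given_dependent,
            "frac_flagged": self.frac_flagged,
            "frac_secreted": self.frac_secreted,
            "frac_rhythmic": self.frac_rhythmic,
            "frac_rhythm_lost_in_ko": self.frac_rhythm_lost_in_ko,
            "frac_mean_shift": self.frac_mean_shift,
            "frac_mapped": self.frac_mapped,
            **{
                f"frac_feeding_responsive[{g}]": v
                for g, v in self.frac_feeding_responsive.items()
            },
        }
        for name, value in props.items():
            if not (0.0 <= value <= 1.0) or not math.isfinite(value):
                raise ParameterError(f"{name} must be in [0, 1], got {value}")
        for name in (
            "effect_log2", "sigma", "plex_sd", "mean_shift_log2",
            "secreted_enrichment", "sigma_expr",
        ):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ParameterError(f"{name} must be finite, got {value}")
        if self.effect_log2 <= 0:
            raise ParameterError("effect_log2 must be > 0")
        if self.sigma < 0 or self.sigma_expr < 0 or self.plex_sd < 0:
            raise ParameterError("standard deviations must be >= 0")
        if not all(0 <= t < 24 for t in self.timepoints):
            raise ParameterError("timepoints must lie in [0, 24)")
        if not (0 < self.amp_range[0] <= self.amp_range[1]):
            raise ParameterError("amp_range must satisfy 0 < lo <= hi")


def _rng(params: SimParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, params.seed])


# ---------------------------------------------------------------------------
# design


def generate_design(params: SimParams) -> pd.DataFrame:
    """Assign genotype × feeding × replicate samples to plexes and channels.

    Each plex reserves one channel for the pooled reference. Samples are
    distributed over plexes in a seeded random order; the assignment is
    fully determined by the seed.
    """
    groups = [(g, f) for g in params.genotypes for f in params.feedings]
    samples = [
        (f"{g}_{f}_{r + 1}", g, f, r + 1)
        for g, f in groups
        for r in range(params.n_per_group)
    ]
    free_per_plex = params.channels_per_plex - 1
    capacity = params.n_plexes * free_per_plex
    if len(samples) > capacity:
        raise SizingError(
            f"design needs {len(samples)} sample channels but only "
            f"{capacity} are available "
            f"({params.n_plexes} plexes x {free_per_plex} free channels)"
        )
    rng = _rng(params, _DESIGN_STREAM)
    order = rng.permutation(len(samples))
    rows = []
    for plex_idx in range(params.n_plexes):
        plex = f"plex{plex_idx + 1}"
        rows.append(
            {
                "sample": f"REF_{plex}",
                "tissue": params.tissue,
                "genotype": POOL,
                "feeding": POOL,
                "plex": plex,
                "channel": "ch01",
                "is_reference": True,
                "replicate": 0,
            }
        )
    for slot, idx in enumerate(order):
        sample, genotype, feeding, rep = samples[idx]
        plex_idx, chan_idx = divmod(slot, free_per_plex)
        rows.append(
            {
                "sample": sample,
                "tissue": params.tissue,
                "genotype": genotype,
                "feeding": feeding,
                "plex": f"plex{plex_idx + 1}",
                "channel": f"ch{chan_idx + 2:02d}",
                "is_reference": False,
                "replicate": rep,
            }
        )
    design = pd.DataFrame(rows).sort_values(
        ["plex", "channel"], ignore_index=True
    )
    return validate_design(design)


# ---------------------------------------------------------------------------
# proteome


def simulate_proteome(
    design: pd.DataFrame, params: SimParams
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Simulate raw reporter intensities plus ground-truth labels.

    Per protein p and sample s the log2 intensity is
    ``base_p + effect(genotype, feeding) + batch(plex) + N(0, sigma)``.
    The pooled reference channel emulates a single pool mixed from *all*
    samples and aliquoted into each plex: it carries the study-wide mean
    of the noiseless log2 values plus that plex's batch term, making
    reference normalization exact (batch and pool terms cancel) in the
    noiseless limit.

    Returns the matrix on raw-intensity scale and a ground-truth frame
    indexed by protein id.
    """
    validate_design(design)
    rng = _rng(params, _PROTEOME_STREAM)
    n = params.n_proteins
    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id")
    genes = [f"G{i:05d}" for i in range(n)]

    base = rng.normal(20.0, 2.0, size=n)
    dependent = rng.random(n) < params.frac_dependent
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    rescued = dependent & (rng.random(n) < params.frac_rescued_given_dependent)

    feeding_resp = {}
    feeding_dir = {}
    for g in params.genotypes:
        frac = params.frac_feeding_responsive.get(g, 0.0)
        feeding_resp[g] = rng.random(n) < frac
        feeding_dir[g] = np.where(rng.random(n) < 0.5, 1.0, -1.0)

    # secretion annotation enriched among dependent proteins (odds multiplier)
    p0 = params.frac_secreted
    if p0 in (0.0, 1.0):
        p_dep = p0
    else:
        odds = p0 / (1.0 - p0) * params.secreted_enrichment
        p_dep = odds / (1.0 + odds)
    secreted = rng.random(n) < np.where(dependent, p_dep, p0)

    flag_kind = rng.integers(0, 3, size=n)
    flagged = rng.random(n) < params.frac_flagged
    flag_contaminant = flagged & (flag_kind == 0)
    flag_decoy = flagged & (flag_kind == 1)
    flag_single_ox = flagged & (flag_kind == 2)

    plexes = sorted(design["plex"].unique())
    batch = dict(zip(plexes, rng.normal(0.0, params.plex_sd, size=len(plexes))))

    nonref = design[~design["is_reference"]]
    outlier_sample = None
    if params.corrupt_outlier:
        ko_trf = nonref[(nonref["genotype"] == "KO") & (nonref["feeding"] == "TRF")]
        if len(ko_trf):
            outlier_sample = ko_trf["sample"].iloc[0]

    def group_effect(genotype: str, feeding: str) -> np.ndarray:
        eff = np.zeros(n)
        if genotype == "KO":
            eff += np.where(dependent, direction * params.effect_log2, 0.0)
        elif genotype == "RE":
            eff += np.where(
                dependent & ~rescued, direction * params.effect_log2, 0.0
            )
        if feeding == "TRF":
            eff += np.where(
                feeding_resp[genotype],
                feeding_dir[genotype] * params.effect_log2,
                0.0,
            )
        return eff

    clean = {}  # noiseless log2 value per sample, excl. batch
    for row in nonref.itertuples(index=False):
        clean[row.sample] = base + group_effect(row.genotype, row.feeding)
    pool = np.mean([clean[s] for s in nonref["sample"]], axis=0)

    values = pd.DataFrame(index=ids, columns=list(design["sample"]), dtype=float)
    for row in nonref.itertuples(index=False):
        noisy = (
            clean[row.sample]
            + batch[row.plex]
            + rng.normal(0.0, params.sigma, size=n)
        )
        if row.sample == outlier_sample:
            noisy = noisy + rng.uniform(-4.0, 4.0, size=n)
        values[row.sample] = np.exp2(noisy)
    for row in design[design["is_reference"]].itertuples(index=False):
        values[row.sample] = np.exp2(pool + batch[row.plex])

    meta = pd.DataFrame(
        {
            "gene": genes,
            "n_peptides": rng.integers(1, 30, size=n),
            "flag_contaminant": flag_contaminant,
            "flag_decoy": flag_decoy,
            "flag_single_oxidized": flag_single_ox,
            "secreted": secreted,
        },
        index=ids,
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "dependent": dependent,
            "direction": np.where(dependent, direction, 0.0),
            "rescued": rescued,
            **{
                f"feeding_responsive_{g}": feeding_resp[g]
                for g in params.genotypes
            },
            "secreted": secreted,
            "flagged": flagged,
            "outlier_sample": outlier_sample or "",
        },
        index=ids,
    )
    return AbundanceMatrix(values, meta, scale=RAW), truth


# ---------------------------------------------------------------------------
# transcriptome


def simulate_transcriptome(
    params: SimParams, protein_truth: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-genotype (WT/KO) diurnal expression table.

    Rhythmic genes follow ``mesor + A*cos(2*pi*(t - phase)/24)`` plus
    Gaussian noise; a configurable subset loses its rhythm in KO, and
    mean-shift genes differ in mesor between genotypes. The first
    ``frac_mapped`` share of genes reuses the protein gene-symbol space so
    proteome and transcriptome can be joined; when ``protein_truth`` is
    given its per-protein labels drive nothing directly, but the returned
    truth records the mapping so planted cross-layer overlaps can be
    engineered by the caller.

    Returns a long-format table (gene, genotype, zt, rep, value) and the
    per-gene ground truth.
    """
    if len(set(params.timepoints)) < 4:
        raise IdentifiabilityError(
            "need >=4 distinct timepoints to identify a 3-parameter cosinor; "
            f"got {sorted(set(params.timepoints))}"
        )
    rng = _rng(params, _TRANSCRIPTOME_STREAM)
    n = params.n_genes
    n_mapped = int(round(params.frac_mapped * n))
    ids = [f"G{i:05d}" for i in range(n_mapped)] + [
        f"GX{i:05d}" for i in range(n - n_mapped)
    ]

    mesor = rng.normal(8.0, 1.0, size=n)
    rhythmic = rng.random(n) < params.frac_rhythmic
    amp = np.where(
        rhythmic, rng.uniform(*params.amp_range, size=n), 0.0
    )
    phase = np.where(rhythmic, rng.uniform(0.0, 24.0, size=n), np.nan)
    lost_in_ko = rhythmic & (rng.random(n) < params.frac_rhythm_lost_in_ko)
    mean_shift = np.where(
        rng.random(n) < params.frac_mean_shift,
        np.where(rng.random(n) < 0.5, 1.0, -1.0) * params.mean_shift_log2,
        0.0,
    )

    times = np.asarray(params.timepoints, dtype=float)
    rows = []
    for genotype in ("WT", "KO"):
        geno_mesor = mesor + (mean_shift if genotype == "KO" else 0.0)
        geno_amp = np.where(lost_in_ko, 0.0, amp) if genotype == "KO" else amp
        for t in times:
            cos_term = geno_amp * np.cos(2.0 * np.pi * (t - np.nan_to_num(phase)) / 24.0)
            mu = geno_mesor + np.where(rhythmic, cos_term, 0.0)
            for rep in range(1, params.reps_per_time + 1):
                vals = mu + rng.normal(0.0, params.sigma_expr, size=n)
                rows.append(
                    pd.DataFrame(
                        {
                            "gene": ids,
                            "genotype": genotype,
                            "zt": t,
                            "rep": rep,
                            "value": vals,
                        }
                    )
                )
    table = pd.concat(rows, ignore_index=True)

    truth = pd.DataFrame(
        {
            "gene": ids,
            "rhythmic": rhythmic,
            "amplitude": amp,
            "phase": phase,
            "rhythmic_in_ko": rhythmic & ~lost_in_ko,
            "mean_shift": mean_shift,
            "mapped": [not g.startswith("GX") for g in ids],
        }
    ).set_index("gene")
    return table, truth


# ---------------------------------------------------------------------------
# convenience bundle


def simulate_all(params: SimParams) -> dict:
    """Generate design, proteome and transcriptome in one call."""
    design = generate_design(params)
    matrix, protein_truth = simulate_proteome(design, params)
    expression, gene_truth = simulate_transcriptome(params, protein_truth)
    return {
        "design": design,
        "matrix": matrix,
        "protein_truth": protein_truth,
        "expression": expression,
        "gene_truth": gene_truth,
    }
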