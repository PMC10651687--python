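"""Tabular readers/writers and the core in-memory types.

All tables are tab-separated UTF-8 text with ``.`` as the decimal mark.
Floats are written with 12 significant digits so that write→read
round-trips are lossless at that precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import IntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

GENOTYPES = ("WT", "KO", "RE")
FEEDINGS = ("AL", "TRF")
#: genotype/feeding placeholder used on pooled-reference rows
POOL = "POOL"

RAW = "raw"
LOG2 = "log2-normalized"

DESIGN_COLUMNS = [
    "sample",
    "tissue",
    "genotype",
    "feeding",
    "plex",
    "channel",
    "is_reference",
    "replicate",
]

META_COLUMNS = [
    "gene",
    "n_peptides",
    "flag_contaminant",
    "flag_decoy",
    "flag_single_oxidized",
]

FLOAT_FMT = "%.12g"


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-design table and return it unchanged.

    Raises
    ------
    SchemaError
        If required columns are missing.
    IntegrityError
        If (plex, channel) pairs or sample ids are duplicated, a plex does
        not have exactly one reference row, or genotype/feeding labels on
        non-reference rows are outside the declared vocabularies.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise SchemaError(f"design table missing columns: {missing}")
    if design["sample"].duplicated().any():
        dupes = design.loc[design["sample"].duplicated(), "sample"].tolist()
        raise IntegrityError(f"duplicated sample ids: {dupes}")
    if design.duplicated(subset=["plex", "channel"]).any():
        raise IntegrityError("duplicated (plex, channel) assignment")
    # a raw design carries exactly one reference per plex; a design that
    # has already been through normalization carries none
    if design["is_reference"].any():
        refs_per_plex = design.groupby("plex")["is_reference"].sum()
        bad = refs_per_plex[refs_per_plex != 1]
        if len(bad):
            raise IntegrityError(
                "each plex needs exactly one reference sample; "
                f"got {bad.to_dict()}"
            )
    nonref = design[~design["is_reference"]]
    bad_geno = set(nonref["genotype"]) - set(GENOTYPES)
    bad_feed = set(nonref["feeding"]) - set(FEEDINGS)
    if bad_geno or bad_feed:
        raise IntegrityError(
            f"unknown labels: genotype={sorted(bad_geno)} feeding={sorted(bad_feed)}"
        )
    return design


@dataclass
class AbundanceMatrix:
    """Features × samples abundance grid plus per-feature metadata.

    ``values`` is indexed by feature id with one column per sample id;
    ``meta`` is indexed identically and carries gene symbol, peptide count
    and the contaminant/decoy/single-oxidized flags. ``scale`` tags the
    unit of ``values`` (:data:`RAW` intensities or :data:`LOG2`).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise IntegrityError(f"unknown value scale tag: {self.scale!r}")
        if self.values.index.duplicated().any():
            raise IntegrityError("duplicated feature ids in abundance matrix")
        if self.values.columns.duplicated().any():
            raise IntegrityError("duplicated sample ids in abundance matrix")
        if not self.values.index.equals(self.meta.index):
            raise IntegrityError("values and metadata feature ids differ")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_features(self, ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.loc[ids], self.meta.loc[ids], scale=self.scale
        )

    def subset_samples(self, ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values[list(ids)], self.meta.copy(), scale=self.scale
        )


@dataclass(frozen=True)
class GeneSet:
    """A named collection of feature identifiers (one GMT line)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise IntegrityError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise IntegrityError(f"gene set {self.name!r} has duplicate members")


# ---------------------------------------------------------------------------
# readers / writers


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    validate_design(design)
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"plex": str, "channel": str})
    design["is_reference"] = design["is_reference"].astype(bool)
    return validate_design(design)


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    out = matrix.meta.copy()
    out.insert(0, "protein_id", matrix.feature_ids)
    for col in matrix.sample_ids:
        out[col] = matrix.values[col].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_abundance(
    path: str | Path, design: pd.DataFrame, scale: str = RAW
) -> AbundanceMatrix:
    """Read an abundance TSV, validating it against the sample design.

    Every sample named in ``design`` must be a column of the file. Feature
    (row) order of the input is preserved.
    """
    validate_design(design)
    table = pd.read_csv(path, sep="\t")
    required = ["protein_id"] + META_COLUMNS
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"abundance table missing columns: {missing}")
    missing_samples = [s for s in design["sample"] if s not in table.columns]
    if missing_samples:
        raise SchemaError(
            f"abundance table missing design samples: {missing_samples}"
        )
    if table["protein_id"].duplicated().any():
        dupes = table.loc[table["protein_id"].duplicated(), "protein_id"].tolist()
        raise IntegrityError(f"duplicated protein ids: {dupes}")
    table = table.set_index("protein_id")
    meta_cols = [c for c in table.columns if c in META_COLUMNS or c == "secreted"]
    meta = table[meta_cols].copy()
    for c in meta.columns:
        if c.startswith("flag_") or c == "secreted":
            meta[c] = meta[c].astype(bool)
    values = table[list(design["sample"])].astype(float)
    return AbundanceMatrix(values, meta, scale=scale)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are dropped (first occurrence kept)
    with a logged warning; a line with fewer than three fields raises
    :class:`ParseError` carrying the 1-based line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >=3 tab-separated fields, got {len(fields)}",
                    line=lineno,
                )
            name, description = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    logger.warning(
                        "gene set %r line %d: duplicate member %r dropped",
                        name, lineno, m,
                    )
                    continue
                seen.add(m)
                members.append(m)
            sets.append(GeneSet(name, description, tuple(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def write_expression(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_expression(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = ["gene", "genotype", "zt", "rep", "value"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"expression table missing columns: {missing}")
    return table


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
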