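"""Tabular I/O for the pipeline: protein-group intensity tables, sample
designs, and GO annotation maps.

All files are UTF-8, tab-separated, one header row (the MaxQuant
``proteinGroups`` dialect for the intensity table). Zero, blank, and
non-numeric intensity cells are read as *missing* — in label-free
quantification a zero is an absent low-abundance measurement, not a
measured zero. Readers tolerate both Unix and Windows line endings
(pandas handles either transparently).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "IntensityMatrix",
    "GOAnnotationMap",
    "read_design",
    "read_protein_groups",
    "read_go_map",
    "write_protein_groups",
    "write_design",
    "write_go_map",
]

TREATMENT_LEVELS = ("control", "treated")
GO_ASPECTS = ("BP", "CC", "MF")


class TableValidationError(ValueError):
    """A tabular artifact violated one of its structural invariants."""


@dataclass(frozen=True)
class SampleDesign:
    """Experimental design: one row per sample.

    Columns: ``sample_id``, ``isolate``, ``treatment`` (``control`` or
    ``treated``), ``dose`` (µM, numeric annotation), ``replicate``
    (positive integer). (isolate, treatment, replicate) triples are
    unique and every (isolate, treatment) group has at least two
    replicates, without which a within-group variance is undefined.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "isolate", "treatment", "dose", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise TableValidationError(f"design is missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise TableValidationError(f"duplicate sample_id {dup!r} in design")
        bad = set(t["treatment"]) - set(TREATMENT_LEVELS)
        if bad:
            raise TableValidationError(
                f"treatment must be one of {TREATMENT_LEVELS}, got {sorted(bad)}"
            )
        if (t["replicate"].astype(int) < 1).any():
            raise TableValidationError("replicate numbers must be positive")
        triples = t[["isolate", "treatment", "replicate"]]
        if triples.duplicated().any():
            row = triples[triples.duplicated()].iloc[0]
            raise TableValidationError(
                "duplicate (isolate, treatment, replicate) triple: "
                f"({row['isolate']}, {row['treatment']}, {row['replicate']})"
            )
        sizes = t.groupby(["isolate", "treatment"]).size()
        small = sizes[sizes < 2]
        if len(small):
            key = small.index[0]
            raise TableValidationError(
                f"group {key} has {small.iloc[0]} replicate(s); "
                "at least 2 are required for a variance"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def isolates(self) -> list[str]:
        return list(dict.fromkeys(self.table["isolate"]))

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """Map (isolate, treatment) → ordered sample_id list."""
        out: dict[tuple[str, str], list[str]] = {}
        for (iso, trt), sub in self.table.groupby(["isolate", "treatment"], sort=False):
            out[(iso, trt)] = list(sub["sample_id"])
        return out

    def samples_for(self, isolate: str, treatment: str) -> list[str]:
        g = self.groups()
        key = (isolate, treatment)
        if key not in g:
            raise KeyError(f"no samples for group {key}")
        return g[key]


@dataclass(frozen=True)
class IntensityMatrix:
    """Protein-group × sample raw intensity matrix bound to a design.

    ``values`` is a DataFrame indexed by accession with one column per
    sample in design order; missing measurements are NaN and every
    present value is strictly positive.
    """

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise TableValidationError(f"duplicate accession {dup!r}")
        if v.columns.duplicated().any():
            raise TableValidationError("duplicate sample columns")
        if v.shape[0] < 1 or v.shape[1] < 2:
            raise TableValidationError(
                f"need at least 1 protein and 2 samples, got {v.shape}"
            )
        if list(v.columns) != self.design.sample_ids:
            raise TableValidationError(
                "intensity columns do not match the design sample order"
            )
        arr = v.to_numpy(dtype=float)
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise TableValidationError(
                "present intensities must be > 0 (zeros are read as missing)"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass(frozen=True)
class GOAnnotationMap:
    """Accession → GO term records (aspect ∈ {BP, CC, MF})."""

    table: pd.DataFrame  # columns: accession, go_id, aspect, term_name

    def __post_init__(self) -> None:
        required = ["accession", "go_id", "aspect", "term_name"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise TableValidationError(f"GO map is missing columns: {missing}")
        bad = set(self.table["aspect"]) - set(GO_ASPECTS)
        if bad:
            raise TableValidationError(
                f"aspect must be one of {GO_ASPECTS}, got {sorted(bad)}"
            )
        pairs = self.table[["accession", "go_id"]]
        if pairs.duplicated().any():
            row = pairs[pairs.duplicated()].iloc[0]
            raise TableValidationError(
                f"duplicate (accession, go_id) pair: ({row['accession']}, {row['go_id']})"
            )

    def __len__(self) -> int:
        return len(self.table)

    def terms_for(self, accession: str) -> pd.DataFrame:
        return self.table[self.table["accession"] == accession]


def read_design(path: str | os.PathLike | io.IOBase) -> SampleDesign:
    """Read and validate a sample design TSV."""
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "isolate": str})
    return SampleDesign(t)


def read_protein_groups(
    path: str | os.PathLike | io.IOBase,
    design: SampleDesign,
    *,
    id_column: str | None = None,
    drop_accessions: Iterable[str] = (),
) -> IntensityMatrix:
    """Read a protein-groups intensity TSV and bind columns to the design.

    The first column (or ``id_column``) holds the UniProt accession; every
    other column is a per-sample intensity and must match a design row.
    Zeros, blanks and non-numeric cells become missing. ``drop_accessions``
    is an optional contaminant/decoy drop list applied after validation;
    no filter is applied by default.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if id_column is None:
        id_column = raw.columns[0]
    if id_column not in raw.columns:
        raise TableValidationError(f"identifier column {id_column!r} not found")
    if raw[id_column].duplicated().any():
        dup = raw.loc[raw[id_column].duplicated(), id_column].iloc[0]
        raise TableValidationError(f"duplicate accession {dup!r} in protein groups file")

    intensity_cols = [c for c in raw.columns if c != id_column]
    unknown = [c for c in intensity_cols if c not in set(design.sample_ids)]
    if unknown:
        raise TableValidationError(
            f"intensity column(s) with no matching design row: {unknown}"
        )
    absent = [s for s in design.sample_ids if s not in intensity_cols]
    if absent:
        raise TableValidationError(f"design sample(s) missing from file: {absent}")

    values = raw.set_index(id_column)[intensity_cols].apply(
        pd.to_numeric, errors="coerce"
    )
    values = values.where(values > 0)  # zeros and negatives → missing
    values = values[design.sample_ids]  # bind: design order, not file order
    drop = set(drop_accessions)
    if drop:
        values = values.loc[[a for a in values.index if a not in drop]]
    return IntensityMatrix(values.astype(float), design)


def read_go_map(path: str | os.PathLike | io.IOBase) -> GOAnnotationMap:
    """Read an (accession, go_id, aspect, term_name) TSV."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    if t.empty and list(t.columns) == [] :
        raise TableValidationError("GO map file has no header")
    return GOAnnotationMap(t)


def write_protein_groups(
    matrix: IntensityMatrix, path: str | os.PathLike, *, float_format: str = "%.6f"
) -> None:
    """Write an intensity matrix as TSV; missing cells become 0 (the
    proteinGroups convention read back as missing)."""
    out = matrix.values.fillna(0.0)
    out.index.name = "accession"
    out.to_csv(path, sep="\t", float_format=float_format)


def write_design(design: SampleDesign, path: str | os.PathLike) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def write_go_map(gomap: GOAnnotationMap, path: str | os.PathLike) -> None:
    gomap.table.to_csv(path, sep="\t", index=False)
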