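"""Core tabular containers shared by every analysis stage.

Quantities are stored in thin dataclass wrappers around pandas objects so
that schema expectations (missingness semantics, sample roles, peptide
flanking residues) are validated once at construction and every downstream
module can rely on them.

Missing intensities are represented as NaN and are *distinct from zero*:
a zero in a DIA report means "not detected", not "absent at zero copies".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "SampleTable",
    "ProteinQuantTable",
    "PeptideQuantTable",
    "EYE_SYNONYMS",
]


class ValidationError(ValueError):
    """A table violates its schema invariants."""


class FormatError(ValueError):
    """An input file does not match the expected dialect."""


#: Accepted spellings for the two eyes, normalized to OD (right) / OS (left).
EYE_SYNONYMS = {
    "od": "OD",
    "right": "OD",
    "r": "OD",
    "oculus dexter": "OD",
    "os": "OS",
    "left": "OS",
    "l": "OS",
    "oculus sinister": "OS",
}

_SAMPLE_COLUMNS = ("person", "eye", "day", "volume", "tpc", "role", "excluded")


def normalize_eye(label: str) -> str:
    key = str(label).strip().lower()
    if key not in EYE_SYNONYMS:
        raise ValidationError(f"unknown eye label: {label!r}")
    return EYE_SYNONYMS[key]


@dataclass
class SampleTable:
    """Per-sample annotations: donor, eye, day, tear volume (µL), total
    protein concentration (µg/µL), replicate role and QC exclusion flag.

    ``df`` is indexed by sample_id.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns and c != "excluded"]
        if missing:
            raise ValidationError(f"sample table lacks columns: {missing}")
        if "excluded" not in df.columns:
            df["excluded"] = False
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id: {dupes}")
        df["eye"] = [normalize_eye(e) for e in df["eye"]]
        df["day"] = df["day"].astype(int)
        if (df["day"] < 1).any():
            raise ValidationError("day must be >= 1")
        for col in ("volume", "tpc"):
            df[col] = df[col].astype(float)
            if (df[col] < 0).any():
                raise ValidationError(f"{col} must be non-negative")
        bad_roles = set(df["role"]) - {"biological", "technical_replicate"}
        if bad_roles:
            raise ValidationError(f"unknown sample roles: {sorted(bad_roles)}")
        bio = df[df["role"] == "biological"]
        key = bio[["person", "eye", "day"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValidationError("duplicate (person, eye, day) among biological samples")
        self.df = df

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def biological_ids(self, include_excluded: bool = False) -> list[str]:
        mask = self.df["role"] == "biological"
        if not include_excluded:
            mask &= ~self.df["excluded"]
        return list(self.df.index[mask])

    @property
    def persons(self) -> list[str]:
        return sorted(self.df.loc[self.df["role"] == "biological", "person"].unique())

    def person_of(self, sample_id: str) -> str:
        return str(self.df.at[sample_id, "person"])

    def copy(self) -> "SampleTable":
        return SampleTable(self.df.copy())


@dataclass
class ProteinQuantTable:
    """Protein-group × sample intensity matrix with explicit missingness.

    ``values``: DataFrame (rows = protein_group_id, columns = sample_id),
    NaN marks a missing (undetected) intensity. ``genes`` maps each protein
    group to a gene symbol. ``annotations`` holds optional per-protein maps
    (e.g. GO category strings keyed by annotation name).
    """

    values: pd.DataFrame
    genes: pd.Series
    annotations: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.genes.index):
            self.genes = self.genes.reindex(self.values.index)
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate protein_group_id")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError("negative intensity")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def observed(self) -> pd.DataFrame:
        """Boolean mask of detected entries."""
        return self.values.notna()

    def subset_samples(self, sample_ids) -> "ProteinQuantTable":
        return ProteinQuantTable(self.values[list(sample_ids)].copy(), self.genes.copy(),
                                 dict(self.annotations))

    def subset_proteins(self, protein_ids) -> "ProteinQuantTable":
        idx = list(protein_ids)
        return ProteinQuantTable(
            self.values.loc[idx].copy(), self.genes.loc[idx].copy(),
            {k: v.reindex(idx) for k, v in self.annotations.items()})

    def ids_for_genes(self, genes) -> list[str]:
        """Protein group ids whose gene symbol is in ``genes`` (order kept)."""
        wanted = set(genes)
        return [pid for pid, g in self.genes.items() if g in wanted]

    def drop_empty(self) -> "ProteinQuantTable":
        """Drop proteins without a single observed value."""
        keep = self.values.notna().any(axis=1)
        return self.subset_proteins(self.values.index[keep])

    def log2(self) -> pd.DataFrame:
        """Log2 intensities (NaN preserved; zeros would be invalid here)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.values)

    def copy(self) -> "ProteinQuantTable":
        return ProteinQuantTable(self.values.copy(), self.genes.copy(),
                                 {k: v.copy() for k, v in self.annotations.items()})


@dataclass
class PeptideQuantTable:
    """Peptide precursor rows with flanking residues and per-sample intensities.

    ``meta``: DataFrame indexed by peptide_id with columns sequence, prev_aa,
    next_aa, modified (bool), protein_group_id and (after classification)
    cleavage_class. ``values``: peptide × sample intensity matrix.
    """

    meta: pd.DataFrame
    values: pd.DataFrame

    _META_REQUIRED = ("sequence", "prev_aa", "next_aa", "modified", "protein_group_id")

    def __post_init__(self) -> None:
        missing = [c for c in self._META_REQUIRED if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"peptide table lacks columns: {missing}")
        if not self.meta.index.equals(self.values.index):
            raise ValidationError("peptide meta and values indexes differ")

    def check_parents(self, proteins: ProteinQuantTable) -> None:
        orphan = set(self.meta["protein_group_id"]) - set(proteins.protein_ids)
        if orphan:
            raise ValidationError(
                f"{len(orphan)} peptides reference protein groups absent "
                f"from the protein table (e.g. {sorted(orphan)[:3]})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "PeptideQuantTable":
        return PeptideQuantTable(self.meta.copy(), self.values.copy())


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
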