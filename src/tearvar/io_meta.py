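"""Reading/writing quantitative reports and sample metadata.

Two report dialects are supported:

* ``long_report`` — one row per (run, protein group) in the style of text
  reports from DIA-type quantification software (columns ``Run``,
  ``Protein.Group``, ``Genes``, ``PG.MaxLFQ``; optional precursor columns
  ``Precursor.Id``, ``Stripped.Sequence``, ``Precursor.Quantity`` plus
  flanking-residue columns for cleavage classification).
* ``wide_matrix`` — protein_group_id, gene, then one intensity column per
  sample.

Zero intensities are converted to missing by default: DIA reports conflate
"not detected" with zero. Duplicate (protein, run) rows are summed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (FormatError, PeptideQuantTable, ProteinQuantTable,
                     SampleTable, ValidationError)

__all__ = [
    "read_quant_report",
    "write_quant_report",
    "read_sample_table",
    "write_sample_table",
    "filter_by_detection",
    "top_share",
    "LONG_COLUMNS",
]

#: Default column names of the long dialect; overridable via ``column_map``.
LONG_COLUMNS = {
    "run": "Run",
    "protein_group": "Protein.Group",
    "gene": "Genes",
    "intensity": "PG.MaxLFQ",
    "precursor": "Precursor.Id",
    "sequence": "Stripped.Sequence",
    "precursor_intensity": "Precursor.Quantity",
    "prev_aa": "Prev.AA",
    "next_aa": "Next.AA",
    "modified": "Modified",
    "cleavage_class": "Cleavage.Class",
}


def read_quant_report(path, format: str = "long_report", column_map: dict | None = None,
                      zero_as_missing: bool = True):
    """Read a quantification report.

    Returns ``(ProteinQuantTable, PeptideQuantTable | None)``; the peptide
    table is populated only for long reports carrying precursor columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "wide_matrix":
        df = pd.read_csv(path, sep="\t")
        required = ["protein_group_id", "gene"]
        absent = [c for c in required if c not in df.columns]
        if absent:
            raise FormatError(f"wide matrix lacks columns: {absent}")
        df = df.set_index("protein_group_id")
        genes = df.pop("gene")
        values = df.astype(float)
        if zero_as_missing:
            values = values.where(values != 0.0)
        return ProteinQuantTable(values, genes), None
    if format != "long_report":
        raise FormatError(f"unknown report format: {format!r}")

    cols = dict(LONG_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t")
    required = [cols[k] for k in ("run", "protein_group", "gene", "intensity")]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise FormatError(f"long report lacks columns: {absent}")

    has_precursors = cols["precursor"] in df.columns
    if has_precursors:
        # PG.MaxLFQ is a protein-level quantity repeated on every precursor
        # row: take it once per (protein, run) instead of summing copies
        protein_rows = df[df[cols["precursor"]].isna()]
        if protein_rows.empty:
            protein_rows = df
        pg = (protein_rows.groupby([cols["protein_group"], cols["run"]])[cols["intensity"]]
              .first().unstack(cols["run"]))
    else:
        pg = (df.groupby([cols["protein_group"], cols["run"]])[cols["intensity"]]
                .sum(min_count=1).unstack(cols["run"]))
    pg.index.name = "protein_group_id"
    genes = (df.groupby(cols["protein_group"])[cols["gene"]].first()
               .reindex(pg.index))
    genes.name = "gene"
    values = pg.astype(float)
    if zero_as_missing:
        values = values.where(values != 0.0)
    proteins = ProteinQuantTable(values, genes)

    peptides = None
    if cols["precursor"] in df.columns and cols["precursor_intensity"] in df.columns:
        pep = df.dropna(subset=[cols["precursor"]])
        vals = (pep.groupby([cols["precursor"], cols["run"]])[cols["precursor_intensity"]]
                   .sum(min_count=1).unstack(cols["run"]).astype(float))
        if zero_as_missing:
            vals = vals.where(vals != 0.0)
        first = pep.groupby(cols["precursor"]).first()
        meta = pd.DataFrame({
            "sequence": first.get(cols["sequence"], pd.Series("", index=first.index)),
            "prev_aa": first.get(cols["prev_aa"], pd.Series("-", index=first.index)),
            "next_aa": first.get(cols["next_aa"], pd.Series("-", index=first.index)),
            "modified": first.get(cols["modified"], pd.Series(False, index=first.index)).astype(bool),
            "protein_group_id": first[cols["protein_group"]],
        }).reindex(vals.index)
        meta.index.name = "peptide_id"
        if cols["cleavage_class"] in first.columns:
            meta["cleavage_class"] = first[cols["cleavage_class"]].reindex(vals.index)
        vals.index.name = "peptide_id"
        peptides = PeptideQuantTable(meta, vals)
    return proteins, peptides


def write_quant_report(table: ProteinQuantTable, path, format: str = "wide_matrix",
                       peptides: PeptideQuantTable | None = None) -> None:
    """Write a report in either dialect (UTF-8, tab-separated)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "wide_matrix":
        out = table.values.copy()
        out.insert(0, "gene", table.genes)
        out.index.name = "protein_group_id"
        out.to_csv(path, sep="\t", float_format="%.10g")
        return
    if format != "long_report":
        raise FormatError(f"unknown report format: {format!r}")
    rows = []
    for sample in table.sample_ids:
        col = table.values[sample]
        obs = col.dropna()
        frame = pd.DataFrame({
            "Run": sample,
            "Protein.Group": obs.index,
            "Genes": table.genes.loc[obs.index].to_numpy(),
            "PG.MaxLFQ": obs.to_numpy(),
        })
        rows.append(frame)
    long = pd.concat(rows, ignore_index=True)
    if peptides is not None:
        prows = []
        pg_lookup = table.values
        for sample in peptides.sample_ids:
            col = peptides.values[sample].dropna()
            m = peptides.meta.loc[col.index]
            frame = pd.DataFrame({
                "Run": sample,
                "Protein.Group": m["protein_group_id"].to_numpy(),
                "Genes": table.genes.reindex(m["protein_group_id"]).to_numpy(),
                "PG.MaxLFQ": pg_lookup.reindex(m["protein_group_id"])[sample].to_numpy()
                if sample in pg_lookup.columns else np.nan,
                "Precursor.Id": col.index,
                "Stripped.Sequence": m["sequence"].to_numpy(),
                "Prev.AA": m["prev_aa"].to_numpy(),
                "Next.AA": m["next_aa"].to_numpy(),
                "Modified": m["modified"].to_numpy(),
                "Precursor.Quantity": col.to_numpy(),
            })
            if "cleavage_class" in m.columns:
                frame["Cleavage.Class"] = m["cleavage_class"].to_numpy()
            prows.append(frame)
        long = pd.concat([long] + prows, ignore_index=True)
    long.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sample_table(path) -> SampleTable:
    """Read and validate a sample-metadata CSV (sample_id, person, eye, day,
    volume, tpc, role[, excluded]); eye labels are normalized to OD/OS."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError("sample table lacks a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample table")
    df = df.set_index("sample_id")
    if "role" not in df.columns:
        df["role"] = "biological"
    if "excluded" not in df.columns:
        df["excluded"] = False
    else:
        df["excluded"] = df["excluded"].astype(bool)
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path) -> None:
    out = samples.df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.10g")


def filter_by_detection(table: ProteinQuantTable, samples: SampleTable,
                        rule: str = "fraction_of_all", threshold: float = 0.9
                        ) -> ProteinQuantTable:
    """Detection-frequency filter over biological samples.

    ``fraction_of_all`` keeps proteins observed in at least ``threshold``
    (a fraction) of all biological samples; ``min_per_person`` keeps
    proteins observed in at least ``threshold`` (a count) samples of every
    person.
    """
    bio = samples.biological_ids()
    bio = [s for s in bio if s in table.values.columns]
    obs = table.values[bio].notna()
    if rule == "fraction_of_all":
        if not (0.0 <= threshold <= 1.0):
            raise ValueError("fraction_of_all threshold must be in [0, 1]")
        keep = obs.sum(axis=1) >= threshold * len(bio)
    elif rule == "min_per_person":
        if threshold < 0:
            raise ValueError("min_per_person threshold must be >= 0")
        person = samples.df.loc[bio, "person"]
        counts = obs.T.groupby(person).sum().T  # protein × person
        keep = (counts >= threshold).all(axis=1)
    else:
        raise ValueError(f"unknown detection rule: {rule!r}")
    if not keep.any():
        warnings.warn("detection filter removed every protein")
    return table.subset_proteins(table.values.index[keep])


def top_share(table: ProteinQuantTable, k: int = 30,
              samples: SampleTable | None = None) -> float:
    """Share of summed mean intensity carried by the ``k`` most abundant
    proteins (missing values treated as absent)."""
    values = table.values
    if samples is not None:
        cols = [s for s in samples.biological_ids() if s in values.columns]
        values = values[cols]
    if k > values.shape[0]:
        raise ValueError(f"k={k} exceeds number of proteins ({values.shape[0]})")
    means = values.mean(axis=1, skipna=True).fillna(0.0)
    top = means.nlargest(k).sum()
    total = means.sum()
    return float(top / total) if total > 0 else float("nan")
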