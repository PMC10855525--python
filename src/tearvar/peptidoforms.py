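"""Peptide-class (proteoform) contribution to observed variance.

Peptides are classified by trypsin consistency of both termini: a peptide is
fully tryptic when its N-terminal side is a genuine K/R cleavage (with the
no-cleavage-before-proline rule) or the protein N-terminus, AND its
C-terminal residue is K/R or the protein C-terminus. Everything else is
semitryptic, indicating endogenous proteolysis. Internal missed cleavages do
not affect the class.

Each peptide's intrapersonal CV is normalized to the median CV of all
peptides of its parent protein ("relative variance", RV), putting peptides
of quiet and noisy proteins on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import variance
from .tables import PeptideQuantTable, SampleTable

__all__ = [
    "classify_cleavage",
    "classify_peptides",
    "class_intensity_fractions",
    "relative_peptide_variance",
    "ClassFractionResult",
    "RelativeVarianceResult",
    "VALID_AA",
]

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
_TERMINUS = "-"


def classify_cleavage(sequence: str, prev_aa: str, next_aa: str) -> str:
    """Return ``"tryptic"`` or ``"semitryptic"`` for one peptide.

    ``prev_aa``/``next_aa`` are the flanking residues or ``"-"`` for a
    protein terminus.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    seq = sequence.upper()
    prev_aa = prev_aa.upper()
    next_aa = next_aa.upper()
    for ch in seq:
        if ch not in VALID_AA:
            raise ValueError(f"invalid residue {ch!r} in sequence")
    for flank, side in ((prev_aa, "prev_aa"), (next_aa, "next_aa")):
        if flank != _TERMINUS and flank not in VALID_AA:
            raise ValueError(f"invalid {side}: {flank!r}")
    n_ok = prev_aa == _TERMINUS or (prev_aa in "KR" and seq[0] != "P")
    c_ok = next_aa == _TERMINUS or seq[-1] in "KR"
    return "tryptic" if (n_ok and c_ok) else "semitryptic"


def classify_peptides(peptides: PeptideQuantTable) -> PeptideQuantTable:
    """Fill/overwrite the ``cleavage_class`` column from the flanking residues."""
    out = peptides.copy()
    out.meta["cleavage_class"] = [
        classify_cleavage(s, p, n)
        for s, p, n in zip(out.meta["sequence"], out.meta["prev_aa"], out.meta["next_aa"])
    ]
    return out


@dataclass
class ClassFractionResult:
    per_sample: pd.DataFrame     # sample × {tryptic, semitryptic, modified}
    per_person: pd.DataFrame     # person × mean fractions
    tests: pd.DataFrame          # pairwise Welch t-tests on the tryptic fraction


def class_intensity_fractions(peptides: PeptideQuantTable,
                              samples: SampleTable) -> ClassFractionResult:
    """Per-sample intensity fractions by cleavage class (summing to 1), the
    modified-peptide intensity fraction, per-person means, and pairwise Welch
    t-tests on the per-sample tryptic fraction between persons.

    Persons with fewer than two samples are excluded from the tests.
    """
    if "cleavage_class" not in peptides.meta.columns or peptides.meta["cleavage_class"].isna().any():
        peptides = classify_peptides(peptides)
    bio = [s for s in samples.biological_ids() if s in peptides.values.columns]
    vals = peptides.values[bio]
    cls = peptides.meta["cleavage_class"]
    total = vals.sum(axis=0, skipna=True)
    frac = {}
    for label in ("tryptic", "semitryptic"):
        frac[label] = vals[cls == label].sum(axis=0, skipna=True) / total
    frac["modified"] = vals[peptides.meta["modified"].astype(bool)].sum(axis=0, skipna=True) / total
    per_sample = pd.DataFrame(frac, index=bio)

    person = samples.df.loc[bio, "person"]
    per_person = per_sample.groupby(person).mean()

    rows = []
    ok_persons = [p for p, n in person.value_counts().items() if n >= 2]
    for a, b in combinations(sorted(ok_persons), 2):
        xa = per_sample.loc[person == a, "tryptic"].dropna()
        xb = per_sample.loc[person == b, "tryptic"].dropna()
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"person_a": a, "person_b": b, "t": float(t), "p": float(p),
                     "mean_a": float(xa.mean()), "mean_b": float(xb.mean())})
    tests = pd.DataFrame(rows, columns=["person_a", "person_b", "t", "p", "mean_a", "mean_b"])
    return ClassFractionResult(per_sample=per_sample, per_person=per_person, tests=tests)


@dataclass
class RelativeVarianceResult:
    records: pd.DataFrame        # per peptide: class, modified, cv, rv, intensity rank
    class_tests: dict            # Mann-Whitney p: semitryptic vs tryptic, modified vs not
    n_excluded_proteins: int


def relative_peptide_variance(peptides: PeptideQuantTable, samples: SampleTable,
                              min_peptides: int = 2) -> RelativeVarianceResult:
    """Relative variance per peptide and class-distribution comparisons.

    Per peptide: intrapersonal CV (median across persons of the within-person
    CV); RV = CV ÷ median CV of its protein's peptides, so each protein's
    peptides have median RV 1 by construction. Proteins contributing fewer
    than ``min_peptides`` quantified peptides are excluded (counted).
    Distributions of RV are compared by two-sided Mann–Whitney tests between
    semitryptic and tryptic and between modified and unmodified peptides.
    """
    if "cleavage_class" not in peptides.meta.columns or peptides.meta["cleavage_class"].isna().any():
        peptides = classify_peptides(peptides)
    scheme = variance.build_grouping(samples, "intrapersonal")
    pseudo = _PeptideAsProteins(peptides)
    cvtab = variance.group_cv(pseudo, scheme)
    cv = cvtab.summary

    meta = peptides.meta
    recs = meta[["protein_group_id", "cleavage_class", "modified"]].copy()
    recs["cv_percent"] = cv
    mean_int = peptides.values.mean(axis=1, skipna=True)
    recs["intensity_rank"] = mean_int.groupby(meta["protein_group_id"]).rank(
        ascending=False, method="min")

    recs = recs[recs["cv_percent"].notna()]
    sizes = recs.groupby("protein_group_id").size()
    keep_prot = set(sizes.index[sizes >= min_peptides])
    n_excluded = int((sizes < min_peptides).sum())
    recs = recs[recs["protein_group_id"].isin(keep_prot)].copy()
    med = recs.groupby("protein_group_id")["cv_percent"].transform("median")
    recs["rv"] = recs["cv_percent"] / med

    def _mw(a: pd.Series, b: pd.Series) -> float:
        a, b = a.dropna(), b.dropna()
        if len(a) < 2 or len(b) < 2:
            return float("nan")
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    tests = {
        "semitryptic_vs_tryptic_p": _mw(
            recs.loc[recs["cleavage_class"] == "semitryptic", "rv"],
            recs.loc[recs["cleavage_class"] == "tryptic", "rv"]),
        "modified_vs_unmodified_p": _mw(
            recs.loc[recs["modified"].astype(bool), "rv"],
            recs.loc[~recs["modified"].astype(bool), "rv"]),
    }
    return RelativeVarianceResult(records=recs, class_tests=tests,
                                  n_excluded_proteins=n_excluded)


class _PeptideAsProteins:
    """Adapter presenting peptide intensities through the protein-table
    surface expected by :func:`tearvar.variance.group_cv`."""

    def __init__(self, peptides: PeptideQuantTable):
        self.values = peptides.values
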