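"""Immunoglobulin-composition profiling.

Ig gene symbols follow IMGT-style nomenclature: IGH* are heavy chains
(isotype from the fourth letter: A/G/M/D/E), IGK*/IGL* are kappa/lambda
light chains, and a V/D/J segment letter marks a variable-region gene while
C (or a bare constant symbol such as IGKC) marks a constant-region gene.
JCHAIN and PIGR are accepted as Ig-associated transport/joining proteins
with a distinct flag; they are reported in correlation views but excluded
from the total-Ig denominator because they are not Ig chains.

Because the total Ig level varies sample to sample, per-sample profiles are
normalized to the summed Ig intensity before clustering, which exposes the
stable personal Ig composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .tables import ProteinQuantTable, SampleTable

__all__ = [
    "IgAnnotation",
    "classify_ig",
    "is_ig_chain",
    "ig_relative_profile",
    "cluster_ig_samples",
    "IgClusterResult",
]

_ASSOCIATED = {"JCHAIN", "PIGR", "IGJ"}  # IGJ is the legacy JCHAIN symbol
_HEAVY_ISOTYPE = {"A": "A", "G": "G", "M": "M", "D": "D", "E": "E"}


@dataclass(frozen=True)
class IgAnnotation:
    gene: str
    isotype: str          # A / G / M / D / E / other
    chain: str | None     # heavy / light / None (associated proteins)
    region: str | None    # constant / variable / None
    light_type: str       # kappa / lambda / none
    ig_associated: bool = False


def classify_ig(gene: str) -> IgAnnotation:
    """Parse an immunoglobulin gene symbol into its classification.

    Raises ValueError for symbols that are neither Ig chains nor the
    accepted Ig-associated proteins (JCHAIN, PIGR).
    """
    g = str(gene).upper().strip()
    if g in _ASSOCIATED:
        return IgAnnotation(gene=g, isotype="other", chain=None, region=None,
                            light_type="none", ig_associated=True)
    if not g.startswith("IG") or len(g) < 3:
        raise ValueError(f"not an immunoglobulin gene symbol: {gene!r}")
    locus = g[2]
    rest = g[3:]
    if locus == "H":
        if g == "IGHD":  # the delta constant gene, not a D segment
            return IgAnnotation(gene=g, isotype="D", chain="heavy",
                                region="constant", light_type="none")
        if rest[:1] in ("V", "D", "J"):
            region = "variable"
            isotype = "other"
        else:
            region = "constant"
            isotype = _HEAVY_ISOTYPE.get(rest[:1], "other")
        return IgAnnotation(gene=g, isotype=isotype, chain="heavy", region=region,
                            light_type="none")
    if locus in ("K", "L"):
        light = "kappa" if locus == "K" else "lambda"
        region = "variable" if rest[:1] in ("V", "J") else "constant"
        return IgAnnotation(gene=g, isotype="other", chain="light", region=region,
                            light_type=light)
    raise ValueError(f"unrecognized immunoglobulin locus in {gene!r}")


def is_ig_chain(gene: str) -> bool:
    """True for genuine Ig heavy/light chain genes (not JCHAIN/PIGR)."""
    try:
        ann = classify_ig(gene)
    except ValueError:
        return False
    return not ann.ig_associated


def ig_relative_profile(table: ProteinQuantTable) -> ProteinQuantTable:
    """Ig-chain sub-table with each sample normalized to its summed Ig
    intensity, so observed Ig values sum to 1 per sample.

    Samples with zero observed Ig intensity become all-missing columns
    (warned).
    """
    pids = [pid for pid, g in table.genes.items() if is_ig_chain(g)]
    if len(pids) < 2:
        raise ValueError("need at least two quantified Ig chains")
    sub = table.values.loc[pids]
    totals = sub.sum(axis=0, skipna=True)
    empty = totals <= 0
    if empty.any():
        warnings.warn(f"samples without Ig signal set missing: {list(totals.index[empty])}")
        totals = totals.where(~empty)
    return ProteinQuantTable(sub / totals, table.genes.loc[pids].copy())


@dataclass
class IgClusterResult:
    linkage: np.ndarray
    clusters: pd.Series         # sample -> cluster label
    purity: float               # fraction of samples in a majority-own-person cluster
    per_person_purity: pd.Series
    top5: dict[str, list[str]]  # per sample, top-5 Ig genes
    modal_top5: list[str]
    stability: pd.Series        # per sample, overlap (0-5) with the modal set


def cluster_ig_samples(profile: ProteinQuantTable, samples: SampleTable
                       ) -> IgClusterResult:
    """Hierarchical clustering of samples on Ig composition plus the top-5
    stability score.

    Samples are clustered with correlation distance (1 − Pearson r between
    profiles) and average linkage, cut to one cluster per person; purity is
    the fraction of samples whose cluster's majority person matches their
    own. Profiles are compared on row-standardized log2 relative intensities
    (each Ig centered/scaled across samples), so the static abundance ladder
    common to every sample does not mask the personal composition signature.
    The modal top-5 Ig set comes from mean relative intensities (ties broken
    by gene name); each sample's stability is the overlap of its own top-5
    set with the modal set.
    """
    bio = [s for s in samples.biological_ids() if s in profile.values.columns]
    vals = profile.values[bio]
    with np.errstate(divide="ignore"):
        z = np.log2(vals)
    z = z.sub(z.mean(axis=1, skipna=True), axis=0)
    sd = z.std(axis=1, ddof=1)
    z = z.div(sd.where(sd > 0), axis=0)
    corr = z.corr(min_periods=3).to_numpy(dtype=float)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - (corr + corr.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    persons = samples.df.loc[bio, "person"]
    k = persons.nunique()
    labels = pd.Series(hierarchy.fcluster(Z, t=k, criterion="maxclust"), index=bio)

    majority = {}
    for lab, members in labels.groupby(labels).groups.items():
        majority[lab] = persons.loc[list(members)].mode().iloc[0]
    own = pd.Series({s: majority[labels[s]] == persons[s] for s in bio})
    per_person = own.groupby(persons).mean()

    genes = profile.genes

    def _top5(series: pd.Series) -> list[str]:
        df = pd.DataFrame({"v": series, "gene": genes.reindex(series.index)})
        df = df.dropna(subset=["v"]).sort_values(["v", "gene"], ascending=[False, True])
        return list(df["gene"].head(5))

    top5 = {s: _top5(vals[s]) for s in bio}
    modal = _top5(vals.mean(axis=1, skipna=True))
    stability = pd.Series({s: len(set(top5[s]) & set(modal)) for s in bio},
                          name="top5_overlap")
    return IgClusterResult(linkage=Z, clusters=labels, purity=float(own.mean()),
                           per_person_purity=per_person, top5=top5,
                           modal_top5=modal, stability=stability)
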