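"""Protein–protein co-abundance analysis.

Pairwise-complete Pearson correlation on log2 intensities, p-values from the
t-distribution transform of r, average-linkage hierarchical clustering on
the distance 1 − r, and per-gene reporting of significantly correlated
partners. Because a constant protein amount is digested per sample
(compositional closure), dominant proteins can show genuine negative
correlations; signs are therefore always retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .tables import ProteinQuantTable

__all__ = [
    "CorrelationResult",
    "protein_correlation",
    "cluster_proteins",
    "key_protein_report",
    "correlation_strength",
]


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    genes: pd.Series
    linkage: np.ndarray | None = None
    clusters: pd.Series | None = None
    n_imputed_for_clustering: int = 0
    q: pd.DataFrame | None = field(default=None, repr=False)


def correlation_strength(r: float) -> str:
    """Qualitative label: tight (r > 0.9), strong (r > 0.8), intermediate
    (r > 0.5), else weak."""
    if r > 0.9:
        return "tight"
    if r > 0.8:
        return "strong"
    if r > 0.5:
        return "intermediate"
    return "weak"


def protein_correlation(table: ProteinQuantTable, min_pairs: int = 6,
                        log_scale: bool = True, compute_q: bool = True
                        ) -> CorrelationResult:
    """Pairwise-complete Pearson correlation between proteins.

    Pairs sharing fewer than ``min_pairs`` observations are missing. p is the
    two-sided probability from ``t = r sqrt((n−2)/(1−r²))`` on n−2 df; a BH
    q-value matrix is attached for export.
    """
    if table.values.shape[0] < 2:
        raise ValueError("need at least two proteins")
    X = table.log2() if log_scale else table.values
    constant = X.std(axis=1, skipna=True).fillna(0.0) == 0.0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant proteins give undefined correlations")

    r = X.T.corr(min_periods=min_pairs)
    obs = X.notna().to_numpy()
    n = obs.astype(int) @ obs.T.astype(int)
    n_df = pd.DataFrame(n, index=X.index, columns=X.index)
    r = r.where(n_df >= min_pairs)

    rv = r.to_numpy(dtype=float)
    nv = n_df.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((nv - 2.0) / np.clip(1.0 - rv**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), np.clip(nv - 2.0, 1.0, None))
    p[~np.isfinite(rv)] = np.nan
    p[np.abs(rv) >= 1.0 - 1e-12] = 0.0
    np.fill_diagonal(p, 0.0)
    p_df = pd.DataFrame(p, index=X.index, columns=X.index)

    q_df = None
    if compute_q:
        iu = np.triu_indices(len(X.index), k=1)
        flat = p[iu]
        ok = np.isfinite(flat)
        qflat = np.full_like(flat, np.nan)
        if ok.any():
            qflat[ok] = stats.false_discovery_control(flat[ok], method="bh")
        q = np.full_like(p, np.nan)
        q[iu] = qflat
        q.T[iu] = qflat
        np.fill_diagonal(q, 0.0)
        q_df = pd.DataFrame(q, index=X.index, columns=X.index)

    return CorrelationResult(r=r, p=p_df, n=n_df, genes=table.genes.copy(), q=q_df)


def cluster_proteins(corr: CorrelationResult, k: int | None = None,
                     cut_r: float | None = None) -> pd.Series:
    """Average-linkage hierarchical clustering on distance 1 − r.

    Exactly one of ``k`` (cut to k clusters) or ``cut_r`` (cut the dendrogram
    at height 1 − cut_r) must be given. Missing correlations are imputed as
    r = 0 for clustering; their count is recorded on the result.
    """
    if (k is None) == (cut_r is None):
        raise ValueError("give exactly one of k, cut_r")
    rv = corr.r.to_numpy(dtype=float).copy()
    np.fill_diagonal(rv, 1.0)
    missing = ~np.isfinite(rv)
    n_imputed = int(missing.sum() // 2)
    if n_imputed:
        warnings.warn(f"{n_imputed} missing correlations imputed as r=0 for clustering")
        rv[missing] = 0.0
    dist = 1.0 - rv
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if k is not None:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(Z, t=1.0 - cut_r, criterion="distance")
    clusters = pd.Series(labels, index=corr.r.index, name="cluster")
    corr.linkage = Z
    corr.clusters = clusters
    corr.n_imputed_for_clustering = n_imputed
    return clusters


def key_protein_report(corr: CorrelationResult, genes: list[str],
                       alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """For each named gene, its significantly correlated partners (p < alpha)
    sorted by |r| descending, signed r retained; self never reported.

    Genes absent from the correlation result map to None in the output.
    """
    gene_to_pid: dict[str, list[str]] = {}
    for pid, g in corr.genes.items():
        gene_to_pid.setdefault(str(g), []).append(pid)
    report: dict[str, pd.DataFrame | None] = {}
    for gene in genes:
        pids = gene_to_pid.get(gene, [])
        if not pids:
            report[gene] = None
            continue
        pid = pids[0]
        r_row = corr.r.loc[pid].drop(index=pid)
        p_row = corr.p.loc[pid].drop(index=pid)
        ok = p_row.notna() & (p_row < alpha) & r_row.notna()
        partners = pd.DataFrame({
            "partner": r_row.index[ok],
            "partner_gene": corr.genes.reindex(r_row.index[ok]).to_numpy(),
            "r": r_row[ok].to_numpy(),
            "p": p_row[ok].to_numpy(),
        })
        partners["strength"] = [correlation_strength(abs(x)) for x in partners["r"]]
        report[gene] = partners.reindex(
            partners["r"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return report
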