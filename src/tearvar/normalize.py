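"""Intensity normalization methods and their benchmarking.

Implemented methods: total-sum, median, quantile, reference-protein
("household protein") scaling, and cluster normalization — total-sum scaling
applied independently inside correlated protein clusters, which compensates
compositional displacement between clusters that whole-column scaling cannot.

Performance is scored per method as the pooled within-person CV (linear
scale), the pooled within-person MAD of log2 intensities, and the mean
within-person sample–sample Pearson correlation (log2 scale). Missing values
are ignored, never imputed, by every scaling statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import correlation as _correlation
from .tables import ProteinQuantTable, SampleTable

__all__ = ["NormalizationResult", "normalize", "evaluate_normalization", "METHODS"]

METHODS = ("total_sum", "median", "quantile", "reference_proteins", "cluster")


@dataclass
class NormalizationResult:
    method: str
    params: dict
    table: ProteinQuantTable
    performance: dict = field(default_factory=dict)


def _rescale_columns(values: pd.DataFrame, stat: pd.Series) -> pd.DataFrame:
    """Scale each column so its ``stat`` equals the grand mean of ``stat``."""
    target = stat.mean()
    return values * (target / stat)


def _total_sum(values: pd.DataFrame) -> pd.DataFrame:
    sums = values.sum(axis=0, skipna=True)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"columns without positive observed intensity: {bad}")
    return _rescale_columns(values, sums)


def _median(values: pd.DataFrame) -> pd.DataFrame:
    med = values.median(axis=0, skipna=True)
    if (med <= 0).any() or med.isna().any():
        bad = list(med.index[(med <= 0) | med.isna()])
        raise ValueError(f"columns without a positive median intensity: {bad}")
    return _rescale_columns(values, med)


def _quantile(values: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalization on observed values.

    Each column's sorted observed values are interpolated onto a common
    quantile grid; the grid mean is the reference distribution; every
    observed value is replaced by the reference at its (tie-averaged) rank
    quantile.
    """
    n_max = int(values.notna().sum(axis=0).max())
    grid = (np.arange(n_max) + 0.5) / n_max
    interp_cols = []
    for c in values.columns:
        obs = np.sort(values[c].dropna().to_numpy())
        if obs.size == 0:
            raise ValueError(f"column {c} has no observed values")
        q = (np.arange(obs.size) + 0.5) / obs.size
        interp_cols.append(np.interp(grid, q, obs))
    reference = np.mean(interp_cols, axis=0)
    out = values.copy()
    for c in values.columns:
        col = values[c]
        obs = col.dropna()
        ranks = obs.rank(method="average")
        q = (ranks - 0.5) / len(obs)
        out.loc[obs.index, c] = np.interp(q, grid, reference)
    return out


def _reference_proteins(table: ProteinQuantTable, genes: list[str]) -> pd.DataFrame:
    if not genes:
        raise ValueError("reference_proteins requires a nonempty gene list")
    pids = table.ids_for_genes(genes)
    if not pids:
        raise ValueError(f"none of the reference genes {genes} present")
    ref = table.values.loc[pids]
    for c in table.values.columns:
        if ref[c].isna().all():
            raise ValueError(f"reference proteins all missing in column {c}")
    factor = ref.mean(axis=0, skipna=True)
    return _rescale_columns(table.values, factor)


def _cluster(table: ProteinQuantTable, k: int = 4,
             clusters: pd.Series | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Total-sum scaling applied independently within each of ``k`` protein
    clusters derived from the (total-sum pre-scaled) correlation structure."""
    if clusters is None:
        if k < 2:
            raise ValueError("cluster normalization requires k >= 2")
        pre = ProteinQuantTable(_total_sum(table.values), table.genes)
        corr = _correlation.protein_correlation(pre, compute_q=False)
        clusters = _correlation.cluster_proteins(corr, k=k)
    out = table.values.copy()
    for label in clusters.unique():
        pids = clusters.index[clusters == label]
        block = table.values.loc[pids]
        sums = block.sum(axis=0, skipna=True)
        if (sums <= 0).any():
            warnings.warn(f"cluster {label} unobserved in some columns; left unscaled there")
            sums = sums.where(sums > 0)
        scale = sums.mean(skipna=True) / sums
        out.loc[pids] = block * scale.fillna(1.0)
    return out, clusters


def normalize(table: ProteinQuantTable, method: str, **params) -> NormalizationResult:
    """Apply one normalization method; dimensions and missingness pattern of
    the table are unchanged.

    Parameters per method: ``reference_proteins`` takes ``genes`` (list of
    gene symbols); ``cluster`` takes ``k`` (default 4) or a precomputed
    ``clusters`` assignment.
    """
    if method not in METHODS:
        raise ValueError(f"unknown normalization method: {method!r}")
    recorded = dict(params)
    if method == "total_sum":
        values = _total_sum(table.values)
    elif method == "median":
        values = _median(table.values)
    elif method == "quantile":
        values = _quantile(table.values)
    elif method == "reference_proteins":
        values = _reference_proteins(table, params.get("genes", []))
    else:
        values, clusters = _cluster(table, k=params.get("k", 4),
                                    clusters=params.get("clusters"))
        recorded["clusters"] = clusters
    out = ProteinQuantTable(values, table.genes.copy(), dict(table.annotations))
    assert out.values.shape == table.values.shape
    return NormalizationResult(method=method, params=recorded, table=out)


# ---------------------------------------------------------------------------
# benchmarking
# ---------------------------------------------------------------------------

def _within_person_cv(table: ProteinQuantTable, samples: SampleTable,
                      min_obs: int = 3) -> pd.Series:
    from . import variance

    scheme = variance.build_grouping(samples, "intrapersonal")
    return variance.group_cv(table, scheme, min_obs=min_obs).summary


def _within_person_mad(values_log2: pd.DataFrame, person: pd.Series) -> float:
    mads = []
    for _, cols in person.groupby(person).groups.items():
        sub = values_log2[list(cols)]
        med = sub.median(axis=1, skipna=True)
        mads.append((sub.sub(med, axis=0)).abs().median(axis=1, skipna=True))
    return float(pd.concat(mads, axis=1).median(axis=1).median(skipna=True))


def _within_person_corr(values_log2: pd.DataFrame, person: pd.Series) -> float:
    rs = []
    for _, cols in person.groupby(person).groups.items():
        cols = list(cols)
        if len(cols) < 2:
            continue
        cm = values_log2[cols].corr(min_periods=3)
        iu = np.triu_indices(len(cols), k=1)
        rs.extend(cm.to_numpy()[iu])
    rs = np.asarray(rs, dtype=float)
    return float(np.nanmean(rs)) if rs.size else float("nan")


def evaluate_normalization(results: list[NormalizationResult],
                           samples: SampleTable) -> pd.DataFrame:
    """Score ≥2 normalization results on a shared sample set.

    Returns a table indexed by method with pooled intragroup CV (median over
    proteins of the within-person CV), pooled intragroup MAD of log2
    intensities, mean within-person sample correlation, and the rank by
    pooled CV (1 = best). Persons with fewer than two samples are excluded
    with a warning.
    """
    if len(results) < 2:
        raise ValueError("need at least two normalization results to compare")
    shared = set(results[0].table.sample_ids)
    for res in results[1:]:
        if set(res.table.sample_ids) != shared:
            raise ValueError("normalization results cover different sample sets")
    bio = [s for s in samples.biological_ids() if s in shared]
    person = samples.df.loc[bio, "person"]
    small = person.value_counts()
    drop_persons = set(small.index[small < 2])
    if drop_persons:
        warnings.warn(f"persons excluded from evaluation (n<2): {sorted(drop_persons)}")
        bio = [s for s in bio if person[s] not in drop_persons]
        person = person.loc[bio]

    rows = []
    for res in results:
        sub = res.table.subset_samples(bio)
        cv = _within_person_cv(sub, samples)
        log2 = sub.log2()
        row = {
            "method": res.method,
            "pooled_intragroup_cv": float(cv.median(skipna=True)),
            "pooled_log2_mad": _within_person_mad(log2, person),
            "mean_intragroup_correlation": _within_person_corr(log2, person),
        }
        res.performance = {k: v for k, v in row.items() if k != "method"}
        rows.append(row)
    out = pd.DataFrame(rows).set_index("method")
    out["rank"] = out["pooled_intragroup_cv"].rank(method="min").astype(int)
    return out.sort_values("rank")
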