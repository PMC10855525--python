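"""Representative-sample selection by the leave-one-out CV (L1OCV) elbow.

For each sample of a person, the L1OCV is the median per-protein CV of the
person's samples recomputed after removing that sample: a low L1OCV marks a
sample whose removal most reduces within-person variance, i.e. an outlier
(typically a reflex-tear-like collection). Samples are ranked ascending by
L1OCV; the count of outliers is read off the knee of the (rank, relative
L1OCV) curve or by a relative-L1OCV limit. Auxiliary QC views: the
sample-to-sample correlation heatmap matrix and a cornification/volume
z-score classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import ProteinQuantTable, SampleTable

__all__ = [
    "L1OCVProfile",
    "l1ocv_profile",
    "l1ocv_by_person",
    "select_representative",
    "sample_correlation_view",
    "qc_classifier",
]


@dataclass
class L1OCVProfile:
    group: str
    table: pd.DataFrame  # index sample_id; columns l1ocv, rank, relative
    degenerate: bool = False
    elbow_index: int | None = field(default=None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def ordered(self) -> pd.DataFrame:
        return self.table.sort_values(["rank"])


def _median_cv_without(values: np.ndarray, min_obs: int = 3) -> np.ndarray:
    """L1OCV for every column of a (proteins × samples) matrix.

    Computed from leave-one-out updates of per-protein sums/sums of squares,
    so the whole profile costs one pass.
    """
    n_prot, n_samp = values.shape
    finite = np.isfinite(values)
    x = np.where(finite, values, 0.0)
    s1 = x.sum(axis=1, keepdims=True)
    s2 = (x**2).sum(axis=1, keepdims=True)
    n = finite.sum(axis=1, keepdims=True).astype(float)

    n_i = n - finite
    s1_i = s1 - x * finite
    s2_i = s2 - x**2 * finite
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1_i / n_i
        var = (s2_i - n_i * mean**2) / (n_i - 1.0)
        var = np.clip(var, 0.0, None)
        cv = 100.0 * np.sqrt(var) / mean
    cv[(n_i < min_obs) | ~(mean > 0)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(cv, axis=0)


def l1ocv_profile(table: ProteinQuantTable, group_samples: list[str],
                  min_obs: int = 3) -> L1OCVProfile:
    """Leave-one-out CV profile of one sample group (a person, usually).

    Groups must keep at least 3 samples after removal, so the group size must
    be ≥ 4. Relative values are L1OCV ÷ the group maximum; ranks ascend with
    L1OCV (rank 1 = strongest outlier candidate), ties broken by sample id.
    """
    cols = [s for s in group_samples if s in table.values.columns]
    if len(cols) < len(group_samples):
        missing = set(group_samples) - set(cols)
        raise KeyError(f"samples absent from table: {sorted(missing)}")
    if len(cols) < 4:
        raise ValueError(f"L1OCV needs a group of >= 4 samples, got {len(cols)}")
    l1 = _median_cv_without(table.values[cols].to_numpy(dtype=float), min_obs=min_obs)
    ser = pd.Series(l1, index=cols, name="l1ocv")
    degenerate = False
    mx = np.nanmax(l1) if np.isfinite(l1).any() else np.nan
    if not np.isfinite(mx) or mx <= 0:
        warnings.warn("degenerate group (all leave-one-out CVs are 0); no outliers flagged")
        relative = pd.Series(1.0, index=cols)
        degenerate = True
    else:
        relative = ser / mx
    order = ser.reset_index().sort_values(["l1ocv", "index"]).set_index("index").index
    rank = pd.Series(np.arange(1, len(cols) + 1), index=order).reindex(cols)
    tab = pd.DataFrame({"l1ocv": ser, "rank": rank.astype(int), "relative": relative})
    return L1OCVProfile(group="", table=tab, degenerate=degenerate)


def l1ocv_by_person(table: ProteinQuantTable, samples: SampleTable,
                    min_obs: int = 3) -> dict[str, L1OCVProfile]:
    """One L1OCV profile per person over its biological samples."""
    out = {}
    bio = samples.biological_ids()
    for person in samples.persons:
        ids = [s for s in bio if samples.df.at[s, "person"] == person
               and s in table.values.columns]
        prof = l1ocv_profile(table, ids, min_obs=min_obs)
        prof.group = person
        out[person] = prof
    return out


def _segment_sse(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    return float(resid @ resid)


def _elbow_count(relative_sorted: np.ndarray, tol: float = 1e-9,
                 min_gain: float = 0.5) -> int:
    """Break-down point of the ascending (rank, relative L1OCV) curve.

    Fits two straight segments split at every candidate rank and takes the
    split with the smallest total squared error (the classic L-method for
    locating the knee of an evaluation curve); the split index is the outlier
    count. A flat curve, or one the two-segment fit does not describe
    markedly better than a single line (SSE reduction below ``min_gain``),
    has no knee and yields zero.
    """
    y = np.asarray(relative_sorted, dtype=float)
    n = y.size
    if n < 4 or np.nanmax(y) - np.nanmin(y) < tol:
        return 0
    x = np.arange(n, dtype=float)
    single = _segment_sse(x, y)
    if single < tol:  # already a straight line
        return 0
    best_b, best_sse = 0, np.inf
    # the knee may not flag a majority of the group: outliers are by premise
    # the minority against a representative plateau; ties go to the smaller
    # count (ascending scan, strict improvement)
    for b in range(1, min(n - 1, n // 2 + 1)):
        sse = _segment_sse(x[:b], y[:b]) + _segment_sse(x[b:], y[b:])
        if sse < best_sse - 1e-15:
            best_b, best_sse = b, sse
    if best_sse > (1.0 - min_gain) * single:
        return 0
    return best_b


def select_representative(profile: L1OCVProfile, method: str = "elbow",
                          limit: float = 0.90) -> tuple[list[str], list[str]]:
    """Split a profile into (representative ids, outlier ids).

    ``elbow``: flag the samples ranked before the knee of the relative-L1OCV
    curve. ``relative_limit``: flag samples with relative L1OCV strictly
    below ``limit`` (boundary samples are kept).
    """
    tab = profile.ordered()
    if profile.degenerate:
        return list(tab.index), []
    if method == "elbow":
        count = _elbow_count(tab["relative"].to_numpy())
        outliers = list(tab.index[:count])
    elif method == "relative_limit":
        outliers = list(tab.index[tab["relative"].to_numpy() < limit])
    else:
        raise ValueError(f"unknown selection method: {method!r}")
    representative = [s for s in tab.index if s not in set(outliers)]
    return representative, outliers


def sample_correlation_view(table: ProteinQuantTable, samples: SampleTable,
                            min_shared: int = 3) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise sample Pearson correlation on log2 intensities over mutually
    observed proteins, plus each sample's mean correlation to the other
    samples of its person."""
    bio = [s for s in samples.biological_ids() if s in table.values.columns]
    if len(bio) < 2:
        raise ValueError("need at least two samples")
    log2 = table.log2()[bio]
    corr = log2.corr(min_periods=min_shared)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    person = samples.df.loc[bio, "person"]
    mean_intra = {}
    for s in bio:
        mates = [t for t in bio if t != s and person[t] == person[s]]
        mean_intra[s] = float(corr.loc[s, mates].mean()) if mates else float("nan")
    return corr, pd.Series(mean_intra, name="mean_intrapersonal_r")


def qc_classifier(table: ProteinQuantTable, samples: SampleTable,
                  cornification_genes: list[str]) -> pd.DataFrame:
    """Per-sample cornification and volume z-scores plus a high-flow flag.

    The cornification score is the summed intensity of the listed genes
    (keratins and other cornified-envelope proteins), z-scored across
    biological samples; high_flow is True when the sample's tear volume lies
    strictly above its person's median volume.
    """
    if not cornification_genes:
        raise ValueError("cornification gene list must be nonempty")
    pids = table.ids_for_genes(cornification_genes)
    if not pids:
        raise ValueError(f"no listed cornification gene present: {cornification_genes}")
    bio = [s for s in samples.biological_ids() if s in table.values.columns]
    corn = table.values.loc[pids, bio].sum(axis=0, skipna=True)
    vol = samples.df.loc[bio, "volume"].astype(float)

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    person = samples.df.loc[bio, "person"]
    med = vol.groupby(person).transform("median")
    return pd.DataFrame({
        "cornification_z": _z(corn),
        "volume_z": _z(vol),
        "high_flow": vol > med,
    }, index=bio)
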