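"""Pairwise differential analysis with randomization-based FDR.

A SAM-style moderated statistic d = Δmean / (se + s0) is computed on log2
intensities per protein; a null distribution of d is built from balanced
label permutations (or exhaustive enumeration / sign flips where the design
is small), and the significance threshold is the loosest |d| cutoff whose
estimated FDR (mean permutation exceedances over observed exceedances) stays
at or below the target. Plain Student t p-values are reported alongside for
the volcano view; paired eye-level tests use exhaustive sign-flip
permutations and report the permutation p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ProteinQuantTable, SampleTable

__all__ = [
    "DiffResult",
    "pairwise_differential",
    "paired_eye_test",
    "cross_comparison_summary",
    "annotate_protein_class",
]


@dataclass
class DiffResult:
    comparison: str
    stats: pd.DataFrame  # per protein: gene, log2fc, t, p, d, significant
    threshold_d: float | None
    settings: dict = field(default_factory=dict)

    @property
    def significant_ids(self) -> set[str]:
        return set(self.stats.index[self.stats["significant"]])


def _two_group_stats(X: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray,
                     s0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row (diff, t, d) for log2 matrix X, nan-aware, pooled-variance
    Student form."""
    XA, XB = X[:, a_idx], X[:, b_idx]
    nA = np.isfinite(XA).sum(axis=1).astype(float)
    nB = np.isfinite(XB).sum(axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mA, mB = np.nanmean(XA, axis=1), np.nanmean(XB, axis=1)
        vA = np.nanvar(XA, axis=1, ddof=1)
        vB = np.nanvar(XB, axis=1, ddof=1)
    df = nA + nB - 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((nA - 1.0) * vA + (nB - 1.0) * vB) / df
        se = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
        diff = mA - mB
        t = diff / se
        d = diff / (se + s0)
    bad = (nA < 2) | (nB < 2)
    diff[bad] = np.nan
    t[bad] = np.nan
    d[bad] = np.nan
    return diff, t, d


def _fdr_threshold(d_obs: np.ndarray, d_null: np.ndarray, fdr: float
                   ) -> tuple[float | None, np.ndarray]:
    """Loosest |d| cutoff with estimated FDR ≤ target.

    ``d_null`` is (n_perm, n_proteins). Returns (threshold, significant mask);
    threshold None when no cutoff qualifies.
    """
    abs_obs = np.abs(d_obs[np.isfinite(d_obs)])
    if abs_obs.size == 0:
        return None, np.zeros_like(d_obs, dtype=bool)
    null_flat = np.sort(np.abs(d_null[np.isfinite(d_null)]))
    n_perm = d_null.shape[0]
    candidates = np.unique(abs_obs)[::-1]  # strict → loose
    best = None
    for c in candidates:
        r = int((abs_obs >= c).sum())
        v = (null_flat.size - np.searchsorted(null_flat, c, side="left")) / n_perm
        est = min(1.0, v / max(r, 1))
        if est <= fdr:
            best = float(c)
    if best is None:
        return None, np.zeros_like(d_obs, dtype=bool)
    mask = np.abs(np.where(np.isfinite(d_obs), d_obs, 0.0)) >= best
    return best, mask


def _balanced_permutations(rng: np.random.Generator, nA: int, nB: int,
                           n_perm: int) -> list[np.ndarray]:
    """Index arrays (into the concatenated A+B columns) forming pseudo-group A.

    Balanced: each pseudo-A takes about half its members from the real A and
    half from the real B, which protects the null distribution from genuine
    group differences.
    """
    idx_a = np.arange(nA)
    idx_b = np.arange(nA, nA + nB)
    kA = nA // 2
    out = []
    for _ in range(n_perm):
        take_a = rng.choice(idx_a, size=kA, replace=False)
        take_b = rng.choice(idx_b, size=nA - kA, replace=False)
        out.append(np.sort(np.concatenate([take_a, take_b])))
    return out


def pairwise_differential(table: ProteinQuantTable, samples: SampleTable,
                          person_a: str, person_b: str, sample_set: str = "all",
                          representative: dict[str, list[str]] | list[str] | None = None,
                          fdr: float = 0.05, s0: float = 0.1, n_perm: int = 250,
                          seed: int = 0, min_presence: float = 0.7) -> DiffResult:
    """Two-person differential analysis on log2 intensities.

    ``sample_set``: ``all`` uses every biological sample of the two persons;
    ``representative`` restricts to the ids in ``representative`` (a flat
    list or a person → ids mapping from the L1OCV selection). Proteins must
    be observed in at least ``min_presence`` of each group's samples. When the
    exhaustive two-group relabelling count C(nA+nB, nA) is below 25 the null
    is enumerated exhaustively (with a warning) instead of sampled.
    """
    if person_a > person_b:
        # canonical orientation keeps the permutation null identical under
        # swapping, so volcano symmetry holds exactly
        res = pairwise_differential(table, samples, person_b, person_a,
                                    sample_set=sample_set,
                                    representative=representative, fdr=fdr,
                                    s0=s0, n_perm=n_perm, seed=seed,
                                    min_presence=min_presence)
        out = res.stats.copy()
        for col in ("log2fc", "t", "d"):
            out[col] = -out[col]
        out = out.rename(columns={"n_a": "n_b", "n_b": "n_a"})
        settings = dict(res.settings)
        settings["n_a"], settings["n_b"] = settings["n_b"], settings["n_a"]
        return DiffResult(comparison=f"{person_a} vs {person_b} ({sample_set})",
                          stats=out, threshold_d=res.threshold_d, settings=settings)

    bio = samples.biological_ids()
    ids_a = [s for s in bio if samples.df.at[s, "person"] == person_a]
    ids_b = [s for s in bio if samples.df.at[s, "person"] == person_b]
    if sample_set == "representative":
        if representative is None:
            raise ValueError("representative sample ids required")
        if isinstance(representative, dict):
            keep = set(representative.get(person_a, [])) | set(representative.get(person_b, []))
        else:
            keep = set(representative)
        ids_a = [s for s in ids_a if s in keep]
        ids_b = [s for s in ids_b if s in keep]
    elif sample_set != "all":
        raise ValueError(f"unknown sample_set: {sample_set!r}")
    if len(ids_a) < 3 or len(ids_b) < 3:
        raise ValueError("each person needs at least 3 samples in the chosen set")

    cols = ids_a + ids_b
    X_full = table.log2()[cols]
    obs = X_full.notna()
    presence_a = obs[ids_a].mean(axis=1) >= min_presence
    presence_b = obs[ids_b].mean(axis=1) >= min_presence
    X = X_full[presence_a & presence_b]
    Xv = X.to_numpy(dtype=float)
    nA, nB = len(ids_a), len(ids_b)
    a_idx = np.arange(nA)
    b_idx = np.arange(nA, nA + nB)

    diff, t, d = _two_group_stats(Xv, a_idx, b_idx, s0)
    n_obs_a = obs[ids_a].loc[X.index].sum(axis=1).to_numpy(dtype=float)
    n_obs_b = obs[ids_b].loc[X.index].sum(axis=1).to_numpy(dtype=float)
    dof = n_obs_a + n_obs_b - 2.0
    p = 2.0 * stats.t.sf(np.abs(t), np.clip(dof, 1.0, None))

    rng = np.random.default_rng(seed)
    from math import comb

    total = comb(nA + nB, nA)
    if total < 25:
        warnings.warn(f"only {total} distinct relabellings; enumerating exhaustively")
        perms = [np.array(c) for c in combinations(range(nA + nB), nA)]
    else:
        perms = _balanced_permutations(rng, nA, nB, n_perm)
    d_null = np.empty((len(perms), Xv.shape[0]))
    all_idx = np.arange(nA + nB)
    for i, pa in enumerate(perms):
        pb = np.setdiff1d(all_idx, pa, assume_unique=True)
        _, _, d_null[i] = _two_group_stats(Xv, pa, pb, s0)

    threshold, sig = _fdr_threshold(d, d_null, fdr)
    out = pd.DataFrame({
        "gene": table.genes.reindex(X.index).to_numpy(),
        "log2fc": diff, "t": t, "p": p, "d": d, "significant": sig,
        "n_a": n_obs_a.astype(int), "n_b": n_obs_b.astype(int),
    }, index=X.index)
    return DiffResult(
        comparison=f"{person_a} vs {person_b} ({sample_set})",
        stats=out, threshold_d=threshold,
        settings={"fdr": fdr, "s0": s0, "n_perm": len(perms), "seed": seed,
                  "sample_set": sample_set, "min_presence": min_presence,
                  "n_a": nA, "n_b": nB},
    )


def paired_eye_test(table: ProteinQuantTable, samples: SampleTable, person: str,
                    fdr: float = 0.05, s0: float = 0.1, n_perm: int = 250,
                    seed: int = 0, min_pairs: int = 3) -> DiffResult:
    """Paired OD-vs-OS test within one person on day-matched log2 differences.

    The per-protein statistic is d = mean(Δ) / (se + s0); the null is built
    from sign-flip permutations of the day pairs (exhaustive when 2^n_pairs
    is manageable) and p is the two-sided sign-flip permutation probability.
    Days lacking either eye are dropped (counted in settings).
    """
    bio = samples.biological_ids()
    sub = samples.df.loc[[s for s in bio if samples.df.at[s, "person"] == person]]
    pairs = []
    dropped = 0
    for day, grp in sub.groupby("day"):
        od = grp.index[grp["eye"] == "OD"]
        os_ = grp.index[grp["eye"] == "OS"]
        if len(od) == 1 and len(os_) == 1 and od[0] in table.values.columns \
                and os_[0] in table.values.columns:
            pairs.append((od[0], os_[0]))
        else:
            dropped += 1
    if len(pairs) < min_pairs:
        raise ValueError(f"person {person} has only {len(pairs)} matched eye pairs")

    log2 = table.log2()
    delta = np.column_stack([
        log2[od].to_numpy(dtype=float) - log2[os_].to_numpy(dtype=float)
        for od, os_ in pairs])
    n = np.isfinite(delta).sum(axis=1).astype(float)
    keep = n >= min_pairs
    delta = delta[keep]
    index = table.values.index[keep]
    n = n[keep]

    def _paired_d(D: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(D, axis=1)
            sd = np.nanstd(D, axis=1, ddof=1)
        nn = np.isfinite(D).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return m / (sd / np.sqrt(nn) + s0)

    d = _paired_d(delta)
    k = delta.shape[1]
    if 2**k <= max(n_perm, 4096):
        signs = np.array(np.meshgrid(*([[1.0, -1.0]] * k))).T.reshape(-1, k)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm, k))
    d_null = np.vstack([_paired_d(delta * srow) for srow in signs])
    p = np.mean(np.abs(d_null) >= np.abs(d)[None, :], axis=0)

    threshold, sig = _fdr_threshold(d, d_null, fdr)
    m = np.nanmean(delta, axis=1)
    out = pd.DataFrame({
        "gene": table.genes.reindex(index).to_numpy(),
        "log2fc": m, "t": d * 0 + d, "p": p, "d": d, "significant": sig,
        "n_pairs": n.astype(int),
    }, index=index)
    out["t"] = d
    return DiffResult(
        comparison=f"{person} OD vs OS (paired)",
        stats=out, threshold_d=threshold,
        settings={"fdr": fdr, "s0": s0, "n_perm": int(signs.shape[0]), "seed": seed,
                  "n_pairs": k, "dropped_days": dropped, "exhaustive": bool(2**k <= max(n_perm, 4096))},
    )


def annotate_protein_class(gene: str) -> str:
    """Coarse protein-class annotation used in comparison summaries."""
    g = str(gene).upper()
    if g.startswith("IG") or g in ("JCHAIN",):
        return "Ig"
    if g.startswith("KRT"):
        return "keratin"
    if g.startswith("CST"):
        return "cystatin"
    return "other"


def cross_comparison_summary(results: list[DiffResult]) -> pd.DataFrame:
    """Cross-comparison membership table.

    Rows are proteins significant in at least one comparison (computed on the
    intersection of the protein universes, with a warning if they differ);
    columns flag per-comparison significance plus ``in_all`` / ``in_at_least_2``
    and the protein-class annotation.
    """
    if len(results) < 2:
        raise ValueError("need at least two comparisons")
    universes = [set(r.stats.index) for r in results]
    universe = set.intersection(*universes)
    if any(u != universe for u in universes):
        warnings.warn("comparisons cover different protein universes; using intersection")
    sig_sets = [r.significant_ids & universe for r in results]
    union = sorted(set.union(*sig_sets))
    genes = results[0].stats["gene"]
    rows = []
    for pid in union:
        flags = [pid in s for s in sig_sets]
        rows.append({
            "protein_group_id": pid,
            "gene": genes.get(pid, ""),
            **{f"sig_{r.comparison}": f for r, f in zip(results, flags)},
            "n_comparisons": int(sum(flags)),
            "in_all": all(flags),
            "in_at_least_2": sum(flags) >= 2,
            "protein_class": annotate_protein_class(genes.get(pid, "")),
        })
    cols = ["protein_group_id", "gene",
            *[f"sig_{r.comparison}" for r in results],
            "n_comparisons", "in_all", "in_at_least_2", "protein_class"]
    return pd.DataFrame(rows, columns=cols).set_index("protein_group_id")
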