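"""Synthetic tear-proteome generator.

Emulates the statistical structure of a repeated-sampling tear proteomics
study: three donors sampled from both eyes (OD/OS) on five consecutive days,
a few hundred protein groups spanning ~5 decades of intensity with the top
30 carrying ~97% of the summed signal, four co-varying protein clusters
(Ig/defense, cornification/intracellular, serum-derived, major tear
proteins), compositional closure from digesting a constant protein amount,
reflex-tear-like outlier samples with elevated volume and cornification
signal, multiplicative lognormal noise, intensity-dependent missingness,
and peptide rows split into tryptic / semitryptic / modified classes with
~90% of intensity tryptic.

Noise is multiplicative lognormal throughout; a coefficient of variation
``cv`` maps to a log-scale standard deviation ``sigma = sqrt(ln(1+cv^2))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .tables import PeptideQuantTable, ProteinQuantTable, SampleTable

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "ConfigurationError",
    "generate_dataset",
    "generate_technical_replicates",
    "CLUSTER_NAMES",
]


class ConfigurationError(ValueError):
    """A SimConfig field is out of range; the message names the field."""


CLUSTER_NAMES = ("ig_defense", "cornification", "serum", "major_tear")

# Curated gene symbols assigned to the most abundant members of each cluster
# so that gene-prefix logic (KRT*, IG*, CST*) downstream is exercised.
_CLUSTER_GENES = {
    "ig_defense": [
        "IGHA1", "IGHA2", "IGHM", "IGKC", "JCHAIN", "PIGR", "IGLC2",
        "IGKV3-20", "IGKV1-39", "IGKV4-1", "IGLV2-14", "IGLV3-21",
        "IGHV3-23", "IGHV1-69", "MUC7", "LPO", "BPIFA2",
    ],
    "cornification": [
        "KRT1", "KRT2", "KRT5", "KRT6A", "KRT9", "KRT10", "KRT13", "KRT14",
        "KRT16", "KRT17", "FLG", "IVL", "CASP14", "DSP", "JUP", "SFN",
    ],
    "serum": [
        "ALB", "TF", "IGHG1", "IGHG2", "IGHG3", "IGHG4", "S100A8", "CP",
        "HP", "APOA1", "SERPINA1", "A2M",
    ],
    "major_tear": [
        "LTF", "LCN1", "LYZ", "LACRT", "PRR4", "CST1", "CST2", "CST4",
        "CSTB", "SCGB2A1", "ZG16B", "DMBT1", "PIP", "PROL1", "SCGB1D1",
    ],
}

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_NO_P = np.array([a for a in _AA if a != "P"])
_AA_NO_KR = np.array([a for a in _AA if a not in "KR"])


def _sigma_log(cv: float) -> float:
    """Log-scale sd of a lognormal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass
class SimConfig:
    """All tunable study conditions of the generator.

    The defaults reproduce the design the downstream statistics assume:
    3 persons × 2 eyes × 5 days, 320 protein groups over 5 intensity
    decades, technical CV 14%, ~20% reflex-like outlier samples, tear
    volume CV 71% and TPC CV 35% with weak correlation, and ~90% of peptide
    intensity in the fully tryptic class.
    """

    n_persons: int = 3
    n_days: int = 5
    eyes: tuple[str, str] = ("OD", "OS")
    n_proteins: int = 320
    n_clusters: int = 4
    cluster_loadings: np.ndarray | float | None = None  # default U(0.8, 0.95)
    abundance_decades: float = 5.0
    top30_target_share: float = 0.97
    technical_cv: float = 0.14
    outlier_probability: float = 0.2
    n_outliers_per_person: int | None = None  # exact injection overrides probability
    outlier_volume_multiplier: float = 2.5
    outlier_cornification_multiplier: float = 10.0
    outlier_extra_noise_cv: float = 0.7
    volume_cv: float = 0.71
    tpc_cv: float = 0.35
    volume_mean: float = 4.0   # µL
    tpc_mean: float = 6.0     # µg/µL
    volume_tpc_correlation: float = 0.2
    sample_noise_cv: float = 0.25
    cluster_factor_sigma: float = 0.7   # log-scale sd of day-to-day cluster swings
    cluster_person_sigma: float = 0.2   # log-scale sd of personal cluster programs
    person_effect_sigma: float = 0.3   # log-scale sd of per-(person, protein) offsets
    n_differential: int = 15
    differential_log2fc: float = 2.0
    peptides_per_protein: int = 5
    semitryptic_intensity_fraction: tuple[float, ...] | float | None = None
    modified_peptide_fraction: float = 0.06
    peptide_noise_cv: float = 0.12
    missingness_midpoint: float | None = 4.5  # log10 intensity of 50% detection
    missingness_slope: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        def _frac(name: str, value: float) -> None:
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")

        if self.n_persons < 2:
            raise ConfigurationError(f"n_persons must be >= 2, got {self.n_persons}")
        if self.n_days < 1:
            raise ConfigurationError(f"n_days must be >= 1, got {self.n_days}")
        if self.n_proteins < self.n_clusters:
            raise ConfigurationError(
                f"n_proteins ({self.n_proteins}) must be >= n_clusters ({self.n_clusters})")
        if self.n_clusters < 1:
            raise ConfigurationError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if len(self.eyes) != 2:
            raise ConfigurationError(f"eyes must be a pair, got {self.eyes!r}")
        if self.abundance_decades <= 0:
            raise ConfigurationError("abundance_decades must be positive")
        _frac("top30_target_share", self.top30_target_share)
        _frac("outlier_probability", self.outlier_probability)
        _frac("modified_peptide_fraction", self.modified_peptide_fraction)
        for name in ("technical_cv", "volume_cv", "tpc_cv", "sample_noise_cv",
                     "peptide_noise_cv", "outlier_extra_noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (-1.0 <= self.volume_tpc_correlation <= 1.0):
            raise ConfigurationError("volume_tpc_correlation must be in [-1, 1]")
        for name in ("outlier_volume_multiplier", "outlier_cornification_multiplier"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for f in self.semitryptic_fractions():
            _frac("semitryptic_intensity_fraction", f)
        if self.n_outliers_per_person is not None:
            if not (0 <= self.n_outliers_per_person <= 2 * self.n_days):
                raise ConfigurationError(
                    "n_outliers_per_person must be between 0 and samples per person")
        if self.peptides_per_protein < 1:
            raise ConfigurationError("peptides_per_protein must be >= 1")

    # -- derived pieces --------------------------------------------------------

    def person_labels(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_persons)]

    def semitryptic_fractions(self) -> np.ndarray:
        """Per-person semitryptic intensity fraction (interpersonal spread
        around ~0.10 by default)."""
        f = self.semitryptic_intensity_fraction
        if f is None:
            return np.linspace(0.07, 0.13, self.n_persons)
        arr = np.atleast_1d(np.asarray(f, dtype=float))
        if arr.size == 1:
            return np.full(self.n_persons, arr[0])
        if arr.size != self.n_persons:
            raise ConfigurationError(
                "semitryptic_intensity_fraction must be scalar or one value per person")
        return arr

    def cluster_names(self) -> list[str]:
        if self.n_clusters == 4:
            return list(CLUSTER_NAMES)
        return [f"cluster_{i + 1}" for i in range(self.n_clusters)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eyes"] = list(self.eyes)
        if isinstance(d.get("cluster_loadings"), np.ndarray):
            d["cluster_loadings"] = d["cluster_loadings"].tolist()
        return d


@dataclass
class SyntheticDataset:
    """A generated study: quantified tables plus the injected ground truth."""

    proteins: ProteinQuantTable
    peptides: PeptideQuantTable
    samples: SampleTable
    truth: dict
    config: SimConfig = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write protein/peptide TSVs, sample CSV, config YAML, truth JSON."""
        from . import io_meta  # local import avoids a cycle

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteins_wide.tsv",
            "report": outdir / "quant_report_long.tsv",
            "samples": outdir / "samples.csv",
            "truth": outdir / "truth.json",
            "config": outdir / "sim_config.yaml",
        }
        io_meta.write_quant_report(self.proteins, paths["proteins"], format="wide_matrix")
        io_meta.write_quant_report(self.proteins, paths["report"], format="long_report",
                                   peptides=self.peptides)
        io_meta.write_sample_table(self.samples, paths["samples"])
        truth = dict(self.truth)
        truth.pop("complete_intensities", None)
        truth["cluster_assignment"] = {k: v for k, v in truth["cluster_assignment"].items()}
        paths["truth"].write_text(json.dumps(truth, indent=1, default=str))
        import yaml

        paths["config"].write_text(yaml.safe_dump(self.config.to_dict()))
        return paths


# ---------------------------------------------------------------------------
# abundance profile
# ---------------------------------------------------------------------------

def _abundance_profile(n: int, decades: float, top_share: float, k: int = 30) -> np.ndarray:
    """Deterministic descending base abundances over ``decades`` calibrated so
    the top ``k`` proteins carry ``top_share`` of the summed intensity.

    Two geometric segments: the head (top ``k`` proteins) spans ~2 decades —
    the spread observed among dominant tear proteins — while the tail runs
    down to ``top − decades``; the tail's upper level is solved so the head
    share equals the target.
    """
    top = 9.0
    k = min(k, n)
    if k == n or n < 4:
        return 10.0 ** np.linspace(top, top - decades, n)
    head_span = min(2.0, 0.4 * decades)
    head = 10.0 ** np.linspace(top, top - head_span, k)
    bottom = top - decades
    m = n - k
    head_sum = head.sum()

    def share(a: float) -> float:
        tail = 10.0 ** np.linspace(a, bottom, m)
        return head_sum / (head_sum + tail.sum())

    hi_a = top - head_span  # tail may not exceed the head's lowest member
    lo_a = bottom + 1e-9
    if share(lo_a) < top_share:  # target unreachable even with a minimal tail
        a = lo_a
    elif share(hi_a) > top_share:
        a = hi_a
    else:
        a = brentq(lambda v: share(v) - top_share, lo_a, hi_a)
    tail = 10.0 ** np.linspace(a, bottom, m)
    return np.concatenate([head, tail])


def _orthogonal_factors(rng: np.random.Generator, k: int, n: int,
                        sigma: float) -> np.ndarray:
    """Per-sample latent factors for ``k`` clusters, empirically orthogonal.

    Cluster programs (secretion, debris influx, serum leakage, ...) are
    modelled as independent; at 30 samples, raw i.i.d. draws show chance
    correlations of ±0.2–0.4 that would blur the injected cluster identity,
    so the draws are centered and orthogonalized, then rescaled to the
    requested per-sample standard deviation.
    """
    if sigma == 0 or n <= k:
        return rng.normal(0.0, sigma, (k, n))
    F = rng.normal(0.0, 1.0, (k, n))
    F -= F.mean(axis=1, keepdims=True)
    # QR on the transposed matrix orthogonalizes the rows
    q, _ = np.linalg.qr(F.T)
    F = q.T[:k]
    F -= F.mean(axis=1, keepdims=True)
    sd = F.std(axis=1, ddof=0, keepdims=True)
    return sigma * F / sd


def _assign_clusters(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Cluster index per abundance-ranked protein.

    Cornification proteins are kept out of the very top ranks (keratins are
    abundant in tears but never the dominant secreted proteins), which keeps
    the baseline cornification share of total intensity at a few percent.
    """
    names = cfg.cluster_names()
    kc = len(names)
    if kc == 4:
        weights = np.array([0.30, 0.14, 0.16, 0.40])
    else:
        weights = np.full(kc, 1.0 / kc)
    assign = rng.choice(kc, size=cfg.n_proteins, p=weights)
    if kc == 4:
        corn = names.index("cornification")
        top = min(12, cfg.n_proteins)
        w = weights.copy()
        w[corn] = 0.0
        w /= w.sum()
        head = assign[:top]
        head[head == corn] = rng.choice(kc, size=(head == corn).sum(), p=w)
        assign[:top] = head
        # guarantee each cluster is non-empty
        for c in range(kc):
            if not (assign == c).any():
                assign[rng.integers(top, cfg.n_proteins)] = c
    return assign


def _gene_symbols(assign: np.ndarray, names: list[str]) -> list[str]:
    """Curated symbols for the most abundant members of each cluster; the
    remainder get neutral synthetic symbols."""
    genes = [""] * len(assign)
    counters = {c: 0 for c in range(len(names))}
    for i, c in enumerate(assign):
        pool = _CLUSTER_GENES.get(names[c], [])
        j = counters[c]
        genes[i] = pool[j] if j < len(pool) else f"GN{names[c][:2].upper()}{i:04d}"
        counters[c] += 1
    return genes


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic study under ``config``.

    Intensity model (log space): base abundance + per-(person, protein)
    offset + cluster latent factor × loading + lognormal sample noise;
    reflex-like outlier samples additionally scale the cornification cluster
    and tear volume and carry extra compositional noise. Columns are then
    rescaled to a constant summed intensity (closure: a constant protein
    amount is digested), and entries are masked by a logistic detection
    model on log10 intensity.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    persons = cfg.person_labels()
    names = cfg.cluster_names()

    # --- sample frame ---------------------------------------------------------
    recs = []
    for person in persons:
        for eye in cfg.eyes:
            for day in range(1, cfg.n_days + 1):
                recs.append({"sample_id": f"{person}_{eye}_d{day}", "person": person,
                             "eye": eye, "day": day, "role": "biological",
                             "excluded": False})
    sdf = pd.DataFrame(recs).set_index("sample_id")
    n_samples = len(sdf)
    person_idx = np.array([persons.index(p) for p in sdf["person"]])

    # --- proteins -------------------------------------------------------------
    base = _abundance_profile(cfg.n_proteins, cfg.abundance_decades, cfg.top30_target_share)
    assign = _assign_clusters(rng, cfg)
    genes = _gene_symbols(assign, names)
    protein_ids = [f"PG{i:04d}" for i in range(cfg.n_proteins)]

    if cfg.cluster_loadings is None:
        loadings = rng.uniform(0.8, 0.95, cfg.n_proteins)
        # dominant secreted proteins (LTF, LCN1, LYZ ... the mass head) are
        # homeostatically damped: a reduced loading keeps their variance
        # moderate and stops the closure constraint from letting the dominant
        # cluster's swings drown every other sample-level signal
        loadings[:12] *= 0.6
    else:
        loadings = np.broadcast_to(np.asarray(cfg.cluster_loadings, dtype=float),
                                   (cfg.n_proteins,)).copy()
        if ((loadings < 0) | (loadings > 1)).any():
            raise ConfigurationError("cluster_loadings must lie in [0, 1]")

    # person effects + designated differential proteins
    person_offsets = rng.normal(0.0, cfg.person_effect_sigma, (cfg.n_persons, cfg.n_proteins))
    differential: list[dict] = []
    if cfg.n_differential > 0:
        lo, hi = min(20, cfg.n_proteins - 1), min(150, cfg.n_proteins)
        pool = np.arange(lo, hi)
        chosen = rng.choice(pool, size=min(cfg.n_differential, pool.size), replace=False)
        for j, prot in enumerate(np.sort(chosen)):
            person_j = j % cfg.n_persons
            person_offsets[person_j, prot] += cfg.differential_log2fc * np.log(2.0)
            differential.append({"protein_group_id": protein_ids[prot],
                                 "gene": genes[prot], "person": persons[person_j],
                                 "log2fc": cfg.differential_log2fc})

    factors = _orthogonal_factors(rng, cfg.n_clusters, n_samples, cfg.cluster_factor_sigma)
    person_factors = rng.normal(0.0, cfg.cluster_person_sigma,
                                (cfg.n_clusters, cfg.n_persons))
    factors = factors + person_factors[:, person_idx]
    noise = rng.normal(0.0, _sigma_log(cfg.sample_noise_cv), (cfg.n_proteins, n_samples))

    # --- outlier selection ----------------------------------------------------
    if cfg.n_outliers_per_person is not None:
        is_outlier = np.zeros(n_samples, dtype=bool)
        for pi in range(cfg.n_persons):
            idx = np.flatnonzero(person_idx == pi)
            hit = rng.choice(idx, size=cfg.n_outliers_per_person, replace=False)
            is_outlier[hit] = True
    else:
        is_outlier = rng.random(n_samples) < cfg.outlier_probability

    log_i = (np.log(base)[:, None]
             + person_offsets[person_idx, :].T
             + loadings[:, None] * factors[assign, :])
    log_i = log_i + noise
    if is_outlier.any():
        corn_rows = assign == (names.index("cornification") if cfg.n_clusters == 4 else 0)
        log_i[np.ix_(corn_rows, is_outlier)] += np.log(cfg.outlier_cornification_multiplier)
        if cfg.outlier_extra_noise_cv > 0:
            extra = rng.normal(0.0, _sigma_log(cfg.outlier_extra_noise_cv),
                               (cfg.n_proteins, int(is_outlier.sum())))
            log_i[:, is_outlier] += extra

    intens = np.exp(log_i)
    total = base.sum()
    intens *= total / intens.sum(axis=0, keepdims=True)  # compositional closure

    # --- metadata: volume / TPC ----------------------------------------------
    rho = cfg.volume_tpc_correlation
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n_samples)
    volume = cfg.volume_mean * np.exp(_sigma_log(cfg.volume_cv) * z[:, 0])
    tpc = cfg.tpc_mean * np.exp(_sigma_log(cfg.tpc_cv) * z[:, 1])
    volume[is_outlier] *= cfg.outlier_volume_multiplier
    sdf["volume"] = volume
    sdf["tpc"] = tpc
    samples = SampleTable(sdf[["person", "eye", "day", "volume", "tpc", "role", "excluded"]])

    complete = pd.DataFrame(intens, index=protein_ids, columns=sdf.index)

    # --- missingness ----------------------------------------------------------
    masked = complete.to_numpy().copy()
    if cfg.missingness_midpoint is not None and cfg.missingness_slope > 0:
        p_detect = expit(cfg.missingness_slope * (np.log10(masked) - cfg.missingness_midpoint))
        masked[rng.random(masked.shape) >= p_detect] = np.nan

    proteins = ProteinQuantTable(
        pd.DataFrame(masked, index=protein_ids, columns=sdf.index),
        pd.Series(genes, index=protein_ids, name="gene"),
    ).drop_empty()

    # --- peptides -------------------------------------------------------------
    peptides = _generate_peptides(rng, cfg, proteins, complete, person_idx)

    truth = {
        "cluster_assignment": {pid: names[c] for pid, c in zip(protein_ids, assign)},
        "outlier_samples": list(sdf.index[is_outlier]),
        "differential": differential,
        "technical_cv": cfg.technical_cv,
        "sample_noise_cv": cfg.sample_noise_cv,
        "semitryptic_fraction_per_person": dict(zip(persons, cfg.semitryptic_fractions().tolist())),
        "complete_intensities": complete,
    }
    return SyntheticDataset(proteins=proteins, peptides=peptides, samples=samples,
                            truth=truth, config=cfg)


def _random_sequence(rng: np.random.Generator, tryptic: bool) -> tuple[str, str, str]:
    """(sequence, prev_aa, next_aa) consistent with the requested class."""
    length = int(rng.integers(8, 16))
    body = rng.choice(_AA, size=length)
    if tryptic:
        prev = str(rng.choice(["K", "R", "-"]))
        if prev != "-":
            body[0] = rng.choice(_AA_NO_P)  # no cleavage before proline
        body[-1] = rng.choice(["K", "R"])
        nxt = str(rng.choice(_AA))
    else:
        if rng.random() < 0.5:  # ragged N-terminus
            prev = str(rng.choice(_AA_NO_KR))
            body[-1] = rng.choice(["K", "R"])
            nxt = str(rng.choice(_AA))
        else:  # ragged C-terminus
            prev = str(rng.choice(["K", "R"]))
            body[0] = rng.choice(_AA_NO_P)
            body[-1] = rng.choice(_AA_NO_KR)
            nxt = str(rng.choice(_AA))
    return "".join(body), prev, nxt


def _generate_peptides(rng, cfg: SimConfig, proteins: ProteinQuantTable,
                       complete: pd.DataFrame, person_idx: np.ndarray) -> PeptideQuantTable:
    """Split each protein's intensity across peptide rows.

    Per person, semitryptic rows carry exactly the configured intensity
    fraction in expectation; modified peptides are a flagged subset of the
    tryptic rows. Peptide-level multiplicative noise is added on top.
    """
    m = cfg.peptides_per_protein
    n_semi = max(1, round(m / 3)) if m >= 2 else 0
    n_tryp = m - n_semi
    semi_frac = cfg.semitryptic_fractions()
    n_persons = cfg.n_persons

    meta_rows = []
    blocks = []
    for pid in proteins.protein_ids:
        w_t = rng.dirichlet(np.full(max(n_tryp, 1), 2.0)) if n_tryp else np.empty(0)
        w_s = rng.dirichlet(np.full(n_semi, 2.0)) if n_semi else np.empty(0)
        # per-person class weights: tryptic rows share (1 - f), semitryptic f
        w = np.zeros((m, n_persons))
        for pi in range(n_persons):
            f = semi_frac[pi] if n_semi else 0.0
            if n_tryp:
                w[:n_tryp, pi] = w_t * (1.0 - f)
            if n_semi:
                w[n_tryp:, pi] = w_s * f
        pep_noise = np.exp(rng.normal(0.0, _sigma_log(cfg.peptide_noise_cv),
                                      (m, complete.shape[1])))
        block = w[:, person_idx] * complete.loc[pid].to_numpy()[None, :] * pep_noise
        blocks.append(block)
        for j in range(m):
            tryptic = j < n_tryp
            seq, prev, nxt = _random_sequence(rng, tryptic)
            modified = bool(tryptic and rng.random() < cfg.modified_peptide_fraction)
            meta_rows.append({
                "peptide_id": f"{pid}.p{j}",
                "sequence": seq, "prev_aa": prev, "next_aa": nxt,
                "modified": modified, "protein_group_id": pid,
                "cleavage_class": "tryptic" if tryptic else "semitryptic",
            })

    meta = pd.DataFrame(meta_rows).set_index("peptide_id")
    vals = np.vstack(blocks)
    if cfg.missingness_midpoint is not None and cfg.missingness_slope > 0:
        with np.errstate(divide="ignore"):
            p_detect = expit(cfg.missingness_slope
                             * (np.log10(vals) - cfg.missingness_midpoint))
        vals = vals.copy()
        vals[rng.random(vals.shape) >= p_detect] = np.nan
    values = pd.DataFrame(vals, index=meta.index, columns=complete.columns)
    return PeptideQuantTable(meta, values)


# ---------------------------------------------------------------------------
# technical replicates
# ---------------------------------------------------------------------------

def generate_technical_replicates(dataset: SyntheticDataset, sample_id: str,
                                  k: int = 3, seed: int | None = None) -> ProteinQuantTable:
    """Simulate ``k`` replicate digests of one sample: the sample's true
    (pre-missingness) intensities × i.i.d. multiplicative lognormal noise at
    the configured technical CV, with detection missingness re-applied.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    complete: pd.DataFrame = dataset.truth["complete_intensities"]
    if sample_id not in complete.columns:
        raise KeyError(f"unknown sample_id: {sample_id}")
    cfg = dataset.config
    if seed is None:
        import zlib

        seed_seq = np.random.SeedSequence([cfg.seed, zlib.crc32(sample_id.encode()), k])
    else:
        seed_seq = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed_seq)

    truth_col = complete[sample_id].to_numpy()
    sigma = _sigma_log(cfg.technical_cv)
    reps = truth_col[:, None] * np.exp(rng.normal(0.0, sigma, (truth_col.size, k)))
    if cfg.missingness_midpoint is not None and cfg.missingness_slope > 0:
        p_detect = expit(cfg.missingness_slope * (np.log10(reps) - cfg.missingness_midpoint))
        reps[rng.random(reps.shape) >= p_detect] = np.nan
    cols = [f"{sample_id}_rep{i + 1}" for i in range(k)]
    values = pd.DataFrame(reps, index=complete.index, columns=cols)
    genes = dataset.proteins.genes.reindex(complete.index)
    # restrict to proteins retained in the dataset's quantified table
    keep = [p for p in complete.index if p in set(dataset.proteins.protein_ids)]
    return ProteinQuantTable(values.loc[keep], genes.loc[keep])
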