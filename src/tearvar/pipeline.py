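"""End-to-end pipeline orchestration.

Stages run in a fixed order: ingest → detection filter → normalization
(with benchmarking) → variance decomposition → outlier selection →
re-normalization on the representative set → protein correlation →
peptidoform analysis → differential analysis (all & representative) → Ig
profiling. A JSON manifest records versions, seeds, parameters, row counts
and output checksums per stage; reruns with the same config are
byte-identical. Randomized procedures draw per-stage streams from one root
seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (correlation, diffexp, igprofile, io_meta, normalize, outliers,
               peptidoforms, syndata, variance)
from .tables import ProteinQuantTable

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError", "STAGES"]

STAGES = (
    "ingest",
    "detection_filter",
    "normalize",
    "variance",
    "outliers",
    "renormalize_representative",
    "correlation",
    "peptidoforms",
    "diffexp",
    "igprofile",
)


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Either ``simulate`` (a SimConfig) or input paths, plus stage settings."""

    simulate: syndata.SimConfig | None = None
    quant_report: str | None = None
    sample_table: str | None = None
    report_format: str = "long_report"
    detection_rule: str = "fraction_of_all"
    detection_threshold: float = 0.9
    normalization_methods: tuple[str, ...] = ("total_sum", "median", "quantile", "cluster")
    default_normalization: str = "cluster"
    cluster_k: int = 4
    outlier_method: str = "elbow"
    relative_limit: float = 0.90
    fdr: float = 0.05
    s0: float = 0.1
    n_perm: int = 250
    seed: int = 0
    output_dir: str = "tearvar_out"

    def validate(self) -> None:
        has_paths = self.quant_report is not None or self.sample_table is not None
        if self.simulate is not None and has_paths:
            raise ValueError("config must give either input paths or simulate, not both")
        if self.simulate is None and not (self.quant_report and self.sample_table):
            raise ValueError("config needs input paths (quant_report + sample_table) "
                             "or a simulate block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            if isinstance(sim, dict):
                if "eyes" in sim:
                    sim["eyes"] = tuple(sim["eyes"])
                sim = syndata.SimConfig(**sim)
            raw["simulate"] = sim
        if "normalization_methods" in raw:
            raw["normalization_methods"] = tuple(raw["normalization_methods"])
        return cls(**raw)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.8g")
    return path


class _Runner:
    def __init__(self, config: PipelineConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.manifest: dict = {"config": _jsonable(config), "stages": []}
        root = np.random.SeedSequence(config.seed)
        self.stage_seeds = {name: int(s.generate_state(1)[0] >> 1)
                            for name, s in zip(STAGES, root.spawn(len(STAGES)))}

    def record(self, name: str, n_rows: int, outputs: dict[str, Path],
               extra: dict | None = None) -> None:
        entry = {"stage": name, "n_rows": int(n_rows),
                 "seed": self.stage_seeds[name],
                 "outputs": {k: {"path": str(p.relative_to(self.outdir)),
                                 "md5": _md5(p)} for k, p in outputs.items()}}
        if extra:
            entry.update(extra)
        self.manifest["stages"].append(entry)


def _jsonable(obj):
    if isinstance(obj, (PipelineConfig,)):
        d = {k: _jsonable(v) for k, v in obj.__dict__.items()}
        return d
    if isinstance(obj, syndata.SimConfig):
        return obj.to_dict()
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Execute every stage; returns the manifest (also written to
    ``manifest.json``). Any stage error aborts with the stage name and cause;
    outputs of completed stages are retained."""
    config.validate()
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Runner(config, outdir)
    state: dict = {}
    for stage in STAGES:
        try:
            _STAGE_FUNCS[stage](run, state)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            (outdir / "manifest.json").write_text(json.dumps(run.manifest, indent=1))
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "manifest.json").write_text(
        json.dumps(run.manifest, indent=1, sort_keys=True))
    return run.manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_ingest(run: _Runner, state: dict) -> None:
    cfg = run.config
    if cfg.simulate is not None:
        dataset = syndata.generate_dataset(cfg.simulate)
        state["dataset"] = dataset
        proteins, peptides, samples = dataset.proteins, dataset.peptides, dataset.samples
    else:
        proteins, peptides = io_meta.read_quant_report(cfg.quant_report,
                                                       format=cfg.report_format)
        samples = io_meta.read_sample_table(cfg.sample_table)
    state.update(proteins=proteins, peptides=peptides, samples=samples)
    p1 = run.outdir / "proteins_raw.tsv"
    io_meta.write_quant_report(proteins, p1, format="wide_matrix")
    p2 = run.outdir / "samples.csv"
    io_meta.write_sample_table(samples, p2)
    run.record("ingest", len(proteins.protein_ids), {"proteins": p1, "samples": p2},
               {"n_samples": len(samples.sample_ids)})


def _stage_filter(run: _Runner, state: dict) -> None:
    cfg = run.config
    filtered = io_meta.filter_by_detection(state["proteins"], state["samples"],
                                           rule=cfg.detection_rule,
                                           threshold=cfg.detection_threshold)
    state["filtered"] = filtered
    p = run.outdir / "proteins_filtered.tsv"
    io_meta.write_quant_report(filtered, p, format="wide_matrix")
    run.record("detection_filter", len(filtered.protein_ids), {"proteins": p},
               {"rule": cfg.detection_rule, "threshold": cfg.detection_threshold,
                "top30_share": io_meta.top_share(
                    filtered, min(30, len(filtered.protein_ids)), state["samples"])})


def _stage_normalize(run: _Runner, state: dict) -> None:
    cfg = run.config
    table = state["filtered"]
    results = []
    for method in cfg.normalization_methods:
        params = {"k": cfg.cluster_k} if method == "cluster" else {}
        results.append(normalize.normalize(table, method, **params))
    perf = normalize.evaluate_normalization(results, state["samples"])
    chosen = next(r for r in results if r.method == cfg.default_normalization)
    state["normalized"] = chosen.table
    p1 = _write_tsv(perf, run.outdir / "normalization_performance.tsv")
    p2 = run.outdir / "proteins_normalized.tsv"
    io_meta.write_quant_report(chosen.table, p2, format="wide_matrix")
    run.record("normalize", len(perf), {"performance": p1, "table": p2},
               {"methods": list(cfg.normalization_methods),
                "default": cfg.default_normalization})


def _stage_variance(run: _Runner, state: dict) -> None:
    table, samples = state["normalized"], state["samples"]
    seed = run.stage_seeds["variance"]
    frames = {}
    for name in ("intra_eye", "intrapersonal", "interpersonal_randomized", "overall"):
        scheme = variance.build_grouping(samples, name,
                                         seed=seed if name == "interpersonal_randomized" else None)
        cvt = variance.group_cv(table, scheme)
        frames[name] = cvt.summary
    cv_summary = pd.DataFrame(frames)
    state["cv_summary"] = cv_summary
    per_protein, (vr, vp) = variance.global_correlations(table, samples, "volume")
    p1 = _write_tsv(cv_summary, run.outdir / "cv_summary.tsv")
    p2 = _write_tsv(per_protein, run.outdir / "protein_vs_volume.tsv")
    extra = {"median_cv": {k: float(v.median(skipna=True)) for k, v in frames.items()},
             "volume_tpc_r": vr, "volume_tpc_p": vp}
    if "dataset" in state:
        ds = state["dataset"]
        rng = np.random.default_rng(seed)
        sample_id = str(rng.choice(ds.samples.biological_ids()))
        reps = syndata.generate_technical_replicates(ds, sample_id, k=3, seed=seed)
        tech = variance.technical_cv(reps)
        extra["technical_cv_median"] = tech.median
        extra["technical_cv_sample"] = sample_id
    run.record("variance", len(cv_summary), {"cv_summary": p1, "volume_corr": p2}, extra)


def _stage_outliers(run: _Runner, state: dict) -> None:
    cfg = run.config
    table, samples = state["normalized"], state["samples"]
    profiles = outliers.l1ocv_by_person(table, samples)
    rep_ids: dict[str, list[str]] = {}
    rows = []
    for person, prof in profiles.items():
        rep, out = outliers.select_representative(prof, method=cfg.outlier_method,
                                                  limit=cfg.relative_limit)
        rep_ids[person] = rep
        tab = prof.ordered()
        tab["person"] = person
        tab["outlier"] = [s in set(out) for s in tab.index]
        rows.append(tab)
    qc = pd.concat(rows)
    corn_genes = [g for g in state["filtered"].genes if str(g).startswith("KRT")]
    if corn_genes:
        clf = outliers.qc_classifier(table, samples, corn_genes)
        qc = qc.join(clf, how="left")
    state["representative"] = rep_ids
    p = _write_tsv(qc, run.outdir / "l1ocv_qc.tsv")
    run.record("outliers", len(qc), {"qc": p},
               {"representative_per_person": {k: len(v) for k, v in rep_ids.items()},
                "method": cfg.outlier_method})


def _stage_renormalize(run: _Runner, state: dict) -> None:
    cfg = run.config
    keep = sorted({s for ids in state["representative"].values() for s in ids})
    sub = state["filtered"].subset_samples(keep)
    params = {"k": cfg.cluster_k} if cfg.default_normalization == "cluster" else {}
    res = normalize.normalize(sub, cfg.default_normalization, **params)
    state["normalized_representative"] = res.table
    p = run.outdir / "proteins_normalized_representative.tsv"
    io_meta.write_quant_report(res.table, p, format="wide_matrix")
    run.record("renormalize_representative", len(res.table.protein_ids), {"table": p},
               {"n_samples": len(keep)})


def _stage_correlation(run: _Runner, state: dict) -> None:
    cfg = run.config
    table = state["normalized_representative"]
    corr = correlation.protein_correlation(table)
    clusters = correlation.cluster_proteins(corr, k=cfg.cluster_k)
    state["correlation"] = corr
    p1 = _write_tsv(corr.r, run.outdir / "protein_correlation_r.tsv")
    p2 = _write_tsv(clusters.to_frame(), run.outdir / "protein_clusters.tsv")
    run.record("correlation", len(corr.r), {"r": p1, "clusters": p2},
               {"k": cfg.cluster_k, "n_imputed": corr.n_imputed_for_clustering})


def _stage_peptidoforms(run: _Runner, state: dict) -> None:
    peptides, samples = state["peptides"], state["samples"]
    if peptides is None:
        run.record("peptidoforms", 0, {}, {"skipped": "no peptide rows in input"})
        return
    peptides = peptidoforms.classify_peptides(peptides)
    fractions = peptidoforms.class_intensity_fractions(peptides, samples)
    rv = peptidoforms.relative_peptide_variance(peptides, samples)
    p1 = _write_tsv(fractions.per_sample, run.outdir / "peptide_class_fractions.tsv")
    p2 = _write_tsv(rv.records, run.outdir / "peptide_relative_variance.tsv")
    run.record("peptidoforms", len(rv.records), {"fractions": p1, "rv": p2},
               {"class_tests": rv.class_tests,
                "tryptic_fraction_per_person":
                    fractions.per_person["tryptic"].round(4).to_dict()})


def _stage_diffexp(run: _Runner, state: dict) -> None:
    cfg = run.config
    samples = state["samples"]
    seed = run.stage_seeds["diffexp"]
    persons = samples.persons
    results = []
    outputs = {}
    for i, (a, b) in enumerate(
            (x, y) for xi, x in enumerate(persons) for y in persons[xi + 1:]):
        for sample_set, table in (("all", state["normalized"]),
                                  ("representative", state["normalized_representative"])):
            res = diffexp.pairwise_differential(
                table, samples, a, b, sample_set=sample_set,
                representative=state["representative"],
                fdr=cfg.fdr, s0=cfg.s0, n_perm=cfg.n_perm, seed=seed + i)
            results.append(res)
            fname = f"diff_{a}_vs_{b}_{sample_set}.tsv"
            outputs[fname] = _write_tsv(res.stats, run.outdir / fname)
    paired = []
    for person in persons:
        res = diffexp.paired_eye_test(state["normalized"], samples, person,
                                      fdr=cfg.fdr, s0=cfg.s0, seed=seed)
        paired.append(res)
        fname = f"paired_eye_{person}.tsv"
        outputs[fname] = _write_tsv(res.stats, run.outdir / fname)
    all_res = [r for r in results if r.settings["sample_set"] == "all"]
    rep_res = [r for r in results if r.settings["sample_set"] == "representative"]
    summary_extra = {}
    for label, group in (("all", all_res), ("representative", rep_res)):
        if len(group) >= 2:
            summary = diffexp.cross_comparison_summary(group)
            fname = f"cross_comparison_{label}.tsv"
            outputs[fname] = _write_tsv(summary, run.outdir / fname)
            summary_extra[f"n_in_all_{label}"] = int(summary["in_all"].sum())
            summary_extra[f"n_in_at_least_2_{label}"] = int(summary["in_at_least_2"].sum())
    state["diff_results"] = results
    run.record("diffexp", sum(len(r.stats) for r in results), outputs,
               {"n_significant": {r.comparison: int(r.stats["significant"].sum())
                                  for r in results + paired},
                **summary_extra})


def _stage_igprofile(run: _Runner, state: dict) -> None:
    table, samples = state["normalized"], state["samples"]
    try:
        profile = igprofile.ig_relative_profile(table)
    except ValueError as exc:
        run.record("igprofile", 0, {}, {"skipped": str(exc)})
        return
    result = igprofile.cluster_ig_samples(profile, samples)
    p1 = run.outdir / "ig_relative_profile.tsv"
    io_meta.write_quant_report(profile, p1, format="wide_matrix")
    p2 = _write_tsv(result.stability.to_frame(), run.outdir / "ig_top5_stability.tsv")
    run.record("igprofile", len(profile.protein_ids), {"profile": p1, "stability": p2},
               {"purity": result.purity, "modal_top5": result.modal_top5})


_STAGE_FUNCS = {
    "ingest": _stage_ingest,
    "detection_filter": _stage_filter,
    "normalize": _stage_normalize,
    "variance": _stage_variance,
    "outliers": _stage_outliers,
    "renormalize_representative": _stage_renormalize,
    "correlation": _stage_correlation,
    "peptidoforms": _stage_peptidoforms,
    "diffexp": _stage_diffexp,
    "igprofile": _stage_igprofile,
}
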