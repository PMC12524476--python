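"""End-to-end orchestration: simulate/ingest -> normalize & filter ->
periodicity screen -> lag estimation -> trajectory embedding -> topic model
-> posterior, with all stage outputs written as TSV/JSON plus a run manifest.

Every stage writes plain-text tables that can be re-loaded and re-run
independently; given fixed seeds the run is deterministic end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GeneSet, SplicedUnsplicedSet, TimeCourseMatrix, read_gmt
from .preprocessing import FilterReport, estimate_size_factors, filter_low_counts, \
    normalize_counts, normalize_pair
from .simulate import SimConfig, cycling_gene_set, simulate_timecourse
from .spectral import records_frame, scan_genes, select_genes, shuffle_null
from .topics import TopicModel, geneset_simplex
from .trajectory import pca_embed
from .velocity import average_cross_correlation

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("cycledecon")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``sim`` (synthetic input) or ``counts_path`` (TSV/CSV counts,
    optionally with ``unspliced_path``) must be provided.
    """

    outdir: str = "cycledecon_run"
    sim: SimConfig | None = None
    counts_path: str | None = None
    unspliced_path: str | None = None
    geneset_path: str | None = None          # GMT for the lag analysis
    filter_threshold: float = 10.0
    spectral_bands: tuple[int, ...] = (1, 2)
    min_score: float = 3.0
    n_shuffles: int = 100
    spectral_seed: int = 7
    log1p: bool = False
    max_lag: int = 5
    k: int = 3
    n_restarts: int = 5
    tol: float = 1e-8
    max_iter: int = 1000
    topic_seed: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        if isinstance(cfg.spectral_bands, list):
            cfg.spectral_bands = tuple(cfg.spectral_bands)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def validate(self) -> None:
        if self.sim is None and self.counts_path is None:
            raise PipelineError("config", "either sim or counts_path must be given")
        for p in (self.counts_path, self.unspliced_path, self.geneset_path):
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"input path does not exist: {p}")


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        pair, truth = simulate_timecourse(config.sim)
        n_cycling = min(67, 2 * config.sim.n_genes_per_component)
        gene_set = cycling_gene_set(truth, n_genes=n_cycling)
        return pair, truth, gene_set
    spliced = TimeCourseMatrix.from_tsv(config.counts_path, layer="spliced")
    pair = None
    if config.unspliced_path is not None:
        unspliced = TimeCourseMatrix.from_tsv(config.unspliced_path, layer="unspliced")
        pair = SplicedUnsplicedSet(spliced=spliced, unspliced=unspliced)
    gene_set = None
    if config.geneset_path is not None:
        gene_set = read_gmt(config.geneset_path)[0]
    return pair if pair is not None else spliced, None, gene_set


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a dict of in-memory results and
    writes all stage outputs under ``config.outdir``."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "stages": [],
    }
    results: dict = {}

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("ingest")
        loaded, truth, gene_set = _load_inputs(config)
        if isinstance(loaded, SplicedUnsplicedSet):
            pair, mat_raw = loaded, loaded.spliced
        else:
            pair, mat_raw = None, loaded
        if truth is not None:
            truth.component_proportions.to_csv(out / "truth_proportions.tsv", sep="\t")
            truth.to_json(out / "truth.json")
            pair.spliced.to_tsv(out / "spliced_raw.tsv")
            pair.unspliced.to_tsv(out / "unspliced_raw.tsv")
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("ingest", str(err)) from err

    try:
        stage("preprocess")
        if pair is not None:
            norm_pair, sf = normalize_pair(pair)
            mat_norm = norm_pair.spliced.with_layer("normalized")
        else:
            sf = estimate_size_factors(mat_raw.with_layer("raw"))
            norm_pair = None
            mat_norm = normalize_counts(mat_raw.with_layer("raw"), sf)
        report = FilterReport(threshold=config.filter_threshold)
        mat = filter_low_counts(mat_norm, config.filter_threshold, report)
        pd.Series(sf.to_numpy(), index=sf.sample_ids, name="size_factor").to_csv(
            out / "size_factors.tsv", sep="\t")
        mat.to_tsv(out / "normalized_filtered.tsv")
        (out / "filter_report.json").write_text(json.dumps(
            {"threshold": report.threshold, "kept": report.kept,
             "removed": report.removed}, indent=1))
        results.update(size_factors=sf, matrix=mat, filter_report=report)
    except Exception as err:
        raise PipelineError("preprocess", str(err)) from err

    try:
        stage("spectral")
        records = scan_genes(mat, log1p=config.log1p)
        rec_df = records_frame(records)
        rec_df.to_csv(out / "periodogram.tsv", sep="\t", index=False)
        null = shuffle_null(mat, config.n_shuffles, config.spectral_seed)
        null.quantiles().to_csv(out / "null_summary.tsv", sep="\t", index=False)
        sel_two = select_genes(records, {2}, config.min_score)
        sel_both = select_genes(records, set(config.spectral_bands), config.min_score)
        (out / "selected_band2.txt").write_text("\n".join(sel_two) + "\n")
        (out / "selected_bands.txt").write_text("\n".join(sel_both) + "\n")
        results.update(records=records, null=null, selected_band2=sel_two,
                       selected_bands=sel_both)
    except Exception as err:
        raise PipelineError("spectral", str(err)) from err

    if pair is not None and gene_set is not None:
        try:
            stage("velocity")
            use_pair = norm_pair if norm_pair is not None else pair
            xcorr = average_cross_correlation(use_pair, gene_set, config.max_lag)
            xcorr.to_frame().to_csv(out / "cross_correlation.tsv", sep="\t", index=False)
            (out / "cross_correlation.json").write_text(json.dumps(
                {"peak_lag": int(xcorr.peak_lag), "n_genes_used": xcorr.n_genes_used,
                 "confidence_band": xcorr.confidence_band}, indent=1))
            results["cross_correlation"] = xcorr
        except Exception as err:
            raise PipelineError("velocity", str(err)) from err

    try:
        stage("trajectory")
        embeddings = {}
        for label, subset in (("band2", results["selected_band2"]),
                              ("bands", results["selected_bands"])):
            if len(subset) >= 3:
                emb = pca_embed(mat, subset, n_components=3)
                emb.scores.to_csv(out / f"pca_scores_{label}.tsv", sep="\t")
                embeddings[label] = emb
        results["embeddings"] = embeddings
    except Exception as err:
        raise PipelineError("trajectory", str(err)) from err

    try:
        stage("topics")
        fit = TopicModel(mat, k=config.k).fit(
            seed=config.topic_seed, n_restarts=config.n_restarts,
            tol=config.tol, max_iter=config.max_iter)
        fit.L.to_csv(out / "topic_proportions_L.tsv", sep="\t")
        fit.F.to_csv(out / "topic_gene_probs_F.tsv", sep="\t")
        fit.structure_frame().to_csv(out / "structure_plot.tsv", sep="\t", index=False)
        diff = fit.diff_expression()
        diff.table.to_csv(out / "topic_diff_expression.tsv", sep="\t", index=False)
        post = fit.posterior()
        post.probs.to_csv(out / "posterior_simplex.tsv", sep="\t")
        for topic in fit.L.columns:
            ranked = diff.table[diff.table.topic == topic].sort_values(
                "z_score", ascending=False).gene_id.tolist()
            (out / f"topic_{topic}_ranked_genes.txt").write_text("\n".join(ranked) + "\n")
        results.update(fit=fit, diff=diff, posterior=post)
        if gene_set is not None:
            try:
                coords, centroid, missing = geneset_simplex(post, gene_set)
                coords.to_csv(out / f"simplex_{gene_set.name}.tsv", sep="\t")
            except Exception:
                pass
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("topics", str(err)) from err

    manifest["n_genes_after_filter"] = mat.n_genes
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    results["manifest"] = manifest
    if truth is not None:
        results["truth"] = truth
    return results
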