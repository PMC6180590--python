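"""End-to-end pipeline: read -> dimension -> cluster -> score -> embed.

Every run writes its artifacts plus a JSON manifest recording package and
library versions, the seed, all parameters, input hashes and per-stage
logs, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .components import component_scores, correlate_genome, grouped_distribution_summary
from .containers import ExpressionMatrix
from .embedding import pc_scores, tsne_embed
from .io import read_annotation, read_expression, write_expression
from .pc_dimension import RULES, auer_gervini_path, compute_spectrum, dimension_by_rule
from .thresher_core import OUTLIER, run_thresher

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run (all recorded in the manifest)."""

    input_path: str
    out_dir: str
    gene_list_path: str | None = None
    annotation_path: str | None = None
    genome_path: str | None = None  # genome-wide matrix for correlation lists
    transform: str = "none"
    rule: str = "twicemean"
    cutoff: float = 0.3
    correlation_threshold: float = 0.5
    perplexity: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {sorted(RULES)}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stages: read -> spectrum/dimension -> two-pass clustering -> component
    scores -> genome correlation -> group summaries -> PC scores -> t-SNE.
    Any stage failure halts the run and is recorded in the manifest before
    the exception propagates.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    versions = {
        "thresher": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    manifest: dict = {
        "config": asdict(config),
        "versions": versions,
        "input_hashes": {},
        "stages": [],
        "status": "running",
    }
    for key in ("input_path", "gene_list_path", "annotation_path", "genome_path"):
        p = getattr(config, key)
        if p is not None:
            manifest["input_hashes"][key] = _sha256(p)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn()
            except Exception as exc:
                manifest["status"] = f"failed at {name}: {exc}"
                (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise
            rec = {"stage": name, "seconds": round(time.perf_counter() - t0, 3)}
            if isinstance(out, dict) and "counts" in out:
                rec.update(out["counts"])
            manifest["stages"].append(rec)
            logger.info("stage %s: done (%.2fs)", name, rec["seconds"])
            return out

        return wrap

    @stage("read")
    def _read():
        annotation = (
            read_annotation(config.annotation_path) if config.annotation_path else None
        )
        matrix = read_expression(
            config.input_path,
            gene_list_path=config.gene_list_path,
            transform=config.transform,
            annotation=annotation,
        )
        return {"matrix": matrix, "counts": {"n_genes": matrix.n_genes, "n_samples": matrix.n_samples}}

    matrix: ExpressionMatrix = _read["matrix"]

    @stage("dimension")
    def _dimension():
        spectrum = compute_spectrum(matrix)
        path = auer_gervini_path(spectrum)
        dims = {rule: dimension_by_rule(path, rule) for rule in RULES}
        payload = {
            "eigenvalues": spectrum.eigenvalues.tolist(),
            "breakpoints": path.breakpoints.tolist(),
            "dims": path.dims.tolist(),
            "step_lengths": {str(d): s for d, s in path.step_lengths.items()},
            "dimension_by_rule": dims,
        }
        (out_dir / "dimension.json").write_text(json.dumps(payload, indent=1))
        return {"dims": dims, "counts": {"dimension": dims[config.rule]}}

    @stage("thresher")
    def _cluster():
        result = run_thresher(
            matrix, rule=config.rule, cutoff=config.cutoff, seed=config.seed
        )
        table = pd.DataFrame(
            {
                "gene": result.assignment.index,
                "cluster": [str(c) for c in result.assignment],
                "magnitude": result.magnitudes.reindex(result.assignment.index).to_numpy(),
            }
        )
        table.to_csv(out_dir / "assignments.csv", index=False)
        (out_dir / "validation.json").write_text(json.dumps(result.validation, indent=1))
        return {
            "result": result,
            "counts": {
                "dimension": result.dimension,
                "n_clusters": result.n_clusters,
                "n_outliers": len(result.outliers),
            },
        }

    result = _cluster["result"]
    if result.n_clusters == 0:
        manifest["status"] = "ok (no significant components; downstream stages skipped)"
        manifest["dimension"] = 0
        manifest["n_clusters"] = 0
        manifest["n_outliers"] = len(result.outliers)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest

    @stage("scores")
    def _scores():
        sm = component_scores(matrix, result)
        out = sm.scores.copy()
        out.index = [f"cluster{c}" for c in out.index]
        out.to_csv(out_dir / "component_scores.csv")
        return {"scores": sm, "counts": {"n_components": len(sm.cluster_ids)}}

    sm = _scores["scores"]

    @stage("correlations")
    def _correlations():
        genome = (
            read_expression(config.genome_path, transform=config.transform)
            if config.genome_path
            else matrix
        )
        lists = correlate_genome(sm, genome, threshold=config.correlation_threshold)
        cdir = out_dir / "correlations"
        cdir.mkdir(exist_ok=True)
        for c, df in lists.items():
            df.to_csv(cdir / f"cluster_{c}.tsv", sep="\t", index=False)
        return {"counts": {"n_listed_genes": int(sum(len(d) for d in lists.values()))}}

    @stage("group_summary")
    def _summary():
        if matrix.sample_groups is None:
            return {"counts": {"n_groups": 0}}
        summary = grouped_distribution_summary(sm, matrix.sample_groups)
        summary.to_json(out_dir / "group_summary.json", orient="records", indent=1)
        return {"counts": {"n_groups": int(summary["group"].nunique())}}

    @stage("embedding")
    def _embed():
        D = max(result.dimension, 1)
        scores = pc_scores(matrix, D)
        emb = tsne_embed(scores, perplexity=config.perplexity, seed=config.seed)
        out = emb.coordinates.copy()
        out.index.name = "sample"
        if matrix.sample_groups is not None:
            out["group"] = matrix.sample_groups.reindex(out.index)
        if matrix.sample_types is not None:
            out["sample_type"] = matrix.sample_types.reindex(out.index)
        out.to_csv(out_dir / "embedding.csv")
        return {"counts": {"n_embedded": out.shape[0]}}

    manifest["status"] = "ok"
    manifest["dimension"] = result.dimension
    manifest["n_clusters"] = result.n_clusters
    manifest["n_outliers"] = len(result.outliers)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
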