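"""End-to-end orchestration: filter -> cluster -> infer -> select -> export.

A run is driven by one TOML config and produces plain-text stage outputs
plus a JSON manifest recording the config snapshot, seeds, package version
and a SHA-256 hash of every output file, so a run can be re-executed and
checked bit-for-bit (floating-point text is written at 12 significant
digits).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    build_templates,
    consensus_cluster,
    sample_pseudo_matrices,
    select_k,
)
from .config import config_from_dict, get_logger, load_config
from .inference import export_network
from .io import collapse_replicates, filter_fold_change, load_expression
from .selection import select_lambdas

__all__ = ["RunManifest", "run_pipeline"]

logger = get_logger("pipeline")

FLOAT_FMT = "%.12g"


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seeds: dict
    version: str
    python: str
    started: str
    finished: str
    stages: dict  # stage -> {file: sha256}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return path


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full protocol described by a TOML config file.

    Stages: load + replicate collapse -> fold-change filter -> consensus
    clustering and cluster-count selection -> template / pseudo-replicate
    construction -> BIC selection of (lambda1, lambda2) -> final BCD fit ->
    network export.  Any stage error aborts with the stage name attached.
    """
    started = datetime.now(timezone.utc).isoformat()
    config_path = Path(config_path)
    cfg = load_config(config_path)
    input_cfg = cfg.get("input", {})
    filter_cfg = cfg.get("filter", {})
    cluster_cfg = cfg.get("cluster", {})
    infer_cfg = cfg.get("infer", {})
    bic_cfg = cfg.get("bic", {})

    out = Path(out_dir or cfg.get("output", {}).get("dir", "temponet_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict[str, str]] = {}

    # ---- load + collapse ----
    expr_path = input_cfg.get("expression")
    if not expr_path:
        raise PipelineError("load", "config lacks [input].expression")
    expr_path = Path(expr_path)
    if not expr_path.is_absolute():
        expr_path = config_path.parent / expr_path
    if not expr_path.exists():
        raise PipelineError("load", f"input expression file not found: {expr_path}")
    try:
        ds = load_expression(
            expr_path,
            schema=input_cfg.get("schema"),
            condition=input_cfg.get("condition", ""),
            impute_missing=bool(input_cfg.get("impute_missing", False)),
        )
        tc = collapse_replicates(ds)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    # ---- fold-change filter ----
    try:
        tc = filter_fold_change(tc, float(filter_cfg.get("threshold", 0.5)))
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    p = _write_tsv(tc.to_frame(), out / "filtered_profiles.tsv")
    stages["filter"] = {p.name: _sha256(p)}

    # ---- consensus clustering ----
    seed = int(cluster_cfg.get("seed", 0))
    k_range = cluster_cfg.get("k_range", list(range(2, 10)))
    if isinstance(k_range, str):
        lo, _, hi = k_range.partition(":")
        k_range = list(range(int(lo), int(hi) + 1))
    try:
        cr = consensus_cluster(
            tc.values,
            k_range=[k for k in k_range if k <= tc.n_transcripts],
            n_runs=int(cluster_cfg.get("runs", 1000)),
            sample_rate=float(cluster_cfg.get("sample_rate", 0.8)),
            seed=seed,
            ids=tc.transcript_ids,
        )
        k_override = cluster_cfg.get("k")
        n_clusters = int(k_override) if k_override else select_k(
            cr, float(cluster_cfg.get("delta_threshold", 0.1))
        )
        from .cluster import kmeans_correlation

        assignment = kmeans_correlation(
            tc.values, n_clusters, seed=seed, ids=tc.transcript_ids
        )
        templates = build_templates(tc.values, assignment, tc.time_points)
        pseudo = sample_pseudo_matrices(
            tc.values,
            assignment,
            int(infer_cfg.get("n_pseudo", 20)),
            seed=seed,
        )
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc
    files = {}
    p = _write_tsv(
        pd.DataFrame(
            {"transcript_id": tc.transcript_ids, "cluster": assignment.labels + 1}
        ),
        out / "cluster_assignment.tsv",
        index=False,
    )
    files[p.name] = _sha256(p)
    cdf_rows = [
        {"K": k, "cdf_area": cr.cdf_areas[k], "delta_area": cr.delta_areas[k]}
        for k in cr.k_values
    ]
    p = _write_tsv(pd.DataFrame(cdf_rows), out / "consensus_cdf.tsv", index=False)
    files[p.name] = _sha256(p)
    if n_clusters in cr.consensus:
        p = _write_tsv(
            pd.DataFrame(
                cr.consensus[n_clusters],
                index=tc.transcript_ids,
                columns=tc.transcript_ids,
            ),
            out / f"consensus_K{n_clusters}.tsv",
        )
        files[p.name] = _sha256(p)
    p = _write_tsv(templates.to_frame(), out / "templates.tsv")
    files[p.name] = _sha256(p)
    stages["cluster"] = files

    # ---- regularization selection + final fit ----
    try:
        base = config_from_dict({**infer_cfg, "seed": seed})
        grid_cfg = bic_cfg.get("grid")
        grid = [tuple(map(float, g)) for g in grid_cfg] if grid_cfg else None
        bic = select_lambdas(pseudo, grid, base, float(bic_cfg.get("zero_tol", 1e-6)))
        result = bic.selected_result
    except Exception as exc:
        raise PipelineError("select", str(exc)) from exc
    files = {}
    p = _write_tsv(bic.to_frame(), out / "bic_grid.tsv", index=False)
    files[p.name] = _sha256(p)
    for t, w in enumerate(result.series.matrices, start=1):
        p = _write_tsv(
            pd.DataFrame(
                w,
                index=templates.template_ids,
                columns=templates.template_ids,
            ),
            out / f"transition_W{t}.tsv",
        )
        files[p.name] = _sha256(p)
    stages["infer"] = files

    # ---- export ----
    try:
        thresh = float(infer_cfg.get("edge_threshold", 1e-3))
        files = {}
        for fmt, name in (
            ("edge-list", "edges.tsv"),
            ("sif", "network.sif"),
            ("graphml", "network.graphml"),
        ):
            p = export_network(result, out / name, edge_threshold=thresh, fmt=fmt)
            files[p.name] = _sha256(p)
    except Exception as exc:
        raise PipelineError("export", str(exc)) from exc
    stages["export"] = files

    manifest = RunManifest(
        config=cfg,
        seeds={"cluster": seed, "infer": base.seed},
        version=__version__,
        python=platform.python_version(),
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
        stages=stages,
    )
    manifest.save(out / "manifest.json")
    logger.info("pipeline complete: %d clusters, outputs in %s", n_clusters, out)
    return manifest
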