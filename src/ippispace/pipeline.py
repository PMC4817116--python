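"""End-to-end orchestration: simulate -> compare -> overlap -> cluster."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cluster as _cluster
from . import overlap as _overlap
from . import synth as _synth
from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    table: pd.DataFrame
    overlap: _overlap.OverlapMatrix
    tree: _cluster.ClusterTree
    assignments: pd.Series | None
    manifest: dict


def _stage(name: str):
    """Wrap a stage so failures abort with the stage name attached."""

    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-raise with context, do not swallow
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write all artifacts.

    Outputs under ``config.output_dir``: the (synthetic or loaded) descriptor
    table, the pairwise overlap matrix with its long-format per-component
    table, the Ward tree in Newick form, cluster assignments when a cut is
    requested, and a run manifest echoing the config.  Identical config +
    seed produces identical numeric outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    logging.getLogger("ippispace").addHandler(handler)
    try:
        return _run(config, out)
    finally:
        logging.getLogger("ippispace").removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> PipelineResult:
    # ----- simulate / load -------------------------------------------------
    @_stage("simulate")
    def simulate() -> pd.DataFrame:
        if config.input_table is not None:
            table = pd.read_csv(config.input_table)
        else:
            specs = []
            for i, s in enumerate(config.specs):
                # derive per-dataset seeds from the run seed
                specs.append(
                    _synth.DatasetSpec(
                        name=s.name,
                        n=s.n,
                        means=s.means,
                        sds=s.sds,
                        bounds=s.bounds,
                        correlation=s.correlation,
                        target=s.target,
                        seed=(config.seed * 1000 + i) % (2**31),
                    )
                )
            table = _synth.generate_collection(specs)
        missing = [d for d in config.descriptors if d not in table.columns]
        if missing:
            raise ValueError(f"descriptor columns missing from table: {missing}")
        return table

    table = simulate()
    _synth.write_table(table, out / "descriptors.csv")

    # ----- overlap ---------------------------------------------------------
    @_stage("overlap")
    def compute_overlap() -> _overlap.OverlapMatrix:
        return _overlap.pairwise_overlap(table, config.descriptors)

    matrix = compute_overlap()
    matrix.write(out / "overlap_matrix.csv", out / "overlap_pairs.csv")

    # ----- cluster ---------------------------------------------------------
    @_stage("cluster")
    def compute_cluster():
        dist = _cluster.overlap_to_distance(matrix.values)
        tree = _cluster.ward_cluster(dist, variant=config.ward_variant)
        assignments = None
        if config.n_clusters is not None:
            assignments = _cluster.cut_tree(tree, config.n_clusters)
        return tree, assignments

    tree, assignments = compute_cluster()
    (out / "datasets.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
    order = tree.leaf_order()
    matrix.values.loc[order, order].to_csv(out / "overlap_matrix_reordered.csv")
    if assignments is not None:
        assignments.to_csv(out / "cluster_assignments.csv", index_label="dataset")

    manifest = {
        "config": config.to_dict(),
        "versions": {
            "python": sys.version.split()[0],
            "ippispace": _package_version(),
        },
        "n_compounds": int(len(table)),
        "datasets": sorted(table["dataset"].unique().tolist()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return PipelineResult(table, matrix, tree, assignments, manifest)


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("ippispace")
    except PackageNotFoundError:
        return "unknown"
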