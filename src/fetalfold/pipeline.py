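"""Pipeline orchestration and configuration.

Binds the stages together: synthesise or load surfaces, measure them,
compute similarity to a template when one is given, run the association
suite, and archive the effective configuration next to the results so a
run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .mesh import read_mesh
from .pattern import (
    FeatureWeights,
    build_basin_graph,
    similarity_index,
    spectral_match,
)
from .stats import CohortTable, run_association_suite

logger = logging.getLogger("fetalfold")

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]


@dataclasses.dataclass
class PipelineConfig:
    """Effective parameters of a full analysis run."""

    spacing: float = 0.75  # mm, voxel edge for closing/depth
    kernel_diameter: float = 15.0  # mm, closing ball
    smooth_iters: int = 10  # curvature smoothing before watershed
    merge_ridge: float = 0.02  # watershed basin-merge ridge height (1/mm)
    tau_position: float = 0.2
    tau_depth: float = 0.2
    tau_area: float = 0.05
    w_position: float = 1 / 3
    w_depth: float = 1 / 3
    w_area: float = 1 / 3
    fdr_q: float = 0.05
    standardize: bool = True
    n_regions: int = 21
    seed: int = 0
    cohort_csv: str | None = None
    mesh_dir: str | None = None
    template_mesh: str | None = None
    out_dir: str = "fetalfold_out"

    def __post_init__(self) -> None:
        for name in (
            "spacing",
            "kernel_diameter",
            "tau_position",
            "tau_depth",
            "tau_area",
            "fdr_q",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.smooth_iters < 0 or self.merge_ridge < 0:
            raise ValueError("smooth_iters and merge_ridge must be >= 0")

    def weights(self) -> FeatureWeights:
        return FeatureWeights(self.w_position, self.w_depth, self.w_area)

    def taus(self) -> dict[str, float]:
        return {
            "position": self.tau_position,
            "depth": self.tau_depth,
            "area": self.tau_area,
        }


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def _similarity_for_mesh(mesh, template_graph, config: PipelineConfig) -> dict:
    graph = build_basin_graph(
        mesh,
        spacing=config.spacing,
        kernel_diameter=config.kernel_diameter,
        smooth_iters=config.smooth_iters,
        merge_ridge=config.merge_ridge,
    )
    if graph.n == 0:
        return {f: 0.0 for f in ("position", "depth", "area", "combined")}
    m = spectral_match(graph, template_graph, config.weights())
    rec = similarity_index(m, graph, template_graph, config.weights(), config.taus())
    return rec.whole_pattern


def run_pipeline(config: PipelineConfig) -> dict:
    """Run measures -> similarity -> association on an existing cohort.

    Requires ``cohort_csv`` (id, gw, sex, pad and/or measure columns).  When
    ``mesh_dir`` is given, global measures are computed per subject from
    ``<mesh_dir>/<id>.off``; when ``template_mesh`` is given, whole-pattern
    similarity columns are added.  Results, reports and the effective
    config are written under ``out_dir``.
    """
    from .morphometry import global_measures

    if config.cohort_csv is None:
        raise ValueError("pipeline requires cohort_csv")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")

    import pandas as pd

    df = pd.read_csv(config.cohort_csv)
    if config.mesh_dir is not None:
        rows = []
        for sid in df["id"]:
            path = Path(config.mesh_dir) / f"{sid}.off"
            try:
                mesh = read_mesh(path)
                gm = global_measures(mesh, config.spacing, config.kernel_diameter)
            except Exception as exc:
                raise RuntimeError(f"stage=measure subject={sid}: {exc}") from exc
            rows.append(gm.as_dict())
            logger.info("measured %s", sid)
        df = pd.concat([df, pd.DataFrame(rows)], axis=1)

    if config.template_mesh is not None:
        if config.mesh_dir is None:
            raise ValueError("similarity requested but mesh_dir not set")
        template = read_mesh(config.template_mesh)
        tgraph = build_basin_graph(
            template,
            spacing=config.spacing,
            kernel_diameter=config.kernel_diameter,
            smooth_iters=config.smooth_iters,
            merge_ridge=config.merge_ridge,
        )
        si_rows = []
        for sid in df["id"]:
            mesh = read_mesh(Path(config.mesh_dir) / f"{sid}.off")
            try:
                si = _similarity_for_mesh(mesh, tgraph, config)
            except Exception as exc:
                raise RuntimeError(f"stage=similarity subject={sid}: {exc}") from exc
            si_rows.append({f"si_{k}": v for k, v in si.items()})
            logger.info("similarity %s", sid)
        df = pd.concat([df, pd.DataFrame(si_rows)], axis=1)

    cohort = CohortTable(df)
    groups = {
        "global": [
            c
            for c in cohort.measures
            if not c.startswith("si_") and "_region" not in c
        ],
    }
    si_cols = [c for c in cohort.measures if c.startswith("si_")]
    if si_cols:
        groups["similarity"] = si_cols
    results = run_association_suite(
        cohort, groups, q=config.fdr_q, standardize=config.standardize
    )
    cohort.to_csv(out / "cohort_with_measures.csv")
    (out / "association.json").write_text(json.dumps(results, indent=2))
    (out / "report.txt").write_text(results["report"] + "\n")
    logger.info("association suite written to %s", out)
    return results
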