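"""End-to-end orchestration: phantom -> segmentation -> coarsening ->
materials -> worst-case solve -> fusion-area optimization.

Every run writes its intermediates (stack, labels, coarse grid, stress
fields, trajectory) plus a manifest recording the config hash, package
version, per-stage timings and every produced file, so a run can be audited
and reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__, fem, optimize as opt
from .imaging import (CoarseningSpec, DiffusionParams, Slab,
                      anisotropic_diffusion, coarsen, crop_epiphyses,
                      mark_nonunion, segment)
from .materials import CalibrationModel, assign_materials
from .optimize import OptimizationConfig
from .phantom import PhantomConfig, Tissue, generate_phantom, write_stack
from .vtkio import write_vtk

log = logging.getLogger("minfuse")


class SolverConfig(BaseModel):
    tol: float = Field(default=1e-8, gt=0)
    method: str = "auto"
    maxiter: int = Field(default=20000, ge=1)
    direct_limit: int = Field(default=30000, ge=0)

    def as_kwargs(self) -> dict:
        return self.model_dump()


class RegionConfig(BaseModel):
    """Axis-aligned nonunion slab in mm; unset bounds are unbounded.

    When no z bounds are given the slab defaults to the phantom's fracture
    gap extent.
    """

    x_min: float | None = None
    x_max: float | None = None
    y_min: float | None = None
    y_max: float | None = None
    z_min: float | None = None
    z_max: float | None = None

    def slab(self, phantom: PhantomConfig) -> Slab:
        z_min, z_max = self.z_min, self.z_max
        if z_min is None and z_max is None:
            zc = phantom.gap_center()
            z_min, z_max = zc - phantom.gap_halfwidth, zc + phantom.gap_halfwidth
        return Slab(x=(self.x_min, self.x_max), y=(self.y_min, self.y_max),
                    z=(z_min, z_max))


class PipelineConfig(BaseModel):
    """Nested configuration of the whole pipeline."""

    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    diffusion: DiffusionParams = Field(default_factory=DiffusionParams)
    coarsening: CoarseningSpec = Field(default_factory=CoarseningSpec)
    crop_proximal: float = Field(default=0.0, ge=0, lt=1)
    crop_distal: float = Field(default=0.0, ge=0, lt=1)
    nonunion: RegionConfig = Field(default_factory=RegionConfig)
    materials: CalibrationModel = Field(default_factory=CalibrationModel)
    body_mass_kg: float = Field(default=80.0, gt=0)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    optimize: OptimizationConfig = Field(default_factory=OptimizationConfig)
    output_dir: str = "minfuse-run"
    log_level: str = "INFO"
    seed: int | None = None  # overrides phantom.seed when set

    def effective_phantom(self) -> PhantomConfig:
        if self.seed is None:
            return self.phantom
        return self.phantom.model_copy(update={"seed": self.seed})


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class ConfigReadError(OSError):
    """Raised when a config file cannot be read at all."""


def load_config(path: str | os.PathLike) -> PipelineConfig:
    diags = validate_config(path)
    if diags:
        raise ValueError("invalid pipeline config:\n" + "\n".join(diags))
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def validate_config(path: str | os.PathLike) -> list[str]:
    """Schema-check a YAML/JSON config file; return all violations at once.

    An unreadable file raises :class:`ConfigReadError`; invalid content is
    reported as diagnostics, one string per violated field.
    """
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise ConfigReadError(f"cannot read config file {path!r}: {exc}") from exc
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        return [f"not valid YAML/JSON: {exc}"]
    if not isinstance(data, dict):
        return ["config root must be a mapping"]
    try:
        PipelineConfig.model_validate(data)
    except ValidationError as exc:
        return [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
    return []


def run_pipeline(config: PipelineConfig,
                 output_dir: str | os.PathLike | None = None) -> dict[str, Any]:
    """Execute all stages, persist artifacts, return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "package": "minfuse",
        "version": __version__,
        "config_hash": config_hash(config),
        "stages": [],
        "files": [],
    }

    def emit(name: str) -> str:
        manifest["files"].append(name)
        return str(out / name)

    (out / "config.yaml").write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
    manifest["files"].append("config.yaml")

    stage_outputs: dict[str, Any] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                manifest["stages"].append(
                    {"name": name, "status": "failed", "error": str(exc),
                     "seconds": round(time.perf_counter() - t0, 3)})
                _write_manifest(out, manifest)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            manifest["stages"].append(
                {"name": name, "status": "ok", "seconds": round(dt, 3)})
            log.info("stage %s: done in %.2fs", name, dt)
        return wrap

    pcfg = config.effective_phantom()

    @stage("phantom")
    def _phantom():
        stack = generate_phantom(pcfg)
        write_stack(stack, emit("phantom.mhd"))
        manifest["files"].append("phantom.raw")  # MetaImage payload
        stage_outputs["stack"] = stack

    @stage("segment")
    def _segment():
        smooth = anisotropic_diffusion(stage_outputs["stack"], config.diffusion)
        labels_full = segment(smooth, config.coarsening.class_thresholds)
        write_stack(_labels_as_stack(labels_full), emit("labels_full.nii.gz"))
        Path(emit("labels_codes.json")).write_text(json.dumps(
            {t.name.lower(): int(t) for t in Tissue}, indent=2))
        stage_outputs["smooth"] = smooth

    @stage("coarsen")
    def _coarsen():
        coarse = coarsen(stage_outputs["smooth"], config.coarsening)
        coarse = crop_epiphyses(coarse, config.crop_proximal, config.crop_distal)
        labels = segment(coarse, config.coarsening.class_thresholds)
        labels = mark_nonunion(labels, config.nonunion.slab(pcfg))
        write_stack(_labels_as_stack(labels), emit("labels_coarse.nii.gz"))
        stage_outputs["coarse"] = coarse
        stage_outputs["labels"] = labels

    @stage("materials")
    def _materials():
        mats = assign_materials(stage_outputs["labels"], config.materials,
                                "worst_case", stage_outputs["coarse"])
        mesh = fem.build_mesh(mats)
        write_vtk(mesh, emit("materials.vtk"),
                  cell_data={"E": mesh.E, "nu": mesh.nu,
                             "label": mesh.labels.astype(float),
                             "nonunion": mesh.nonunion.astype(float)})
        stage_outputs["mesh"] = mesh

    @stage("solve")
    def _solve():
        mesh = stage_outputs["mesh"]  # built from the worst-case materials
        load = fem.apply_load_case(mesh, config.body_mass_kg)
        disp = fem.solve(mesh, load, **config.solver.as_kwargs())
        fieldv = fem.element_stress(mesh, disp)
        ref = float(fieldv.von_mises.max())
        fieldv = fem.scale_stresses(fieldv, ref)
        write_vtk(mesh, emit("worst_case.vtk"),
                  cell_data={"von_mises": fieldv.von_mises,
                             "scaled": fieldv.scaled},
                  point_data={"displacement": disp.u})
        stage_outputs["reference_max"] = ref
        log.info("worst-case reference max: %.4g Pa", ref)

    @stage("optimize")
    def _optimize():
        result = opt.minimal_fusion(
            stage_outputs["labels"], config.materials, stage_outputs["coarse"],
            config.optimize, config.body_mass_kg, config.solver.as_kwargs())
        summary = opt.summarize(result)
        Path(emit("trajectory.csv")).write_text(opt.summary_to_csv(summary))
        Path(emit("result.json")).write_text(json.dumps(
            {**summary,
             "reference_max_pa": result.reference_max,
             "initial_nonunion_cells": result.initial_count,
             "surviving_cells": result.surviving_count,
             "stopped_reason": result.stopped_reason,
             "failed": result.failed}, indent=2))
        mesh = stage_outputs["mesh"]
        iv = mesh.elem_voxels
        surviving = result.surviving_mask[iv[:, 0], iv[:, 1], iv[:, 2]]
        write_vtk(mesh, emit("minimal_fusion.vtk"),
                  cell_data={"surviving": surviving.astype(float),
                             "nonunion": mesh.nonunion.astype(float)})
        stage_outputs["result"] = result

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    manifest["files"] = sorted(set(manifest["files"]) | {"manifest.json"})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _labels_as_stack(labels):
    from .phantom import ImageStack

    return ImageStack(values=labels.labels.astype(np.uint16),
                      spacing=labels.spacing, origin=labels.origin)
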