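"""Iterative detection of the minimal mechanically relevant fusion area.

The idea: with the nonunion fully interposed by soft tissue (the *worst
case*), the fixation implant carries the entire axial load; its peak von
Mises stress defines the scaling reference ``max`` (mapped to 100).
Starting instead from *full fusion* (nonunion set to cortical bone), each
sweep solves the FE model, demotes every still-fused nonunion cell whose
von Mises stress lies below ``threshold * max`` back to soft tissue, and
repeats.  Cells are never re-promoted.  The loop stops when a sweep would
push the scaled global maximum above the stop cap (that sweep is rolled
back), when no cell qualifies for demotion, or at the step cap.  The cells
that survive are the minimal fusion set: the part of the nonunion that must
actually consolidate for the construct to stay within the stress envelope.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field

from . import fem
from .imaging import LabelVolume
from .materials import CalibrationModel, assign_materials
from .phantom import ImageStack


class OptimizationConfig(BaseModel):
    """Demotion threshold, stop cap and iteration limit.

    ``threshold`` is the fraction of the reference maximum below which a
    fused nonunion cell is considered mechanically irrelevant (default 0.2);
    ``stop_cap`` is the ceiling on the scaled global maximum (default 84 on
    the 0-100 scale, anchored at the worst-case maximum) beyond which a
    sweep is rolled back.  By default the demotion threshold tracks the
    maximum von Mises stress arising in the current step
    (``per_step_reference=True``); with ``False`` it stays anchored at the
    fixed worst-case maximum.  The per-step anchor is the default because
    with an interposed plate the worst-case maximum is dominated by implant
    bending and can sit orders of magnitude above any fused-bone stress, in
    which case a fixed anchor demotes every cell in the first sweep and the
    loop degenerates to an immediate rollback.
    """

    threshold: float = Field(default=0.2, gt=0, lt=1)
    stop_cap: float = Field(default=84.0, gt=0, le=100)
    max_steps: int = Field(default=20, ge=1)
    per_step_reference: bool = True


@dataclass
class StepRecord:
    """One row of the removal trajectory."""

    step: int
    demoted: int
    reduction_pct: float  # demoted cells this step, % of initial nonunion
    cumulative_reduction_pct: float
    scaled_max: float  # scaled global max von Mises after this step


@dataclass
class OptimizationResult:
    """Trajectory plus the surviving (mechanically relevant) fusion mask."""

    steps: list[StepRecord]
    initial_count: int
    surviving_mask: np.ndarray  # 3-D bool, subset of the initial nonunion mask
    total_reduction_pct: float
    remaining_pct: float
    reference_max: float  # Pa
    stopped_reason: str  # "stop_cap" | "no_demotion" | "max_steps" | "solver_failure"
    failed: bool = False
    failure_message: str | None = None

    @property
    def surviving_count(self) -> int:
        return int(self.surviving_mask.sum())


@dataclass
class _Runner:
    """Shared FE state across scenario solves (topology never changes)."""

    labels: LabelVolume
    model: CalibrationModel
    gray: ImageStack | None
    body_mass_kg: float
    solver: dict

    def __post_init__(self) -> None:
        base = assign_materials(self.labels, self.model, "worst_case", self.gray)
        self.mesh = fem.build_mesh(base)
        self.load = fem.apply_load_case(self.mesh, self.body_mass_kg)
        self.nn_elems = np.flatnonzero(self.mesh.nonunion)
        self.e_base = self.mesh.E.copy()
        self.nu_base = self.mesh.nu.copy()

    def solve_state(self, fused_elems: np.ndarray) -> fem.StressField:
        """Solve with the given nonunion elements fused (cortical), the
        rest of the nonunion soft."""
        E = self.e_base.copy()
        nu = self.nu_base.copy()
        E[self.nn_elems] = self.model.e_soft
        nu[self.nn_elems] = self.model.nu_soft
        E[fused_elems] = self.model.e_cortical
        nu[fused_elems] = self.model.nu_bone
        self.mesh.E = E
        self.mesh.nu = nu
        disp = fem.solve(self.mesh, self.load, **self.solver)
        return fem.element_stress(self.mesh, disp)


def worst_case_reference(
    labels: LabelVolume,
    model: CalibrationModel | None = None,
    gray: ImageStack | None = None,
    body_mass_kg: float = 80.0,
    solver: dict | None = None,
):
    """Solve the no-fusion scenario and return ``(max, field, mesh)``.

    The entire nonunion is soft tissue, so the implant must carry the load;
    the global maximum von Mises stress of this solve is the scaling
    reference that maps to 100.
    """
    model = model or CalibrationModel()
    if not labels.nonunion_mask.any():
        raise ValueError("nonunion mask is empty; mark the nonunion first")
    runner = _Runner(labels, model, gray, body_mass_kg, solver or {})
    fieldv = runner.solve_state(np.empty(0, dtype=np.int64))
    ref = float(fieldv.von_mises.max())
    return ref, fem.scale_stresses(fieldv, ref), runner.mesh


def minimal_fusion(
    labels: LabelVolume,
    model: CalibrationModel | None = None,
    gray: ImageStack | None = None,
    config: OptimizationConfig | None = None,
    body_mass_kg: float = 80.0,
    solver: dict | None = None,
) -> OptimizationResult:
    """Run the stress-guided removal loop from full fusion.

    Deterministic given its inputs.  On a solver failure mid-run the result
    up to the last completed step is returned with ``failed=True``.
    """
    model = model or CalibrationModel()
    config = config or OptimizationConfig()
    if not labels.nonunion_mask.any():
        raise ValueError("nonunion mask is empty; mark the nonunion first")
    runner = _Runner(labels, model, gray, body_mass_kg, solver or {})

    # worst case defines the reference maximum
    wc_field = runner.solve_state(np.empty(0, dtype=np.int64))
    ref_max = float(wc_field.von_mises.max())

    nn = runner.nn_elems
    n0 = nn.size
    active = np.ones(n0, dtype=bool)  # fused (still relevant) nonunion cells

    def record_mask() -> np.ndarray:
        mask = np.zeros(labels.shape, dtype=bool)
        iv = runner.mesh.elem_voxels[nn[active]]
        mask[iv[:, 0], iv[:, 1], iv[:, 2]] = True
        return mask

    steps: list[StepRecord] = []
    failed = False
    failure_message = None
    reason = "max_steps"

    fieldv = runner.solve_state(nn)  # full fusion, step 0
    scaled_max = 100.0 * float(fieldv.von_mises.max()) / ref_max
    steps.append(StepRecord(0, 0, 0.0, 0.0, scaled_max))

    cum = 0.0
    for step in range(1, config.max_steps + 1):
        ref = (float(fieldv.von_mises.max()) if config.per_step_reference
               else ref_max)
        vm_nn = fieldv.von_mises[nn]
        demote = active & (vm_nn < config.threshold * ref)  # ties retained
        if not demote.any():
            reason = "no_demotion"
            break
        candidate = active & ~demote
        try:
            trial = runner.solve_state(nn[candidate])
        except fem.SolverError as exc:
            failed = True
            failure_message = str(exc)
            reason = "solver_failure"
            break
        trial_scaled = 100.0 * float(trial.von_mises.max()) / ref_max
        if trial_scaled > config.stop_cap:
            # look-ahead: this sweep would leave the validity envelope
            reason = "stop_cap"
            break
        active = candidate
        fieldv = trial
        red = 100.0 * demote.sum() / n0
        cum += red
        steps.append(StepRecord(step, int(demote.sum()), red, cum, trial_scaled))
    else:
        reason = "max_steps"

    return OptimizationResult(
        steps=steps,
        initial_count=n0,
        surviving_mask=record_mask(),
        total_reduction_pct=cum,
        remaining_pct=100.0 - cum,
        reference_max=ref_max,
        stopped_reason=reason,
        failed=failed,
        failure_message=failure_message,
    )


def summarize(result: OptimizationResult | Sequence[float]) -> dict:
    """Tabulate a removal trajectory.

    Accepts a full :class:`OptimizationResult` or a bare sequence of
    per-step reduction percentages.  Returns a dict with per-step rows, the
    total reduction (sum of per-step reductions) and the remaining fraction
    (100 - total), both in percent.
    """
    if isinstance(result, OptimizationResult):
        rows = [
            {"step": s.step, "reduction_pct": s.reduction_pct,
             "scaled_max": s.scaled_max}
            for s in result.steps
        ]
        reductions = [s.reduction_pct for s in result.steps if s.step > 0]
    else:
        reductions = [float(r) for r in result]
        rows = [
            {"step": i + 1, "reduction_pct": r, "scaled_max": None}
            for i, r in enumerate(reductions)
        ]
    total = float(sum(reductions))
    return {
        "steps": rows,
        "total_reduction_pct": total,
        "remaining_pct": 100.0 - total,
    }


def summary_to_csv(summary: dict) -> str:
    """Render a trajectory summary as CSV text (the per-step table)."""
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["step", "reduction_pct", "scaled_max"])
    for row in summary["steps"]:
        w.writerow([row["step"], row["reduction_pct"], row["scaled_max"]])
    w.writerow(["total", summary["total_reduction_pct"], ""])
    w.writerow(["remaining", summary["remaining_pct"], ""])
    return buf.getvalue()


def summary_to_json(summary: dict) -> str:
    return json.dumps(summary, indent=2)
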