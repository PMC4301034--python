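"""Grayscale → Hounsfield → apparent density → elastic constants.

Bone voxels get a Young's modulus from the densitometric power law
``E = a * rho^b`` (rho in g/cm^3, E in MPa, converted to Pa), with the
grayscale first mapped linearly to the Hounsfield scale and then, through a
calibration line, to apparent density.  Soft tissue and the titanium implant
carry fixed literature constants.  The nonunion region is overridden per
scenario: *worst case* sets it to soft tissue (no fusion at all), *full
fusion* to cortical bone, and an explicit mask mixes the two — the state the
fusion-area optimization iterates over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .imaging import LabelVolume
from .phantom import ImageStack, Tissue

SCENARIO_WORST_CASE = "worst_case"
SCENARIO_FULL_FUSION = "full_fusion"


class CalibrationModel(BaseModel):
    """Calibration lines, power law and elastic constants.

    Defaults map the phantom's cancellous and cortical gray levels (1300,
    2600) to apparent densities 0.5 and 1.8 g/cm^3 — the role a calibration
    phantom plays for a real scanner — and use a literature-range power law
    a = 6850 MPa, b = 1.49 on apparent density.
    """

    hu_slope: float = 1.0
    hu_intercept: float = -1024.0
    rho_slope: float = 0.001  # g/cm^3 per HU
    rho_intercept: float = 0.224
    power_a: float = Field(default=6850.0, gt=0)  # MPa at rho = 1 g/cm^3
    power_b: float = Field(default=1.49, gt=0)
    e_min: float = Field(default=0.1e6, gt=0)  # Pa, floor for meshed voxels
    e_cortical: float = Field(default=16.7e9, gt=0)  # Pa, also the bone cap
    e_implant: float = Field(default=105.0e9, gt=0)  # Pa, titanium
    e_soft: float = Field(default=1.0e6, gt=0)  # Pa
    e_cancellous: float | None = None  # None -> power law at rho=0.5
    nu_bone: float = 0.3
    nu_soft: float = 0.45
    nu_implant: float = 0.34

    @model_validator(mode="after")
    def _check(self) -> "CalibrationModel":
        for name in ("nu_bone", "nu_soft", "nu_implant"):
            nu = getattr(self, name)
            if not (0.0 < nu < 0.5):
                raise ValueError(f"{name} must lie in (0, 0.5)")
        if self.e_min > self.e_cortical:
            raise ValueError("e_min must not exceed e_cortical")
        return self

    def cancellous_modulus(self) -> float:
        if self.e_cancellous is not None:
            return self.e_cancellous
        return float(density_to_modulus(0.5, self))


@dataclass
class MaterialMap:
    """Per-voxel Young's modulus (Pa) and Poisson ratio, plus provenance."""

    E: np.ndarray
    nu: np.ndarray
    labels: LabelVolume

    def __post_init__(self) -> None:
        if self.E.shape != self.labels.shape or self.nu.shape != self.labels.shape:
            raise ValueError("material arrays must match the label volume shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.labels.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.labels.origin


def gray_to_hounsfield(values, model: CalibrationModel | None = None):
    """Linear 12-bit grayscale → Hounsfield map (defaults: HU = g - 1024)."""
    model = model or CalibrationModel()
    return model.hu_slope * np.asarray(values, dtype=np.float64) + model.hu_intercept


def hounsfield_to_density(hu, model: CalibrationModel | None = None):
    """Calibration line HU → apparent density (g/cm^3), clipped at zero."""
    model = model or CalibrationModel()
    rho = model.rho_slope * np.asarray(hu, dtype=np.float64) + model.rho_intercept
    return np.maximum(rho, 0.0)


def density_to_modulus(rho, model: CalibrationModel | None = None):
    """Power law E = a * rho^b, returned in Pa; monotone increasing in rho."""
    model = model or CalibrationModel()
    rho = np.asarray(rho, dtype=np.float64)
    if np.any(rho < 0):
        raise ValueError("apparent density must be >= 0")
    return model.power_a * rho**model.power_b * 1.0e6


def assign_materials(
    labels: LabelVolume,
    model: CalibrationModel | None = None,
    scenario: str | np.ndarray = SCENARIO_WORST_CASE,
    gray: ImageStack | None = None,
) -> MaterialMap:
    """Build the per-voxel (E, nu) map for one fusion scenario.

    Bone voxels get the power-law modulus from their (smoothed) grayscale
    when ``gray`` is given, clamped to ``[e_min, e_cortical]``; without a
    grayscale the class defaults are used.  Implant and soft voxels carry
    their fixed constants.  Nonunion-masked voxels are then overridden:
    ``"worst_case"`` → soft tissue, ``"full_fusion"`` → cortical bone, or a
    boolean array (same shape) → cortical where true, soft elsewhere.
    Background keeps E = 0 and is excluded from meshing.
    """
    model = model or CalibrationModel()
    lab = labels.labels
    E = np.zeros(lab.shape, dtype=np.float64)
    nu = np.full(lab.shape, model.nu_bone, dtype=np.float64)

    soft = lab == Tissue.SOFT
    implant = lab == Tissue.IMPLANT
    bone = (lab == Tissue.CANCELLOUS) | (lab == Tissue.CORTICAL)

    if gray is not None:
        if gray.values.shape != lab.shape:
            raise ValueError("grayscale stack shape does not match labels")
        rho = hounsfield_to_density(gray_to_hounsfield(gray.values, model), model)
        e_bone = density_to_modulus(rho, model)
        E[bone] = np.clip(e_bone[bone], model.e_min, model.e_cortical)
    else:
        E[lab == Tissue.CANCELLOUS] = np.clip(
            model.cancellous_modulus(), model.e_min, model.e_cortical)
        E[lab == Tissue.CORTICAL] = model.e_cortical
    E[soft] = model.e_soft
    nu[soft] = model.nu_soft
    E[implant] = model.e_implant
    nu[implant] = model.nu_implant

    nn = labels.nonunion_mask
    if isinstance(scenario, str):
        if scenario == SCENARIO_WORST_CASE:
            fused = np.zeros(lab.shape, dtype=bool)
        elif scenario == SCENARIO_FULL_FUSION:
            fused = nn
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
    else:
        fused = np.asarray(scenario, dtype=bool)
        if fused.shape != lab.shape:
            raise ValueError("explicit fusion mask shape does not match labels")
        fused = fused & nn
    # nonunion override: fused voxels behave like cortical bone, the rest
    # like interposed soft tissue
    E[nn & fused] = model.e_cortical
    nu[nn & fused] = model.nu_bone
    E[nn & ~fused] = model.e_soft
    nu[nn & ~fused] = model.nu_soft
    return MaterialMap(E=E, nu=nu, labels=labels)
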