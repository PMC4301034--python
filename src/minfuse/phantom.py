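"""Synthetic CT-like phantom of a plated fractured long bone.

The phantom emulates the kind of scan the rest of the pipeline consumes: a
12-bit grayscale stack of a long-bone diaphysis (cortical shell around a
cancellous core), severed by a transverse fracture gap filled with
soft-tissue gray values, and bridged laterally by a locking-plate slab whose
screws cross the bone above and below the gap.  Gaussian noise emulates CT
detector noise.  Geometry is specified in millimetres; the long axis of the
bone is the third array axis, voxel centers sit at ``origin + (i+0.5)*spacing``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import IntEnum
import numpy as np
import SimpleITK as sitk
from pydantic import BaseModel, Field, model_validator


class Tissue(IntEnum):
    """Integer codes for the five tissue classes a voxel can belong to."""

    BACKGROUND = 0
    SOFT = 1
    CANCELLOUS = 2
    CORTICAL = 3
    IMPLANT = 4


#: Default 12-bit gray levels, chosen so the classes are separable by
#: simple thresholds (the implant is sprayed to be radiographically bright).
DEFAULT_GRAY_LEVELS: dict[str, int] = {
    "background": 0,
    "soft": 300,
    "cancellous": 1300,
    "cortical": 2600,
    "implant": 4000,
}

GRAY_MAX = 4095


class StackFormatError(ValueError):
    """Raised when a stack file has an unsupported extension."""


class MissingSpacingError(ValueError):
    """Raised when a stack file carries no voxel-spacing metadata."""


@dataclass
class ImageStack:
    """A 3-D grayscale volume with physical voxel spacing.

    ``values`` is indexed ``[i, j, k]`` with axis 2 the bone's long axis;
    spacing and origin are in millimetres.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis (mm)."""
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]


class PhantomConfig(BaseModel):
    """Geometry, gray levels and noise of the synthetic plated-bone scan.

    All lengths are millimetres.  The defaults are a desk-scale stand-in for
    a clinical scan of an instrumented tibia: a 48 mm field of view around a
    28 mm diameter diaphysis, a 6 mm transverse gap at mid-shaft, a lateral
    titanium plate in contact with the cortex and two bicortical screws on
    either side of the gap.
    """

    grid_dims: tuple[int, int, int] = (48, 48, 120)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    outer_radius: float = 14.0
    cortical_thickness: float = 3.0
    gap_halfwidth: float = 3.0
    gap_center_z: float | None = None  # None -> mid-shaft
    plate_offset: float = 0.0
    plate_thickness: float = 4.0
    plate_width: float = 12.0
    plate_z_extent: tuple[float, float] = (12.0, 108.0)
    screw_radius: float = 2.5
    screw_z_positions: tuple[float, ...] = (30.0, 45.0, 75.0, 90.0)
    gray_levels: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_GRAY_LEVELS))
    noise_sd: float = 25.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomConfig":
        for name in ("outer_radius", "cortical_thickness", "gap_halfwidth",
                     "plate_thickness", "plate_width", "screw_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.cortical_thickness >= self.outer_radius:
            raise ValueError("cortical_thickness must be smaller than outer_radius")
        missing = set(DEFAULT_GRAY_LEVELS) - set(self.gray_levels)
        if missing:
            raise ValueError(f"gray_levels missing classes: {sorted(missing)}")
        for cls, g in self.gray_levels.items():
            if not (0 <= g <= GRAY_MAX):
                raise ValueError(f"gray level for {cls!r} outside [0, {GRAY_MAX}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lx, ly, lz = self.extent
        zc = self.gap_center()
        if not (0 < zc - self.gap_halfwidth and zc + self.gap_halfwidth < lz):
            raise ValueError("gap must lie inside the shaft extent along z")
        # geometry must fit inside the grid; report the offending dimension
        cx, cy = lx / 2.0, ly / 2.0
        plate_x1 = cx + self.outer_radius + self.plate_offset + self.plate_thickness
        if plate_x1 > lx:
            raise ValueError(
                f"plate extends to x={plate_x1:.1f} mm beyond grid extent {lx:.1f} mm (dimension x)")
        if self.outer_radius > min(cx, cy):
            axis = "x" if cx <= cy else "y"
            raise ValueError(
                f"outer_radius {self.outer_radius:.1f} mm exceeds half-extent (dimension {axis})")
        if cy + self.plate_width / 2.0 > ly:
            raise ValueError(
                f"plate width {self.plate_width:.1f} mm does not fit (dimension y)")
        z0, z1 = self.plate_z_extent
        if not (0 <= z0 < z1 <= lz):
            raise ValueError(
                f"plate z extent {self.plate_z_extent} outside grid (dimension z)")
        return self

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(d * s for d, s in zip(self.grid_dims, self.spacing))  # type: ignore[return-value]

    def gap_center(self) -> float:
        if self.gap_center_z is not None:
            return self.gap_center_z
        return self.extent[2] / 2.0


def phantom_labels(config: PhantomConfig) -> np.ndarray:
    """Ground-truth tissue-class volume of the phantom (no noise, no grays).

    Construction order: bone cylinder (cortical shell, cancellous core),
    transverse gap overriding bone with soft tissue, then plate and screws
    overriding everything they intersect with implant.
    """
    nx, ny, nz = config.grid_dims
    sx, sy, sz = config.spacing
    lx, ly, lz = config.extent
    cx, cy = lx / 2.0, ly / 2.0

    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    labels = np.full(config.grid_dims, Tissue.BACKGROUND, dtype=np.int8)

    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    inner = config.outer_radius - config.cortical_thickness
    bone = r2 <= config.outer_radius**2
    labels[np.broadcast_to(bone, labels.shape)] = Tissue.CORTICAL
    core = r2 <= inner**2
    labels[np.broadcast_to(core, labels.shape)] = Tissue.CANCELLOUS

    zc = config.gap_center()
    in_gap = np.abs(Z - zc) <= config.gap_halfwidth
    gap_mask = np.broadcast_to(bone & in_gap, labels.shape)
    labels[gap_mask] = Tissue.SOFT

    px0 = cx + config.outer_radius + config.plate_offset
    px1 = px0 + config.plate_thickness
    pz0, pz1 = config.plate_z_extent
    plate = ((X >= px0) & (X < px1)
             & (np.abs(Y - cy) <= config.plate_width / 2.0)
             & (Z >= pz0) & (Z <= pz1))
    labels[np.broadcast_to(plate, labels.shape)] = Tissue.IMPLANT

    # bicortical screws: cylinders along x from the far cortex to the plate
    sx0 = cx - config.outer_radius
    for zs in config.screw_z_positions:
        screw = (((Y - cy) ** 2 + (Z - zs) ** 2 <= config.screw_radius**2)
                 & (X >= sx0) & (X < px1))
        labels[np.broadcast_to(screw, labels.shape)] = Tissue.IMPLANT
    return labels


def generate_phantom(config: PhantomConfig) -> ImageStack:
    """Render the phantom to a 12-bit grayscale stack.

    Deterministic for a fixed ``config.seed``; with ``noise_sd=0`` every
    voxel equals exactly one configured gray level.
    """
    labels = phantom_labels(config)
    lut = np.array(
        [config.gray_levels[t.name.lower()] for t in Tissue], dtype=np.float64
    )
    values = lut[labels]
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
        values = np.clip(values, 0, GRAY_MAX)
    return ImageStack(values=values, spacing=config.spacing)


_SUPPORTED_EXT = (".mhd", ".nii", ".nii.gz")


def _format_of(path: str) -> str:
    low = path.lower()
    if low.endswith(".mhd"):
        return "mhd"
    if low.endswith(".nii") or low.endswith(".nii.gz"):
        return "nifti"
    raise StackFormatError(
        f"unsupported stack format for {path!r}; expected one of {_SUPPORTED_EXT}")


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as MetaImage (.mhd/.raw) or NIfTI-1 (.nii/.nii.gz)."""
    path = os.fspath(path)
    _format_of(path)
    arr = stack.values
    if np.issubdtype(arr.dtype, np.integer) or np.all(arr == np.round(arr)):
        arr = arr.astype(np.uint16)
    else:
        arr = arr.astype(np.float64)
    # SimpleITK expects [z, y, x] array order
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(stack.spacing))
    img.SetOrigin(tuple(stack.origin))
    sitk.WriteImage(img, path)


def read_stack(path: str | os.PathLike) -> ImageStack:
    """Read a MetaImage or NIfTI stack; spacing metadata is mandatory."""
    path = os.fspath(path)
    fmt = _format_of(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "mhd":
        with open(path, "r", errors="replace") as fh:
            header_keys = [line.split("=")[0].strip() for line in fh if "=" in line]
        if "ElementSpacing" not in header_keys and "ElementSize" not in header_keys:
            raise MissingSpacingError(f"{path!r} has no ElementSpacing metadata")
    img = sitk.ReadImage(path)
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise MissingSpacingError(f"{path!r} carries non-positive voxel spacing {spacing}")
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageStack(
        values=np.asarray(values, dtype=np.float64),
        spacing=spacing,  # type: ignore[arg-type]
        origin=img.GetOrigin(),  # type: ignore[arg-type]
    )
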