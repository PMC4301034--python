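"""Image processing: edge-preserving smoothing, segmentation, nonunion
marking, in-plane coarsening and epiphysis cropping.

Segmentation is deliberately simple: a Perona–Malik anisotropic diffusion
pass regularizes the grayscale while preserving the bone/implant edges, and
fixed grayscale thresholds then split the volume into the five tissue
classes.  The nonunion region — interactively outlined in a clinical
workflow — is specified here as an explicit axis-aligned slab in physical
coordinates so runs are reproducible.

Coarsening merges ``level x level`` pixel windows in the transverse image
plane into one larger pixel by arithmetic averaging (the long axis is left
untouched: slice thickness is already coarse relative to pixel spacing).
Trailing pixels that do not fill a whole window are dropped, so an N-pixel
width becomes ``floor(N / level)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .phantom import DEFAULT_GRAY_LEVELS, ImageStack, Tissue

#: Grayscale cut points separating background/soft/cancellous/cortical/implant
#: for the default phantom gray levels (0, 300, 1300, 2600, 4000).
DEFAULT_THRESHOLDS: tuple[float, float, float, float] = (150.0, 800.0, 1950.0, 3300.0)


@dataclass
class LabelVolume:
    """Per-voxel tissue class plus a boolean nonunion mask."""

    labels: np.ndarray  # int8 over Tissue codes
    nonunion_mask: np.ndarray  # bool, same shape
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.nonunion_mask = np.asarray(self.nonunion_mask, dtype=bool)
        if self.labels.shape != self.nonunion_mask.shape:
            raise ValueError("labels and nonunion_mask shapes differ")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        bad = self.nonunion_mask & np.isin(
            self.labels, (Tissue.BACKGROUND, Tissue.IMPLANT)
        )
        if bad.any():
            raise ValueError(
                "nonunion mask may only cover soft/cancellous/cortical voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]


class DiffusionParams(BaseModel):
    """Explicit Perona–Malik scheme parameters.

    ``kappa`` is the gradient scale in grayscale units (gradients well above
    it are treated as edges and preserved); ``dt`` is the explicit time step,
    stable for the 6-neighbourhood 3-D stencil up to 1/6.
    """

    iterations: int = Field(default=10, ge=0)
    kappa: float = Field(default=120.0, gt=0)
    dt: float = Field(default=1.0 / 6.0, gt=0, le=1.0 / 6.0)


class CoarseningSpec(BaseModel):
    """In-plane window size and the class cut points applied after averaging."""

    level: int = Field(default=2, ge=1)
    class_thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS

    @model_validator(mode="after")
    def _check(self) -> "CoarseningSpec":
        t = self.class_thresholds
        if any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError("class_thresholds must be strictly increasing")
        return self


def anisotropic_diffusion(stack: ImageStack, params: DiffusionParams) -> ImageStack:
    """Edge-preserving smoothing of a grayscale stack.

    Explicit forward-Euler Perona–Malik diffusion with exponential
    conductance ``g(|∇I|) = exp(-(|∇I|/kappa)^2)``, 6-neighbourhood fluxes
    and zero-flux boundaries; the flux form conserves the global gray sum.
    Zero iterations returns the input unchanged.
    """
    if params.iterations == 0:
        return stack
    u = np.asarray(stack.values, dtype=np.float64).copy()
    k2 = params.kappa**2
    for _ in range(params.iterations):
        acc = np.zeros_like(u)
        for axis in range(3):
            d = np.diff(u, axis=axis)  # forward differences between neighbours
            flux = np.exp(-(d * d) / k2) * d
            pad = [(0, 0)] * 3
            pad[axis] = (1, 0)
            fp = np.pad(flux, pad)  # flux across the "lower" face of each voxel
            pad[axis] = (0, 1)
            fm = np.pad(flux, pad)  # flux across the "upper" face
            acc += fm - fp
        u += params.dt * acc
    return ImageStack(values=u, spacing=stack.spacing, origin=stack.origin)


def segment(
    stack: ImageStack,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> LabelVolume:
    """Threshold a grayscale stack into the five tissue classes.

    ``thresholds`` are 4 strictly increasing cut points; values in bin *i*
    get class code *i* (background, soft, cancellous, cortical, implant).
    """
    t = tuple(float(x) for x in thresholds)
    if len(t) != 4 or any(a >= b for a, b in zip(t, t[1:])):
        raise ValueError("thresholds must be 4 strictly increasing cut points")
    labels = np.digitize(stack.values, t).astype(np.int8)
    return LabelVolume(
        labels=labels,
        nonunion_mask=np.zeros(stack.values.shape, dtype=bool),
        spacing=stack.spacing,
        origin=stack.origin,
    )


@dataclass(frozen=True)
class Slab:
    """Axis-aligned region in mm; ``None`` bounds are unbounded."""

    x: tuple[float | None, float | None] = (None, None)
    y: tuple[float | None, float | None] = (None, None)
    z: tuple[float | None, float | None] = (None, None)


def mark_nonunion(labels: LabelVolume, region: Slab) -> LabelVolume:
    """Mark the nonunion: tissue voxels whose centers fall inside a slab.

    Implant and background voxels are never part of the nonunion.  An empty
    intersection is signalled with a warning and yields an empty mask.
    """
    mask = np.ones(labels.shape, dtype=bool)
    for axis, (lo, hi) in enumerate((region.x, region.y, region.z)):
        c = labels.voxel_centers(axis)
        sel = np.ones(c.shape, dtype=bool)
        if lo is not None:
            sel &= c >= lo
        if hi is not None:
            sel &= c <= hi
        shape = [1, 1, 1]
        shape[axis] = -1
        mask &= sel.reshape(shape)
    mask &= np.isin(labels.labels, (Tissue.SOFT, Tissue.CANCELLOUS, Tissue.CORTICAL))
    if not mask.any():
        warnings.warn("nonunion region does not intersect any tissue voxel",
                      stacklevel=2)
    return LabelVolume(
        labels=labels.labels.copy(),
        nonunion_mask=mask,
        spacing=labels.spacing,
        origin=labels.origin,
    )


def _block_mean_inplane(values: np.ndarray, level: int) -> np.ndarray:
    nx, ny = values.shape[:2]
    mx, my = nx // level, ny // level
    v = values[: mx * level, : my * level]
    v = v.reshape(mx, level, my, level, values.shape[2])
    return v.mean(axis=(1, 3))


def coarsen(obj, spec: CoarseningSpec):
    """Merge level x level in-plane pixel windows into one coarser pixel.

    For an :class:`ImageStack` the window is reduced to its arithmetic-mean
    grayscale (classification of the homogenized value is done by
    :func:`segment` on the result).  For a :class:`LabelVolume` each class is
    represented by its default gray level, windows are averaged and the mean
    re-classified with ``spec.class_thresholds``; the nonunion mask is
    coarsened by majority.  In-plane spacing grows by the level; the slice
    axis is untouched.  Level 1 is the identity.
    """
    level = spec.level
    shape = obj.shape
    if level > min(shape[0], shape[1]):
        raise ValueError(
            f"coarsening level {level} exceeds in-plane image width {min(shape[:2])}")
    new_spacing = (obj.spacing[0] * level, obj.spacing[1] * level, obj.spacing[2])
    if isinstance(obj, ImageStack):
        if level == 1:
            return ImageStack(obj.values.copy(), obj.spacing, obj.origin)
        return ImageStack(
            values=_block_mean_inplane(np.asarray(obj.values, dtype=np.float64), level),
            spacing=new_spacing,
            origin=obj.origin,
        )
    if isinstance(obj, LabelVolume):
        if level == 1:
            return LabelVolume(obj.labels.copy(), obj.nonunion_mask.copy(),
                               obj.spacing, obj.origin)
        lut = np.array([DEFAULT_GRAY_LEVELS[t.name.lower()] for t in Tissue],
                       dtype=np.float64)
        mean_gray = _block_mean_inplane(lut[obj.labels], level)
        new_labels = np.digitize(mean_gray, spec.class_thresholds).astype(np.int8)
        mask = _block_mean_inplane(obj.nonunion_mask.astype(np.float64), level) > 0.5
        mask &= ~np.isin(new_labels, (Tissue.BACKGROUND, Tissue.IMPLANT))
        return LabelVolume(new_labels, mask, new_spacing, obj.origin)
    raise TypeError(f"cannot coarsen object of type {type(obj).__name__}")


def coarsened_width(n: int, level: int) -> int:
    """Coarse in-plane width: ``floor(n / level)`` (remainder pixels dropped)."""
    if level < 1:
        raise ValueError("level must be >= 1")
    return n // level


def reduction_percent(n_from: int, n_to: int) -> float:
    """Percentage reduction of a voxel count, e.g. between coarsening levels."""
    if n_from <= 0:
        raise ValueError("n_from must be positive")
    return 100.0 * (1.0 - n_to / n_from)


def crop_epiphyses(obj, proximal_fraction: float, distal_fraction: float):
    """Drop a fraction of slices from each end of the long axis.

    ``distal_fraction`` removes slices from the low-z end, ``proximal_fraction``
    from the high-z end; the origin shifts by the removed distal slices.
    """
    if proximal_fraction < 0 or distal_fraction < 0:
        raise ValueError("crop fractions must be >= 0")
    if proximal_fraction + distal_fraction >= 1:
        raise ValueError("crop fractions must sum to < 1")
    nz = obj.shape[2]
    n_prox = int(nz * proximal_fraction)
    n_dist = int(nz * distal_fraction)
    sl = slice(n_dist, nz - n_prox)
    origin = (obj.origin[0], obj.origin[1], obj.origin[2] + n_dist * obj.spacing[2])
    if isinstance(obj, ImageStack):
        return ImageStack(obj.values[:, :, sl].copy(), obj.spacing, origin)
    if isinstance(obj, LabelVolume):
        return LabelVolume(obj.labels[:, :, sl].copy(),
                           obj.nonunion_mask[:, :, sl].copy(), obj.spacing, origin)
    raise TypeError(f"cannot crop object of type {type(obj).__name__}")
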