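"""Synthetic voxel phantoms: a tumor embedded in a box of normal tissue.

The phantom stands in for patient imaging: a 3-D integer label volume
(0 = outside the computational domain, 1 = normal tissue, 2 = tumor) with a
physical voxel spacing.  Coordinates follow the voxel-center convention:
the physical position of index ``(i, j, k)`` is ``origin + index * spacing``,
with everything in cm.  Masks round-trip through NIfTI (spacing stored in mm,
the format's native unit).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, ValidationError

__all__ = [
    "Phantom",
    "make_spherical_phantom",
    "make_ellipsoidal_phantom",
    "read_mask",
    "write_mask",
    "save_field_nifti",
]

OUTSIDE, NORMAL, TUMOR = 0, 1, 2


@dataclass
class Phantom:
    """A labeled voxel grid with physical spacing (cm)."""

    labels: np.ndarray                    # int array, values in {0, 1, 2}
    spacing: tuple[float, float, float]   # cm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # cm, voxel (0,0,0) center
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be integer-valued")
        extra = set(np.unique(self.labels)) - {OUTSIDE, NORMAL, TUMOR}
        if extra:
            raise ValidationError(f"labels outside {{0, 1, 2}}: {sorted(extra)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be three positive lengths (cm)")
        self.origin = tuple(float(o) for o in self.origin)

    # -- masks and measures -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, cm^3."""
        return float(np.prod(self.spacing))

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == TUMOR

    @property
    def normal_mask(self) -> np.ndarray:
        return self.labels == NORMAL

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != OUTSIDE

    @property
    def tumor_volume(self) -> float:
        """Tumor volume, cm^3 (label count times voxel volume)."""
        return float(self.tumor_mask.sum()) * self.voxel_volume

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates along each axis, cm."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def validate(self) -> None:
        """Check the structural invariants: one connected tumor, strictly interior."""
        tumor = self.tumor_mask
        if not tumor.any():
            raise ValidationError("phantom contains no tumor voxels")
        _, n_components = ndimage.label(tumor)
        if n_components != 1:
            raise ValidationError(
                f"tumor must be a single connected component, found {n_components}"
            )
        # A tumor voxel on the array border or face-adjacent to OUTSIDE touches
        # the outer boundary.
        padded = np.pad(self.labels, 1, constant_values=OUTSIDE)
        tumor_p = padded == TUMOR
        for axis in range(3):
            for shift in (1, -1):
                neighbor = np.roll(padded, shift, axis=axis)
                if np.any(tumor_p & (neighbor == OUTSIDE)):
                    raise ValidationError("tumor touches the outer boundary")


def make_spherical_phantom(
    tumor_radius: float,
    domain_half_width: float,
    spacing: float,
) -> Phantom:
    """Centered spherical tumor inside a cube of normal tissue.

    The cube spans ``[-domain_half_width, domain_half_width]`` per axis.  A
    resolution guard requires ``spacing <= tumor_radius / 5`` so the tumor is
    at least ~10 voxels across.
    """
    if not 0.0 < tumor_radius < domain_half_width:
        raise ValidationError("require 0 < tumor_radius < domain_half_width")
    if spacing > tumor_radius / 5.0:
        raise ValidationError(
            f"spacing {spacing:g} cm too coarse for tumor radius {tumor_radius:g} cm; "
            f"use spacing <= {tumor_radius / 5.0:g} cm"
        )
    x = _axis_coords(domain_half_width, spacing)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r2 = X**2 + Y**2 + Z**2
    labels = np.where(r2 <= tumor_radius**2, TUMOR, NORMAL).astype(np.int8)
    phantom = Phantom(
        labels=labels,
        spacing=(spacing,) * 3,
        origin=(x[0],) * 3,
        provenance=(
            f"sphere r={tumor_radius:g} cm in cube half-width "
            f"{domain_half_width:g} cm, spacing {spacing:g} cm"
        ),
    )
    phantom.validate()
    return phantom


def make_ellipsoidal_phantom(
    semi_axes: tuple[float, float, float],
    domain_half_width: float,
    spacing: float,
    seed: int = 0,
    lobedness: float = 0.0,
    max_retries: int = 5,
) -> Phantom:
    """Ellipsoidal tumor with an optional smooth lobed surface perturbation.

    ``lobedness`` scales a seeded, smooth angular modulation of the surface
    (quadrupole-like directional terms), emulating irregular lobed tumor
    shapes.  ``lobedness = 0`` gives the exact ellipsoid.  Regenerates with a
    perturbed seed up to ``max_retries`` times if the perturbation disconnects
    the tumor.
    """
    a, b, c = (float(s) for s in semi_axes)
    if min(a, b, c) <= 0:
        raise ValidationError("all semi-axes must be positive")
    if max(a, b, c) >= domain_half_width:
        raise ValidationError("semi-axes must be smaller than domain_half_width")
    if lobedness < 0:
        raise ValidationError("lobedness must be non-negative")
    if spacing > min(a, b, c) / 5.0:
        raise ValidationError(
            f"spacing {spacing:g} cm too coarse for smallest semi-axis "
            f"{min(a, b, c):g} cm; use spacing <= {min(a, b, c) / 5.0:g} cm"
        )

    x = _axis_coords(domain_half_width, spacing)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        U = np.stack([X, Y, Z]) / np.where(r > 0, r, 1.0)
    rho = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)

    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        if lobedness > 0:
            dirs = rng.normal(size=(4, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            weights = rng.uniform(-1.0, 1.0, size=4)
            g = np.zeros_like(r)
            for w, d in zip(weights, dirs):
                proj = d[0] * U[0] + d[1] * U[1] + d[2] * U[2]
                g += w * (proj**2 - 1.0 / 3.0)
            peak = np.max(np.abs(g))
            if peak > 0:
                g /= peak
        else:
            g = np.zeros_like(r)
        labels = np.where(rho <= 1.0 + lobedness * g, TUMOR, NORMAL).astype(np.int8)
        phantom = Phantom(
            labels=labels,
            spacing=(spacing,) * 3,
            origin=(x[0],) * 3,
            provenance=(
                f"ellipsoid semi-axes {(a, b, c)} cm, lobedness {lobedness:g}, "
                f"seed {seed} (attempt {attempt}), spacing {spacing:g} cm"
            ),
        )
        try:
            phantom.validate()
        except ValidationError:
            continue
        return phantom
    raise ValidationError(
        f"could not generate a connected interior tumor in {max_retries} attempts"
    )


def _axis_coords(half_width: float, spacing: float) -> np.ndarray:
    """Symmetric voxel-center coordinates covering [-half_width, half_width]."""
    n = int(round(2.0 * half_width / spacing))
    n += 1 - n % 2  # odd count so a voxel center sits at the origin
    return (np.arange(n) - n // 2) * spacing


# -- NIfTI I/O --------------------------------------------------------------

_CM_TO_MM = 10.0


def write_mask(phantom: Phantom, path: str | Path) -> None:
    """Write the label volume as a NIfTI mask (spacing stored in mm).

    Uses the NIfTI-2 variant of the format, whose header keeps the affine in
    double precision so geometry round-trips exactly.
    """
    affine = np.diag([s * _CM_TO_MM for s in phantom.spacing] + [1.0])
    affine[:3, 3] = [o * _CM_TO_MM for o in phantom.origin]
    img = nib.Nifti2Image(phantom.labels.astype(np.int16), affine)
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))


def read_mask(path: str | Path) -> Phantom:
    """Read a NIfTI mask with integer labels in {0, 1, 2} into a Phantom."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"{path}: mask contains non-integer labels")
    labels = np.round(data).astype(np.int16)
    extra = set(np.unique(labels)) - {OUTSIDE, NORMAL, TUMOR}
    if extra:
        raise FormatError(f"{path}: labels outside {{0, 1, 2}}: {sorted(extra)}")
    affine = img.affine
    spacing_mm = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if np.any(spacing_mm <= 0) or not np.all(np.isfinite(spacing_mm)):
        raise FormatError(f"{path}: missing or invalid spacing metadata")
    return Phantom(
        labels=labels,
        spacing=tuple(spacing_mm / _CM_TO_MM),
        origin=tuple(affine[:3, 3] / _CM_TO_MM),
        provenance=f"read from {path}",
    )


def save_field_nifti(phantom: Phantom, values: np.ndarray, path: str | Path) -> None:
    """Write a scalar field defined on the phantom grid as a float NIfTI volume."""
    values = np.asarray(values, dtype=np.float32)
    if values.shape != phantom.shape:
        raise ValidationError("field shape does not match phantom grid")
    affine = np.diag([s * _CM_TO_MM for s in phantom.spacing] + [1.0])
    affine[:3, 3] = [o * _CM_TO_MM for o in phantom.origin]
    img = nib.Nifti1Image(values, affine)
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
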