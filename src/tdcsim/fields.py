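"""Electric-field derivation and cortical-surface maps.

E = -grad V via central differences (one-sided where the stencil would
cross into air, so scalp fields are not contaminated by the near-insulating
exterior), |E| per voxel, the operational cortical surface (gray voxels
facing CSF), outward surface normals, and the signed normal component
E.n with the convention *positive = inward current* (anodal, somatically
depolarizing; negative = outward, hyperpolarizing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .phantoms import LabelVolume
from .solver import PotentialField


@dataclass
class EFieldVolume:
    """Vector field E (V/m) and its magnitude on the voxel grid."""

    E: np.ndarray          # shape (nx, ny, nz, 3)
    magnitude: np.ndarray  # shape (nx, ny, nz)
    voxel_mm: float


@dataclass
class CorticalSurface:
    """Operational cortical surface: gray voxels 6-adjacent to CSF."""

    locations: np.ndarray  # (M, 3) integer voxel indices, lexicographic order
    normals: np.ndarray    # (M, 3) outward unit vectors
    voxel_mm: float


@dataclass
class CorticalMap:
    """|E| and signed normal component sampled on the cortical surface."""

    locations: np.ndarray
    normals: np.ndarray
    ef_magnitude: np.ndarray
    ef_normal: np.ndarray  # positive = inward current
    voxel_mm: float
    sign_convention: str = "positive = inward (anodal) current"

    def __len__(self) -> int:
        return len(self.locations)


@dataclass
class Slice2D:
    data: np.ndarray
    axis: int
    index: int
    voxel_mm: float


def gradient_to_efield(
    pot: PotentialField, head: Optional[LabelVolume] = None
) -> EFieldVolume:
    """E = -grad V (V/m), central differences in the interior.

    When ``head`` is given, voxels whose central stencil would reach into
    air get a one-sided difference taken from the tissue side.
    """
    h_m = pot.voxel_mm * 1e-3
    V = pot.V
    grads = np.gradient(V, h_m, edge_order=1)
    E = -np.stack(grads, axis=-1)

    if head is not None:
        air = head.mask("air")
        tissue = ~air
        for axis in range(3):
            air_plus = _neighbor(air, axis, +1, fill=True)
            air_minus = _neighbor(air, axis, -1, fill=True)
            t_plus = _neighbor(tissue, axis, +1, fill=False)
            t_minus = _neighbor(tissue, axis, -1, fill=False)
            v_plus = _neighbor(V, axis, +1, fill=0.0)
            v_minus = _neighbor(V, axis, -1, fill=0.0)
            # tissue voxel with air on one side only: one-sided from tissue
            one_sided_minus = tissue & air_plus & t_minus
            one_sided_plus = tissue & air_minus & t_plus
            E[..., axis][one_sided_minus] = -(V - v_minus)[one_sided_minus] / h_m
            E[..., axis][one_sided_plus] = -(v_plus - V)[one_sided_plus] / h_m
            # isolated along this axis: no meaningful derivative
            E[..., axis][tissue & air_plus & air_minus] = 0.0

    magnitude = np.linalg.norm(E, axis=-1)
    return EFieldVolume(E=E, magnitude=magnitude, voxel_mm=pot.voxel_mm)


def _neighbor(a: np.ndarray, axis: int, shift: int, fill) -> np.ndarray:
    """a's neighbor value at +-1 along axis; out-of-grid neighbors = fill."""
    out = np.full(a.shape, fill, dtype=a.dtype if a.dtype != bool else bool)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift == +1:
        src[axis] = slice(1, None)
        dst[axis] = slice(None, -1)
    else:
        src[axis] = slice(None, -1)
        dst[axis] = slice(1, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def extract_cortical_surface(
    head: LabelVolume, smoothing_sigma_vox: float = 2.0
) -> CorticalSurface:
    """Gray voxels with a 6-neighbor in CSF, with outward unit normals.

    Normals point from gray toward CSF: the gradient of a Gaussian-smoothed
    gray-matter indicator decreases outward, so the outward normal is its
    negated, normalized gradient.  Degenerate (zero-gradient) voxels fall
    back to the radial direction from the head center.
    """
    gray = head.mask("gray")
    csf = head.mask("csf")
    if not gray.any():
        raise ValueError("no gray-matter voxels in volume")
    csf_adjacent = np.zeros_like(gray)
    for axis in range(3):
        for shift in (+1, -1):
            csf_adjacent |= _neighbor(csf, axis, shift, fill=False)
    surface = gray & csf_adjacent
    if not surface.any():
        raise ValueError("no gray/CSF adjacency: cannot define a cortical surface")

    smoothed = ndimage.gaussian_filter(gray.astype(np.float64), smoothing_sigma_vox)
    g = np.stack(np.gradient(smoothed), axis=-1)
    locations = np.argwhere(surface)  # lexicographic order
    n = -g[tuple(locations.T)]
    norms = np.linalg.norm(n, axis=1)
    degenerate = norms < 1e-12
    if degenerate.any():
        c = np.asarray(head.center_vox)
        radial = locations[degenerate] - c
        rn = np.linalg.norm(radial, axis=1, keepdims=True)
        n[degenerate] = radial / np.maximum(rn, 1e-12)
        norms = np.linalg.norm(n, axis=1)
    n /= norms[:, None]
    return CorticalSurface(locations=locations, normals=n, voxel_mm=head.voxel_mm)


def normal_component_map(ef: EFieldVolume, surface: CorticalSurface) -> CorticalMap:
    """Sample |E| at the surface and project E on the outward normal.

    ``ef_normal = -E . n_outward`` so that current flowing *into* the cortex
    is positive.
    """
    loc = tuple(surface.locations.T)
    E_at = ef.E[loc]
    mag_at = ef.magnitude[loc]
    ef_normal = -np.einsum("ij,ij->i", E_at, surface.normals)
    return CorticalMap(
        locations=surface.locations,
        normals=surface.normals,
        ef_magnitude=mag_at,
        ef_normal=ef_normal,
        voxel_mm=surface.voxel_mm,
    )


def cross_section_slice(
    fieldlike: Union[EFieldVolume, PotentialField, np.ndarray],
    axis: int,
    index: int,
) -> Slice2D:
    """Extract one 2-D cross-section (no interpolation)."""
    if isinstance(fieldlike, EFieldVolume):
        data, voxel_mm = fieldlike.magnitude, fieldlike.voxel_mm
    elif isinstance(fieldlike, PotentialField):
        data, voxel_mm = fieldlike.V, fieldlike.voxel_mm
    else:
        data, voxel_mm = np.asarray(fieldlike), float("nan")
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    if not 0 <= index < data.shape[axis]:
        raise IndexError(
            f"slice index {index} out of range for axis {axis} "
            f"(size {data.shape[axis]})"
        )
    return Slice2D(data=np.take(data, index, axis=axis), axis=axis,
                   index=index, voxel_mm=voxel_mm)


def cortical_map_to_dataframe(cmap: CorticalMap):
    """CorticalMap as a tidy table: x,y,z,nx,ny,nz,|E|,E.n (voxel indices)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x": cmap.locations[:, 0],
            "y": cmap.locations[:, 1],
            "z": cmap.locations[:, 2],
            "nx": cmap.normals[:, 0],
            "ny": cmap.normals[:, 1],
            "nz": cmap.normals[:, 2],
            "ef_magnitude_V_per_m": cmap.ef_magnitude,
            "ef_normal_V_per_m": cmap.ef_normal,
        }
    )
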