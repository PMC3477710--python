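"""Synthetic voxelized head phantoms.

Digital stand-ins for segmented anatomical head volumes: concentric-shell
spheres with the six canonical tissue classes (skin, skull, CSF, gray matter,
white matter, air), optionally with a sinusoidal gyral folding of the
gray/CSF interface, plus homogeneous slabs for closed-form solver checks.

Voxels are classified by their *center* position (no partial-volume
fractions), matching a 1 mm voxelized segmentation workflow and keeping
brute-force geometric oracles simple.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np

#: Canonical label integers used by every phantom and by rasterized montages.
LABEL_CODES: dict[str, int] = {
    "air": 0,
    "skin": 1,
    "skull": 2,
    "csf": 3,
    "gray": 4,
    "white": 5,
    "sponge": 6,
    "gel": 7,
    "electrode": 8,
}

#: Shell order from the outside in (air outside, white at the core).
SHELL_ORDER = ("skin", "skull", "csf", "gray")

_AIR_PAD_VOX = 3  # air voxels padded around every phantom


@dataclass(frozen=True)
class SphereSpec:
    """Geometry of a layered-sphere head phantom.

    Parameters
    ----------
    outer_radius_mm:
        Scalp (outermost skin) radius.
    layer_thicknesses_mm:
        Radial thickness of each shell, outside-in: ``skin``, ``skull``,
        ``csf``, ``gray``. White matter fills the remaining core.
    voxel_mm:
        Isotropic voxel edge length; 1.0 mm reproduces an anatomical-MRI
        resolution workflow.
    """

    outer_radius_mm: float
    layer_thicknesses_mm: Mapping[str, float]
    voxel_mm: float = 1.0

    def __post_init__(self) -> None:
        missing = [k for k in SHELL_ORDER if k not in self.layer_thicknesses_mm]
        if missing:
            raise ValueError(f"layer_thicknesses_mm missing layers: {missing}")
        for name in SHELL_ORDER:
            t = self.layer_thicknesses_mm[name]
            if not t > 0:
                raise ValueError(
                    f"layer_thicknesses_mm[{name!r}] must be > 0, got {t}"
                )
        total = sum(self.layer_thicknesses_mm[k] for k in SHELL_ORDER)
        if not total < self.outer_radius_mm:
            raise ValueError(
                "sum of layer_thicknesses_mm "
                f"({total} mm) must be < outer_radius_mm ({self.outer_radius_mm} mm)"
            )
        if self.voxel_mm <= 0:
            raise ValueError(f"voxel_mm must be > 0, got {self.voxel_mm}")
        if self.outer_radius_mm / self.voxel_mm < 20:
            raise ValueError(
                "outer_radius_mm / voxel_mm must be >= 20 to resolve the shells "
                f"(got {self.outer_radius_mm / self.voxel_mm:.1f})"
            )

    @property
    def shell_outer_radii_mm(self) -> dict[str, float]:
        """Outer radius of each shell (skin, skull, csf, gray, white)."""
        radii = {}
        r = self.outer_radius_mm
        radii["skin"] = r
        for name in SHELL_ORDER[1:]:
            r -= self.layer_thicknesses_mm[SHELL_ORDER[SHELL_ORDER.index(name) - 1]]
            radii[name] = r
        radii["white"] = r - self.layer_thicknesses_mm["gray"]
        return radii


@dataclass(frozen=True)
class GyriSpec:
    """Sinusoidal gyral folding of the gray/CSF interface.

    The interface radius is modulated as

        r(theta, phi) = r0 + A * sin(k * theta) * sin(k * phi + phase(seed))

    with the gray thickness preserved along the radial direction, so fold
    troughs become CSF-filled grooves (sulci) and fold crests push gray
    outward (gyral crowns).  ``phase(seed)`` maps the integer seed to an
    angle via a Knuth multiplicative hash:
    ``phase = 2*pi * ((seed * 2654435761) mod 2**32) / 2**32``,
    so phantoms are portable across implementations.
    """

    fold_amplitude_mm: float
    fold_wavenumber: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_amplitude_mm < 0:
            raise ValueError(
                f"fold_amplitude_mm must be >= 0, got {self.fold_amplitude_mm}"
            )
        if int(self.fold_wavenumber) != self.fold_wavenumber or self.fold_wavenumber < 2:
            raise ValueError(
                f"fold_wavenumber must be an integer >= 2, got {self.fold_wavenumber}"
            )

    @property
    def phase_rad(self) -> float:
        return 2.0 * np.pi * ((int(self.seed) * 2654435761) % 2**32) / 2**32


@dataclass
class LabelVolume:
    """A 3-D integer tissue-label grid with voxel spacing — the digital head.

    Attributes
    ----------
    labels:
        3-D int array; every voxel carries exactly one code from
        ``label_codes``.
    voxel_mm:
        Isotropic voxel edge length in mm.
    label_codes:
        Mapping tissue/material name -> integer code.
    center_vox:
        Geometric head center in (possibly fractional) voxel indices.  Set
        by the sphere generators; for imported volumes it defaults to the
        centroid of non-air voxels.
    """

    labels: np.ndarray
    voxel_mm: float
    label_codes: dict[str, int] = field(default_factory=lambda: dict(LABEL_CODES))
    center_vox: Optional[Tuple[float, float, float]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        known = set(self.label_codes.values())
        present = set(np.unique(self.labels).tolist())
        if not present <= known:
            raise ValueError(f"labels contain unknown codes: {sorted(present - known)}")
        if self.center_vox is None:
            air = self.label_codes.get("air", 0)
            head = np.argwhere(self.labels != air)
            if len(head):
                self.center_vox = tuple(head.mean(axis=0))

    def code(self, name: str) -> int:
        try:
            return self.label_codes[name]
        except KeyError:
            raise KeyError(f"unknown tissue label {name!r}") from None

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.code(name)

    def count(self, name: str) -> int:
        return int(self.mask(name).sum())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            labels=self.labels.copy(),
            voxel_mm=self.voxel_mm,
            label_codes=dict(self.label_codes),
            center_vox=self.center_vox,
            meta=dict(self.meta),
        )

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate grids (mm) relative to ``center_vox``."""
        cx, cy, cz = self.center_vox
        nx, ny, nz = self.labels.shape
        x = (np.arange(nx) - cx)[:, None, None] * self.voxel_mm
        y = (np.arange(ny) - cy)[None, :, None] * self.voxel_mm
        z = (np.arange(nz) - cz)[None, None, :] * self.voxel_mm
        return np.broadcast_arrays(x, y, z)


def _sphere_grid(spec: SphereSpec):
    """Grid shape, center index, and radial/angular coordinate arrays."""
    half = int(np.ceil(spec.outer_radius_mm / spec.voxel_mm)) + _AIR_PAD_VOX
    n = 2 * half + 1
    c = float(half)
    ax = (np.arange(n) - c) * spec.voxel_mm
    x = ax[:, None, None]
    y = ax[None, :, None]
    z = ax[None, None, :]
    r = np.sqrt(x * x + y * y + z * z)
    return n, c, x, y, z, r


def make_layered_sphere_phantom(spec: SphereSpec) -> LabelVolume:
    """Concentric-shell sphere phantom: white core, gray, CSF, skull, skin, air.

    Deterministic given ``spec``; each voxel's label is decided by its
    center's distance from the phantom center.
    """
    n, c, _, _, _, r = _sphere_grid(spec)
    radii = spec.shell_outer_radii_mm
    labels = np.full((n, n, n), LABEL_CODES["air"], dtype=np.int16)
    # outside-in so inner shells overwrite
    labels[r < radii["skin"]] = LABEL_CODES["skin"]
    labels[r < radii["skull"]] = LABEL_CODES["skull"]
    labels[r < radii["csf"]] = LABEL_CODES["csf"]
    labels[r < radii["gray"]] = LABEL_CODES["gray"]
    labels[r < radii["white"]] = LABEL_CODES["white"]
    return LabelVolume(
        labels=labels,
        voxel_mm=spec.voxel_mm,
        center_vox=(c, c, c),
        meta={"kind": "layered_sphere", "spec": dataclasses.asdict(spec) | {
            "layer_thicknesses_mm": dict(spec.layer_thicknesses_mm)}},
    )


def make_gyrated_phantom(spec: SphereSpec, gyri: GyriSpec) -> LabelVolume:
    """Layered sphere with a sinusoidally folded gray/CSF interface.

    The gray/CSF interface radius is ``r0 + A sin(k theta) sin(k phi + phase)``
    and the gray *thickness along the radius* is preserved, so inward folds
    carve CSF-filled sulci into the gray/white territory and outward folds
    form gyral crowns that locally displace CSF.  Identical (spec, gyri)
    inputs produce bit-identical volumes.
    """
    csf_t = spec.layer_thicknesses_mm["csf"]
    gray_t = spec.layer_thicknesses_mm["gray"]
    if not gyri.fold_amplitude_mm < csf_t + gray_t:
        raise ValueError(
            f"fold_amplitude_mm ({gyri.fold_amplitude_mm} mm) must be < "
            f"csf + gray thickness ({csf_t + gray_t} mm): folds must not "
            "pierce the skull or the white core"
        )
    if gyri.fold_amplitude_mm == 0:
        return make_layered_sphere_phantom(spec)

    n, c, x, y, z, r = _sphere_grid(spec)
    radii = spec.shell_outer_radii_mm
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, z / np.maximum(r, 1e-12), 1.0), -1, 1))
    phi = np.arctan2(y, x)
    k = gyri.fold_wavenumber
    mod = gyri.fold_amplitude_mm * np.sin(k * theta) * np.sin(k * phi + gyri.phase_rad)

    gray_out = np.minimum(radii["gray"] + mod, radii["csf"])  # never pierce skull
    gray_in = gray_out - gray_t

    labels = np.full((n, n, n), LABEL_CODES["air"], dtype=np.int16)
    labels[r < radii["skin"]] = LABEL_CODES["skin"]
    labels[r < radii["skull"]] = LABEL_CODES["skull"]
    labels[r < radii["csf"]] = LABEL_CODES["csf"]
    labels[r < gray_out] = LABEL_CODES["gray"]
    labels[r < gray_in] = LABEL_CODES["white"]
    return LabelVolume(
        labels=labels,
        voxel_mm=spec.voxel_mm,
        center_vox=(c, c, c),
        meta={
            "kind": "gyrated_sphere",
            "spec": dataclasses.asdict(spec) | {
                "layer_thicknesses_mm": dict(spec.layer_thicknesses_mm)},
            "gyri": dataclasses.asdict(gyri),
        },
    )


def make_slab_phantom(
    extent_mm: Tuple[float, float, float],
    tissue: str = "gray",
    voxel_mm: float = 1.0,
) -> LabelVolume:
    """Homogeneous box of one tissue label surrounded by one-voxel air padding."""
    if any(e <= 0 for e in extent_mm):
        raise ValueError(f"extent_mm components must be > 0, got {extent_mm}")
    if tissue not in LABEL_CODES:
        raise KeyError(f"unknown tissue label {tissue!r}")
    dims = tuple(int(round(e / voxel_mm)) for e in extent_mm)
    labels = np.full(tuple(d + 2 for d in dims), LABEL_CODES["air"], dtype=np.int16)
    labels[1:-1, 1:-1, 1:-1] = LABEL_CODES[tissue]
    return LabelVolume(
        labels=labels,
        voxel_mm=voxel_mm,
        meta={"kind": "slab", "extent_mm": tuple(extent_mm), "tissue": tissue},
    )
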