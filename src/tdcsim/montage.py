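"""Electrode montages and their rasterization onto a head volume.

Two presets mirror common motor-cortex stimulation setups:

* ``preset_pad_m1_so`` — two 5 cm x 5 cm sponge pads, anode over the
  left-hemisphere motor area ("M1", approximately C3), cathode over the
  contralateral supraorbital ridge.
* ``preset_hd_4x1`` — a high-definition 4x1 ring: one central 12 mm anode
  disc at the same scalp location as the pad anode, surrounded by four
  12 mm cathode discs at 6 cm scalp-geodesic distance, gel-coupled.

The total injected current defaults to 1 mA.  Electrode positions are
spherical angles on the scalp; placement assumes a head that is star-convex
about its center (true for all phantoms; imported anatomies must be roughly
head-shaped for angle-based placement to make sense).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import ndimage

from .phantoms import LABEL_CODES, LabelVolume, make_slab_phantom

Role = Literal["anode", "cathode"]
Shape = Literal["pad", "disc"]

#: Physically typical coupling-layer defaults (mm); not anatomy, convention.
DEFAULT_CONTACT_THICKNESS_MM = {"sponge": 5.0, "gel": 2.0}
DEFAULT_CONDUCTOR_THICKNESS_MM = 1.0


def _load_default_angles() -> dict:
    text = resources.files("tdcsim.presets").joinpath("subjects.yaml").read_text()
    return yaml.safe_load(text)["montage_angles_deg"]


@dataclass(frozen=True)
class Electrode:
    """One stimulation electrode: conductor plus its contact layer.

    ``size_mm`` is (length, width) for a pad and the diameter for a disc.
    ``position`` is (theta, phi) in radians on the scalp sphere, theta polar
    from +z, phi azimuthal.
    """

    name: str
    role: Role
    shape: Shape
    size_mm: Tuple[float, float] | float
    position: Tuple[float, float]
    contact_medium: Literal["sponge", "gel"] = "sponge"
    contact_thickness_mm: float = 5.0
    conductor_thickness_mm: float = DEFAULT_CONDUCTOR_THICKNESS_MM

    def __post_init__(self) -> None:
        if self.role not in ("anode", "cathode"):
            raise ValueError(f"role must be anode|cathode, got {self.role!r}")
        if self.shape not in ("pad", "disc"):
            raise ValueError(f"shape must be pad|disc, got {self.shape!r}")
        if self.contact_thickness_mm <= 0 or self.conductor_thickness_mm <= 0:
            raise ValueError("contact and conductor thicknesses must be > 0")
        if self.shape == "pad":
            l, w = self.size_mm
            if l <= 0 or w <= 0:
                raise ValueError("pad size_mm components must be > 0")
        else:
            if not float(self.size_mm) > 0:
                raise ValueError("disc diameter must be > 0")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from head center toward the electrode center."""
        theta, phi = self.position
        return np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )


@dataclass(frozen=True)
class Montage:
    """An ordered set of electrodes plus the total injected current (dose)."""

    electrodes: Tuple[Electrode, ...]
    total_current_A: float = 1e-3
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "electrodes", tuple(self.electrodes))
        anodes = [e for e in self.electrodes if e.role == "anode"]
        cathodes = [e for e in self.electrodes if e.role == "cathode"]
        if len(anodes) != 1:
            raise ValueError(f"montage needs exactly one anode, got {len(anodes)}")
        if not cathodes:
            raise ValueError("montage needs at least one cathode")
        if self.total_current_A <= 0:
            raise ValueError("total_current_A must be > 0")

    @property
    def anode(self) -> Electrode:
        return next(e for e in self.electrodes if e.role == "anode")

    @property
    def cathodes(self) -> Tuple[Electrode, ...]:
        return tuple(e for e in self.electrodes if e.role == "cathode")

    def with_current(self, total_current_A: float) -> "Montage":
        return dataclasses.replace(self, total_current_A=total_current_A)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "total_current_A": self.total_current_A,
            "electrodes": [
                {
                    "name": e.name,
                    "role": e.role,
                    "shape": e.shape,
                    "size_mm": list(e.size_mm) if e.shape == "pad" else e.size_mm,
                    "position_rad": list(e.position),
                    "contact_medium": e.contact_medium,
                    "contact_thickness_mm": e.contact_thickness_mm,
                    "conductor_thickness_mm": e.conductor_thickness_mm,
                }
                for e in self.electrodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        electrodes = tuple(
            Electrode(
                name=e["name"],
                role=e["role"],
                shape=e["shape"],
                size_mm=tuple(e["size_mm"]) if e["shape"] == "pad" else float(e["size_mm"]),
                position=tuple(e["position_rad"]),
                contact_medium=e["contact_medium"],
                contact_thickness_mm=e["contact_thickness_mm"],
                conductor_thickness_mm=e["conductor_thickness_mm"],
            )
            for e in d["electrodes"]
        )
        return cls(electrodes=electrodes, total_current_A=d["total_current_A"],
                   name=d.get("name", ""))


def preset_pad_m1_so(
    head: LabelVolume,
    total_current_A: float = 1e-3,
    anode_angles_rad: Optional[Tuple[float, float]] = None,
    cathode_angles_rad: Optional[Tuple[float, float]] = None,
) -> Montage:
    """Conventional pad montage: 50x50 mm sponge pads, M1 anode / contralateral
    supraorbital cathode, 1 mA by default."""
    angles = _load_default_angles()
    if anode_angles_rad is None:
        anode_angles_rad = (np.deg2rad(angles["m1"]["theta"]), np.deg2rad(angles["m1"]["phi"]))
    if cathode_angles_rad is None:
        cathode_angles_rad = (np.deg2rad(angles["so"]["theta"]), np.deg2rad(angles["so"]["phi"]))
    pads = (
        Electrode("anode_m1", "anode", "pad", (50.0, 50.0), anode_angles_rad,
                  "sponge", DEFAULT_CONTACT_THICKNESS_MM["sponge"]),
        Electrode("cathode_so", "cathode", "pad", (50.0, 50.0), cathode_angles_rad,
                  "sponge", DEFAULT_CONTACT_THICKNESS_MM["sponge"]),
    )
    montage = Montage(pads, total_current_A=total_current_A, name="pad_m1_so")
    _check_footprints_on_skin(head, montage)
    return montage


def preset_hd_4x1(
    head: LabelVolume,
    total_current_A: float = 1e-3,
    center_angles_rad: Optional[Tuple[float, float]] = None,
    ring_geodesic_mm: float = 60.0,
    disc_diameter_mm: float = 12.0,
) -> Montage:
    """4x1 high-definition ring: center anode disc at the pad-montage anode
    location, four cathode discs at 90 deg increments, each ``ring_geodesic_mm``
    along the scalp from the center; 12 mm discs, gel-coupled, 1 mA."""
    angles = _load_default_angles()
    if center_angles_rad is None:
        center_angles_rad = (np.deg2rad(angles["m1"]["theta"]), np.deg2rad(angles["m1"]["phi"]))
    r_scalp = _scalp_radius_mm(head)
    ring_angle = ring_geodesic_mm / r_scalp
    if ring_angle >= np.pi / 2:
        raise ValueError(
            f"ring geodesic {ring_geodesic_mm} mm exceeds a quarter great-circle "
            f"on a scalp of radius {r_scalp:.1f} mm: ring falls off the modeled scalp"
        )
    u = _unit_from_angles(center_angles_rad)
    e_theta, e_phi = _tangent_basis(u)
    gel = DEFAULT_CONTACT_THICKNESS_MM["gel"]
    electrodes = [
        Electrode("anode_center", "anode", "disc", disc_diameter_mm,
                  center_angles_rad, "gel", gel)
    ]
    for i, az in enumerate(np.deg2rad([0.0, 90.0, 180.0, 270.0])):
        tangent = np.cos(az) * e_theta + np.sin(az) * e_phi
        v = np.cos(ring_angle) * u + np.sin(ring_angle) * tangent
        electrodes.append(
            Electrode(f"cathode_ring_{i}", "cathode", "disc", disc_diameter_mm,
                      _angles_from_unit(v), "gel", gel)
        )
    montage = Montage(tuple(electrodes), total_current_A=total_current_A, name="hd_4x1")
    _check_footprints_on_skin(head, montage)
    return montage


# ---------------------------------------------------------------------------
# rasterization


@dataclass
class ElectrodeRaster:
    """Voxel realization of one electrode on the grid (flat indices)."""

    electrode: Electrode
    contact_idx: np.ndarray
    conductor_idx: np.ndarray
    footprint_scalp_idx: np.ndarray
    #: one entry per exterior conductor face: the flat index of the conductor
    #: voxel owning a face to air (or to the grid boundary)
    exterior_face_cells: np.ndarray


@dataclass
class MontageRaster:
    """A head volume with the montage burnt in, plus per-electrode voxel sets."""

    volume: LabelVolume
    montage: Montage
    electrodes: dict[str, ElectrodeRaster]

    @property
    def anode_raster(self) -> ElectrodeRaster:
        return self.electrodes[self.montage.anode.name]


def _unit_from_angles(position: Tuple[float, float]) -> np.ndarray:
    theta, phi = position
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def _angles_from_unit(v: np.ndarray) -> Tuple[float, float]:
    v = v / np.linalg.norm(v)
    return (float(np.arccos(np.clip(v[2], -1, 1))), float(np.arctan2(v[1], v[0])))


def _tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local (theta-hat, phi-hat) unit vectors at direction u on the sphere."""
    theta, phi = _angles_from_unit(u)
    e_theta = np.array(
        [np.cos(theta) * np.cos(phi), np.cos(theta) * np.sin(phi), -np.sin(theta)]
    )
    e_phi = np.array([-np.sin(phi), np.cos(phi), 0.0])
    return e_theta, e_phi


def _scalp_surface_mask(head: LabelVolume) -> np.ndarray:
    """Non-air voxels with a 6-neighbor in air."""
    air = head.mask("air")
    interior = ~air
    eroded = ndimage.binary_erosion(interior, structure=_six_conn(), border_value=0)
    return interior & ~eroded


def _six_conn() -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1)


def _scalp_radius_mm(head: LabelVolume) -> float:
    surf = np.argwhere(_scalp_surface_mask(head))
    c = np.asarray(head.center_vox)
    return float(np.linalg.norm((surf - c) * head.voxel_mm, axis=1).mean())


def _footprint_membership(
    head: LabelVolume, electrode: Electrode, dirs: np.ndarray, r_scalp: float
) -> np.ndarray:
    """Boolean membership of direction unit-vectors in the electrode footprint.

    ``dirs`` has shape (..., 3).  Footprint extent is measured as scalp
    geodesic (arc length) from the electrode center.
    """
    u = electrode.direction
    cosang = np.clip(dirs @ u, -1.0, 1.0)
    ang = np.arccos(cosang)
    if electrode.shape == "disc":
        return ang * r_scalp <= float(electrode.size_mm) / 2.0
    # pad: decompose the tangent offset onto the local (theta, phi) axes
    e_theta, e_phi = _tangent_basis(u)
    t = dirs - cosang[..., None] * u  # tangential residual
    t_norm = np.linalg.norm(t, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_hat = t / np.maximum(t_norm[..., None], 1e-300)
    arc = ang * r_scalp
    a = arc * (t_hat @ e_theta)
    b = arc * (t_hat @ e_phi)
    length, width = electrode.size_mm
    inside = (np.abs(a) <= length / 2.0) & (np.abs(b) <= width / 2.0)
    inside &= ang < np.pi / 2  # never wrap to the far hemisphere
    return inside


def _check_footprints_on_skin(head: LabelVolume, montage: Montage) -> None:
    scalp = _scalp_surface_mask(head)
    scalp_idx = np.argwhere(scalp)
    c = np.asarray(head.center_vox)
    offs = (scalp_idx - c) * head.voxel_mm
    dirs = offs / np.linalg.norm(offs, axis=1, keepdims=True)
    r_scalp = _scalp_radius_mm(head)
    skin = head.code("skin")
    labels_at = head.labels[tuple(scalp_idx.T)]
    for e in montage.electrodes:
        inside = _footprint_membership(head, e, dirs, r_scalp)
        if not inside.any():
            raise ValueError(f"electrode {e.name!r}: footprint misses the scalp entirely")
        if np.any(labels_at[inside] != skin):
            bad = np.unique(labels_at[inside])
            raise ValueError(
                f"electrode {e.name!r}: footprint does not land entirely on skin "
                f"(labels under footprint: {bad.tolist()})"
            )


def rasterize_montage(head: LabelVolume, montage: Montage) -> MontageRaster:
    """Burn the montage into a copy of ``head``.

    Contact-medium voxels (sponge/gel) grow outward from the skin surface to
    the contact thickness, then conductor voxels to the conductor thickness;
    growth follows the exterior distance field so it tracks the local
    outward normal.  No tissue voxel is overwritten.  Per electrode, the
    exterior conductor faces (faces to remaining air or the grid boundary)
    are recorded; the solver applies the injected current there.
    """
    overlay_codes = {head.code("sponge"), head.code("gel"), head.code("electrode")}
    if np.isin(head.labels, list(overlay_codes)).any():
        raise ValueError(
            "head already carries electrode/sponge/gel voxels: montage is "
            "already rasterized (overlapping montages are an error)"
        )
    _check_footprints_on_skin(head, montage)

    h = head.voxel_mm
    air = head.mask("air")
    # distance (in voxels) from each air voxel to the nearest head voxel
    dist_vox = ndimage.distance_transform_edt(air)
    c = np.asarray(head.center_vox)
    idx = np.indices(head.shape).reshape(3, -1).T
    offs = (idx - c) * h
    rr = np.linalg.norm(offs, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = offs / np.maximum(rr[:, None], 1e-300)
    r_scalp = _scalp_radius_mm(head)

    scalp = _scalp_surface_mask(head)
    flat_air = air.ravel()
    flat_dist = dist_vox.ravel()

    out = head.copy()
    flat_labels = out.labels.ravel()
    owner = np.full(flat_labels.shape, -1, dtype=np.int32)  # electrode index per voxel
    rasters: dict[str, ElectrodeRaster] = {}

    for ei, e in enumerate(montage.electrodes):
        n_contact = max(1, int(round(e.contact_thickness_mm / h)))
        n_conduct = max(1, int(round(e.conductor_thickness_mm / h)))
        inside = _footprint_membership(head, e, dirs.reshape(head.shape + (3,)), r_scalp)
        inside = inside.ravel()
        shell = flat_air & inside & (flat_dist > 0)
        contact = shell & (flat_dist <= n_contact)
        conduct = shell & (flat_dist > n_contact) & (flat_dist <= n_contact + n_conduct)
        newly = contact | conduct
        clash = newly & (owner >= 0)
        if clash.any():
            other = montage.electrodes[int(owner[clash][0])]
            raise ValueError(
                f"electrode footprints overlap: {e.name!r} and {other.name!r}"
            )
        owner[newly] = ei
        medium_code = head.code(e.contact_medium)
        flat_labels[contact] = medium_code
        flat_labels[conduct] = head.code("electrode")
        foot_scalp = scalp.ravel() & inside
        rasters[e.name] = ElectrodeRaster(
            electrode=e,
            contact_idx=np.flatnonzero(contact),
            conductor_idx=np.flatnonzero(conduct),
            footprint_scalp_idx=np.flatnonzero(foot_scalp),
            exterior_face_cells=np.empty(0, dtype=np.int64),
        )
        if len(rasters[e.name].conductor_idx) == 0:
            raise ValueError(f"electrode {e.name!r}: no conductor voxels rasterized")

    # exterior conductor faces, after all electrodes are burnt in
    final_air = out.labels == head.code("air")
    for e in montage.electrodes:
        raster = rasters[e.name]
        mask = np.zeros(flat_labels.shape, dtype=bool)
        mask[raster.conductor_idx] = True
        mask3 = mask.reshape(head.shape)
        faces: list[np.ndarray] = []
        for axis in range(3):
            for sign in (+1, -1):
                nb_air = _shifted(final_air, axis, -sign, fill=True)
                faces.append(np.flatnonzero(mask3 & nb_air))
        raster.exterior_face_cells = np.concatenate(faces)
        if len(raster.exterior_face_cells) == 0:
            raise ValueError(f"electrode {e.name!r}: conductor has no exterior face")

    return MontageRaster(volume=out, montage=montage, electrodes=rasters)


def _shifted(mask: np.ndarray, axis: int, shift: int, fill: bool) -> np.ndarray:
    """Mask of voxels whose neighbor at ``shift`` along ``axis`` is True;
    neighbors beyond the grid boundary count as ``fill``."""
    out = np.full(mask.shape, fill, dtype=bool)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift == +1:
        src[axis] = slice(1, None)
        dst[axis] = slice(None, -1)
    else:
        src[axis] = slice(None, -1)
        dst[axis] = slice(1, None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def footprint_area_mm2(raster: MontageRaster, electrode_name: str) -> float:
    """Scalp contact area of one electrode, from its rasterized footprint.

    A staircase surface patch with outward normal n exposes, per axis a,
    face area A_true * |n_a|; counting the exposed faces per axis (F_x,
    F_y, F_z) under the footprint therefore recovers
    A_true = h^2 * sqrt(F_x^2 + F_y^2 + F_z^2) for a locally flat patch —
    an estimator that is unbiased on oblique staircases, where raw
    surface-voxel counting is not.
    """
    er = raster.electrodes[electrode_name]
    h = raster.volume.voxel_mm
    foot = np.zeros(raster.volume.labels.size, dtype=bool)
    foot[er.footprint_scalp_idx] = True
    foot3 = foot.reshape(raster.volume.shape)
    air = raster.volume.labels == raster.volume.code("air")
    # faces from footprint scalp voxels into air (or contact medium placed
    # on top of them), per axis
    above = air.copy()
    for medium in ("sponge", "gel", "electrode"):
        above |= raster.volume.labels == raster.volume.code(medium)
    sq_sum = 0.0
    for axis in range(3):
        f_axis = 0
        for sign in (+1, -1):
            f_axis += int((foot3 & _shifted(above, axis, sign, fill=True)).sum())
        sq_sum += float(f_axis) ** 2
    return h**2 * np.sqrt(sq_sum)


def geodesic_separation_mm(head: LabelVolume, a: Electrode, b: Electrode) -> float:
    """Scalp-geodesic (great-circle arc) distance between two electrode centers."""
    r_scalp = _scalp_radius_mm(head)
    cosang = float(np.clip(a.direction @ b.direction, -1, 1))
    return r_scalp * np.arccos(cosang)


def make_slab_with_plates(
    extent_mm: Tuple[float, float, float] = (100.0, 100.0, 50.0),
    tissue: str = "gray",
    voxel_mm: float = 2.0,
    total_current_A: float = 1e-3,
) -> MontageRaster:
    """Homogeneous slab with full-face plate electrodes on the +z and -z faces.

    A closed-form test bed: with plate area A and conductivity sigma the
    interior field is uniform with |E| = I / (A sigma).  The +z plate is the
    anode, the -z plate the ground; plates are one voxel of conductor
    occupying the slab's air padding.
    """
    vol = make_slab_phantom(extent_mm, tissue=tissue, voxel_mm=voxel_mm)
    labels = vol.labels
    ecode = vol.code("electrode")
    # padding layers above/below the slab become plates
    labels[1:-1, 1:-1, -1] = ecode
    labels[1:-1, 1:-1, 0] = ecode
    n = labels.size
    flat = np.arange(n).reshape(labels.shape)
    anode_idx = flat[1:-1, 1:-1, -1].ravel()
    cathode_idx = flat[1:-1, 1:-1, 0].ravel()
    plate = (float(extent_mm[0]), float(extent_mm[1]))
    anode = Electrode("plate_top", "anode", "pad", plate, (0.0, 0.0),
                      "gel", contact_thickness_mm=voxel_mm)
    cathode = Electrode("plate_bottom", "cathode", "pad", plate, (np.pi, 0.0),
                        "gel", contact_thickness_mm=voxel_mm)
    montage = Montage((anode, cathode), total_current_A=total_current_A, name="slab_plates")
    rasters = {
        "plate_top": ElectrodeRaster(anode, np.empty(0, np.int64), anode_idx,
                                     np.empty(0, np.int64), anode_idx.copy()),
        "plate_bottom": ElectrodeRaster(cathode, np.empty(0, np.int64), cathode_idx,
                                        np.empty(0, np.int64), cathode_idx.copy()),
    }
    return MontageRaster(volume=vol, montage=montage, electrodes=rasters)
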