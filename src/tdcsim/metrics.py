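"""Comparison metrics and dose normalization.

The headline per-head scalar is the peak cortical electric-field magnitude
(max |E| over cortical-surface locations); a robust peak (99.9th
percentile) is reported alongside because voxelized fields can carry
discretization spikes.  Inter-individual spread is summarized as the
fold-variation max/min over a set of peaks.  Focality of a ring montage is
quantified as the fraction of suprathreshold cortex whose radial scalp
projection falls inside the ring (containment).  Dose normalization
rescales the injected current by reference_peak / subject_peak, which is
exact for this linear DC problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .fields import CorticalMap

ROBUST_PERCENTILE = 99.9


@dataclass(frozen=True)
class PeakResult:
    peak_V_per_m: float
    robust_peak_V_per_m: float
    location: Tuple[int, int, int]


@dataclass(frozen=True)
class RingRegion:
    """Scalp disc of the HD ring: everything within ``radius_mm`` geodesic of
    the ring center direction, radially projected onto the cortex."""

    center_direction: Tuple[float, float, float]
    radius_mm: float
    scalp_radius_mm: float
    center_vox: Tuple[float, float, float]

    @property
    def half_angle_rad(self) -> float:
        return self.radius_mm / self.scalp_radius_mm


@dataclass(frozen=True)
class MetricsReport:
    peak_ef_V_per_m: float
    robust_peak_V_per_m: float
    peak_location: Tuple[int, int, int]
    focality_volume_mm3: float
    containment_fraction: Optional[float]
    n_surface_locations: int


@dataclass(frozen=True)
class DoseNormalizationResult:
    scale_factor: float
    normalized_current_A: float
    reference_subject: str = ""


def peak_cortical_ef(cmap: CorticalMap) -> PeakResult:
    """Max and 99.9th-percentile |E| over cortical locations.

    Ties go to the lexicographically first grid location (surface locations
    are stored in lexicographic order).
    """
    if len(cmap) == 0:
        raise ValueError("empty cortical map")
    values = cmap.ef_magnitude
    i = int(np.argmax(values))  # first occurrence = lexicographic tie-break
    return PeakResult(
        peak_V_per_m=float(values[i]),
        robust_peak_V_per_m=float(np.percentile(values, ROBUST_PERCENTILE)),
        location=tuple(int(v) for v in cmap.locations[i]),
    )


def fold_variation(peaks: Sequence[float]) -> float:
    """max/min over a set of per-head peak values (scale invariant)."""
    peaks = np.asarray(list(peaks), dtype=float)
    if len(peaks) < 2:
        raise ValueError("fold variation needs at least two peak values")
    if np.any(peaks <= 0):
        raise ValueError("peak values must be positive")
    return float(peaks.max() / peaks.min())


def containment_fraction(
    cmap: CorticalMap,
    region: RingRegion,
    threshold_frac: float = 0.5,
) -> Optional[float]:
    """Fraction of suprathreshold cortex inside the ring's scalp projection.

    Suprathreshold = |E| >= threshold_frac x robust peak.  A location is
    inside when its direction from the head center is within the ring's
    half-angle of the ring center direction (radial projection).  Returns
    None when the suprathreshold set is empty (undefined).
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    robust = np.percentile(cmap.ef_magnitude, ROBUST_PERCENTILE)
    if robust <= 0:
        return None  # no field anywhere: suprathreshold set undefined
    supra = cmap.ef_magnitude >= threshold_frac * robust
    if not supra.any():
        return None
    offs = (cmap.locations[supra] - np.asarray(region.center_vox)) * cmap.voxel_mm
    dirs = offs / np.linalg.norm(offs, axis=1, keepdims=True)
    u = np.asarray(region.center_direction, dtype=float)
    u = u / np.linalg.norm(u)
    ang = np.arccos(np.clip(dirs @ u, -1.0, 1.0))
    return float(np.mean(ang <= region.half_angle_rad))


def focality_volume_mm3(cmap: CorticalMap, threshold_frac: float = 0.5) -> float:
    """Cortical volume (mm^3) with |E| above threshold_frac x robust peak."""
    robust = np.percentile(cmap.ef_magnitude, ROBUST_PERCENTILE)
    n = int((cmap.ef_magnitude >= threshold_frac * robust).sum())
    return n * cmap.voxel_mm**3


def metrics_report(
    cmap: CorticalMap,
    region: Optional[RingRegion] = None,
    threshold_frac: float = 0.5,
) -> MetricsReport:
    peak = peak_cortical_ef(cmap)
    contain = containment_fraction(cmap, region, threshold_frac) if region else None
    return MetricsReport(
        peak_ef_V_per_m=peak.peak_V_per_m,
        robust_peak_V_per_m=peak.robust_peak_V_per_m,
        peak_location=peak.location,
        focality_volume_mm3=focality_volume_mm3(cmap, threshold_frac),
        containment_fraction=contain,
        n_surface_locations=len(cmap),
    )


def normalize_dose(
    subject_peak_V_per_m: float,
    reference_peak_V_per_m: float,
    base_current_A: float = 1e-3,
    reference_subject: str = "",
) -> DoseNormalizationResult:
    """Current rescaling that matches the subject's peak to the reference's.

    ``scale_factor = reference_peak / subject_peak`` and
    ``normalized_current = base_current x scale_factor``; by linearity of
    the DC volume-conduction problem, re-solving the subject at the
    normalized current reproduces the reference peak exactly.
    """
    if subject_peak_V_per_m <= 0 or reference_peak_V_per_m <= 0:
        raise ValueError("peak values must be positive")
    scale = reference_peak_V_per_m / subject_peak_V_per_m
    return DoseNormalizationResult(
        scale_factor=scale,
        normalized_current_A=base_current_A * scale,
        reference_subject=reference_subject,
    )
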