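"""Closed-form series solution for an N-layer concentric-sphere head.

Independent validation oracle for the finite-volume solver: two point
current electrodes (+I, -I) on the scalp of a sphere of concentric
isotropic layers.  Per Legendre degree n, the radial profile in layer j is

    f_j(r) = A_j (r/R)^n + B_j (R/r)^(n+1)

with B = 0 in the core (regularity), continuity of V and of the radial
current density sigma dV/dr across each interface, and the surface
condition sigma_1 dV/dr|_R = I (2n+1) / (4 pi R^2) per degree for a point
source (the n = 0 monopole terms cancel between the paired electrodes).
Coefficients are propagated core-outward with a per-degree 2x2 recursion
in radius *ratios*, which stays well-scaled to high degree.  The potential
carries a free additive constant; compare against grounded solutions after
mean alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy.special import eval_legendre


@dataclass(frozen=True)
class SphereModel:
    """Concentric-layer sphere with two scalp point-current electrodes.

    ``layer_radii_m`` lists outer radii, outermost first, strictly
    decreasing; ``layer_sigmas_S_per_m`` matches (layer j spans
    radii[j] down to radii[j+1], the last layer is the core).
    ``electrodes`` are (unit_direction, current_A) pairs whose currents
    must sum to zero.
    """

    layer_radii_m: Tuple[float, ...]
    layer_sigmas_S_per_m: Tuple[float, ...]
    electrodes: Tuple[Tuple[Tuple[float, float, float], float], ...]
    n_terms: int = 120
    truncation_tol: float = 1e-4

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.layer_radii_m)
        sigmas = tuple(float(s) for s in self.layer_sigmas_S_per_m)
        object.__setattr__(self, "layer_radii_m", radii)
        object.__setattr__(self, "layer_sigmas_S_per_m", sigmas)
        if len(radii) != len(sigmas):
            raise ValueError("need one conductivity per layer")
        if any(r <= 0 for r in radii) or any(np.diff(radii) >= 0):
            raise ValueError("layer radii must be positive and strictly decreasing")
        if any(s <= 0 for s in sigmas):
            raise ValueError("layer conductivities must be positive")
        elecs = tuple(
            ((float(d[0]), float(d[1]), float(d[2])), float(i))
            for d, i in self.electrodes
        )
        object.__setattr__(self, "electrodes", elecs)
        if abs(sum(i for _, i in elecs)) > 1e-12 * max(abs(i) for _, i in elecs):
            raise ValueError("electrode currents must sum to zero")
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")

    @property
    def outer_radius_m(self) -> float:
        return self.layer_radii_m[0]


def _radial_coefficients(model: SphereModel) -> np.ndarray:
    """Per-layer, per-degree coefficients (A_j(n), B_j(n)) for unit current.

    Returns array of shape (n_layers, 2, n_terms) for degrees 1..n_terms,
    scaled for a +1 A point electrode on the outer surface.
    """
    R = model.outer_radius_m
    sig = model.layer_sigmas_S_per_m
    radii = model.layer_radii_m
    L = len(radii)
    n = np.arange(1, model.n_terms + 1, dtype=np.float64)

    A = np.zeros((L, len(n)))
    B = np.zeros((L, len(n)))
    A[L - 1] = 1.0  # core: unit A, B = 0 (regular at the origin)
    # propagate outward across each interface at radius c = radii[j]
    for j in range(L - 2, -1, -1):
        c = radii[j + 1]
        t = c / R
        P = t**n
        Q = t ** -(n + 1)
        u1 = A[j + 1] * P + B[j + 1] * Q
        u2 = (sig[j + 1] / sig[j]) * (n * A[j + 1] * P - (n + 1) * B[j + 1] * Q)
        A[j] = ((n + 1) * u1 + u2) / ((2 * n + 1) * P)
        B[j] = (n * u1 - u2) / ((2 * n + 1) * Q)

    # outer-surface flux condition for a +1 A point source
    f_n = (2 * n + 1) / (4 * np.pi * R**2)
    deriv = sig[0] * (n * A[0] - (n + 1) * B[0]) / R
    if np.any(deriv == 0) or not np.all(np.isfinite(deriv)):
        raise FloatingPointError("singular radial recursion; reduce n_terms")
    s = f_n / deriv
    coeffs = np.stack([A * s, B * s], axis=1)
    if not np.all(np.isfinite(coeffs)):
        raise FloatingPointError("non-finite series coefficients; reduce n_terms")
    return coeffs


def _layer_of(model: SphereModel, r: np.ndarray) -> np.ndarray:
    """Index of the layer containing each radius (outermost layer = 0)."""
    edges = np.asarray(model.layer_radii_m[1:])
    return np.searchsorted(-edges, -r, side="right")


def _prepare(model: SphereModel, points: np.ndarray):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    R = model.outer_radius_m
    if np.any(r > R * (1 + 1e-12)):
        raise ValueError("query points must lie inside the outer radius")
    layer = _layer_of(model, np.minimum(r, R))
    return pts, r, layer


def _legendre_and_derivative(nmax: int, u: np.ndarray):
    """P_n(u) and P_n'(u) for n = 1..nmax, u shape (M,). Returns (M, nmax)."""
    n = np.arange(1, nmax + 1)
    P = eval_legendre(n[None, :], u[:, None])
    Pm1 = eval_legendre((n - 1)[None, :], u[:, None])
    denom = u[:, None] ** 2 - 1.0
    near_pole = np.abs(denom) < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        dP = n[None, :] * (u[:, None] * P - Pm1) / denom
    # endpoint limits: P_n'(1) = n(n+1)/2, P_n'(-1) = (-1)^(n+1) n(n+1)/2
    lim_pos = n * (n + 1) / 2.0
    lim = np.where(u[:, None] >= 0, lim_pos, (-1.0) ** (n + 1) * lim_pos)
    dP = np.where(near_pole, lim, dP)
    return P, dP


def sphere_potential(model: SphereModel, points) -> np.ndarray:
    """Series potential (V) at one or more interior points.

    The result carries a free additive constant (only degrees >= 1 are
    defined for net-zero total current).  Raises if the truncated series
    has not converged at any query point.
    """
    pts, r, layer = _prepare(model, points)
    coeffs = _radial_coefficients(model)
    R = model.outer_radius_m
    n = np.arange(1, model.n_terms + 1, dtype=np.float64)
    rho = np.clip(r / R, 1e-12, 1.0)
    pow_in = rho[:, None] ** n[None, :]
    A = coeffs[layer, 0, :]
    B = coeffs[layer, 1, :]
    pow_out = _outward_powers(rho, n, B, model)
    f = A * pow_in + B * pow_out  # (M, n_terms)

    total = np.zeros(len(pts))
    tail = np.zeros(len(pts))
    for direction, current in model.electrodes:
        u = _cosangle(pts, r, np.asarray(direction))
        P, _ = _legendre_and_derivative(model.n_terms, u)
        terms = current * f * P
        total += terms.sum(axis=1)
        tail += np.abs(terms[:, -1])
    _check_truncation(total, tail, model)
    return total if np.asarray(points).ndim > 1 else total[0]


def sphere_efield(model: SphereModel, points) -> np.ndarray:
    """Analytic E = -grad V (V/m) by term-by-term differentiation."""
    pts, r, layer = _prepare(model, points)
    coeffs = _radial_coefficients(model)
    R = model.outer_radius_m
    n = np.arange(1, model.n_terms + 1, dtype=np.float64)
    r_safe = np.maximum(r, 1e-12)
    rho = np.clip(r_safe / R, 1e-12, 1.0)
    pow_in = rho[:, None] ** n[None, :]
    A = coeffs[layer, 0, :]
    B = coeffs[layer, 1, :]
    pow_out = _outward_powers(rho, n, B, model)
    f = A * pow_in + B * pow_out
    fprime = (n * A * pow_in - (n + 1) * B * pow_out) / r_safe[:, None]

    r_hat = pts / r_safe[:, None]
    grad = np.zeros_like(pts)
    tail = np.zeros(len(pts))
    ref = np.zeros(len(pts))
    for direction, current in model.electrodes:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        u = _cosangle(pts, r, d)
        P, dP = _legendre_and_derivative(model.n_terms, u)
        # grad u = (d_hat - u r_hat) / r
        grad_u = (d[None, :] - u[:, None] * r_hat) / r_safe[:, None]
        radial = (current * fprime * P).sum(axis=1)
        angular = (current * f * dP).sum(axis=1)
        grad += radial[:, None] * r_hat + angular[:, None] * grad_u
        tail += np.abs(current * fprime[:, -1] * P[:, -1])
        tail += np.abs(current * f[:, -1] * dP[:, -1]) / r_safe
        ref += np.abs(radial) + np.abs(angular) / r_safe
    _check_truncation(ref, tail, model)
    E = -grad
    return E if np.asarray(points).ndim > 1 else E[0]


def _outward_powers(
    rho: np.ndarray, n: np.ndarray, B: np.ndarray, model: SphereModel
) -> np.ndarray:
    """(r/R)^-(n+1), evaluated safely: core-layer points have B = 0 exactly,
    so their (otherwise overflowing) outward powers are irrelevant and rho is
    floored at the innermost interface ratio to keep the product finite."""
    floor = model.layer_radii_m[-1] / model.outer_radius_m if len(
        model.layer_radii_m) > 1 else 1.0
    rho_safe = np.where((B != 0).any(axis=1), rho, np.maximum(rho, floor))
    return rho_safe[:, None] ** -(n[None, :] + 1)


def _cosangle(pts: np.ndarray, r: np.ndarray, direction: np.ndarray) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (pts @ d) / np.maximum(r, 1e-12)
    return np.clip(u, -1.0, 1.0)


def _check_truncation(total: np.ndarray, tail: np.ndarray, model: SphereModel) -> None:
    # scale against the largest field value among the queries: per-point
    # ratios blow up spuriously on symmetry planes where the field vanishes
    scale = max(float(np.max(np.abs(total))), 1e-30)
    worst = float(np.max(tail)) / scale
    if worst > model.truncation_tol:
        raise ValueError(
            f"series not converged at n_terms={model.n_terms}: last-term bound "
            f"{worst:.2e} exceeds truncation_tol={model.truncation_tol:g}; "
            "increase n_terms (or move query points away from the electrodes)"
        )


def homogeneous_sphere_potential(
    radius_m: float,
    sigma_S_per_m: float,
    electrode_direction,
    current_A: float,
    points,
) -> np.ndarray:
    """Closed-form potential of a single +I point electrode on a homogeneous
    sphere's surface (free constant; n >= 1 part only).

    V(r, gamma) = I / (4 pi sigma R) * [ 2 / sqrt(1 - 2 t u + t^2) - 2
                  + ln( 2 / (1 - t u + sqrt(1 - 2 t u + t^2)) ) ],
    with t = r / R and u = cos(gamma); the independent check for the
    degenerate single-layer series.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    d = np.asarray(electrode_direction, dtype=float)
    d = d / np.linalg.norm(d)
    t = r / radius_m
    u = _cosangle(pts, r, d)
    root = np.sqrt(1.0 - 2.0 * t * u + t * t)
    series1 = 1.0 / root - 1.0                     # sum t^n P_n
    series2 = np.log(2.0 / (1.0 - t * u + root))   # sum t^n P_n / n
    out = current_A / (4 * np.pi * sigma_S_per_m * radius_m) * (2 * series1 + series2)
    return out if np.asarray(points).ndim > 1 else out[0]
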