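"""Radial parametric geometry for synthetic vessel cross-sections.

A vessel is two closed curves, star-shaped about a common centre:

* the lumen boundary ``R_in(θ)`` — an ellipse radius optionally modulated
  by a low-order Fourier perturbation, so lumens are flattened and
  irregular rather than circular;
* the outer wall boundary ``R_out(θ) = R_in(θ) + t(θ)``, where the radial
  wall thickness ``t(θ) = t0·(1 + m·cos(kθ + ψ))`` models walls that are
  thicker on one side than the other (eccentric lumens).

Both radii are trigonometric polynomials, so every integral used for
areas is evaluated with the midpoint rule on a uniform angular grid —
which is *exact* for trigonometric polynomials of degree below half the
grid size.  The "truth" areas attached to synthetic vessels are therefore
exact up to floating-point rounding, not raster approximations.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

#: number of uniform angular nodes used for quadrature and rasterization
N_THETA = 4096

THETA = np.linspace(0.0, 2.0 * np.pi, N_THETA, endpoint=False)


def ellipse_radius(a: float, b: float, theta: np.ndarray, rotation: float = 0.0) -> np.ndarray:
    """Radius of an ellipse with semi-axes ``a, b`` rotated by ``rotation``.

    ``r(θ) = ab / sqrt((b cos u)² + (a sin u)²)`` with ``u = θ − rotation``.
    """
    u = theta - rotation
    return (a * b) / np.hypot(b * np.cos(u), a * np.sin(u))


def fourier_modulation(
    theta: np.ndarray,
    orders: tuple[int, ...],
    amplitudes: tuple[float, ...],
    phases: tuple[float, ...],
) -> np.ndarray:
    """``1 + Σ_k ε_k cos(kθ + φ_k)`` — a smooth multiplicative wobble."""
    if not (len(orders) == len(amplitudes) == len(phases)):
        raise GeometryError("orders, amplitudes and phases must have equal length")
    mod = np.ones_like(theta)
    for k, eps, phi in zip(orders, amplitudes, phases):
        mod = mod + eps * np.cos(k * theta + phi)
    return mod


def lumen_radius(
    a: float,
    b: float,
    rotation: float = 0.0,
    orders: tuple[int, ...] = (),
    amplitudes: tuple[float, ...] = (),
    phases: tuple[float, ...] = (),
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """Perturbed-ellipse lumen boundary radius on the angular grid."""
    th = THETA if theta is None else theta
    r = ellipse_radius(a, b, th, rotation) * fourier_modulation(th, orders, amplitudes, phases)
    if np.any(r <= 0):
        raise GeometryError(
            "lumen boundary radius is non-positive: perturbation amplitudes too large"
        )
    return r


def enclosed_area(radius: np.ndarray) -> float:
    """Area enclosed by a star-shaped curve: ``½∮R² dθ`` (exact midpoint rule)."""
    return float(np.pi * np.mean(radius ** 2))


def thickness_profile(
    t0: float,
    modulation: float,
    order: int,
    phase: float,
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """Radial wall thickness ``t(θ) = t0·(1 + m cos(kθ + ψ))``, strictly positive."""
    th = THETA if theta is None else theta
    if t0 <= 0:
        raise GeometryError(f"wall thickness base must be > 0, got {t0}")
    if not 0.0 <= modulation < 1.0:
        raise GeometryError(f"thickness modulation must lie in [0, 1), got {modulation}")
    return t0 * (1.0 + modulation * np.cos(order * th + phase))


def wall_area(r_in: np.ndarray, thickness: np.ndarray) -> float:
    """Exact area between ``R_in`` and ``R_in + t``: ``½∮((R+t)² − R²) dθ``."""
    return enclosed_area(r_in + thickness) - enclosed_area(r_in)


def solve_thickness_base(
    r_in: np.ndarray,
    wall_area_target: float,
    modulation: float = 0.0,
    order: int = 1,
    phase: float = 0.0,
) -> float:
    """Solve for the base thickness giving a prescribed wall area.

    With ``t(θ) = t0 g(θ)`` the wall area is exactly quadratic in ``t0``:
    ``A_W(t0) = B t0 + C t0²`` with ``B = ∮ R_in g dθ`` and
    ``C = ½ ∮ g² dθ``, so the positive root is closed-form.  This is what
    lets the generator hit a sampled lumen:wall area ratio to machine
    precision.
    """
    if wall_area_target <= 0:
        raise GeometryError(f"wall area target must be > 0, got {wall_area_target}")
    g = 1.0 + modulation * np.cos(order * THETA + phase)
    B = 2.0 * np.pi * float(np.mean(r_in * g))
    C = np.pi * float(np.mean(g ** 2))
    disc = B * B + 4.0 * C * wall_area_target
    t0 = (-B + np.sqrt(disc)) / (2.0 * C)
    if t0 <= 0:
        raise GeometryError("thickness solve produced a non-positive root")
    return t0


def rasterize_star_region(
    r_in: np.ndarray,
    r_out: np.ndarray,
    microns_per_pixel: float,
    image_size: int,
) -> np.ndarray:
    """Rasterize the two star-shaped boundaries into a 3-label grid.

    A pixel belongs to a region iff its centre lies inside the region
    (no anti-aliasing): lumen where ``r ≤ R_in(θ)``, wall where
    ``R_in(θ) < r ≤ R_out(θ)``.  The construction centre sits at the
    image centre; boundary radii are interpolated on the angular grid.
    """
    if np.any(r_out < r_in):
        raise GeometryError("outer boundary lies inside the lumen boundary")
    half_extent = (image_size - 1) / 2.0 * microns_per_pixel
    if float(np.max(r_out)) >= half_extent - microns_per_pixel:
        raise GeometryError(
            f"vessel (outer radius {np.max(r_out):.2f} μm) does not fit an "
            f"image of {image_size} px at {microns_per_pixel} μm/px"
        )
    c = (image_size - 1) / 2.0
    # only pixels inside the vessel's bounding box can be non-background
    r_max_px = float(np.max(r_out)) / microns_per_pixel
    lo = max(0, int(np.floor(c - r_max_px)) - 1)
    hi = min(image_size, int(np.ceil(c + r_max_px)) + 2)
    coords = (np.arange(lo, hi) - c) * microns_per_pixel
    yy = coords[:, None]
    xx = coords[None, :]
    rr = np.hypot(xx, yy)
    tt = np.mod(np.arctan2(yy, xx), 2.0 * np.pi)

    # periodic linear interpolation of the boundary radii
    grid = np.concatenate([THETA, [2.0 * np.pi]])
    rin_p = np.concatenate([r_in, [r_in[0]]])
    rout_p = np.concatenate([r_out, [r_out[0]]])
    rin_at = np.interp(tt, grid, rin_p)
    rout_at = np.interp(tt, grid, rout_p)

    box = np.zeros(rr.shape, dtype=np.uint8)
    box[rr <= rout_at] = 2
    box[rr <= rin_at] = 1
    labels = np.zeros((image_size, image_size), dtype=np.uint8)
    labels[lo:hi, lo:hi] = box
    return labels
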