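"""Spherical-cap geometry of strongly adhering vesicles and adhesion thresholds.

A vesicle adhering strongly to a planar substrate takes a spherical-cap
shape characterized by the effective contact angle ``theta_eff`` (0: flat
pancake, pi: free sphere touching at a point).  With sphere radius R and
``c = cos(theta_eff)`` the cap formulas give

    A1 = 2*pi*R^2*(1 - c)          (unbound cap area)
    A2 = pi*R^2*(1 - c^2)          (bound contact-disk area)
    h  = R*(1 - c)                 (cap height)
    V  = (pi/3)*h^2*(3R - h)       (enclosed volume)

so the unbound area fraction is the scale-free

    q1 = A1/(A1 + A2) = 2/(3 + cos(theta_eff)),

which runs from 1/2 (pancake) through 2/3 (hemisphere) to 1 (point
contact).  The reduced volume ``v = V / ((4*pi/3)*(A/4pi)**1.5)`` (1 for a
sphere) increases monotonically with the contact angle, so ``q1`` is
uniquely determined by ``v`` and vice versa.

The strong-adhesion criterion compares the contact curvature radius
``Rco = sqrt(kappa/(2|W|))`` (bending rigidity kappa, adhesion free energy
per area W < 0) with a resolution length ``Lstar``: adhesion is strong once
``|W|`` exceeds ``|W|* = kappa/(2*Lstar**2)`` and dominates the membrane
tension scale ``2*pi*kappa/A`` arising from vesicle closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "KB",
    "T_ROOM",
    "CapGeometry",
    "AdhesionStrength",
    "q1_from_angle",
    "cap_geometry",
    "reduced_volume_from_angle",
    "angle_from_reduced_volume",
    "q1_from_reduced_volume",
    "contact_radius",
    "strong_adhesion_threshold",
    "in_strong_regime",
    "kappa_in_kBT",
]

#: Boltzmann constant [J/K].
KB = 1.380649e-23
#: Room temperature used for kBT conversions, 25 C [K].
T_ROOM = 298.15


def _check_angle(theta_eff: float) -> None:
    if not (0.0 < theta_eff <= math.pi):
        raise ValueError(f"theta_eff must lie in (0, pi] radians, got {theta_eff}")


def q1_from_angle(theta_eff: float) -> float:
    """Unbound area fraction ``q1 = 2/(3 + cos(theta_eff))``.

    Monotonically increasing on (0, pi]; 1/2 in the pancake limit, 2/3 for a
    hemisphere, 1 at point contact.
    """
    _check_angle(theta_eff)
    return 2.0 / (3.0 + math.cos(theta_eff))


@dataclass(frozen=True)
class CapGeometry:
    """Spherical-cap shape descriptors at a given contact angle.

    Areas and volume are reported for the given sphere radius ``R``; the
    dimensionless outputs ``q1`` and ``v`` are scale invariant.
    """

    theta_eff: float
    q1: float
    v: float
    R: float
    A1: float
    A2: float
    A: float
    V: float


def cap_geometry(theta_eff: float, R: float = 1.0) -> CapGeometry:
    """Full spherical-cap geometry (areas, volume, q1, reduced volume)."""
    _check_angle(theta_eff)
    if R <= 0:
        raise ValueError(f"R must be positive, got {R}")
    c = math.cos(theta_eff)
    A1 = 2.0 * math.pi * R * R * (1.0 - c)
    A2 = math.pi * R * R * (1.0 - c) * (1.0 + c)
    A = A1 + A2
    h = R * (1.0 - c)
    V = (math.pi / 3.0) * h * h * (3.0 * R - h)
    r_ve = math.sqrt(A / (4.0 * math.pi))
    v = V / ((4.0 * math.pi / 3.0) * r_ve**3)
    return CapGeometry(theta_eff=theta_eff, q1=2.0 / (3.0 + c), v=v,
                       R=R, A1=A1, A2=A2, A=A, V=V)


def reduced_volume_from_angle(theta_eff: float) -> float:
    """Reduced volume ``v`` of the cap; strictly increasing, v(pi) = 1."""
    return cap_geometry(theta_eff).v


def angle_from_reduced_volume(v: float) -> float:
    """Invert ``v(theta_eff)`` on (0, pi] by monotone root search."""
    if not (0.0 < v <= 1.0):
        raise ValueError(f"reduced volume must lie in (0, 1], got {v}")
    if v == 1.0:
        return math.pi
    # v(theta) ~ 0.53*theta as theta -> 0; below ~1e-7 rad the cap area
    # underflows, and such a flat pancake is far outside the model's use.
    lo = 1e-7
    if v <= reduced_volume_from_angle(lo):
        raise ValueError(f"reduced volume {v} too small to invert reliably")
    return brentq(lambda th: reduced_volume_from_angle(th) - v,
                  lo, math.pi, xtol=1e-14)


def q1_from_reduced_volume(v: float) -> float:
    """Unbound area fraction at given reduced volume (osmotic control)."""
    return q1_from_angle(angle_from_reduced_volume(v))


@dataclass(frozen=True)
class AdhesionStrength:
    """Adhesion-strength summary for a (kappa, W) pair."""

    kappa: float
    W: float
    Rco: float
    Lstar: float
    W_star: float
    strong: bool


def contact_radius(kappa: float, W: float) -> float:
    """Contact curvature radius ``Rco = sqrt(kappa / (2|W|))``.

    ``W`` must be negative (attractive substrate); kappa positive.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if W >= 0:
        raise ValueError(f"adhesion free energy W must be negative (attractive), got {W}")
    return math.sqrt(kappa / (2.0 * abs(W)))


def strong_adhesion_threshold(kappa: float, Lstar: float) -> float:
    """Threshold adhesion strength ``|W|* = kappa / (2 Lstar^2)``.

    ``Lstar`` is the resolution length below which the contact curvature is
    unresolvable (0.5 um for optical microscopy of giant vesicles).
    """
    if kappa <= 0 or Lstar <= 0:
        raise ValueError("kappa and Lstar must be positive")
    return kappa / (2.0 * Lstar * Lstar)


def in_strong_regime(
    kappa: float,
    W: float,
    A: float,
    Lstar: float = 0.5e-6,
    tension_factor: float = 10.0,
) -> bool:
    """Whether (kappa, W, A) lies in the strong-adhesion (spherical-cap) regime.

    Requires both ``Rco < Lstar`` (equivalently ``|W| > |W|*``) and ``|W|``
    exceeding the closure-tension scale ``2*pi*kappa/A`` by
    ``tension_factor`` (default 10, a documented margin standing in for the
    asymptotic 'much greater than').
    """
    if A <= 0:
        raise ValueError(f"membrane area A must be positive, got {A}")
    rco = contact_radius(kappa, W)
    return rco < Lstar and abs(W) > tension_factor * (2.0 * math.pi * kappa / A)


def adhesion_summary(kappa: float, W: float, A: float, Lstar: float = 0.5e-6) -> AdhesionStrength:
    """Bundle Rco, |W|* and the strong-regime flag for reporting."""
    return AdhesionStrength(
        kappa=kappa, W=W, Rco=contact_radius(kappa, W), Lstar=Lstar,
        W_star=strong_adhesion_threshold(kappa, Lstar),
        strong=in_strong_regime(kappa, W, A, Lstar=Lstar),
    )


def kappa_in_kBT(kappa: float, T: float = T_ROOM) -> float:
    """Bending rigidity expressed in units of ``kB*T`` (default room T)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return kappa / (KB * T)
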