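"""Near-wall sphere hydrodynamics and the quasi-static force balance.

The bacterium is a rigid sphere of radius ``a`` whose surface sits a gap
``delta`` above a plane wall (the wall is ``z = 0``; flow is along ``+x``;
the unperturbed fluid velocity is ``v_x = shear_rate * z``).  Inertia is
neglected (overdamped Stokes regime), so the instantaneous rigid-body
velocity solves a linear resistance problem.

Wall proximity is handled with scalar correction factors of the classic
near-wall sphere literature (Goldman-Cox-Brenner type), anchored at their
known contact asymptotes and decaying to the free-space Stokes values far
from the wall:

* shear force on a stationary sphere: ``6 pi mu a (g h) * F*``, with
  ``F* -> 1.7005`` at contact;
* shear torque: ``4 pi mu a^3 g * T*``, with ``T* -> 0.9440`` at contact;
* parallel translation resistance from the method-of-reflections series;
* perpendicular translation resistance ``1 + a/delta`` (lubrication-correct
  leading order);
* rotation resistance from the reflection series.

The resistance matrix is kept diagonal per rigid-body component (no
translation-rotation coupling); with freely pivoting tethers this secondary
coupling has negligible effect on the force balance.

Units in this module: lengths um, forces pN, torques pN*um, stresses Pa,
viscosity Pa*s, time s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FlowCondition",
    "CellGeometry",
    "shear_drag",
    "resistance_matrix",
    "resolve_motion",
    "DEFAULT_RADIUS_UM",
    "DEFAULT_GAP_UM",
]

# Radius calibrated so that the drag on the resting cell at 0.01 Pa wall
# shear stress is 0.2 pN (the model's hydrodynamic anchor) at the default
# resting gap and the viscosity of water.
DEFAULT_RADIUS_UM = 0.7940
DEFAULT_GAP_UM = 0.05

# contact asymptotes of the shear force/torque corrections on a stationary
# sphere touching a wall in linear shear flow
_FSTAR_CONTACT = 1.7005
_TSTAR_CONTACT = 0.9440


@dataclass
class FlowCondition:
    """Linear shear flow characterized by wall shear stress and viscosity."""

    wall_shear_stress: float        # Pa
    viscosity: float = 1.0e-3       # Pa*s (water)

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")
        if self.wall_shear_stress < 0:
            raise ValueError("wall shear stress must be >= 0")

    @property
    def shear_rate(self) -> float:
        """Shear rate (1/s) = stress / viscosity."""
        return self.wall_shear_stress / self.viscosity


@dataclass
class CellGeometry:
    """Sphere pose above the wall.  ``height`` is the center height."""

    radius: float = DEFAULT_RADIUS_UM    # um
    gap: float = DEFAULT_GAP_UM          # um, surface-to-wall separation
    position: np.ndarray = field(
        default_factory=lambda: np.zeros(2))  # (x, y) of the center

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.gap <= 0:
            raise ValueError("gap must be > 0: sphere in contact with wall")

    @property
    def height(self) -> float:
        return self.gap + self.radius


def _s(geom_radius: float, height: float) -> float:
    return geom_radius / height


def shear_force_factor(s: float) -> float:
    """Wall correction on the shear force; 1 far away, 1.7005 at contact."""
    return 1.0 + (_FSTAR_CONTACT - 1.0) * s ** 3


def shear_torque_factor(s: float) -> float:
    """Wall correction on the shear torque; 1 far away, 0.9440 at contact."""
    return 1.0 - (1.0 - _TSTAR_CONTACT) * s ** 3


def translation_parallel_factor(s: float) -> float:
    """Resistance increase for translation parallel to the wall
    (method-of-reflections series in a/h)."""
    denom = 1.0 - 9.0 / 16.0 * s + 1.0 / 8.0 * s ** 3 \
        - 45.0 / 256.0 * s ** 4 - 1.0 / 16.0 * s ** 5
    return 1.0 / denom


def translation_perpendicular_factor(s: float) -> float:
    """Resistance increase for translation normal to the wall.

    ``1 + a/delta`` reproduces the lubrication divergence at contact and the
    Stokes value far away.
    """
    eps = (1.0 - s) / s  # gap / radius
    return 1.0 + 1.0 / eps


def rotation_factor(s: float) -> float:
    """Resistance increase for rotation near the wall (reflection series)."""
    return 1.0 / (1.0 - 5.0 / 16.0 * s ** 3)


def shear_drag(flow: FlowCondition, geom: CellGeometry):
    """Drag force (pN, along +x) and torque (pN*um, about +y) on a
    stationary sphere held in the linear shear flow.

    Both scale linearly with wall shear stress.
    """
    if geom.gap <= 0:
        raise ValueError("gap must be > 0")
    a = geom.radius
    h = geom.height
    s = _s(a, h)
    g = flow.shear_rate
    mu = flow.viscosity
    # 6 pi mu a (g h) F*  -> pN with a, h in um and mu in Pa*s
    force = 6.0 * math.pi * mu * a * g * h * shear_force_factor(s)
    torque = 4.0 * math.pi * mu * a ** 3 * g * shear_torque_factor(s)
    return force, torque


def resistance_matrix(flow: FlowCondition, geom: CellGeometry) -> np.ndarray:
    """Diagonal 6x6 resistance matrix ``diag(translation, rotation)``.

    Translation entries in pN*s/um, rotation entries in pN*um*s.
    """
    a = geom.radius
    s = _s(a, geom.height)
    mu = flow.viscosity
    ct = 6.0 * math.pi * mu * a
    cr = 8.0 * math.pi * mu * a ** 3
    fpar = translation_parallel_factor(s)
    fperp = translation_perpendicular_factor(s)
    frot = rotation_factor(s)
    return np.diag([ct * fpar, ct * fpar, ct * fperp,
                    cr * frot, cr * frot, cr * frot])


def resolve_motion(flow: FlowCondition, geom: CellGeometry,
                   applied_forces=()):
    """Quasi-static rigid-body velocity of the sphere.

    ``applied_forces`` is an iterable of ``(force_pN[3], point_um[3])``
    pairs with the application point given relative to the sphere center.
    Returns ``(translational_velocity um/s [3], angular_velocity 1/s [3])``
    solving ``R v = F_drag + sum(F_i)`` with torques about the center.
    """
    F = np.zeros(3)
    T = np.zeros(3)
    fd, td = shear_drag(flow, geom)
    F[0] += fd
    T[1] += td
    for force, point in applied_forces:
        force = np.asarray(force, dtype=float)
        point = np.asarray(point, dtype=float)
        if not np.all(np.isfinite(force)):
            raise ValueError("applied forces must be finite")
        F += force
        T += np.cross(point, force)
    R = resistance_matrix(flow, geom)
    v = np.linalg.solve(R, np.concatenate([F, T]))
    return v[:3], v[3:]
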