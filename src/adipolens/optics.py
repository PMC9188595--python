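"""Vector ray-optics primitives.

Mirror reflection, Snell refraction of a direction vector, total internal
reflection (TIR) detection and the unpolarized Fresnel reflectance of a
dielectric interface.  All functions are pure and operate on 3-vectors
(`numpy` arrays of shape ``(3,)``) and scalars; angles are in radians.

Conventions
-----------
* ``e1`` is the unit direction of the incident ray, ``n`` the unit normal of
  the interface.  Before the reflection/refraction formulas are applied the
  normal is re-oriented so that ``a = e1 . n < 0`` (normal facing the
  incoming ray); the formulas are orientation-sensitive and this fixes one
  deterministic convention.
* ``mu = n1 / n2`` is the ratio of the refractive index on the incident side
  to the index on the transmit side.  TIR can occur only for ``mu > 1``.
* Refraction past the critical angle returns ``None`` (the TIR signal); the
  caller is expected to reflect instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContractViolation",
    "FresnelResult",
    "reflect",
    "reflection_matrix",
    "refract",
    "refract_components",
    "snell_angle",
    "critical_angle",
    "fresnel_reflectance",
    "interface_reflectance",
    "orient_against",
]

#: tolerance on the norm of vectors that are required to be unit
UNIT_TOL = 1e-6

#: below this incidence angle (rad) the Fresnel formula is evaluated by its
#: analytic normal-incidence limit ((n1 - n2) / (n1 + n2))^2
NORMAL_INCIDENCE_TOL = 1e-6

#: |e1 . n| below this is grazing incidence, a degenerate geometry
GRAZING_TOL = 1e-9


class ContractViolation(ValueError):
    """An input violated a documented precondition (e.g. non-unit vector)."""


@dataclass(frozen=True)
class FresnelResult:
    """Unpolarized reflectance of one interface crossing.

    Attributes
    ----------
    R : float
        Reflectance in [0, 1].
    tir : bool
        True when the crossing is beyond the critical angle; then ``R == 1``.
    """

    R: float
    tir: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.R <= 1.0):
            raise ContractViolation(f"reflectance R={self.R} outside [0, 1]")
        if self.tir and self.R != 1.0:
            raise ContractViolation("TIR requires R = 1")


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ContractViolation(f"{name} must be a 3-vector, got shape {v.shape}")
    nrm = math.sqrt(float(v @ v))
    if abs(nrm - 1.0) > UNIT_TOL:
        raise ContractViolation(f"{name} must be unit-norm, |{name}| = {nrm!r}")
    return v


def orient_against(e1: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Return ``n`` flipped if necessary so that ``e1 . n <= 0``."""
    return -n if float(e1 @ n) > 0.0 else n


def reflect(e1, n) -> np.ndarray:
    """Specular reflection ``e1' = e1 - 2 (e1 . n) n``.

    ``n`` may face either way; the formula is orientation-invariant.
    The result is re-normalized to guard against rounding drift.
    """
    e1 = _as_unit(e1, "e1")
    n = _as_unit(n, "n")
    out = e1 - 2.0 * float(e1 @ n) * n
    return out / math.sqrt(float(out @ out))


def reflection_matrix(n) -> np.ndarray:
    """Householder matrix ``I - 2 n n^T``: the component-wise form of the
    mirror law, equivalent to :func:`reflect` applied to any direction."""
    n = _as_unit(n, "n")
    return np.eye(3) - 2.0 * np.outer(n, n)


def refract(e1, n, mu: float):
    """Refract direction ``e1`` at an interface with normal ``n``.

    ``mu = n1 / n2``.  Returns the unit direction of the transmitted ray,
    coplanar with ``(e1, n)`` and satisfying Snell's law, or ``None`` when
    the incidence is beyond the critical angle (total internal reflection).

    Raises
    ------
    ContractViolation
        For non-unit inputs, ``mu <= 0``, or grazing incidence
        (``|e1 . n| < 1e-9``).
    """
    e1 = _as_unit(e1, "e1")
    n = _as_unit(n, "n")
    if mu <= 0.0:
        raise ContractViolation(f"mu must be positive, got {mu}")
    n = orient_against(e1, n)
    a = float(e1 @ n)
    if abs(a) < GRAZING_TOL:
        raise ContractViolation("grazing incidence: |e1 . n| < 1e-9")
    disc = (1.0 - mu * mu) / (mu * mu * a * a) + 1.0
    if disc < 0.0:
        return None  # total internal reflection
    e2 = mu * e1 + (math.sqrt(disc) - 1.0) * mu * a * n
    return e2 / math.sqrt(float(e2 @ e2))


def refract_components(e1, n, mu: float):
    """Component-wise evaluation of the refraction formula.

    Same contract as :func:`refract`; exists so the scalar component form
    and the vector form can be checked against each other.
    """
    e1 = _as_unit(e1, "e1")
    n = _as_unit(n, "n")
    if mu <= 0.0:
        raise ContractViolation(f"mu must be positive, got {mu}")
    n = orient_against(e1, n)
    a = e1[0] * n[0] + e1[1] * n[1] + e1[2] * n[2]
    if abs(a) < GRAZING_TOL:
        raise ContractViolation("grazing incidence: |e1 . n| < 1e-9")
    disc = (1.0 - mu * mu) / (mu * mu * a * a) + 1.0
    if disc < 0.0:
        return None
    g = (math.sqrt(disc) - 1.0) * mu * a
    e2x = mu * e1[0] + g * n[0]
    e2y = mu * e1[1] + g * n[1]
    e2z = mu * e1[2] + g * n[2]
    nrm = math.sqrt(e2x * e2x + e2y * e2y + e2z * e2z)
    return np.array([e2x / nrm, e2y / nrm, e2z / nrm])


def snell_angle(alpha_i: float, mu: float):
    """Refraction angle ``arcsin(mu sin alpha_i)``, or ``None`` on TIR.

    Scalar companion of :func:`refract`; feeds the Fresnel formula.
    """
    if not 0.0 <= alpha_i < math.pi / 2:
        raise ContractViolation(f"alpha_i must be in [0, pi/2), got {alpha_i}")
    s = mu * math.sin(alpha_i)
    if s > 1.0:
        return None
    return math.asin(s)


def critical_angle(mu: float) -> float:
    """Critical angle ``arcsin(1/mu)`` for ``mu > 1`` (e.g. exiting a cell)."""
    if mu <= 1.0:
        raise ContractViolation("critical angle exists only for mu > 1")
    return math.asin(1.0 / mu)


def fresnel_reflectance(alpha_i: float, alpha_t: float, mu: float | None = None) -> FresnelResult:
    """Unpolarized Fresnel reflectance from incidence and refraction angles.

    ``R = 1/2 [ sin^2(ai - at)/sin^2(ai + at) + tan^2(ai - at)/tan^2(ai + at) ]``

    Evaluated in a cosine form that stays finite when ``ai + at = pi/2``
    (the tangent term vanishes there — Brewster suppression).  At (near-)
    normal incidence the formula is 0/0 and the analytic limit
    ``((n1 - n2)/(n1 + n2))^2 = ((mu - 1)/(mu + 1))^2`` is used, which
    requires ``mu``.
    """
    if not (0.0 <= alpha_i < math.pi / 2 and 0.0 <= alpha_t < math.pi / 2):
        raise ContractViolation("angles must be in [0, pi/2)")
    if alpha_i < NORMAL_INCIDENCE_TOL:
        if mu is None:
            raise ContractViolation("normal-incidence limit requires mu")
        r = (mu - 1.0) / (mu + 1.0)
        return FresnelResult(R=r * r, tir=False)
    d = alpha_i - alpha_t
    s = alpha_i + alpha_t
    sin_d, sin_s = math.sin(d), math.sin(s)
    cos_d, cos_s = math.cos(d), math.cos(s)
    # tan^2 d / tan^2 s = (sin_d cos_s)^2 / (sin_s cos_d)^2; cos_d > 0 always
    # since |d| < pi/2, and cos_s -> 0 kills the term at Brewster-complement.
    base = (sin_d * sin_d) / (sin_s * sin_s)
    r = 0.5 * base * (1.0 + (cos_s * cos_s) / (cos_d * cos_d))
    return FresnelResult(R=min(r, 1.0), tir=False)


def interface_reflectance(alpha_i: float, mu: float) -> FresnelResult:
    """Reflectance of a crossing given the incidence angle and ``mu = n1/n2``.

    Combines :func:`snell_angle` and :func:`fresnel_reflectance`, returning
    ``R = 1`` with the TIR flag past the critical angle.
    """
    alpha_t = snell_angle(alpha_i, mu)
    if alpha_t is None:
        return FresnelResult(R=1.0, tir=True)
    return fresnel_reflectance(alpha_i, alpha_t, mu=mu)
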