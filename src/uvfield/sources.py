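"""Closed-form radiation models for directional, point and diffuse line sources.

Three far-field source models, each returning the *fluence rate* (power
through the point per unit cross-section, W/m^2, direction-independent) and
the *irradiance* (power onto the oriented surface per unit area, W/m^2,
incidence-cosine weighted) at an examined surface point ``p`` with outward
unit normal ``n``:

* **Directional** — a collimated beam of fluence rate ``E0`` travelling along
  the unit vector ``u``.  With ``c = -n.u`` (positive when the surface faces
  the beam): fluence rate ``E0*H(c)``, irradiance ``E0*c*H(c)``.

* **Point (LED)** — maximum radiant intensity ``I_max`` (W/sr) shaped by an
  azimuthally symmetric relative-intensity profile ``f(theta)`` about the
  optical axis.  At distance ``d``: fluence rate ``I_max*f(theta)/d^2 * H(c)``,
  irradiance that times the incidence cosine ``c``.

* **Diffuse line (LPM lamp, LSDE)** — a lamp of power ``P_o`` and radiating
  length ``L`` idealized as a line of diffuse differential emitters: a slice
  ``dl`` radiates intensity ``(P_o/(pi^2 L)) cos(gamma) dl`` where ``gamma``
  is the elevation from the plane perpendicular to the lamp axis.  Only the
  *effective radiating segment* — the part of the lamp above the point's
  tangent plane — contributes.  The integrals over that segment have the
  closed forms implemented here; in the symmetric centered-detector
  configuration the irradiance reduces to the Keitz formula
  ``E = P_o (2a + sin 2a) / (2 pi^2 L D)`` with ``a = arctan(L/(2D))``,
  which :func:`keitz_power` inverts for lamp output measurement.

The Heaviside convention is ``H(0) = 1``, and ``H`` multiplies fluence rate
as well as irradiance (a surface element facing away from a source is in
shadow for both quantities).  The models are far-field: points closer than
``D_MIN`` to a point source's center or a line source's axis are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AxisProximityError, NearFieldError, ValidationError
from .geometry import Pose, require_unit, rotation_aligning_z, unit

#: Minimum source-point distance (m) for the far-field models.
D_MIN = 1e-6


def heaviside(x):
    """H(x) with H(0) = 1."""
    return np.where(np.asarray(x) >= 0.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# Directional source
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionalSource:
    """Collimated beam: fluence rate ``fluence_rate_0`` (W/m^2) along ``direction``."""

    fluence_rate_0: float
    direction: np.ndarray  # unit propagation direction of the rays

    def __post_init__(self):
        if self.fluence_rate_0 < 0:
            raise ValidationError("directional source fluence rate must be >= 0")
        object.__setattr__(self, "direction", require_unit(self.direction, "direction"))


def directional_field(src: DirectionalSource, points, normals):
    """Vectorized (N,3)/(N,3) -> fluence rate, irradiance arrays (N,)."""
    normals = np.atleast_2d(np.asarray(normals, float))
    c = -normals @ src.direction
    h = heaviside(c)
    fr = src.fluence_rate_0 * h
    return fr, fr * np.maximum(c, 0.0)


def radiate_directional(src: DirectionalSource, point, normal):
    """Fluence rate and irradiance (W/m^2) at one oriented point."""
    require_unit(normal)
    fr, irr = directional_field(src, np.atleast_2d(point), normal)
    return float(fr[0]), float(irr[0])


# ---------------------------------------------------------------------------
# Relative intensity profiles and point (LED) sources
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelativeIntensityProfile:
    """Datasheet relative-intensity lookup f(theta), theta in degrees from axis.

    ``mode='linear'`` interpolates piecewise-linearly between knots,
    ``mode='closest'`` snaps to the nearest knot.  Angles beyond the last knot
    return 0 (no extrapolation); azimuthal symmetry is assumed.
    """

    angles_deg: np.ndarray
    values: np.ndarray
    mode: str = "linear"

    def __post_init__(self):
        a = np.asarray(self.angles_deg, float).reshape(-1)
        v = np.asarray(self.values, float).reshape(-1)
        if a.size == 0 or a.size != v.size:
            raise ValidationError("profile needs matching non-empty angle/value arrays")
        if a[0] != 0.0 or np.any(np.diff(a) <= 0):
            raise ValidationError("profile angles must start at 0 and be strictly ascending")
        if np.any(v < 0) or np.any(v > 1):
            raise ValidationError("profile values must lie in [0, 1]")
        if abs(v.max() - 1.0) > 1e-12:
            raise ValidationError("profile peak value must be 1")
        if self.mode not in ("linear", "closest"):
            raise ValidationError(f"unknown profile mode {self.mode!r}")
        object.__setattr__(self, "angles_deg", a)
        object.__setattr__(self, "values", v)

    def __call__(self, theta_deg):
        theta = np.asarray(theta_deg, float)
        if np.any(theta < 0):
            raise ValidationError("relative-intensity angle must be >= 0")
        if self.mode == "linear":
            out = np.interp(theta, self.angles_deg, self.values)
        else:
            idx = np.clip(np.searchsorted(self.angles_deg, theta), 1, self.angles_deg.size - 1)
            left = self.angles_deg[idx - 1]
            right = self.angles_deg[idx]
            nearest = np.where(theta - left <= right - theta, idx - 1, idx)
            out = self.values[nearest]
        return np.where(theta > self.angles_deg[-1], 0.0, out)

    @classmethod
    def cosine(cls, n_knots: int = 91, mode: str = "linear") -> "RelativeIntensityProfile":
        """Ideal Lambertian (cosine) emitter sampled on [0, 90] degrees."""
        ang = np.linspace(0.0, 90.0, n_knots)
        return cls(ang, np.cos(np.radians(ang)), mode)

    @classmethod
    def from_csv(cls, path, mode: str = "linear") -> "RelativeIntensityProfile":
        """Two-column CSV: angle_deg, relative_value."""
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), mode)


def relative_intensity(profile: RelativeIntensityProfile, theta_deg):
    """Evaluate a relative-intensity profile at ``theta_deg``."""
    return profile(theta_deg)


def hemisphere_profile_integral(profile: RelativeIntensityProfile,
                                n_nodes: int = 20001) -> float:
    """solid-angle integral of f: 2*pi * int f(theta) sin(theta) dtheta (sr).

    Trapezoid on a dense uniform grid up to the profile's last knot (or 180
    degrees, whichever is smaller); exact pi for the ideal cosine emitter to
    quadrature accuracy.
    """
    upper = min(float(profile.angles_deg[-1]), 180.0)
    theta = np.radians(np.linspace(0.0, upper, n_nodes))
    f = profile(np.degrees(theta))
    return float(2.0 * np.pi * np.trapezoid(f * np.sin(theta), theta))


def i_max_from_power(power_w: float, profile: RelativeIntensityProfile,
                     n_nodes: int = 20001) -> float:
    """Maximum intensity I_max (W/sr) given total radiated power and profile.

    Inverts ``P = I_max * int f(theta) dOmega``; for an ideal cosine emitter
    this is ``P/pi``.
    """
    if power_w <= 0:
        raise ValidationError("power must be > 0")
    return power_w / hemisphere_profile_integral(profile, n_nodes)


@dataclass(frozen=True)
class PointSource:
    """LED-style emitter: ``i_max`` (W/sr) shaped by ``profile`` about the
    optical axis (the pose's local +Z mapped to the base frame)."""

    i_max: float
    profile: RelativeIntensityProfile
    pose: Pose
    spectrum: Optional[object] = None   # inactivation.EmissionSpectrum
    rated_power_w: Optional[float] = None

    def __post_init__(self):
        if self.i_max <= 0:
            raise ValidationError("point source i_max must be > 0")

    @property
    def center(self) -> np.ndarray:
        return self.pose.translation

    @property
    def axis(self) -> np.ndarray:
        return self.pose.rotation[:, 2]

    @classmethod
    def from_center_axis(cls, i_max, profile, center, axis, **kw) -> "PointSource":
        pose = Pose.from_rotation_translation(rotation_aligning_z(unit(axis, "axis")), center)
        return cls(i_max=i_max, profile=profile, pose=pose, **kw)


def point_field(src: PointSource, points, normals):
    """Vectorized fluence rate / irradiance of a point source at (N,3) points."""
    points = np.atleast_2d(np.asarray(points, float))
    normals = np.atleast_2d(np.asarray(normals, float))
    rel = points - src.center
    d = np.linalg.norm(rel, axis=1)
    if np.any(d < D_MIN):
        raise NearFieldError(
            f"point within {D_MIN} m of a point source center; the point model "
            "is invalid at the emitter")
    s = rel / d[:, None]                       # unit source -> point
    cos_theta = np.clip(s @ src.axis, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_theta))
    c = -np.einsum("ij,ij->i", normals, s)     # incidence cosine
    fr = src.i_max * src.profile(theta) / d**2 * heaviside(c)
    return fr, fr * np.maximum(c, 0.0)


def radiate_point(src: PointSource, point, normal):
    """Fluence rate and irradiance (W/m^2) at one oriented point."""
    require_unit(normal)
    fr, irr = point_field(src, point, normal)
    return float(fr[0]), float(irr[0])


# ---------------------------------------------------------------------------
# Diffuse line source (LSDE)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineSource:
    """Cylindrical lamp as a diffuse line: power ``power`` (W), radiating
    length ``length`` (m), axis = pose's local +Z in the base frame."""

    power: float
    length: float
    pose: Pose

    def __post_init__(self):
        if self.power <= 0:
            raise ValidationError("line source power must be > 0")
        if self.length <= 0:
            raise ValidationError("line source length must be > 0")

    @property
    def center(self) -> np.ndarray:
        return self.pose.translation

    @property
    def axis(self) -> np.ndarray:
        return self.pose.rotation[:, 2]

    @classmethod
    def from_center_axis(cls, power, length, center, axis) -> "LineSource":
        pose = Pose.from_rotation_translation(rotation_aligning_z(unit(axis, "axis")), center)
        return cls(power=power, length=length, pose=pose)


@dataclass(frozen=True)
class EffectiveSegment:
    """The lamp segment above the examined point's tangent plane, plus the
    per-point constants of the closed form.

    ``l_minus``/``l_plus`` are axial coordinates along the lamp axis measured
    from the lamp center; an empty segment has ``l_plus == l_minus``.  ``d``
    is the perpendicular point-to-axis distance, ``c1 = n.v`` (axial slope of
    the incidence-cosine numerator) and ``c2 = -n.q`` (its offset, with ``q``
    the axis-to-point perpendicular vector).
    """

    l_minus: float
    l_plus: float
    d: float
    c1: float
    c2: float

    @property
    def empty(self) -> bool:
        return self.l_plus <= self.l_minus


def _line_geometry(src: LineSource, points, normals):
    points = np.atleast_2d(np.asarray(points, float))
    normals = np.atleast_2d(np.asarray(normals, float))
    rel = points - src.center
    l_foot = rel @ src.axis                       # axial coordinate of the foot point
    q = rel - l_foot[:, None] * src.axis          # perpendicular axis -> point
    d = np.linalg.norm(q, axis=1)
    if np.any(d < D_MIN):
        raise AxisProximityError(
            f"point within {D_MIN} m of a line source axis; the line model is "
            "singular on the axis")
    c1 = normals @ src.axis                       # a: slope of n.(x(l)-p) in l
    c2 = -np.einsum("ij,ij->i", normals, q)       # b: its value at the foot point
    return l_foot, d, c1, c2


def _segments(src: LineSource, l_foot, c1, c2):
    """Clip [-L/2, L/2] to the half-space n.(x(l) - p) >= 0.

    n.(x(l) - p) = c1*(l - l_foot) + c2 is linear in the axial coordinate l,
    so the clip is a single interval.
    """
    half = 0.5 * src.length
    lo = np.full_like(l_foot, -half)
    hi = np.full_like(l_foot, half)
    with np.errstate(divide="ignore", invalid="ignore"):
        crossing = l_foot - c2 / c1               # root of the linear plane test
    pos_slope = c1 > 0
    neg_slope = c1 < 0
    lo = np.where(pos_slope, np.maximum(lo, np.minimum(crossing, half)), lo)
    hi = np.where(neg_slope, np.minimum(hi, np.maximum(crossing, -half)), hi)
    # c1 == 0: plane parallel to the lamp; fully above (keep) or fully below (empty)
    flat_below = (c1 == 0) & (c2 < 0)
    hi = np.where(flat_below, lo, hi)
    return lo, hi


def effective_segment(src: LineSource, point, normal) -> EffectiveSegment:
    """Effective radiating segment and closed-form constants for one point."""
    require_unit(normal)
    l_foot, d, c1, c2 = _line_geometry(src, point, normal)
    lo, hi = _segments(src, l_foot, c1, c2)
    return EffectiveSegment(l_minus=float(lo[0]), l_plus=float(hi[0]),
                            d=float(d[0]), c1=float(c1[0]), c2=float(c2[0]))


def line_field(src: LineSource, points, normals):
    """Vectorized closed-form fluence rate / irradiance of a diffuse line source.

    With the axial coordinate ``t`` measured from the foot of the point's
    perpendicular, ``rho^2 = t^2 + D^2``, the effective segment [u, v] in t:

    fluence rate  = P/(pi^2 L D) * [ t/rho ]_u^v
    irradiance    = P D/(pi^2 L) * [ -c1/(2 rho^2)
                     + c2/(2 D^3) * (arctan(t/D) + t D/rho^2) ]_u^v
    """
    l_foot, d, c1, c2 = _line_geometry(src, points, normals)
    lo, hi = _segments(src, l_foot, c1, c2)
    u = lo - l_foot
    v = hi - l_foot
    scale = src.power / (np.pi**2 * src.length)

    def f_fluence(t):
        return t / np.sqrt(t * t + d * d)

    def f_irr(t):
        rho2 = t * t + d * d
        return -c1 / (2.0 * rho2) + c2 / (2.0 * d**3) * (np.arctan(t / d) + t * d / rho2)

    nonempty = v > u
    fr = np.where(nonempty, scale / d * (f_fluence(v) - f_fluence(u)), 0.0)
    irr = np.where(nonempty, scale * d * (f_irr(v) - f_irr(u)), 0.0)
    # guard tiny negative round-off on grazing segments
    return np.maximum(fr, 0.0), np.maximum(irr, 0.0)


def radiate_line(src: LineSource, point, normal):
    """Fluence rate and irradiance (W/m^2) at one oriented point."""
    require_unit(normal)
    fr, irr = line_field(src, point, normal)
    return float(fr[0]), float(irr[0])


# ---------------------------------------------------------------------------
# Keitz relation
# ---------------------------------------------------------------------------

def keitz_irradiance(power_w: float, distance_d: float, length_l: float) -> float:
    """Irradiance at a centered, perpendicular, lamp-facing detector:
    ``E = P (2a + sin 2a) / (2 pi^2 L D)``, ``a = arctan(L/(2D))``."""
    if power_w <= 0 or distance_d <= 0 or length_l <= 0:
        raise ValidationError("Keitz relation needs positive power, distance and length")
    alpha = np.arctan(length_l / (2.0 * distance_d))
    return power_w * (2.0 * alpha + np.sin(2.0 * alpha)) / (
        2.0 * np.pi**2 * length_l * distance_d)


def keitz_power(irradiance: float, distance_d: float, length_l: float) -> float:
    """Lamp optical power from a centered perpendicular irradiance reading
    (inverse of :func:`keitz_irradiance`)."""
    if irradiance <= 0 or distance_d <= 0 or length_l <= 0:
        raise ValidationError("Keitz inversion needs positive irradiance, distance and length")
    alpha = np.arctan(length_l / (2.0 * distance_d))
    return irradiance * 2.0 * np.pi**2 * length_l * distance_d / (
        2.0 * alpha + np.sin(2.0 * alpha))


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

LightSource = (DirectionalSource, PointSource, LineSource)


def field_at(source, points, normals):
    """Fluence rate and irradiance of any source type at (N,3) points."""
    if isinstance(source, DirectionalSource):
        return directional_field(source, points, normals)
    if isinstance(source, PointSource):
        return point_field(source, points, normals)
    if isinstance(source, LineSource):
        return line_field(source, points, normals)
    raise ValidationError(f"unknown light source type {type(source).__name__}")
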