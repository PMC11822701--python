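"""Light-environment configuration: schema validation, presets, expansion.

A light environment is a YAML/JSON-friendly dict with a ``sources`` list.
Each entry describes a directional, point or line source, either singly or as
a regular array (``grid``), and is expanded by :func:`build_environment` into
concrete source objects.  Shipped presets reproduce two reference setups on a
plane 0.1 m above the base XY plane: a row of 20 compact twin-tube
low-pressure mercury lamps (2.5 W each) spanning 1.5 m along X, and a
50 x 5 grid of 110 mW UVC LEDs over 1.5 m x 0.2 m.

All lengths are meters and powers watts; axes are unit-normalized on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .errors import ConfigError
from .geometry import Pose
from .power import TWIN_TUBE_ARC, TWIN_TUBE_GAP
from .sources import (DirectionalSource, LineSource, PointSource,
                      RelativeIntensityProfile, i_max_from_power)

_SOURCE_TYPES = ("directional", "point", "line")


@dataclass
class EnvironmentReport:
    """Bookkeeping from environment expansion."""

    n_sources: int
    total_rated_power_w: float
    power_toward_base_w: float
    notes: List[str] = field(default_factory=list)


def _as_vec(value, path, problems, length=3):
    try:
        v = np.asarray(value, float).reshape(length)
        return v
    except Exception:
        problems.append((path, f"expected {length} numbers"))
        return None


def _axis(entry, path, problems, default=None):
    if "axis" not in entry:
        if default is not None:
            return np.asarray(default, float)
        problems.append((path + ".axis", "required"))
        return None
    v = _as_vec(entry["axis"], path + ".axis", problems)
    if v is None:
        return None
    n = np.linalg.norm(v)
    if n == 0:
        problems.append((path + ".axis", "axis must be nonzero"))
        return None
    return v / n


def _centers(entry, path, problems):
    """One center, or a grid of centers from a grid spec."""
    if "grid" in entry:
        g = entry["grid"]
        if not isinstance(g, dict):
            problems.append((path + ".grid", "must be a mapping"))
            return []
        shape = g.get("shape")
        span = g.get("span")
        center = _as_vec(g.get("center", [0.0, 0.0, 0.0]), path + ".grid.center", problems)
        if (not isinstance(shape, (list, tuple)) or len(shape) != 2
                or any(int(s) < 1 for s in shape)):
            problems.append((path + ".grid.shape", "expected [nx, ny] positive ints"))
            return []
        if not isinstance(span, (list, tuple)) or len(span) != 2:
            problems.append((path + ".grid.span", "expected [span_x, span_y] in m"))
            return []
        if center is None:
            return []
        nx, ny = int(shape[0]), int(shape[1])
        sx, sy = float(span[0]), float(span[1])
        xs = np.linspace(-sx / 2.0, sx / 2.0, nx) if nx > 1 else np.array([0.0])
        ys = np.linspace(-sy / 2.0, sy / 2.0, ny) if ny > 1 else np.array([0.0])
        return [center + np.array([x, y, 0.0]) for x in xs for y in ys]
    if "pose" in entry:
        try:
            return [Pose.from_flat(entry["pose"]).translation]
        except Exception as exc:
            problems.append((path + ".pose", f"invalid pose: {exc}"))
            return []
    center = _as_vec(entry.get("center", [0.0, 0.0, 0.0]), path + ".center", problems)
    return [] if center is None else [center]


def _profile(entry, path, problems):
    prof = entry.get("profile", "cosine")
    if prof == "cosine":
        return RelativeIntensityProfile.cosine()
    if isinstance(prof, dict) and "angles_deg" in prof and "values" in prof:
        try:
            return RelativeIntensityProfile(prof["angles_deg"], prof["values"],
                                            prof.get("mode", "linear"))
        except Exception as exc:
            problems.append((path + ".profile", str(exc)))
            return None
    if isinstance(prof, str):
        try:
            return RelativeIntensityProfile.from_csv(prof, entry.get("profile_mode", "linear"))
        except Exception as exc:
            problems.append((path + ".profile", f"cannot read profile CSV: {exc}"))
            return None
    problems.append((path + ".profile", "expected 'cosine', a CSV path, or "
                     "{angles_deg, values}"))
    return None


def build_environment(config: dict) -> Tuple[list, EnvironmentReport]:
    """Expand a configuration dict into concrete light sources.

    Returns ``(sources, report)``; the report carries the total rated power
    and the power directed toward the base half-space (full rated power for
    downward-facing point sources, half for horizontal diffuse line sources).
    Schema violations are collected exhaustively and raised as one
    :class:`~uvfield.errors.ConfigError`.
    """
    problems: list = []
    entries = config.get("sources")
    if not isinstance(entries, list):
        raise ConfigError([("sources", "required list of source entries")])

    sources: list = []
    rated = 0.0
    toward_base = 0.0
    notes: List[str] = []

    for i, entry in enumerate(entries):
        path = f"sources[{i}]"
        if not isinstance(entry, dict):
            problems.append((path, "must be a mapping"))
            continue
        stype = entry.get("type")
        if stype not in _SOURCE_TYPES:
            problems.append((path + ".type", f"must be one of {_SOURCE_TYPES}"))
            continue

        if stype == "directional":
            direction = _axis(entry, path, problems)
            e0 = entry.get("fluence_rate_w_m2")
            if e0 is None or float(e0) < 0:
                problems.append((path + ".fluence_rate_w_m2", "required, >= 0"))
                continue
            if direction is None:
                continue
            sources.append(DirectionalSource(float(e0), direction))
            continue

        centers = _centers(entry, path, problems)
        axis = _axis(entry, path, problems, default=None)
        if axis is None or not centers:
            continue

        if stype == "point":
            profile = _profile(entry, path, problems)
            if profile is None:
                continue
            power = entry.get("power_w")
            i_max = entry.get("i_max_w_sr")
            if i_max is None and power is None:
                problems.append((path, "point source needs power_w or i_max_w_sr"))
                continue
            if i_max is None:
                i_max = i_max_from_power(float(power), profile)
            for c in centers:
                src = PointSource.from_center_axis(
                    float(i_max), profile, c, axis,
                    rated_power_w=None if power is None else float(power))
                sources.append(src)
                p = float(power) if power is not None else float(
                    i_max) * np.pi  # cosine-equivalent fallback
                rated += p
                if axis[2] < -0.999999:       # facing the base plane
                    toward_base += p
        else:  # line
            power = entry.get("power_w")
            length = entry.get("length_m")
            if power is None or float(power) <= 0:
                problems.append((path + ".power_w", "required, > 0"))
                continue
            if length is None or float(length) <= 0:
                problems.append((path + ".length_m", "required, > 0"))
                continue
            gap = entry.get("twin_tube_gap_m")
            offsets = [np.zeros(3)]
            split = 1.0
            if gap is not None:
                off_axis = _as_vec(entry.get("tube_offset_axis", [1.0, 0.0, 0.0]),
                                   path + ".tube_offset_axis", problems)
                if off_axis is None:
                    continue
                offsets = [+0.5 * float(gap) * off_axis, -0.5 * float(gap) * off_axis]
                split = 0.5
            for c in centers:
                for off in offsets:
                    sources.append(LineSource.from_center_axis(
                        float(power) * split, float(length), c + off, axis))
            n_units = len(centers)
            rated += float(power) * n_units
            if abs(axis[2]) < 1e-9:           # horizontal tube: half goes down
                toward_base += 0.5 * float(power) * n_units
            else:
                notes.append(f"{path}: non-horizontal line source; its share of "
                             "power toward the base plane is not accounted")

    if problems:
        raise ConfigError(problems)
    report = EnvironmentReport(n_sources=len(sources), total_rated_power_w=rated,
                               power_toward_base_w=toward_base, notes=notes)
    return sources, report


def lpm_preset(n_lamps: int = 20, lamp_power_w: float = 2.5, span_m: float = 1.5,
               height_m: float = 0.1) -> dict:
    """Row of compact twin-tube LPM lamps along X, axes along Y.

    Each lamp expands into two parallel tubes 14 mm apart with a 129 mm
    radiating arc; half of each lamp's rated power reaches the base
    half-space (horizontal diffuse emitters), 25 W total for the defaults.
    """
    return {"sources": [{
        "type": "line",
        "grid": {"shape": [n_lamps, 1], "span": [span_m, 0.0],
                 "center": [0.0, 0.0, height_m]},
        "axis": [0.0, 1.0, 0.0],
        "power_w": lamp_power_w,
        "length_m": TWIN_TUBE_ARC,
        "twin_tube_gap_m": TWIN_TUBE_GAP,
        "tube_offset_axis": [1.0, 0.0, 0.0],
    }]}


def led_preset(nx: int = 50, ny: int = 5, led_power_w: float = 0.110,
               span_x_m: float = 1.5, span_y_m: float = 0.2,
               height_m: float = 0.1) -> dict:
    """Grid of downward-facing UVC LEDs (cosine profile by default).

    All of each LED's rated power enters the downward hemisphere, 27.5 W
    total for the defaults.
    """
    return {"sources": [{
        "type": "point",
        "grid": {"shape": [nx, ny], "span": [span_x_m, span_y_m],
                 "center": [0.0, 0.0, height_m]},
        "axis": [0.0, 0.0, -1.0],
        "power_w": led_power_w,
        "profile": "cosine",
    }]}
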