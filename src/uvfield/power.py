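"""Lamp optical-power estimation from multi-distance irradiance measurements.

A (possibly composite, e.g. twin-tube) lamp is modeled as parallel diffuse
line sources with fixed power fractions.  The modeled irradiance is linear in
the total power, so each reading at a known detector position yields a
per-measurement power estimate ``reading / modeled_unit_irradiance``; the
lamp's output is reported as the arithmetic mean over all distances, together
with each measurement's relative deviation from the mean-power model curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import require_unit
from .sources import LineSource, line_field

#: Twin-tube lamp geometry: tube centers sit half this gap either side (m).
TWIN_TUBE_GAP = 0.014
#: Radiating arc length of the compact twin-tube lamp (m).
TWIN_TUBE_ARC = 0.129


@dataclass(frozen=True)
class IrradianceMeasurement:
    """One detector reading: distance (m, detector face to lamp midplane)
    and irradiance (W/m^2)."""

    distance: float
    irradiance: float

    def __post_init__(self):
        if self.distance <= 0:
            raise ValidationError("measurement distance must be > 0")
        if self.irradiance < 0:
            raise ValidationError("measured irradiance must be >= 0")


@dataclass
class CompositeLamp:
    """Parallel line-source tubes with power fractions summing to 1."""

    tubes: List[LineSource]
    fractions: List[float] = None

    def __post_init__(self):
        if not self.tubes:
            raise ValidationError("a composite lamp needs at least one tube")
        if self.fractions is None:
            self.fractions = [1.0 / len(self.tubes)] * len(self.tubes)
        if len(self.fractions) != len(self.tubes):
            raise ValidationError("one power fraction per tube is required")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("power fractions must sum to 1")
        axes = np.stack([t.axis for t in self.tubes])
        if np.max(np.abs(np.abs(axes @ axes[0]) - 1.0)) > 1e-9:
            raise ValidationError("composite lamp tubes must be parallel")

    def with_total_power(self, total_power: float) -> "CompositeLamp":
        tubes = [LineSource(power=total_power * frac, length=t.length, pose=t.pose)
                 for t, frac in zip(self.tubes, self.fractions)]
        return CompositeLamp(tubes=tubes, fractions=list(self.fractions))

    def irradiance_at(self, point, normal) -> float:
        """Summed tube irradiance at one oriented point (W/m^2)."""
        total = 0.0
        for tube in self.tubes:
            _, irr = line_field(tube, point, normal)
            total += float(irr[0])
        return total


def twin_tube_lamp(total_power: float = 1.0, gap: float = TWIN_TUBE_GAP,
                   length: float = TWIN_TUBE_ARC, axis=(0.0, 1.0, 0.0),
                   center=(0.0, 0.0, 0.0), offset_axis=(0.0, 0.0, 1.0)) -> CompositeLamp:
    """Compact twin-tube lamp: two identical parallel tubes, equal power split,
    centers ``gap/2`` either side of ``center`` along ``offset_axis``."""
    center = np.asarray(center, float)
    off = 0.5 * gap * np.asarray(offset_axis, float)
    tubes = [LineSource.from_center_axis(total_power / 2.0, length, center + s * off, axis)
             for s in (+1.0, -1.0)]
    return CompositeLamp(tubes=tubes)


@dataclass
class PowerEstimate:
    power_w: float                       # mean over measurements
    per_measurement_w: np.ndarray        # (M,)
    model_deviation: np.ndarray          # (M,) relative deviation of each
                                         # reading from the mean-power curve


def estimate_source_power(measurements: Sequence[IrradianceMeasurement],
                          lamp: CompositeLamp,
                          detector_normal=(-1.0, 0.0, 0.0),
                          detector_direction=(1.0, 0.0, 0.0)) -> PowerEstimate:
    """Lamp power from readings at multiple distances along a fixed axis.

    The detector sits at ``distance * detector_direction`` from the lamp
    midplane with the fixed ``detector_normal`` (defaults match a detector
    facing the lamp center along +X).  Each reading is divided by the
    unit-total-power modeled irradiance at its position; the estimate is the
    arithmetic mean.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValidationError("need at least one measurement")
    normal = require_unit(detector_normal, "detector normal")
    direction = np.asarray(detector_direction, float)
    unit_lamp = lamp.with_total_power(1.0)
    unit_irr = np.empty(len(measurements))
    for i, m in enumerate(measurements):
        unit_irr[i] = unit_lamp.irradiance_at(m.distance * direction, normal)
    if np.any(unit_irr <= 0):
        bad = [m.distance for m, u in zip(measurements, unit_irr) if u <= 0]
        raise ValidationError(
            f"detector receives no modeled irradiance at distance(s) {bad}; "
            "it is behind the lamp plane or misoriented")
    readings = np.array([m.irradiance for m in measurements])
    per = readings / unit_irr
    mean_power = float(np.mean(per))
    deviation = (readings - mean_power * unit_irr) / (mean_power * unit_irr)
    return PowerEstimate(power_w=mean_power, per_measurement_w=per,
                         model_deviation=deviation)


def read_measurements_csv(path) -> List[IrradianceMeasurement]:
    """CSV with columns distance_m, irradiance_W_m2."""
    df = pd.read_csv(path)
    return [IrradianceMeasurement(float(d), float(e))
            for d, e in zip(df.iloc[:, 0], df.iloc[:, 1])]
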