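"""Deterministic TMS dosing and targeting calculators.

Stimulation intensity starts from the motor threshold (MT, in % maximum
stimulator output), is corrected for the scalp–cortex distance difference
between the frontal target and the motor hotspot (intensity falls off at
2.7 %MSO per mm of extra depth), multiplied to 110% of the adjusted MT,
and bounded to 70–130% of MT and to the stimulator ceiling.  A separate
comfort-threshold pass scales both sites' intensities by the largest
relative reduction either site required; a reduction below 80% of the
prescription excludes the participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DoseSpec",
    "SitePlan",
    "distance_adjusted_intensity",
    "comfort_propagation",
    "aggregate_target",
]


@dataclass
class DoseSpec:
    """Inputs to the distance-adjusted dose calculation.

    mt: motor threshold, %MSO.  d_target / d_motor: scalp–cortex distances
    (mm) at the stimulation target and at the motor hotspot where MT was
    measured.  rate: intensity fall-off per mm (%MSO/mm).  multiplier:
    fraction of the adjusted MT actually applied.  bounds: permissible
    intensity range as fractions of MT.
    """

    mt: float
    d_target: float
    d_motor: float
    rate: float = 2.7
    multiplier: float = 1.10
    bounds: tuple[float, float] = (0.70, 1.30)

    def __post_init__(self) -> None:
        if not 0 < self.mt <= 100:
            raise ValueError("mt must lie in (0, 100] %MSO")
        if self.d_target < 0 or self.d_motor < 0:
            raise ValueError("distances must be >= 0")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be ordered")


@dataclass
class SitePlan:
    """Candidate target coordinates (mm triplets) with hemisphere labels."""

    coordinates: np.ndarray
    hemispheres: list[str]

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.shape[0] == 0:
            raise ValueError("empty site plan")
        if self.coordinates.shape[0] != len(self.hemispheres):
            raise ValueError("one hemisphere label per coordinate required")
        bad = set(self.hemispheres) - {"left", "right"}
        if bad:
            raise ValueError(f"unknown hemisphere labels: {bad}")


def distance_adjusted_intensity(spec: DoseSpec) -> float:
    """Applied intensity in %MSO after distance adjustment, multiplier,
    MT-relative bounds and the stimulator ceiling.

    adjMT = MT + rate·(d_target − d_motor);  intensity = multiplier·adjMT,
    clamped to [0.70·MT, 1.30·MT] and to ≤ 100 %MSO.  Clamping is part of
    the contract, not an error.
    """
    adj_mt = spec.mt + spec.rate * (spec.d_target - spec.d_motor)
    intensity = spec.multiplier * adj_mt
    lo = spec.bounds[0] * spec.mt
    hi = spec.bounds[1] * spec.mt
    return float(min(max(intensity, lo), hi, 100.0))


def comfort_propagation(prescribed, comfort) -> tuple[list[int], bool]:
    """Propagate the largest comfort-driven reduction to every site.

    Each site's comfort/prescribed ratio is computed; the smallest ratio
    is applied to all sites (rounded to integer %MSO, as stimulators
    accept).  The exclusion flag is set when any applied intensity falls
    below 80% of its prescription.
    """
    prescribed = np.asarray(prescribed, dtype=float)
    comfort = np.asarray(comfort, dtype=float)
    if prescribed.shape != comfort.shape or prescribed.size == 0:
        raise ValueError("prescribed and comfort must be matching nonempty lists")
    if (comfort > prescribed).any():
        raise ValueError("comfort threshold cannot exceed the prescription")
    if (prescribed <= 0).any():
        raise ValueError("prescribed intensities must be > 0")
    ratio = float((comfort / prescribed).min())
    applied = [int(round(p * ratio)) for p in prescribed]
    excluded = bool(any(a < 0.80 * p for a, p in zip(applied, prescribed)))
    return applied, excluded


def aggregate_target(plan: SitePlan) -> np.ndarray:
    """Aggregate per-measure virtual-sensor locations into one TMS target.

    The mean is taken within the hemisphere holding the majority of the
    sensors; an even split defaults to the right hemisphere (the stronger
    prior for a role in stopping).  A single-hemisphere plan reduces to
    the plain Euclidean mean.
    """
    hemis = np.asarray(plan.hemispheres)
    n_right = int((hemis == "right").sum())
    n_left = int((hemis == "left").sum())
    if n_right >= n_left:
        use = hemis == "right" if n_right > 0 else slice(None)
    else:
        use = hemis == "left"
    return plan.coordinates[use].mean(axis=0)
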