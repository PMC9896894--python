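"""Monotone depth-to-age mapping built from dated anchor points.

Ages enter the pipeline as given: radionuclide (unsupported Pb-210, Cs-137)
age models are produced upstream and summarized as (depth, age) anchors.
Within the anchor range ages are piecewise-linearly interpolated (constant
sedimentation rate per segment); beyond either end the nearest segment's
rate is extrapolated, optionally capped to guard against absurd ages far
below the deepest dated layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AgeAnchor:
    """A dated horizon: depth in cm below the sediment-water interface
    (layer midpoint convention), age in years before sampling."""

    depth: float
    age: float


class AgeModel:
    """Piecewise-linear depth→age interpolator over strictly monotone anchors."""

    def __init__(self, anchors: list[AgeAnchor] | list[tuple[float, float]],
                 max_extrapolated_age: float | None = None):
        pairs = sorted(
            (a if isinstance(a, AgeAnchor) else AgeAnchor(*a) for a in anchors),
            key=lambda a: a.depth,
        )
        if len(pairs) < 2:
            raise ValueError("an age model needs at least 2 anchors")
        for lo, hi in zip(pairs, pairs[1:]):
            if not (hi.depth > lo.depth and hi.age > lo.age):
                raise ValueError(
                    "anchors must be strictly increasing in depth and age; "
                    f"offending pair: ({lo.depth}, {lo.age}) -> ({hi.depth}, {hi.age})"
                )
        self.anchors = pairs
        self._depths = np.array([a.depth for a in pairs])
        self._ages = np.array([a.age for a in pairs])
        self.max_extrapolated_age = max_extrapolated_age

    @property
    def sedimentation_rates(self) -> np.ndarray:
        """Per-segment sedimentation rates in cm/year."""
        return np.diff(self._depths) / np.diff(self._ages)

    def age_at_depth(self, depth):
        """Age (years) at one depth or an array of depths (cm).

        Interpolates between anchors; extrapolates with the nearest
        segment's rate outside the anchor range.  Negative depths are an
        error; ages are clipped to ``max_extrapolated_age`` when set.
        """
        d = np.asarray(depth, dtype=float)
        if np.any(d < 0):
            raise ValueError("depth must be >= 0")
        slopes = np.diff(self._ages) / np.diff(self._depths)  # yr/cm
        age = np.interp(d, self._depths, self._ages)
        below = d > self._depths[-1]
        age = np.where(below, self._ages[-1] + (d - self._depths[-1]) * slopes[-1], age)
        above = d < self._depths[0]
        age = np.where(above, self._ages[0] + (d - self._depths[0]) * slopes[0], age)
        if self.max_extrapolated_age is not None:
            age = np.minimum(age, self.max_extrapolated_age)
        return float(age) if np.isscalar(depth) else age

    def __call__(self, depth):
        return self.age_at_depth(depth)
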