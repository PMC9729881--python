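"""Hexagon-paradigm lobule geometry from vascular point patterns.

For every central vein the distances to its k nearest portal tracts are
computed; the mean distance as a function of k shows a jump ("step") where
a lobule's own portal tracts end and the next shell begins.  In mammalian
liver the step sits at k = 3:4 — three portal tracts per lobule cross
section.  The mean of those three distances is the modelled lobule
circumradius r, and the lobule-as-hexagon paradigm gives the
cross-sectional area A = (3√3/2)·r².
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .patterns import CENTRAL, PORTAL, MarkedPointPattern, cross_nn_distances, intensity

__all__ = [
    "StepProfile",
    "StepDetection",
    "LobuleEstimate",
    "HEX_AREA_FACTOR",
    "step_profile",
    "detect_step",
    "lobule_estimates",
    "portal_density",
]

#: A = HEX_AREA_FACTOR · r² for a regular hexagon of circumradius r
HEX_AREA_FACTOR = 1.5 * math.sqrt(3.0)


@dataclass
class StepProfile:
    """Mean distance to the kth nearest portal tract, k = 1..k_max."""

    k_values: np.ndarray
    mean_distance_per_k: np.ndarray
    per_central_vein_distances: np.ndarray  # (n_central, k_max)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mean_distance_per_k) < -1e-9):
            raise ValueError("mean distances must be non-decreasing in k")


@dataclass
class StepDetection:
    """Detected k:k+1 segregation boundary."""

    k_star: int
    magnitude: float  # mean_{k*+1} − mean_{k*}
    is_flat: bool  # True when the profile is constant (no real step)


@dataclass
class LobuleEstimate:
    """Per-central-vein hexagon-model radius and area, plus the section mean."""

    radii: np.ndarray  # µm
    areas: np.ndarray  # µm²
    interior: np.ndarray | None = None

    @property
    def section_mean_area(self) -> float:
        return float(self.areas.mean()) if len(self.areas) else math.nan


def step_profile(pattern: MarkedPointPattern, k_max: int = 6) -> StepProfile:
    """k-nearest-portal distance profile over all central veins.

    Row i of the distance matrix is central vein i's sorted distances to
    its k_max nearest portal tracts; the profile is the column mean.
    """
    d = cross_nn_distances(pattern, CENTRAL, PORTAL, k_max)
    return StepProfile(
        k_values=np.arange(1, k_max + 1),
        mean_distance_per_k=d.mean(axis=0),
        per_central_vein_distances=d,
    )


def detect_step(profile: StepProfile) -> StepDetection:
    """Largest jump in the mean k-distance profile.

    k* = argmax_k (mean_{k+1} − mean_k); ties break toward the smallest k
    (the conservative lobule definition).  A constant profile yields k* = 1
    flagged ``is_flat``.
    """
    means = profile.mean_distance_per_k
    if len(means) < 2:
        raise ValueError("need k_max >= 2 to detect a step")
    diffs = np.diff(means)
    dmax = diffs.max()
    # relative tolerance so ties survive rescaling of the coordinates
    tied = diffs >= dmax - 1e-9 * max(abs(dmax), 1e-300)
    k_star = int(np.argmax(tied)) + 1  # smallest k among maximal diffs
    mag = float(diffs[k_star - 1])
    return StepDetection(k_star=k_star, magnitude=mag, is_flat=mag == 0.0)


def lobule_estimates(
    pattern: MarkedPointPattern, exclude_boundary: bool = False
) -> LobuleEstimate:
    """Hexagon-paradigm lobule radius/area for every central vein.

    r_i is the mean distance from central vein i to its three nearest
    portal tracts; A_i = (3√3/2)·r_i².  With ``exclude_boundary`` central
    veins closer than the section mean r to the window edge are dropped
    (their nearest-portal distances are biased upward); the default keeps
    every vein, matching whole-section analysis.
    """
    d = cross_nn_distances(pattern, CENTRAL, PORTAL, 3)
    if d.shape[0] == 0:
        warnings.warn("no central veins in pattern; empty estimate", stacklevel=2)
        return LobuleEstimate(radii=np.empty(0), areas=np.empty(0))
    radii = d.mean(axis=1)
    centrals = pattern.points[pattern.marks == CENTRAL]
    interior = (
        pattern.interior[pattern.marks == CENTRAL]
        if pattern.interior is not None
        else None
    )
    if exclude_boundary:
        w = pattern.window
        r_bar = radii.mean()
        bdist = np.minimum.reduce(
            [
                centrals[:, 0] - w.x_min,
                w.x_max - centrals[:, 0],
                centrals[:, 1] - w.y_min,
                w.y_max - centrals[:, 1],
            ]
        )
        keep = bdist >= r_bar
        radii = radii[keep]
        if interior is not None:
            interior = interior[keep]
    return LobuleEstimate(
        radii=radii, areas=HEX_AREA_FACTOR * radii**2, interior=interior
    )


def portal_density(pattern: MarkedPointPattern) -> float:
    """Portal-tract intensity in counts per mm² (1 mm² = 10⁶ µm²)."""
    return intensity(pattern, PORTAL) * 1e6
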