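"""Ground-truthed synthetic liver tissue: vascular lattices and nuclear populations.

The classical liver lobule is idealised as a regular hexagon with the
central vein at the centre and portal tracts at (a subset of) the apices;
in most sections only about three of the six apices carry a recognisable
portal tract.  The generator realises that idealisation as a jittered
honeycomb: central veins on a triangular lattice of hexagon centres,
portal tracts on occupied honeycomb vertices, with isotropic Gaussian
positional noise.  Because the geometry is closed-form, every downstream
estimator (k-step profile, hexagon-paradigm lobule area, intensities) has
an exact known truth to recover.

Vertex occupancy modes
----------------------
``three_alternate``
    Every hexagon contributes its three alternating apices — one of the two
    bipartite vertex sublattices of the honeycomb.  Shared vertices are
    deduplicated; the occupied sublattice is itself a triangular lattice
    with one vertex per hexagon, so with zero jitter every interior central
    vein sees exactly 3 portal tracts at distance r0 and the next 3 at 2·r0.
``all_vertices``
    All six apices occupied (6 nearest portals at r0).
``random_fraction``
    Each honeycomb vertex kept independently with probability p.

The nuclear generator draws per-class morphology features from truncated
normal distributions centred on a typical hepatocyte nucleus of 70 µm²,
places binucleated hepatocytes as touching pairs of hepatocyte-like nuclei,
and clusters non-hepatocyte nuclei so that dense mutually-touching cliques
exist — the context that the binuclear reclassification cascade must avoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .nuclei import (
    CLASS_BINUCLEAR,
    CLASS_HEPATOCYTE,
    CLASS_OTHER,
    TYPICAL_NUCLEUS_AREA_UM2,
    NucleusRecord,
)
from .patterns import CENTRAL, PORTAL, MarkedPointPattern, Window

__all__ = [
    "SyntheticTissueConfig",
    "FeatureModel",
    "NucleusPopulationConfig",
    "generate_lobular_lattice",
    "generate_csr",
    "generate_clustered",
    "generate_nuclei",
    "hexagon_area",
]


def hexagon_area(r0: float) -> float:
    """Area of a regular hexagon with circumradius r0: (3√3/2)·r0²."""
    return 1.5 * math.sqrt(3.0) * r0 * r0


@dataclass(frozen=True)
class SyntheticTissueConfig:
    """Parameters of the jittered-honeycomb vascular lattice.

    lattice_radius_r0
        Hexagon circumradius (centre-to-vertex distance), µm.
    jitter_sd
        Isotropic Gaussian positional noise applied to every point, µm.
    portal_occupancy
        "three_alternate", "all_vertices" or "random_fraction".
    occupancy_fraction
        Keep-probability p for "random_fraction" (ignored otherwise).
    """

    lattice_radius_r0: float = 100.0
    jitter_sd: float = 0.0
    portal_occupancy: str = "three_alternate"
    occupancy_fraction: float = 0.5
    window_width: float = 2000.0
    window_height: float = 2000.0
    seed: int = 0
    n_sections: int = 1

    def __post_init__(self) -> None:
        if self.lattice_radius_r0 <= 0:
            raise ValueError("lattice_radius_r0 must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.portal_occupancy not in (
            "three_alternate",
            "all_vertices",
            "random_fraction",
        ):
            raise ValueError(f"unknown occupancy {self.portal_occupancy!r}")
        if self.portal_occupancy == "random_fraction" and not (
            0 < self.occupancy_fraction <= 1
        ):
            raise ValueError("occupancy_fraction must be in (0, 1]")
        if self.window_width <= 0 or self.window_height <= 0:
            raise ValueError("window dimensions must be > 0")


# honeycomb geometry: hexagon centres form a triangular lattice with basis
# a1 = (√3·r0, 0), a2 = (√3/2·r0, 3/2·r0); vertices sit at angles
# 30°, 90°, ..., 330° from each centre.  Alternating apices at 30°/150°/270°
# form one bipartite vertex sublattice, consistently across the tiling.
_SUBLATTICE_A = (30.0, 150.0, 270.0)
_SUBLATTICE_B = (90.0, 210.0, 330.0)


def _honeycomb(config: SyntheticTissueConfig):
    r0 = config.lattice_radius_r0
    W, H = config.window_width, config.window_height
    a1 = np.array([math.sqrt(3.0) * r0, 0.0])
    a2 = np.array([math.sqrt(3.0) / 2.0 * r0, 1.5 * r0])
    i_max = int(W / a1[0]) + 3
    j_max = int(H / a2[1]) + 3
    ii, jj = np.meshgrid(
        np.arange(-i_max - j_max, i_max + j_max + 1),
        np.arange(-3, j_max + 1),
        indexing="ij",
    )
    centers = ii[..., None] * a1 + jj[..., None] * a2
    centers = centers.reshape(-1, 2)
    angles = np.deg2rad(_SUBLATTICE_A + _SUBLATTICE_B)
    offsets = r0 * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    return centers, offsets


def generate_lobular_lattice(config: SyntheticTissueConfig) -> MarkedPointPattern:
    """Honeycomb lobule lattice clipped to the window.

    Central veins at hexagon centres, portal tracts at occupied (and
    deduplicated) vertices, Gaussian jitter of sd ``jitter_sd`` on every
    point.  Central veins whose six parent vertices all fall inside the
    window are flagged interior.  Raises if the window cannot contain a
    complete hexagon.
    """
    r0 = config.lattice_radius_r0
    window = Window(0.0, config.window_width, 0.0, config.window_height)
    if config.window_width < math.sqrt(3.0) * r0 or config.window_height < 2.0 * r0:
        raise ValueError(
            "window too small to contain one complete hexagon "
            f"(needs at least {math.sqrt(3) * r0:.1f} x {2 * r0:.1f} µm)"
        )
    rng = np.random.default_rng(config.seed)
    centers, offsets = _honeycomb(config)
    # random lattice phase: a section cuts the lobular tiling at an arbitrary
    # position, so the lattice is shifted by a uniform offset within one cell
    phase = rng.uniform([0.0, 0.0], [math.sqrt(3.0) * r0, 3.0 * r0])
    centers = centers + phase

    vertices = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    in_win_center = Window(0, config.window_width, 0, config.window_height).contains(
        centers
    )
    # interior flag: all six vertices of the hexagon inside the window
    verts_per_center = centers[:, None, :] + offsets[None, :, :]
    all_in = (
        (verts_per_center[..., 0] >= 0)
        & (verts_per_center[..., 0] <= config.window_width)
        & (verts_per_center[..., 1] >= 0)
        & (verts_per_center[..., 1] <= config.window_height)
    ).all(axis=1)
    centers_kept = centers[in_win_center]
    interior_centers = all_in[in_win_center]

    if config.portal_occupancy == "three_alternate":
        occ = (centers[:, None, :] + offsets[None, :3, :]).reshape(-1, 2)
    elif config.portal_occupancy == "all_vertices":
        occ = vertices
    else:
        occ = vertices
    occ = np.unique(np.round(occ, 6), axis=0)
    if config.portal_occupancy == "random_fraction":
        keep = rng.random(len(occ)) < config.occupancy_fraction
        occ = occ[keep]
    occ = occ[window.contains(occ)]

    if config.jitter_sd > 0:
        centers_kept = centers_kept + rng.normal(
            0.0, config.jitter_sd, centers_kept.shape
        )
        occ = occ + rng.normal(0.0, config.jitter_sd, occ.shape)
        # jitter may push points out of the window; clamp to keep the
        # pattern valid (boundary effect only, interior flags unaffected)
        centers_kept[:, 0] = np.clip(centers_kept[:, 0], 0, config.window_width)
        centers_kept[:, 1] = np.clip(centers_kept[:, 1], 0, config.window_height)
        occ[:, 0] = np.clip(occ[:, 0], 0, config.window_width)
        occ[:, 1] = np.clip(occ[:, 1], 0, config.window_height)

    points = np.vstack([centers_kept, occ])
    marks = np.array(
        [CENTRAL] * len(centers_kept) + [PORTAL] * len(occ), dtype=object
    )
    interior = np.concatenate(
        [interior_centers, np.zeros(len(occ), dtype=bool)]
    )
    return MarkedPointPattern(
        points=points,
        marks=marks,
        window=window,
        section_id="synthetic",
        group="synthetic",
        interior=interior,
    )


def generate_csr(
    intensity: float,
    window: Window,
    seed: int = 0,
    mark: str = PORTAL,
) -> MarkedPointPattern:
    """Homogeneous Poisson (CSR) pattern: N ~ Poisson(intensity·|W|), uniform."""
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * window.area)
    x = rng.uniform(window.x_min, window.x_max, n)
    y = rng.uniform(window.y_min, window.y_max, n)
    return MarkedPointPattern(
        points=np.column_stack([x, y]),
        marks=np.array([mark] * n, dtype=object),
        window=window,
        section_id="csr",
    )


def generate_clustered(
    parent_intensity: float,
    offspring_per_parent: float,
    cluster_sd: float,
    window: Window,
    seed: int = 0,
    mark: str = PORTAL,
) -> MarkedPointPattern:
    """Thomas-like clustered pattern: Poisson parents, Gaussian offspring."""
    rng = np.random.default_rng(seed)
    n_par = rng.poisson(parent_intensity * window.area)
    px = rng.uniform(window.x_min, window.x_max, n_par)
    py = rng.uniform(window.y_min, window.y_max, n_par)
    pts = []
    for cx, cy in zip(px, py):
        m = rng.poisson(offspring_per_parent)
        pts.append(
            np.column_stack(
                [rng.normal(cx, cluster_sd, m), rng.normal(cy, cluster_sd, m)]
            )
        )
    xy = np.vstack(pts) if pts else np.empty((0, 2))
    inside = window.contains(xy)
    xy = xy[inside]
    return MarkedPointPattern(
        points=xy,
        marks=np.array([mark] * len(xy), dtype=object),
        window=window,
        section_id="clustered",
    )


# ---------------------------------------------------------------------------
# nuclear populations


@dataclass(frozen=True)
class FeatureModel:
    """Truncated-normal feature distributions for one nuclear class.

    Each entry is (mean, sd); areas are truncated at 0 (impossible negative
    areas), circularity clipped to (0, 1], elongation truncated at 1.
    """

    area: tuple[float, float] = (TYPICAL_NUCLEUS_AREA_UM2, 15.0)
    circularity: tuple[float, float] = (0.85, 0.07)
    elongation: tuple[float, float] = (1.15, 0.12)
    intensity_mean: tuple[float, float] = (120.0, 18.0)
    intensity_sd: tuple[float, float] = (15.0, 5.0)

    def __post_init__(self) -> None:
        for name in ("area", "circularity", "elongation", "intensity_mean", "intensity_sd"):
            _, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} sd must be >= 0")


HEPATOCYTE_FEATURES = FeatureModel()
OTHER_FEATURES = FeatureModel(
    area=(45.0, 16.0),
    circularity=(0.76, 0.11),
    elongation=(1.35, 0.28),
    intensity_mean=(135.0, 25.0),
    intensity_sd=(21.0, 8.0),
)


@dataclass(frozen=True)
class NucleusPopulationConfig:
    """Composition and geometry of a synthetic nuclear population.

    ``n_binuclear`` counts binucleated cells; each contributes a *pair* of
    touching hepatocyte-like nucleus records.  ``touching_distance`` is the
    centroid separation below which two nuclei are considered touching
    (a little above one nuclear diameter, ≈9.4 µm for 70 µm²).
    """

    n_hepatocyte: int = 1100
    n_binuclear: int = 60
    n_other: int = 700
    hepatocyte_features: FeatureModel = field(default_factory=lambda: HEPATOCYTE_FEATURES)
    other_features: FeatureModel = field(default_factory=lambda: OTHER_FEATURES)
    touching_distance: float = 12.0
    window_width: float = 1000.0
    window_height: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hepatocyte, self.n_binuclear, self.n_other) < 0:
            raise ValueError("class counts must be >= 0")
        if self.touching_distance <= 0:
            raise ValueError("touching_distance must be > 0")


def _draw_features(model: FeatureModel, n: int, rng: np.random.Generator):
    def trunc(mean, sd, lo, hi=np.inf):
        v = rng.normal(mean, sd, n)
        bad = (v <= lo) | (v > hi)
        while bad.any():  # redraw outside the support
            v[bad] = rng.normal(mean, sd, bad.sum())
            bad = (v <= lo) | (v > hi)
        return v

    return {
        "area": trunc(*model.area, 1e-6),
        "circularity": trunc(*model.circularity, 1e-6, 1.0),
        "elongation": trunc(*model.elongation, 1.0),
        "intensity_mean": trunc(*model.intensity_mean, 0.0),
        "intensity_sd": trunc(*model.intensity_sd, 0.0),
    }


def _place_inhibited(
    n: int,
    existing: list[np.ndarray],
    min_dist: float,
    width: float,
    height: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequential inhibition (Matérn-like): uniform proposals rejected within
    min_dist of already accepted points."""
    accepted = list(existing)
    out = []
    tree_pts = np.array(accepted).reshape(-1, 2)
    for _ in range(n):
        for _attempt in range(200):
            p = rng.uniform([0, 0], [width, height])
            if len(tree_pts) == 0:
                break
            d = np.min(np.hypot(tree_pts[:, 0] - p[0], tree_pts[:, 1] - p[1]))
            if d >= min_dist:
                break
        out.append(p)
        tree_pts = np.vstack([tree_pts, p]) if len(tree_pts) else p.reshape(1, 2)
    return np.array(out).reshape(-1, 2)


def generate_nuclei(config: NucleusPopulationConfig) -> list[NucleusRecord]:
    """Synthetic nuclear population with ground-truth classes.

    Singleton hepatocytes are placed with mutual inhibition (plate spacing),
    binucleated cells as touching hepatocyte-like pairs, and non-hepatocyte
    nuclei in small Gaussian clusters so that mutually-touching cliques
    occur.  Context features (nearest-neighbour distance, touching count)
    are computed from the realised geometry.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    W, H = config.window_width, config.window_height
    touch = config.touching_distance

    records: list[NucleusRecord] = []
    placed: list[np.ndarray] = []

    # singleton hepatocytes: inhibited at 1.5x touching distance
    hep_xy = _place_inhibited(
        config.n_hepatocyte, placed, 1.5 * touch, W, H, rng
    )
    placed.extend(hep_xy)

    # binuclear pairs: each pair must touch only its own partner, so the
    # centroid keeps > touching_distance + member offset from hepatocytes
    # and a wider berth from other pair centroids
    hep_arr = hep_xy.reshape(-1, 2)
    centroids: list[np.ndarray] = []
    for _ in range(config.n_binuclear):
        for _attempt in range(500):
            c = rng.uniform([0, 0], [W, H])
            ok = True
            if len(hep_arr):
                if np.min(np.hypot(hep_arr[:, 0] - c[0], hep_arr[:, 1] - c[1])) < 1.6 * touch:
                    ok = False
            if ok and centroids:
                ca = np.array(centroids)
                if np.min(np.hypot(ca[:, 0] - c[0], ca[:, 1] - c[1])) < 3.0 * touch:
                    ok = False
            if ok:
                break
        centroids.append(c)
    bin_xy = []
    for c in centroids:
        sep = rng.uniform(0.5, 0.95) * touch
        ang = rng.uniform(0, 2 * np.pi)
        off = 0.5 * sep * np.array([np.cos(ang), np.sin(ang)])
        bin_xy.extend([c + off, c - off])
        placed.extend([c + off, c - off])
    bin_xy = np.array(bin_xy).reshape(-1, 2)

    # non-hepatocytes: clustered (inflammatory foci / portal accumulations);
    # cluster centres keep clear of planted binuclear pairs — those sit inside
    # hepatocyte plates, away from inflammatory foci, and the pair contract
    # requires a clique-free context
    oth_xy = []
    n_left = config.n_other
    while n_left > 0:
        size = min(int(rng.poisson(3.0)) + 1, n_left)
        for _attempt in range(100):
            center = rng.uniform([0, 0], [W, H])
            if len(bin_xy) == 0:
                break
            d = np.min(np.hypot(bin_xy[:, 0] - center[0], bin_xy[:, 1] - center[1]))
            if d >= 2.5 * touch:
                break
        pts = rng.normal(center, 0.45 * touch, size=(size, 2))
        oth_xy.append(pts)
        n_left -= size
    oth_xy = (
        np.clip(np.vstack(oth_xy), [0, 0], [W, H])
        if oth_xy
        else np.empty((0, 2))
    )

    all_xy = np.vstack([hep_xy, bin_xy, oth_xy])
    classes = (
        [CLASS_HEPATOCYTE] * len(hep_xy)
        + [CLASS_BINUCLEAR] * len(bin_xy)
        + [CLASS_OTHER] * len(oth_xy)
    )

    feats_hep = _draw_features(config.hepatocyte_features, len(hep_xy), rng)
    feats_bin = _draw_features(config.hepatocyte_features, len(bin_xy), rng)
    feats_oth = _draw_features(config.other_features, len(oth_xy), rng)
    feats = {
        k: np.concatenate([feats_hep[k], feats_bin[k], feats_oth[k]])
        for k in feats_hep
    }

    # context features from the realised geometry
    if len(all_xy) > 1:
        tree = cKDTree(all_xy)
        d, _ = tree.query(all_xy, k=2)
        nn_dist = d[:, 1]
        neighbors = tree.query_ball_point(all_xy, touch)
        touching = np.array([len(nb) - 1 for nb in neighbors])
    else:
        nn_dist = np.full(len(all_xy), np.inf)
        touching = np.zeros(len(all_xy), dtype=int)

    # perimeter back-solved from circularity: C = 4πA/P²  =>  P = sqrt(4πA/C)
    perimeter = np.sqrt(4.0 * np.pi * feats["area"] / feats["circularity"])

    for i in range(len(all_xy)):
        records.append(
            NucleusRecord(
                id=i,
                x=float(all_xy[i, 0]),
                y=float(all_xy[i, 1]),
                area=float(feats["area"][i]),
                perimeter=float(perimeter[i]),
                circularity=float(feats["circularity"][i]),
                elongation=float(feats["elongation"][i]),
                intensity_mean=float(feats["intensity_mean"][i]),
                intensity_sd=float(feats["intensity_sd"][i]),
                nn_distance=float(nn_dist[i]),
                touching_count=int(touching[i]),
                true_class=classes[i],
            )
        )
    return records
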