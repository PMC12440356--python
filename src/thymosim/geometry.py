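"""Static TEC niche: body placement, protrusion growth, occupancy metrics.

The simulated organ is a 5-um-deep slice of the lower half of the radially
symmetric embryonic thymus (about one tenth of the organ volume). Thymic
epithelial cells (TECs) are static star-shaped agents: one body sphere plus
chains of tangent protrusion spheres. They are placed on concentric arcs
subdividing the half-disc; the number of arcs (``n_subdivisions``) sets TEC
density. All TECs present the Notch ligand Dll4 on their surface; a subset
(by default those in the outer, cortical half of the organ) secrete IL-7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .params import SimulationParams


class GeometryError(ValueError):
    """The domain cannot host the requested geometry."""


@dataclass(frozen=True)
class Domain:
    """Half-disc slice: ``x^2 + y^2 <= radius^2``, ``y <= 0``, ``0 <= z <= depth``."""

    radius: float = 46.0
    depth: float = 5.0

    @property
    def volume(self) -> float:
        return 0.5 * np.pi * self.radius**2 * self.depth

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the half-disc slice (shrunk by margin)."""
        points = np.atleast_2d(points)
        rr = np.hypot(points[:, 0], points[:, 1])
        return (
            (rr <= self.radius - margin)
            & (points[:, 1] <= -margin)
            & (points[:, 2] >= margin)
            & (points[:, 2] <= self.depth - margin)
        )


@dataclass
class TecCell:
    """One static epithelial agent: body sphere plus protrusion spheres."""

    body_center: np.ndarray
    body_radius: float
    protrusions: list[tuple[np.ndarray, float]] = field(default_factory=list)
    dll4: bool = True
    il7_secreting: bool = False

    @property
    def volume(self) -> float:
        """Total sphere volume (tangent spheres do not overlap)."""
        v = 4.0 / 3.0 * np.pi * self.body_radius**3
        for _, r in self.protrusions:
            v += 4.0 / 3.0 * np.pi * r**3
        return v

    def spheres(self) -> tuple[np.ndarray, np.ndarray]:
        """All (centers, radii) of this TEC, body first."""
        centers = [self.body_center] + [c for c, _ in self.protrusions]
        radii = [self.body_radius] + [r for _, r in self.protrusions]
        return np.asarray(centers, dtype=float), np.asarray(radii, dtype=float)


@dataclass
class TecNiche:
    """Aggregated immutable TEC network with flat sphere arrays for the solver."""

    domain: Domain
    tecs: list[TecCell]
    sphere_centers: np.ndarray  # (M, 3)
    sphere_radii: np.ndarray    # (M,)
    sphere_secreting: np.ndarray  # (M,) bool

    @property
    def n_tecs(self) -> int:
        return len(self.tecs)

    def total_volume(self) -> float:
        return float(sum(t.volume for t in self.tecs))


# ----------------------------------------------------------------------

def place_tec_bodies(
    domain: Domain,
    n_subdivisions: int,
    tec_radius: float,
    rng: np.random.Generator,
    spacing_factor: float = 2.9,
) -> np.ndarray:
    """Place TEC body centers on concentric arcs of the half-disc.

    Arc ``k`` (k = 1..n_subdivisions) sits at radius ``k/(n+1) * R``; bodies
    are spaced ``spacing_factor * tec_radius`` apart along each arc with a
    small random angular jitter. More subdivisions means more arcs and
    strictly more TECs. Deterministic given the rng state.
    """
    if n_subdivisions < 1:
        raise GeometryError("n_subdivisions must be >= 1")
    spacing = spacing_factor * tec_radius
    centers: list[np.ndarray] = []
    z = domain.depth / 2.0
    for k in range(1, n_subdivisions + 1):
        arc_r = k / (n_subdivisions + 1) * domain.radius
        m = int(np.floor(np.pi * arc_r / spacing))
        if m < 1:
            m = 1
        dtheta = np.pi / m
        jitter = rng.normal(0.0, 0.05, size=m)
        for j in range(m):
            theta = -np.pi + (j + 0.5 + jitter[j]) * dtheta
            centers.append(
                np.array([arc_r * np.cos(theta), arc_r * np.sin(theta), z])
            )
    if not centers:
        raise GeometryError("domain too small to host a single TEC")
    return np.asarray(centers)


def grow_protrusions(
    tec: TecCell,
    n_protrusions: int,
    domain: Domain,
    rng: np.random.Generator,
    ratio: float = 0.5,
    chain_length: int = 3,
) -> TecCell:
    """Attach ``n_protrusions`` chains of tangent spheres to a placed body.

    Chains radiate in the slice plane at evenly spaced angles with a random
    rotation offset and per-chain jitter; each chain holds ``chain_length``
    tangent spheres of radius ``ratio * body_radius``. Spheres that would
    leave the half-disc are clipped (the chain is truncated there).
    """
    tec.protrusions = []
    if n_protrusions <= 0:
        return tec
    pr = ratio * tec.body_radius
    base = rng.uniform(0.0, 2.0 * np.pi)
    for i in range(n_protrusions):
        angle = base + 2.0 * np.pi * i / n_protrusions + rng.normal(0.0, 0.15)
        direction = np.array([np.cos(angle), np.sin(angle), 0.0])
        for j in range(chain_length):
            dist = tec.body_radius + pr + 2.0 * pr * j
            center = tec.body_center + dist * direction
            rr = np.hypot(center[0], center[1])
            if rr + pr > domain.radius or center[1] + pr > 0.0:
                break  # clipped at the domain boundary
            tec.protrusions.append((center, pr))
    return tec


def build_niche(params: SimulationParams, rng: np.random.Generator) -> TecNiche:
    """Generate the full static TEC network for one scenario.

    IL-7 secretion is assigned per TEC: in ``cortical_subset`` mode an evenly
    interleaved fraction (``il7_cortical_fraction``) of the TECs whose body
    lies in the outer half-annulus (body radius > R/2) secrete, reproducing
    the patchy, short-ranged cortical IL-7 expression with a reproducible
    source count; ``all_tecs`` and ``none`` override this uniformly.
    """
    domain = Domain(params.domain_radius, params.domain_depth)
    centers = place_tec_bodies(
        domain,
        params.n_subdivisions,
        params.tec_radius,
        rng,
        spacing_factor=params.tec_spacing_factor,
    )
    tecs: list[TecCell] = []
    cortical_index = 0
    frac = params.il7_cortical_fraction
    for c in centers:
        tec = TecCell(body_center=c, body_radius=params.tec_radius)
        grow_protrusions(
            tec,
            params.n_protrusions,
            domain,
            rng,
            ratio=params.protrusion_ratio,
            chain_length=params.protrusion_spheres,
        )
        rr = np.hypot(c[0], c[1])
        if params.il7_expression_mode == "all_tecs":
            tec.il7_secreting = True
        elif params.il7_expression_mode == "none":
            tec.il7_secreting = False
        else:  # cortical_subset: every 1/frac-th cortical TEC along the arc
            if rr > domain.radius / 2.0:
                take = int((cortical_index + 1) * frac) > int(
                    cortical_index * frac
                )
                tec.il7_secreting = bool(take and frac > 0)
                cortical_index += 1
            else:
                tec.il7_secreting = False
        tecs.append(tec)

    all_centers, all_radii, secreting = [], [], []
    for tec in tecs:
        cs, rs = tec.spheres()
        all_centers.append(cs)
        all_radii.append(rs)
        secreting.append(np.full(len(rs), tec.il7_secreting))
    return TecNiche(
        domain=domain,
        tecs=tecs,
        sphere_centers=np.concatenate(all_centers),
        sphere_radii=np.concatenate(all_radii),
        sphere_secreting=np.concatenate(secreting),
    )


# ----------------------------------------------------------------------

@dataclass(frozen=True)
class OccupancyRecord:
    """Union-of-spheres volume shares inside the domain."""

    thymocyte_share: float
    tec_share: float
    occupancy: float           # occupied volume / domain volume
    thymocyte_volume: float
    tec_volume: float
    defined: bool              # False when no cell volume exists


def compute_occupancy(
    tec_spheres: tuple[np.ndarray, np.ndarray] | TecNiche | None,
    thymocyte_centers: np.ndarray,
    thymocyte_radii: np.ndarray,
    domain: Domain,
    rng: np.random.Generator,
    n_samples: int = 40_000,
) -> OccupancyRecord:
    """Monte-Carlo union-of-spheres occupancy of the organ slice.

    Uniform sample points inside the half-disc slice are classified as lying
    inside any thymocyte sphere and/or any TEC sphere; union volumes never
    double-count overlapping spheres of the same class. Shares are fractions
    of the combined occupied cell volume and sum to 1 whenever any cell
    exists.
    """
    if isinstance(tec_spheres, TecNiche):
        tec_centers, tec_radii = tec_spheres.sphere_centers, tec_spheres.sphere_radii
    elif tec_spheres is None:
        tec_centers = np.zeros((0, 3))
        tec_radii = np.zeros(0)
    else:
        tec_centers, tec_radii = tec_spheres
    thymocyte_centers = np.asarray(thymocyte_centers, dtype=float).reshape(-1, 3)
    thymocyte_radii = np.asarray(thymocyte_radii, dtype=float).ravel()

    # uniform points in the half-disc slice via polar inversion sampling
    rr = domain.radius * np.sqrt(rng.uniform(size=n_samples))
    theta = rng.uniform(-np.pi, 0.0, size=n_samples)
    z = rng.uniform(0.0, domain.depth, size=n_samples)
    pts = np.column_stack([rr * np.cos(theta), rr * np.sin(theta), z])

    tree = cKDTree(pts)

    def _hit_mask(centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
        mask = np.zeros(n_samples, dtype=bool)
        for c, r in zip(centers, radii):
            idx = tree.query_ball_point(c, r)
            mask[idx] = True
        return mask

    in_thy = _hit_mask(thymocyte_centers, thymocyte_radii)
    in_tec = _hit_mask(tec_centers, tec_radii)

    v_dom = domain.volume
    v_thy = in_thy.mean() * v_dom
    v_tec = in_tec.mean() * v_dom
    occupied = (in_thy | in_tec).mean()
    total_cell = v_thy + v_tec
    if total_cell <= 0.0:
        return OccupancyRecord(np.nan, np.nan, 0.0, 0.0, 0.0, defined=False)
    return OccupancyRecord(
        thymocyte_share=v_thy / total_cell,
        tec_share=v_tec / total_cell,
        occupancy=float(occupied),
        thymocyte_volume=float(v_thy),
        tec_volume=float(v_tec),
        defined=True,
    )


def geometry_table(niche: TecNiche) -> "pd.DataFrame":
    """Geometry dump: one sphere per row (for rendering and regression)."""
    import pandas as pd

    rows = []
    for i, tec in enumerate(niche.tecs):
        cs, rs = tec.spheres()
        for j, (c, r) in enumerate(zip(cs, rs)):
            rows.append(
                {
                    "cell_id": i,
                    "type": "tec_body" if j == 0 else "tec_protrusion",
                    "x": c[0],
                    "y": c[1],
                    "z": c[2],
                    "radius": r,
                    "dll4": tec.dll4,
                    "il7_secreting": tec.il7_secreting,
                }
            )
    return pd.DataFrame(rows)
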