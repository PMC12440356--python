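"""Thymocyte mechanics and motility; immigration and departure handling.

Cells are overdamped soft spheres confined to the 5-um organ slice, so
dynamics are effectively planar (all centres sit on the mid-plane).
Pairwise interactions are linear-spring repulsion under overlap and a weak
linear adhesion out to 1.2x the contact distance; TEC spheres exert the same
forces but never move. Active motility is a persistent random walk whose
heading diffuses at a stage-specific rate: early thymic progenitors move
faster and straighter than maturing thymocytes. New ETPs appear at regular
intervals on the ventral (outer arc) boundary; positively selected cells
walk back out through it, and apoptotic cells shrink until removal.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import _kernels
from .geometry import Domain, TecNiche
from .params import SimulationParams


def step_forces(
    positions: np.ndarray,
    radii: np.ndarray,
    exit_bound: np.ndarray,
    niche: TecNiche | None,
    domain: Domain,
    params: SimulationParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Passive displacements for one agent step plus Notch-contact flags.

    A displacement that would exceed the cell radius is truncated there
    (effective sub-stepping of a runaway overlap over several agent steps)
    and a warning is recorded.
    """
    n = len(radii)
    if n == 0:
        return np.zeros((0, 3)), np.zeros(0, dtype=bool)
    if niche is not None:
        tc, tr = niche.sphere_centers, niche.sphere_radii
    else:
        tc, tr = np.zeros((0, 3)), np.zeros(0)
    args = (
        np.ascontiguousarray(tc, dtype=np.float64),
        np.ascontiguousarray(tr, dtype=np.float64),
        domain.radius,
        0.0,
        params.relaxation_per_step,
        params.adhesion_ratio,
        params.adhesion_range,
        params.notch_contact_range,
    )
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    rad = np.ascontiguousarray(radii, dtype=np.float64)
    eb = np.ascontiguousarray(exit_bound, dtype=np.uint8)
    disp, contact, n_clipped = _kernels.mechanics_step(pos, rad, eb, *args)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} mechanical displacement(s) exceeded one radius; "
            "truncated (overlap relaxes over subsequent steps)"
        )
    return disp, contact.astype(bool)


def update_headings(
    heading: np.ndarray,
    turn_noise: np.ndarray,
    dt_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rotational diffusion of in-plane headings (noise in rad/sqrt(min))."""
    if heading.size == 0:
        return heading
    sd = turn_noise * np.sqrt(dt_s / 60.0)
    return heading + rng.normal(0.0, 1.0, size=heading.shape) * sd


def active_displacement(
    heading: np.ndarray,
    speed_um_min: np.ndarray,
    dt_s: float,
) -> np.ndarray:
    """Persistent-random-walk displacement over one step (um)."""
    step = speed_um_min * dt_s / 60.0
    out = np.zeros((heading.size, 3))
    out[:, 0] = step * np.cos(heading)
    out[:, 1] = step * np.sin(heading)
    return out


def outward_heading(positions: np.ndarray) -> np.ndarray:
    """Radially outward heading angles (exit-bound drift to the ventral arc)."""
    return np.arctan2(positions[:, 1], positions[:, 0])


def spawn_position(
    domain: Domain, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Entry position on the ventral boundary arc (random angle, mid-plane)."""
    theta = rng.uniform(-np.pi, 0.0)
    rr = domain.radius - radius
    return np.array(
        [rr * np.cos(theta), rr * np.sin(theta), domain.depth / 2.0]
    )


def spawn_is_blocked(
    candidate: np.ndarray,
    radius: float,
    positions: np.ndarray,
    radii: np.ndarray,
    tolerance: float = 0.5,
) -> bool:
    """True when the candidate overlaps an existing cell by more than
    ``tolerance`` of the contact distance."""
    if len(radii) == 0:
        return False
    d = np.linalg.norm(positions[:, :2] - candidate[:2], axis=1)
    return bool((d < tolerance * (radii + radius)).any())


def exit_mask(positions: np.ndarray, exit_bound: np.ndarray,
              domain: Domain) -> np.ndarray:
    """Exit-bound cells whose centre crossed the ventral boundary."""
    rr = np.hypot(positions[:, 0], positions[:, 1])
    return exit_bound & (rr >= domain.radius)


def death_mask(radii: np.ndarray, apoptotic: np.ndarray,
               floor: float) -> np.ndarray:
    """Apoptotic cells shrunk below the removal radius."""
    return apoptotic & (radii <= floor)
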