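"""Extracellular IL-7 reaction-diffusion field on a voxel grid.

The concentration c(x, t) obeys

    dc/dt = D * laplacian(c) - k * c + sum_i s_i  [- sinks]

with no-flux boundaries on the masked organ slice. Sources are the voxels
intersecting IL-7-secreting TEC spheres (and, for the autocrine lesion, the
lesioned thymocytes' own voxels). Without depletion the field ignores
thymocytes entirely; with depletion every thymocyte removes ligand at the
rate of its own signal-transduction activation (receptor level x local
concentration x activation rate), and dominant-active clones at the constant
rate of their receptor level. Internalized IL-7 is permanently removed from
the extracellular pool; a per-substep clamp keeps voxels nonnegative and is
counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import Domain, TecNiche


class StabilityError(ValueError):
    """Requested substep violates the explicit solver's stability bound."""


class BoundaryError(ValueError):
    """A cell lies fully outside the grid."""


@dataclass
class FieldBudget:
    """Per-step mass bookkeeping (mass units = concentration x voxel volume)."""

    mass_before: float
    mass_after: float
    source_in: float
    decay_out: float
    sink_out: float
    n_clamped: int

    @property
    def residual(self) -> float:
        """|dM - (in - decay - sink)| relative to turnover."""
        dm = self.mass_after - self.mass_before
        expected = self.source_in - self.decay_out - self.sink_out
        scale = max(abs(self.mass_before), abs(self.source_in),
                    abs(self.decay_out), 1e-30)
        return abs(dm - expected) / scale


class CytokineGrid:
    """Voxelized IL-7 concentration field over an axis-aligned box.

    ``mask`` selects the in-organ voxels (no-flux boundaries along its rim);
    a plain box grid (all-true mask) is useful for solver verification.
    """

    def __init__(
        self,
        origin: tuple[float, float, float],
        shape: tuple[int, int, int],
        voxel_size: float,
        diffusion_coeff: float,
        decay_rate: float,
        secretion_rate: float,
        mask: np.ndarray | None = None,
    ) -> None:
        self.origin = tuple(float(v) for v in origin)
        self.voxel_size = float(voxel_size)
        self.diffusion_coeff = float(diffusion_coeff)
        self.decay_rate = float(decay_rate)
        self.secretion_rate = float(secretion_rate)
        self.concentrations = np.zeros(shape, dtype=np.float64)
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        self.mask = np.ascontiguousarray(mask, dtype=bool)
        self.budget: FieldBudget | None = None

    # -- construction ---------------------------------------------------
    @classmethod
    def for_domain(
        cls,
        domain: Domain,
        voxel_size: float,
        diffusion_coeff: float,
        decay_rate: float,
        secretion_rate: float,
    ) -> "CytokineGrid":
        """Grid covering the half-disc slice, masked to the organ interior."""
        R, depth = domain.radius, domain.depth
        nx = int(np.ceil(2 * R / voxel_size))
        ny = int(np.ceil(R / voxel_size))
        nz = max(int(np.round(depth / voxel_size)), 1)
        origin = (-R, -R, 0.0)
        grid = cls(origin, (nx, ny, nz), voxel_size, diffusion_coeff,
                   decay_rate, secretion_rate)
        centers = grid.voxel_centers()
        rr = np.hypot(centers[..., 0], centers[..., 1])
        grid.mask = (rr <= R) & (centers[..., 1] <= 0.0)
        return grid

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre coordinates."""
        h = self.voxel_size
        ox, oy, oz = self.origin
        nx, ny, nz = self.concentrations.shape
        xs = ox + (np.arange(nx) + 0.5) * h
        ys = oy + (np.arange(ny) + 0.5) * h
        zs = oz + (np.arange(nz) + 0.5) * h
        return np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    def total_mass(self) -> float:
        return float(self.concentrations[self.mask].sum() * self.voxel_volume)

    # -- sources and sinks ----------------------------------------------
    def voxelize_spheres(
        self, centers: np.ndarray, radii: np.ndarray
    ) -> np.ndarray:
        """Boolean map of in-mask voxels intersecting any of the spheres.

        A voxel counts as intersecting when its centre lies within
        ``radius + voxel_size/2`` of the sphere centre (so spheres smaller
        than a voxel still claim their host voxel).
        """
        out = np.zeros(self.concentrations.shape, dtype=bool)
        if len(radii) == 0:
            return out
        vox = self.voxel_centers()
        half = self.voxel_size / 2.0
        for c, r in zip(np.atleast_2d(centers), np.atleast_1d(radii)):
            d2 = ((vox - np.asarray(c)) ** 2).sum(axis=-1)
            out |= d2 <= (r + half) ** 2
        return out & self.mask

    def accumulate_sources(
        self,
        niche: TecNiche | None,
        autocrine_centers: np.ndarray | None = None,
        autocrine_radii: np.ndarray | None = None,
    ) -> np.ndarray:
        """Source-rate map (conc/s): secreting TEC spheres plus any
        autocrine lesioned thymocytes, each contributing the secretion rate
        over the voxels its volume intersects."""
        source = np.zeros_like(self.concentrations)
        if niche is not None and niche.sphere_secreting.any():
            sel = niche.sphere_secreting
            hit = self.voxelize_spheres(
                niche.sphere_centers[sel], niche.sphere_radii[sel]
            )
            source[hit] += self.secretion_rate
        if autocrine_centers is not None and len(autocrine_centers):
            rates = np.full(len(autocrine_centers), self.secretion_rate)
            _kernels.deposit_cell_rates(
                source,
                self.mask,
                np.ascontiguousarray(autocrine_centers, dtype=np.float64),
                np.ascontiguousarray(autocrine_radii, dtype=np.float64),
                rates,
                *self.origin,
                self.voxel_size,
            )
        return source

    def accumulate_sinks(
        self,
        positions: np.ndarray,
        radii: np.ndarray,
        il7r_levels: np.ndarray,
        activation_rate_hr: float,
        da_mask: np.ndarray | None = None,
        depletion: bool = True,
        efficiency: float = 1.0,
    ) -> np.ndarray:
        """Sink-rate map (conc/s) for IL-7 internalization by thymocytes.

        With ``depletion`` off the map is identically zero. Otherwise each
        wild-type thymocyte removes ligand over its voxels at its
        signal-transduction activation rate, receptor x local mean
        concentration x activation rate; dominant-active cells (``da_mask``)
        remove at the constant rate of their receptor level instead.
        ``efficiency`` converts signal-transduction activity (arbitrary
        units) into extracellular concentration loss; it is a model constant
        calibrated so that depletion at reference rates perturbs the field
        mildly.
        """
        sink = np.zeros_like(self.concentrations)
        n = len(radii)
        if not depletion or n == 0:
            return sink
        positions = np.ascontiguousarray(positions, dtype=np.float64)
        radii = np.ascontiguousarray(radii, dtype=np.float64)
        local = self.local_mean_concentration(positions, radii)
        a_s = efficiency * activation_rate_hr / 3600.0
        rates = il7r_levels * local * a_s
        if da_mask is not None and da_mask.any():
            rates = np.where(
                da_mask, efficiency * il7r_levels / 3600.0, rates
            )
        _kernels.deposit_cell_rates(
            sink, self.mask, positions, radii,
            np.ascontiguousarray(rates, dtype=np.float64),
            *self.origin, self.voxel_size,
        )
        return sink

    # -- time stepping ---------------------------------------------------
    def max_stable_dt(self) -> float:
        if self.diffusion_coeff == 0.0:
            return np.inf
        return self.voxel_size**2 / (6.0 * self.diffusion_coeff)

    def step(
        self,
        dt: float,
        sources: np.ndarray | None = None,
        sinks: np.ndarray | None = None,
        substeps: int | None = None,
    ) -> FieldBudget:
        """Advance the field by ``dt`` seconds.

        Substeps default to the largest stable subdivision of ``dt``; an
        explicit ``substeps`` that violates the stability bound raises
        :class:`StabilityError` naming the admissible substep.
        """
        dt_max = self.max_stable_dt()
        if substeps is None:
            substeps = max(int(np.ceil(dt / (0.9 * dt_max))), 1) \
                if np.isfinite(dt_max) else 1
        dt_sub = dt / substeps
        if dt_sub > dt_max * (1 + 1e-12):
            raise StabilityError(
                f"substep {dt_sub:.4g} s exceeds the stability bound; use a "
                f"substep <= {dt_max:.4g} s"
            )
        if sources is None:
            sources = np.zeros_like(self.concentrations)
        if sinks is None:
            sinks = np.zeros_like(self.concentrations)
        mass_before = self.total_mass()
        src, dec, snk, ncl = _kernels.diffuse(
            self.concentrations, self.mask, sources, sinks,
            self.diffusion_coeff, self.decay_rate,
            self.voxel_size, dt_sub, substeps,
        )
        vv = self.voxel_volume
        self.budget = FieldBudget(
            mass_before=mass_before,
            mass_after=self.total_mass(),
            source_in=src * vv,
            decay_out=dec * vv,
            sink_out=snk * vv,
            n_clamped=int(ncl),
        )
        if not np.isfinite(self.concentrations).all():
            raise FloatingPointError("cytokine field became non-finite")
        return self.budget

    # -- readouts ---------------------------------------------------------
    def local_mean_concentration(
        self, positions: np.ndarray, radii: np.ndarray | float
    ) -> np.ndarray:
        """Arithmetic mean concentration over the voxels each cell's sphere
        intersects (the cell's microenvironment). Raises
        :class:`BoundaryError` for a cell fully outside the grid."""
        positions = np.ascontiguousarray(
            np.atleast_2d(positions), dtype=np.float64
        )
        radii = np.ascontiguousarray(
            np.broadcast_to(np.asarray(radii, dtype=np.float64),
                            positions.shape[:1]),
        )
        out = _kernels.sample_local_mean(
            self.concentrations, self.mask, positions, radii,
            *self.origin, self.voxel_size,
        )
        if (out < 0).any():
            raise BoundaryError("cell lies fully outside the cytokine grid")
        return out

    def summarize_field(self) -> tuple[float, np.ndarray]:
        """(domain-wide mean, sum projection over z).

        The mean runs over every in-organ voxel, including cell-free space,
        matching a whole-volume average of a confocal stack; the projection
        sums the z-planes per (x, y) column like a sum projection image.
        """
        mean = float(self.concentrations[self.mask].mean()) \
            if self.mask.any() else 0.0
        projection = self.concentrations.sum(axis=2)
        return mean, projection
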