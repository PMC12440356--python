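"""Simulation driver: the per-step update loop, scans, and result container.

Update order within one 15-s agent step is fixed and documented: cytokine
diffusion substeps, then signaling updates, then fate (cycle, division,
differentiation, selection), then mechanics and active motility, then
immigration and departures, then logging. Each run starts from an empty
organ with the first early thymic progenitor entering at t = 0 and is fully
reproducible from (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import cycle as cyc
from . import mechanics as mech
from . import signaling as sig
from .field import CytokineGrid
from .geometry import Domain, OccupancyRecord, TecNiche, build_niche, compute_occupancy
from .lineage import LineageForest, rounds_of_division
from .params import SimulationParams

HOMEOSTASIS_START_HR = 60.0


class SimulationError(RuntimeError):
    """Numerical failure during a run (non-finite field, runaway overlap)."""


@dataclass
class SimulationResult:
    """Everything one run produces, sufficient for every published readout."""

    params: SimulationParams
    population: pd.DataFrame            # time_hr, count
    homeostatic_mean: float
    homeostatic_sd: float
    occupancy: list[OccupancyRecord]
    field_summary: pd.DataFrame         # time_hr, mean_il7
    forest: LineageForest
    events: pd.DataFrame                # time_hr, event, cell_id, clone_id, lesioned
    clone_series: pd.DataFrame          # time_hr, clone_id, count
    final_projection: np.ndarray
    max_budget_residual: float
    n_sink_clamped: int
    niche: TecNiche | None = None

    # -- derived ---------------------------------------------------------
    def mean_occupancy_shares(self) -> tuple[float, float]:
        recs = [r for r in self.occupancy if r.defined]
        if not recs:
            return (np.nan, np.nan)
        thy = float(np.mean([r.thymocyte_share for r in recs]))
        tec = float(np.mean([r.tec_share for r in recs]))
        return thy, tec

    def reconcile_events(self) -> bool:
        """Check that sampled population counts equal the cumulative event
        balance (+spawn, +divide, -die, -exit) at every sample time."""
        delta = {"spawn": 1, "divide": 1, "die": -1, "exit": -1}
        ev = self.events
        for t, count in zip(self.population.time_hr, self.population["count"]):
            upto = ev[ev.time_hr <= t + 1e-9]
            balance = sum(delta[e] for e in upto.event)
            if balance != count:
                return False
        return True


def summarize_population(
    result: SimulationResult, window_start: float = HOMEOSTASIS_START_HR
) -> tuple[float, float]:
    """Time-averaged population mean and SD over [window_start, end]."""
    pop = result.population
    if pop.empty or window_start >= pop.time_hr.max():
        raise ValueError("homeostatic window is empty")
    window = pop[pop.time_hr >= window_start]["count"]
    return float(window.mean()), float(window.std(ddof=0))


# ----------------------------------------------------------------------
# internal struct-of-arrays cell state
# ----------------------------------------------------------------------

_FLOAT_COLS = (
    "u", "sig7", "sign", "radius", "phi", "cyc_T", "cyc_el",
    "commit_prog", "diff_prog", "exit_timer",
)
_BOOL_COLS = ("committed", "exit_bound", "contact")
_INT_COLS = ("cell_id", "clone_id")


class _Cells:
    """Dynamic struct-of-arrays holding all live thymocytes."""

    def __init__(self) -> None:
        self.pos = np.zeros((0, 3))
        for c in _FLOAT_COLS:
            setattr(self, c, np.zeros(0))
        for c in _BOOL_COLS:
            setattr(self, c, np.zeros(0, dtype=bool))
        for c in _INT_COLS:
            setattr(self, c, np.zeros(0, dtype=np.int64))
        self.stage = np.zeros(0, dtype=np.int8)
        self.flags = np.zeros(0, dtype=np.int16)

    @property
    def n(self) -> int:
        return len(self.radius)

    def append(self, rows: dict[str, Any]) -> None:
        k = len(rows["cell_id"])
        self.pos = np.vstack([self.pos, rows["pos"]])
        for c in _FLOAT_COLS:
            setattr(self, c, np.append(getattr(self, c),
                                       np.asarray(rows[c], dtype=float)))
        for c in _BOOL_COLS:
            setattr(self, c, np.append(getattr(self, c),
                                       np.asarray(rows.get(c, [False] * k))))
        for c in _INT_COLS:
            setattr(self, c, np.append(getattr(self, c),
                                       np.asarray(rows[c], dtype=np.int64)))
        self.stage = np.append(self.stage,
                               np.asarray(rows["stage"], dtype=np.int8))
        self.flags = np.append(self.flags,
                               np.asarray(rows["flags"], dtype=np.int16))

    def keep(self, mask: np.ndarray) -> None:
        self.pos = self.pos[mask]
        for c in _FLOAT_COLS + _BOOL_COLS + _INT_COLS + ("stage", "flags"):
            setattr(self, c, getattr(self, c)[mask])


# ----------------------------------------------------------------------

def run_simulation(
    params: SimulationParams,
    record_clone_series: bool = True,
    occupancy_stride: int = 4000,
    keep_niche: bool = False,
) -> SimulationResult:
    """Execute one full virtual-thymus run.

    The loop applies, in order: diffusion substeps, signaling, fate,
    mechanics/motility, immigration/departures, logging. Raises
    :class:`SimulationError` on numerical failure.
    """
    rng = np.random.default_rng(params.seed)
    domain = Domain(params.domain_radius, params.domain_depth)
    niche = build_niche(params, rng)
    grid = CytokineGrid.for_domain(
        domain, params.voxel_size, params.diffusion_coeff,
        params.il7_decay, params.il7_secretion,
    )
    static_source = grid.accumulate_sources(niche)
    il7_norm = sig.il7_normalization(params.il7_reference_peak)
    da_bit = sig.LESION_BITS["IL7R_DA"]
    notchda_bit = sig.LESION_BITS["NOTCH1_DA"]
    autocrine_bit = sig.LESION_BITS["IL7_AUTOCRINE"]
    slow_bit = sig.LESION_BITS["SLOW_SPEED"]
    delayed_bit = sig.LESION_BITS["DELAYED_DIFF"]
    lesion_bits = sig.lesion_flags(params.lesion)

    cells = _Cells()
    dt_hr = params.dt_hr
    dt_s = params.step_duration
    z_mid = domain.depth / 2.0

    next_id = 0
    next_spawn_hr = 0.0
    lesion_pending = params.lesion is not None

    node_birth: dict[int, tuple[int, int, float]] = {}  # id -> (clone, parent, t)
    node_end: dict[int, tuple[float, str]] = {}
    sublineage: dict[int, str] = {}
    founder_records: list[dict] = []
    events: list[tuple] = []
    pop_samples: list[tuple] = []
    field_samples: list[tuple] = []
    clone_samples: list[tuple] = []
    occupancy_records: list[OccupancyRecord] = []
    max_residual = 0.0
    n_clamped = 0

    def _log_event(t_hr: float, kind: str, cell_id: int, clone_id: int,
                   lesioned: bool) -> None:
        events.append((t_hr, kind, cell_id, clone_id, lesioned))

    def _new_cells(k: int, parent: int, clone: int, base_pos: np.ndarray,
                   t_hr: float, u: float, flags: int, stage: int,
                   commit_prog: float, diff_prog: float,
                   sig7: float, sign: float) -> None:
        nonlocal next_id
        ids, rows_pos = [], []
        for _ in range(k):
            ids.append(next_id)
            next_id += 1
        offsets = rng.normal(0.0, 1.0, size=(k, 2))
        norms = np.linalg.norm(offsets, axis=1)
        norms[norms == 0] = 1.0
        offsets = offsets / norms[:, None] * (0.3 * params.thymocyte_radius)
        if k == 1:
            offsets[:] = 0.0
        for i in range(k):
            p = base_pos.copy()
            p[0] += offsets[i, 0]
            p[1] += offsets[i, 1]
            p[2] = z_mid
            rows_pos.append(p)
        cells.append(
            {
                "cell_id": ids,
                "clone_id": [clone] * k,
                "pos": np.asarray(rows_pos),
                "u": [u] * k,
                "sig7": [sig7] * k,
                "sign": [sign] * k,
                "radius": [params.thymocyte_radius] * k,
                "phi": rng.uniform(-np.pi, np.pi, size=k),
                "cyc_T": cyc.draw_cycle_duration(
                    rng, params.mean_cycle_duration, size=k,
                    shape=params.erlang_shape,
                ),
                "cyc_el": [0.0] * k,
                "exit_timer": [0.0] * k,
                "commit_prog": [commit_prog] * k,
                "diff_prog": [diff_prog] * k,
                "stage": [stage] * k,
                "flags": [flags] * k,
            }
        )
        for cid in ids:
            node_birth[cid] = (clone, parent, t_hr)

    for step in range(params.n_steps):
        t_hr = step * dt_hr
        n = cells.n

        # 1 -- cytokine field -------------------------------------------
        sources = static_source
        if n and (cells.flags & autocrine_bit).any():
            auto = (cells.flags & autocrine_bit) > 0
            sources = static_source + grid.accumulate_sources(
                None, cells.pos[auto], cells.radius[auto]
            )
        sinks = None
        if params.depletion and n:
            sinks = grid.accumulate_sinks(
                cells.pos, cells.radius, cells.u,
                params.il7_activation_rate,
                da_mask=(cells.flags & da_bit) > 0,
                efficiency=params.depletion_efficiency,
            )
        try:
            budget = grid.step(dt_s, sources, sinks)
        except FloatingPointError as exc:
            raise SimulationError(str(exc)) from exc
        max_residual = max(max_residual, budget.residual)
        n_clamped += budget.n_clamped

        if n:
            # 2 -- signaling --------------------------------------------
            local = grid.local_mean_concentration(cells.pos, cells.radius)
            cells.sig7 = sig.update_il7_signal(
                cells.sig7, cells.u, local,
                params.il7_activation_rate, params.il7_deactivation_rate,
                dt_hr, da_mask=(cells.flags & da_bit) > 0,
            )
            cells.sign = sig.update_notch_signal(
                cells.sign, cells.contact,
                params.notch_on_rate, params.notch_off_rate, dt_hr,
                pinned_mask=(cells.flags & notchda_bit) > 0,
            )

            # 3 -- fate --------------------------------------------------
            score = sig.combined_proliferative_signal(
                cells.sig7, cells.sign, il7_norm
            )
            cells.committed = cyc.attempt_cycle_entry(
                cells.committed, cells.stage == cyc.STAGE_ETP,
                score, params.proliferation_threshold,
            )
            cells.cyc_el, divide = cyc.advance_cycle(
                cells.committed, cells.cyc_el, cells.cyc_T,
                params.g1_fraction, dt_hr,
            )
            rate_scale = np.where((cells.flags & delayed_bit) > 0, 0.5, 1.0)
            (cells.stage, cells.commit_prog, cells.diff_prog,
             ready) = cyc.advance_differentiation(
                cells.stage, cells.commit_prog, cells.diff_prog, cells.sign,
                params.min_proliferative_duration, rate_scale, dt_hr,
                strict=params.strict_commitment,
            )
            if ready.any():
                positive = cyc.thymic_selection(ready, params.p_select, rng)
                lineage_draw = rng.uniform(size=int(ready.sum())) < 0.5
                for cid, is_a in zip(cells.cell_id[ready], lineage_draw):
                    sublineage[int(cid)] = "lineage_A" if is_a else "lineage_B"
                # positively selected cells dwell as mature naive T cells
                # before drifting out through the ventral surface
                cells.exit_timer = np.where(
                    positive, params.exit_delay, cells.exit_timer
                )
                cells.stage = np.where(
                    positive, cyc.STAGE_DIFFERENTIATED, cells.stage
                ).astype(np.int8)
                negative = ready & ~positive
                cells.stage = np.where(
                    negative, cyc.STAGE_APOPTOTIC, cells.stage
                ).astype(np.int8)
            mature = (cells.stage == cyc.STAGE_DIFFERENTIATED) & ~cells.exit_bound
            if mature.any():
                cells.exit_timer = np.where(
                    mature, cells.exit_timer - dt_hr, cells.exit_timer
                )
                cells.exit_bound = cells.exit_bound | (
                    mature & (cells.exit_timer <= 0.0)
                )
            apop = cells.stage == cyc.STAGE_APOPTOTIC
            if apop.any():
                cells.radius = np.where(
                    apop,
                    cells.radius - params.apoptosis_shrink_rate * dt_hr,
                    cells.radius,
                )

            if divide.any():
                mothers = np.flatnonzero(divide)
                for mi in mothers:
                    mid = int(cells.cell_id[mi])
                    clone = int(cells.clone_id[mi])
                    lesioned = cells.flags[mi] != 0
                    node_end[mid] = (t_hr, "divided")
                    _log_event(t_hr, "divide", mid, clone, bool(lesioned))
                    _new_cells(
                        2, mid, clone, cells.pos[mi], t_hr,
                        float(cells.u[mi]), int(cells.flags[mi]),
                        int(cells.stage[mi]), float(cells.commit_prog[mi]),
                        float(cells.diff_prog[mi]), float(cells.sig7[mi]),
                        float(cells.sign[mi]),
                    )
                keep = np.ones(cells.n, dtype=bool)
                keep[mothers] = False
                cells.keep(keep)

        # 4 -- mechanics and motility -----------------------------------
        n = cells.n
        if n:
            eb = cells.exit_bound
            noise = np.where(
                cells.stage == cyc.STAGE_ETP,
                params.etp_turn_noise, params.thymocyte_turn_noise,
            )
            cells.phi = mech.update_headings(cells.phi, noise, dt_s, rng)
            if eb.any():
                cells.phi = np.where(
                    eb,
                    mech.outward_heading(cells.pos)
                    + rng.normal(0.0, 0.3, size=n),
                    cells.phi,
                )
            speed = np.where(
                cells.stage == cyc.STAGE_ETP,
                params.etp_speed, params.thymocyte_speed,
            )
            speed = np.where(cells.stage == cyc.STAGE_APOPTOTIC, 0.0, speed)
            speed = speed * np.where((cells.flags & slow_bit) > 0, 0.5, 1.0)
            active = mech.active_displacement(cells.phi, speed, dt_s)
            passive, contact = mech.step_forces(
                cells.pos, cells.radius, eb, niche, domain, params
            )
            cells.pos = cells.pos + active + passive
            cells.pos[:, 2] = z_mid
            cells.contact = contact
            if np.abs(cells.pos[:, :2]).max(initial=0.0) > 3 * domain.radius:
                raise SimulationError("runaway cell position")

        # 5 -- immigration ----------------------------------------------
        if t_hr >= next_spawn_hr - 1e-9:
            placed = False
            for _ in range(10):
                cand = mech.spawn_position(domain, params.thymocyte_radius, rng)
                if not mech.spawn_is_blocked(
                    cand, params.thymocyte_radius, cells.pos, cells.radius
                ):
                    placed = True
                    break
            if placed:
                flags = 0
                if lesion_pending and t_hr >= params.lesion_entry_time:
                    flags = lesion_bits
                    lesion_pending = False
                if flags:
                    u = sig.lesioned_il7r_level(params.lesion, rng)
                else:
                    u = float(rng.uniform(0.0, 1.0))
                cid = next_id
                _new_cells(1, -1, cid, cand, t_hr, u, flags,
                           cyc.STAGE_ETP, 0.0, 0.0, 0.0, 0.0)
                founder_records.append(
                    {"clone_id": cid, "homing_hr": t_hr,
                     "lesioned": bool(flags), "il7r_level": u}
                )
                _log_event(t_hr, "spawn", cid, cid, bool(flags))
                next_spawn_hr += params.homing_interval
            # else: spawn blocked; defer to the next step

        # 6 -- departures -----------------------------------------------
        n = cells.n
        if n:
            gone_exit = mech.exit_mask(cells.pos, cells.exit_bound, domain)
            gone_death = mech.death_mask(
                cells.radius, cells.stage == cyc.STAGE_APOPTOTIC,
                params.apoptosis_floor,
            )
            gone = gone_exit | gone_death
            if gone.any():
                for i in np.flatnonzero(gone):
                    cid = int(cells.cell_id[i])
                    clone = int(cells.clone_id[i])
                    lesioned = bool(cells.flags[i])
                    cause = "exited" if gone_exit[i] else "died"
                    node_end[cid] = (t_hr, cause)
                    _log_event(
                        t_hr, "exit" if gone_exit[i] else "die",
                        cid, clone, lesioned,
                    )
                cells.keep(~gone)

        # 7 -- logging ---------------------------------------------------
        if step % params.sample_stride == 0:
            pop_samples.append((t_hr, cells.n))
            mean_il7, _ = grid.summarize_field()
            field_samples.append((t_hr, mean_il7))
            if record_clone_series and cells.n:
                ids_, counts_ = np.unique(cells.clone_id, return_counts=True)
                for cl, ct in zip(ids_, counts_):
                    clone_samples.append((t_hr, int(cl), int(ct)))
        if (
            occupancy_stride
            and step % occupancy_stride == 0
            and t_hr >= HOMEOSTASIS_START_HR
        ):
            occupancy_records.append(
                compute_occupancy(
                    niche, cells.pos, cells.radius, domain, rng,
                    n_samples=30_000,
                )
            )

    # -- finalize ---------------------------------------------------------
    end_hr = params.total_time_hr
    for cid in cells.cell_id:
        node_end[int(cid)] = (end_hr, "alive_at_end")
    node_records = [
        {
            "cell_id": cid,
            "clone_id": clone,
            "parent_id": parent,
            "birth_hr": birth,
            "end_hr": node_end.get(cid, (np.nan, "alive_at_end"))[0],
            "end_cause": node_end.get(cid, (np.nan, "alive_at_end"))[1],
            "sublineage": sublineage.get(cid, "undecided"),
        }
        for cid, (clone, parent, birth) in node_birth.items()
    ]
    forest = LineageForest(
        nodes=pd.DataFrame(
            node_records,
            columns=["cell_id", "clone_id", "parent_id", "birth_hr",
                     "end_hr", "end_cause", "sublineage"],
        ),
        founders=pd.DataFrame(
            founder_records,
            columns=["clone_id", "homing_hr", "lesioned", "il7r_level"],
        ),
    )
    population = pd.DataFrame(pop_samples, columns=["time_hr", "count"])
    try:
        h_mean, h_sd = None, None
        window = population[population.time_hr >= HOMEOSTASIS_START_HR]
        if not window.empty:
            h_mean = float(window["count"].mean())
            h_sd = float(window["count"].std(ddof=0))
    except Exception:  # pragma: no cover - defensive
        h_mean = h_sd = None
    _, projection = grid.summarize_field()
    return SimulationResult(
        params=params,
        population=population,
        homeostatic_mean=h_mean if h_mean is not None else np.nan,
        homeostatic_sd=h_sd if h_sd is not None else np.nan,
        occupancy=occupancy_records,
        field_summary=pd.DataFrame(
            field_samples, columns=["time_hr", "mean_il7"]
        ),
        forest=forest,
        events=pd.DataFrame(
            events,
            columns=["time_hr", "event", "cell_id", "clone_id", "lesioned"],
        ),
        clone_series=pd.DataFrame(
            clone_samples, columns=["time_hr", "clone_id", "count"]
        ),
        final_projection=projection,
        max_budget_residual=max_residual,
        n_sink_clamped=n_clamped,
        niche=niche if keep_niche else None,
    )


# ----------------------------------------------------------------------

def run_scan(
    scenarios: Sequence[SimulationParams],
    labels: Sequence[str] | None = None,
    record_clone_series: bool = False,
) -> pd.DataFrame:
    """Run every scenario and aggregate one summary row per run.

    Individual failures are recorded as failed rows and the scan continues;
    results are independent of execution order (each run owns its seed).
    """
    if len(scenarios) == 0:
        raise ValueError("scan list is empty")
    if labels is None:
        labels = [f"run{i}" for i in range(len(scenarios))]
    rows = []
    for label, p in zip(labels, scenarios):
        row: dict[str, Any] = {
            "label": label,
            "seed": p.seed,
            "n_subdivisions": p.n_subdivisions,
            "n_protrusions": p.n_protrusions,
            "tec_radius": p.tec_radius,
            "depletion": p.depletion,
            "il7_activation_rate": p.il7_activation_rate,
            "il7_deactivation_rate": p.il7_deactivation_rate,
            "il7_expression_mode": p.il7_expression_mode,
            "lesion": ",".join(sorted(p.lesion.kinds)) if p.lesion else "",
            "status": "ok",
        }
        try:
            res = run_simulation(
                p, record_clone_series=record_clone_series,
                occupancy_stride=0,
            )
            row["homeostatic_mean"] = res.homeostatic_mean
            row["homeostatic_sd"] = res.homeostatic_sd
            normal = res.forest.clone_sizes(lesioned=False)
            row["rounds_normal"] = (
                rounds_of_division(normal) if len(normal) else np.nan
            )
            lesioned = res.forest.clone_sizes(lesioned=True)
            row["rounds_lesioned"] = (
                rounds_of_division(lesioned) if len(lesioned) else np.nan
            )
        except Exception as exc:
            row["status"] = f"failed: {exc.__class__.__name__}"
            row["homeostatic_mean"] = np.nan
            row["homeostatic_sd"] = np.nan
            row["rounds_normal"] = np.nan
            row["rounds_lesioned"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
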