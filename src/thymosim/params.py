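"""Scenario configuration: parameter sets, lesion catalogue, scans.

A simulation is fully specified by a :class:`SimulationParams` object. The
biologically varied parameters (TEC placement density ``n_subdivisions``,
protrusion number, TEC radius, IL-7 depletion flag, IL-7 signaling rates,
proliferation threshold, cell-cycle mean, minimum proliferative duration)
carry the reference values of the embryonic medaka thymus model as defaults;
everything else (domain size, motility, Notch kinetics, cytokine constants,
selection probability) is a calibration constant frozen against the reference
configuration and exposed here for transparency.

Configs are human-readable YAML files with a ``schema_version`` key; omitted
keys fall back to the reference defaults. Named scenarios (the architecture
scan s1–s26, the IL-7 signaling scan, and the lesion screens) are shipped as
a YAML catalogue inside the package.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

SCHEMA_VERSION = 1

#: Lesion kinds that can be applied to the single lesioned founder clone.
LESION_KINDS = frozenset(
    {
        "IL7R_WT",
        "IL7R_DA",
        "IL7R_HI",
        "IL7_AUTOCRINE",
        "NOTCH1_DA",
        "DELAYED_DIFF",
        "SLOW_SPEED",
    }
)

#: Parameter levels explored by the published scans; values outside these
#: levels are accepted but flagged as exploratory.
SCAN_LEVELS = {
    "n_subdivisions": (2, 3, 4),
    "n_protrusions": (3, 4, 5),
    "tec_radius": (2.0, 2.5, 3.0),
}

IL7_EXPRESSION_MODES = ("cortical_subset", "all_tecs", "none")


class ConfigError(ValueError):
    """A config file failed to parse or named an unknown key."""


class ValidationError(ValueError):
    """A parameter combination violates a model invariant."""


class UnknownScenarioError(KeyError):
    """A scenario label is not in the shipped catalogue."""


@dataclass(frozen=True)
class LesionSpec:
    """Lesion(s) carried by the single lesioned founder clone and its progeny.

    ``kinds`` is a set because lesions compose (e.g. a dominant-active IL7R
    clone that also differentiates slowly). ``IL7R_DA`` and ``IL7R_HI`` are
    mutually exclusive; ``il7r_hi_level`` is the receptor level used by
    ``IL7R_HI`` (10-fold the wild-type maximum of 1 by default).
    """

    kinds: frozenset[str] = frozenset()
    il7r_hi_level: float = 10.0

    def __post_init__(self) -> None:
        unknown = set(self.kinds) - LESION_KINDS
        if unknown:
            raise ValidationError(f"unknown lesion kinds: {sorted(unknown)}")
        if "IL7R_DA" in self.kinds and "IL7R_HI" in self.kinds:
            raise ValidationError("IL7R_DA and IL7R_HI are mutually exclusive")
        if not self.il7r_hi_level > 1:
            raise ValidationError(
                "il7r_hi_level must exceed the wild-type maximum of 1"
            )
        object.__setattr__(self, "kinds", frozenset(self.kinds))

    def to_dict(self) -> dict[str, Any]:
        return {"kinds": sorted(self.kinds), "il7r_hi_level": self.il7r_hi_level}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "LesionSpec":
        extra = set(d) - {"kinds", "il7r_hi_level"}
        if extra:
            raise ConfigError(f"unknown lesion keys: {sorted(extra)}")
        return cls(
            kinds=frozenset(d.get("kinds", ())),
            il7r_hi_level=float(d.get("il7r_hi_level", 10.0)),
        )


@dataclass(frozen=True)
class SimulationParams:
    """Complete parameterization of one virtual-thymus run.

    The first block holds the parameters varied in the published scans
    (reference values as defaults); the second block fixes the simulated
    clock; the remaining fields are model constants calibrated once on the
    reference configuration (homeostatic population, ~3-day transit,
    thymocyte/TEC volume shares) and then frozen for every scenario.
    """

    # -- scanned parameters (reference defaults) --
    n_subdivisions: int = 3          # N: concentric TEC-placement subdivisions
    n_protrusions: int = 4           # p_TEC: protrusion chains per TEC
    tec_radius: float = 2.5          # r_TEC, um; also scales protrusion spheres
    depletion: bool = False          # DEPL: thymocytes internalize IL-7
    il7_activation_rate: float = 240.0    # a_IL-7, 1/hr
    il7_deactivation_rate: float = 50.0   # d_IL-7, 1/hr
    proliferation_threshold: float = 1.4  # theta_prol, combined-signal G1 gate
    mean_cycle_duration: float = 7.0      # mu, hr
    min_proliferative_duration: float = 24.0  # T_diff, hr
    il7_expression_mode: str = "cortical_subset"
    il7_cortical_fraction: float = 0.5  # secreting fraction of cortical TECs

    # -- clock --
    step_duration: float = 15.0      # s per agent step
    n_steps: int = 48_000            # 720,000 s ~ 8.3 days

    # -- lesion scenario --
    lesion: LesionSpec | None = None
    lesion_entry_time: float = 60.0  # hr; first immigrant after this is flagged

    # -- replication --
    seed: int = 0
    replicate_count: int = 1

    # -- domain geometry (calibration constants) --
    domain_radius: float = 46.0      # um, half-disc radius
    domain_depth: float = 5.0        # um, slice thickness
    thymocyte_radius: float = 2.5    # um
    tec_spacing_factor: float = 2.6  # arc spacing in units of tec_radius
    protrusion_ratio: float = 0.5    # protrusion sphere radius / body radius
    protrusion_spheres: int = 3      # tangent spheres per protrusion chain

    # -- immigration / departure --
    homing_interval: float = 1.5     # hr between ETP immigrations
    p_select: float = 0.73           # positive-selection probability
    exit_delay: float = 14.0         # hr maturation dwell before exit drift
    apoptosis_shrink_rate: float = 1.0  # um/hr radius shrink when apoptotic
    apoptosis_floor: float = 1.0     # um; removal radius

    # -- motility (um/min; persistence as heading-noise SD, rad/sqrt(min)) --
    etp_speed: float = 4.0
    thymocyte_speed: float = 2.0
    etp_turn_noise: float = 0.6
    thymocyte_turn_noise: float = 1.2

    # -- mechanics --
    relaxation_per_step: float = 0.2   # fraction of pair overlap relaxed/step
    adhesion_ratio: float = 0.25       # adhesive vs repulsive stiffness
    adhesion_range: float = 1.2        # adhesive shell, units of contact dist

    # -- IL-7 cytokine field --
    voxel_size: float = 2.5          # um
    diffusion_coeff: float = 1.0     # D_IL-7, um^2/s
    il7_decay: float = 0.08          # k_IL-7, 1/s
    il7_secretion: float = 2.9e-4    # s_i, conc units/s per source voxel
    il7_reference_peak: float = 1.0 / 240.0  # c*, normalization concentration
    depletion_efficiency: float = 0.1  # signaling->concentration conversion

    # -- Notch signaling --
    notch_contact_range: float = 0.5  # um surface gap counting as contact
    notch_on_rate: float = 1.0        # 1/hr rise toward max under contact
    notch_off_rate: float = 2.5       # 1/hr decay without contact

    # -- cell cycle / differentiation --
    erlang_shape: int = 50
    g1_fraction: float = 0.5
    commitment_floor: float = 0.25    # zero-Notch commitment-rate floor
    strict_commitment: bool = False   # rate strictly proportional to Notch

    # -- output --
    sample_stride: int = 40           # population sampling, steps

    def __post_init__(self) -> None:
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if self.n_subdivisions < 1:
            raise ValidationError("n_subdivisions must be >= 1")
        if self.n_protrusions < 0:
            raise ValidationError("n_protrusions must be >= 0")
        if not self.proliferation_threshold > 0:
            raise ValidationError("proliferation_threshold must be > 0")
        if not self.mean_cycle_duration > 0:
            raise ValidationError("mean_cycle_duration must be > 0")
        for name in ("il7_activation_rate", "il7_deactivation_rate",
                     "il7_decay", "diffusion_coeff", "il7_secretion"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.p_select <= 1.0:
            raise ValidationError("p_select must lie in [0, 1]")
        if self.il7_expression_mode not in IL7_EXPRESSION_MODES:
            raise ValidationError(
                f"il7_expression_mode must be one of {IL7_EXPRESSION_MODES}"
            )
        if self.tec_radius <= 0 or self.thymocyte_radius <= 0:
            raise ValidationError("cell radii must be positive")
        if self.step_duration <= 0 or self.n_steps < 1:
            raise ValidationError("clock must be positive")
        if self.replicate_count < 1:
            raise ValidationError("replicate_count must be >= 1")
        for key, levels in SCAN_LEVELS.items():
            value = getattr(self, key)
            if value not in levels:
                warnings.warn(
                    f"{key}={value} is outside the scanned levels {levels}; "
                    "accepted as exploratory",
                    stacklevel=3,
                )

    # ------------------------------------------------------------------
    def replace(self, **overrides: Any) -> "SimulationParams":
        """Return a copy with ``overrides`` applied (re-validated)."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["lesion"] = self.lesion.to_dict() if self.lesion else None
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationParams":
        d = dict(d)
        d.pop("schema_version", None)
        lesion = d.pop("lesion", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if lesion is not None and not isinstance(lesion, LesionSpec):
            lesion = LesionSpec.from_dict(lesion)
        return cls(lesion=lesion, **d)

    # -- derived quantities -------------------------------------------
    @property
    def total_time_hr(self) -> float:
        return self.n_steps * self.step_duration / 3600.0

    @property
    def dt_hr(self) -> float:
        return self.step_duration / 3600.0


# ----------------------------------------------------------------------
# Config file I/O
# ----------------------------------------------------------------------

def load_config(path: str | Path) -> SimulationParams:
    """Load a YAML config, applying reference defaults for omitted keys.

    An empty file yields the reference parameterization. Unknown keys raise
    :class:`ConfigError` naming the offending key; invariant violations raise
    :class:`ValidationError`.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return SimulationParams.from_dict(raw)


def save_config(params: SimulationParams, path: str | Path) -> None:
    """Serialize ``params`` so that :func:`load_config` round-trips."""
    Path(path).write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=True, default_flow_style=False)
    )


# ----------------------------------------------------------------------
# Named scenarios
# ----------------------------------------------------------------------

def _architecture_catalogue() -> dict[str, dict[str, Any]]:
    """Number the 26 non-reference TEC-architecture permutations.

    The published scan names only scenarios 1 (smaller TECs, everything else
    at reference), 6 (all three architecture parameters at their low level)
    and 26 (all three at their high level); the remaining permutations are
    numbered in lexicographic (N, p_TEC, r_TEC) order as a documented
    convention of this package, not a fact of the study.
    """
    reference = (3, 4, 2.5)
    pinned = {(3, 4, 2.0): "s1", (2, 3, 2.0): "s6", (4, 5, 3.0): "s26"}
    combos = [
        c
        for c in itertools.product(
            SCAN_LEVELS["n_subdivisions"],
            SCAN_LEVELS["n_protrusions"],
            SCAN_LEVELS["tec_radius"],
        )
        if c != reference
    ]
    free_labels = iter(
        f"s{i}" for i in range(1, 27) if f"s{i}" not in pinned.values()
    )
    catalogue: dict[str, dict[str, Any]] = {}
    for combo in sorted(combos):
        label = pinned.get(combo, None) or next(free_labels)
        n, p, r = combo
        catalogue[label] = {
            "n_subdivisions": n,
            "n_protrusions": p,
            "tec_radius": r,
        }
    return catalogue


def _signaling_catalogue() -> dict[str, dict[str, Any]]:
    # IL-7 signaling scan: the four scenarios the study reports numerically.
    return {
        "s27": {"il7_expression_mode": "all_tecs"},
        "s28": {"il7_expression_mode": "none"},
        "s29": {"depletion": False, "il7_deactivation_rate": 100.0,
                "il7_activation_rate": 120.0},
        "s36": {"depletion": True, "il7_deactivation_rate": 50.0,
                "il7_activation_rate": 240.0},
        "s44": {"depletion": True, "il7_deactivation_rate": 25.0,
                "il7_activation_rate": 480.0},
        "s45": {"depletion": False, "il7_deactivation_rate": 25.0,
                "il7_activation_rate": 480.0},
    }


def _lesion_catalogue() -> dict[str, dict[str, Any]]:
    single = {
        "lesion-il7r-wt": ["IL7R_WT"],
        "lesion-il7r-da": ["IL7R_DA"],
        "lesion-il7r-hi": ["IL7R_HI"],
        "lesion-il7-autocrine": ["IL7_AUTOCRINE"],
        "lesion-notch1-da": ["NOTCH1_DA"],
        "lesion-delayed-diff": ["DELAYED_DIFF"],
        "lesion-slow-speed": ["SLOW_SPEED"],
    }
    return {label: {"lesion": {"kinds": kinds}} for label, kinds in single.items()}


def _builtin_catalogue() -> dict[str, dict[str, Any]]:
    catalogue: dict[str, dict[str, Any]] = {"reference": {}}
    catalogue.update(_architecture_catalogue())
    catalogue.update(_signaling_catalogue())
    catalogue.update(_lesion_catalogue())
    return catalogue


def _load_catalogue() -> dict[str, dict[str, Any]]:
    """Scenario catalogue, preferring the shipped data file."""
    try:
        text = (
            importlib.resources.files("thymosim") / "data" / "scenarios.yaml"
        ).read_text()
        loaded = yaml.safe_load(text)
        if isinstance(loaded, Mapping):
            return {k: (v or {}) for k, v in loaded.items()}
    except (FileNotFoundError, ModuleNotFoundError, yaml.YAMLError):
        pass
    return _builtin_catalogue()


def scenario_catalogue() -> dict[str, dict[str, Any]]:
    """All named scenarios as {label: parameter overrides}."""
    return dict(_load_catalogue())


def named_scenario(label: str, **overrides: Any) -> SimulationParams:
    """Resolve a scenario label from the catalogue to full parameters.

    Raises :class:`UnknownScenarioError` listing the available labels for an
    unknown label. Extra keyword overrides (e.g. ``seed``) are applied on top.
    """
    catalogue = _load_catalogue()
    if label not in catalogue:
        raise UnknownScenarioError(
            f"unknown scenario {label!r}; available: {sorted(catalogue)}"
        )
    merged = dict(catalogue[label])
    merged.update(overrides)
    return SimulationParams.from_dict(merged)


# ----------------------------------------------------------------------
# Scan expansion and seed derivation
# ----------------------------------------------------------------------

_SEED_MULTIPLIER = 1_000_003
_SEED_MOD = 2**31


def derive_seed(base_seed: int, flat_index: int) -> int:
    """Deterministic per-run seed below 2^31.

    Counter-based: injective over flat indices smaller than 2^31, so distinct
    (scenario, replicate) slots always receive distinct stream seeds.
    """
    return (base_seed * _SEED_MULTIPLIER + flat_index) % _SEED_MOD


def expand_scan(
    grid: Mapping[str, Sequence[Any]],
    replicates: int = 1,
    base_seed: int = 0,
    base: SimulationParams | None = None,
) -> list[SimulationParams]:
    """Cartesian product of parameter levels x replicates.

    Every entry receives a distinct deterministic seed derived from
    ``base_seed``; calling twice with the same arguments yields an identical
    list.
    """
    if base is None:
        base = SimulationParams()
    known = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(grid) - known
    if unknown:
        raise ValidationError(f"unknown scan keys: {sorted(unknown)}")
    for key, levels in grid.items():
        if len(levels) == 0:
            raise ValidationError(f"scan key {key!r} has no levels")
    keys = list(grid)
    out: list[SimulationParams] = []
    flat = 0
    for values in itertools.product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, values))
        for rep in range(replicates):
            out.append(
                base.replace(
                    seed=derive_seed(base_seed, flat),
                    replicate_count=1,
                    **overrides,
                )
            )
            flat += 1
    return out
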