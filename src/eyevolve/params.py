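"""Simulation parameters, validation, YAML configs, and the seven presets.

Distance-like founder/wave parameters are expressed in mean cell diameters
(multiples of 2 * avg_cell_size): the exclusion radius as *clear* spacing
between founders, edge margins and wave ranges as center distances.
Furrow-event offsets ("distance from furrow") and the furrow velocity are
raw world units.  See ``specification.distance_to_world`` and
``specification.exclusion_to_world``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources

import yaml

from .epithelium import ParameterError

PRESET_NAMES = (
    "drosophila",
    "strepsiptera",
    "lepidoptera_larva",
    "diving_beetle",
    "ocelli",
    "one_eye_expansion",
    "one_eye_fusion",
)


@dataclass(frozen=True)
class FounderParams:
    """Founder (R8-like) selection: spacing and placement of unit-seeding cells."""

    exclusion_radius: float  # minimal founder spacing, cell diameters
    target_radius: float  # world units
    min_distance_from_edge: float  # cell diameters
    distance_from_furrow: float = 0.0  # world units behind the furrow

    def validate(self) -> None:
        for name in ("exclusion_radius", "target_radius", "min_distance_from_edge", "distance_from_furrow"):
            if getattr(self, name) < 0:
                raise ParameterError(f"founder.{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class WaveParams:
    """One photoreceptor recruitment wave (R2/R5-, R3/R4- or R1/R6-like)."""

    selection_count: int  # cells recruited per unit
    target_radius: float  # world units
    max_distance_from_r8: float  # cell diameters
    distance_from_furrow: float  # world units behind the furrow

    def validate(self, which: str = "wave") -> None:
        if not float(self.selection_count).is_integer() or self.selection_count < 0:
            raise ParameterError(
                f"{which}.selection_count must be a non-negative integer, got {self.selection_count}"
            )
        for name in ("target_radius", "max_distance_from_r8", "distance_from_furrow"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{which}.{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class BorderParams:
    """Border (pigment/support) cell recruitment in concentric contact layers."""

    border_radius: int  # number of layers
    target_radius: float  # world units
    distance_from_furrow: float  # world units behind the furrow

    def validate(self) -> None:
        if not float(self.border_radius).is_integer() or self.border_radius < 0:
            raise ParameterError(
                f"border.border_radius must be a non-negative integer, got {self.border_radius}"
            )
        for name in ("target_radius", "distance_from_furrow"):
            if getattr(self, name) < 0:
                raise ParameterError(f"border.{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class DeathParams:
    """Apoptotic pruning of still-undifferentiated cells behind the furrow."""

    death_chance: float  # percent, [0, 100], applied per cycle
    distance_from_furrow: float  # world units behind the furrow
    one_shot: bool = False  # if set, each cell draws its death lottery once

    def validate(self) -> None:
        if not (0.0 <= self.death_chance <= 100.0):
            raise ParameterError(f"death.death_chance must be in [0, 100], got {self.death_chance}")
        if self.distance_from_furrow < 0:
            raise ParameterError(
                f"death.distance_from_furrow must be >= 0, got {self.distance_from_furrow}"
            )


@dataclass(frozen=True)
class SimulationParams:
    """The full input parameter set for one simulation run."""

    min_cell_count: int
    avg_cell_size: float
    cell_size_variance: float
    cell_max_size: float
    cell_growth_rate: float
    furrow_velocity: float
    founder: FounderParams
    waves: tuple[WaveParams, WaveParams, WaveParams]
    border: BorderParams
    death: DeathParams
    simulation_speed: float = 100.0  # display throttle; ignored headless
    seed: int | None = None
    name: str = "custom"

    def validate(self) -> None:
        if not float(self.min_cell_count).is_integer() or self.min_cell_count < 1:
            raise ParameterError(
                f"min_cell_count must be a positive integer, got {self.min_cell_count}"
            )
        for nm in ("avg_cell_size", "cell_max_size"):
            if getattr(self, nm) <= 0:
                raise ParameterError(f"{nm} must be positive, got {getattr(self, nm)}")
        for nm in ("cell_size_variance", "cell_growth_rate", "simulation_speed"):
            if getattr(self, nm) < 0:
                raise ParameterError(f"{nm} must be >= 0, got {getattr(self, nm)}")
        if self.furrow_velocity <= 0:
            raise ParameterError(f"furrow_velocity must be positive, got {self.furrow_velocity}")
        self.founder.validate()
        if len(self.waves) != 3:
            raise ParameterError(f"exactly 3 waves are required, got {len(self.waves)}")
        for k, w in enumerate(self.waves, start=1):
            w.validate(f"wave{k}")
        self.border.validate()
        self.death.validate()

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["waves"] = [asdict(w) for w in self.waves]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        try:
            founder = FounderParams(**d.pop("founder"))
            waves = tuple(WaveParams(**w) for w in d.pop("waves"))
            border = BorderParams(**d.pop("border"))
            death = DeathParams(**d.pop("death"))
        except TypeError as e:
            raise ParameterError(f"bad parameter structure: {e}") from None
        return cls(founder=founder, waves=waves, border=border, death=death, **d)


def load_config(path) -> SimulationParams:
    """Read a YAML config mirroring the SimulationParams field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    p = SimulationParams.from_dict(data)
    p.validate()
    return p


def save_config(params: SimulationParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_preset(name: str, variant: str | None = None) -> SimulationParams:
    """Return one of the seven named parameter presets.

    ``one_eye_fusion`` carries two exclusion-radius variants,
    ``early_fusion`` (0.8) and ``late_fusion`` (1, the default).
    """
    if name not in PRESET_NAMES:
        raise ParameterError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    text = resources.files("eyevolve").joinpath("presets", f"{name}.yaml").read_text()
    data = yaml.safe_load(text)
    variants = data.pop("variants", {})
    if variant is not None:
        if variant not in variants:
            raise ParameterError(
                f"preset {name!r} has no variant {variant!r}; "
                f"valid variants: {', '.join(variants) or '(none)'}"
            )
        for key, sub in variants[variant].items():
            if isinstance(sub, dict):
                data[key] = {**data[key], **sub}
            else:
                data[key] = sub
    p = SimulationParams.from_dict(data)
    p.validate()
    return p
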