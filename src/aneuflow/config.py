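"""Case configuration: a YAML-serializable description of one simulation.

A case config fully determines a run (geometry, inlet waveform, rheology,
numerics, age-transport protocol and report thresholds), so identical
configs give bit-identical outputs.  Bundled constructors provide the
standard study conditions: a two-sac comparison channel driven by the
printed case-1 inlet parameters (271.7 mL/min at 63 bpm).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError
from .geometry import Geometry2D, make_channel_aneurysm_geometry
from .rheology import RheologyParams
from .solver import NumericsConfig
from .waveform import InletWaveform, make_inlet_waveform

__all__ = ["CaseConfig", "two_sac_comparison", "straight_channel",
           "bifurcation_case"]

#: disturbed-flow threshold on max RRT (1/Pa); sacs above it are flagged
DEFAULT_RRT_THRESHOLD = 2.0


@dataclass
class CaseConfig:
    case_id: str
    geometry: dict = field(default_factory=dict)
    waveform: dict = field(default_factory=dict)
    rheology: dict = field(default_factory=lambda: {"model": "herschel_bulkley"})
    numerics: dict = field(default_factory=dict)
    age: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=lambda: {
        "rrt_per_pa": DEFAULT_RRT_THRESHOLD})

    # -- builders --------------------------------------------------------

    def build_geometry(self) -> Geometry2D:
        g = dict(self.geometry)
        try:
            return make_channel_aneurysm_geometry(
                channel_width=g["channel_width"],
                channel_length=g["channel_length"],
                sac_specs=g.get("sacs", []),
                grid_spacing=g.get("grid_spacing", 4e-4),
                outlet_spec=g.get("outlet_spec"),
            )
        except KeyError as e:
            raise ConfigError(f"geometry config missing key {e}") from None

    def build_waveform(self) -> InletWaveform:
        w = dict(self.waveform)
        try:
            return make_inlet_waveform(
                q_mean=w["q_mean_ml_min"],
                heart_rate=w["heart_rate_bpm"],
                shape=w.get("shape", "ica"),
                n_samples=w.get("n_samples", 200),
            )
        except KeyError as e:
            raise ConfigError(f"waveform config missing key {e}") from None

    def build_rheology(self) -> RheologyParams:
        return RheologyParams(**self.rheology)

    def build_numerics(self) -> NumericsConfig:
        return NumericsConfig(**self.numerics)

    @property
    def age_cycles(self) -> int:
        return int(self.age.get("cycles", 5))

    @property
    def age_scheme(self) -> str:
        return self.age.get("scheme", "upwind")

    @property
    def slope_window_cycles(self) -> int:
        return int(self.age.get("slope_window_cycles", 3))

    @property
    def rrt_threshold(self) -> float:
        return float(self.thresholds.get("rrt_per_pa", DEFAULT_RRT_THRESHOLD))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        if "case_id" not in d:
            raise ConfigError("config must define a case_id")
        known = {"case_id", "geometry", "waveform", "rheology", "numerics",
                 "age", "thresholds"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: not a mapping")
        return cls.from_dict(d)

    def digest(self) -> str:
        """Stable hash of the canonicalized config."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        """Build every component once to surface config errors early."""
        self.build_geometry()
        self.build_waveform()
        self.build_rheology()
        self.build_numerics()


# ---------------------------------------------------------------------------
# bundled study conditions
# ---------------------------------------------------------------------------


def two_sac_comparison(grid_spacing: float = 4e-4,
                       rheology_model: str = "herschel_bulkley") -> CaseConfig:
    """The standard two-sac discriminant case.

    A 4 mm parent channel (case-1 inlet conditions: 271.7 mL/min at 63 bpm)
    carries two sidewall sacs: ``stagnant`` is a deep 8 mm pocket behind a
    3.2 mm neck (narrow-neck, poorly washed - the atherosclerosis-prone
    archetype) and ``washed`` is a small shallow 4.2 mm pocket behind a
    4 mm neck (wide-neck relative to its dome, well flushed), echoing the
    small-washed versus large-stagnant pairing seen clinically.
    """
    return CaseConfig(
        case_id=f"two-sac-{rheology_model}",
        geometry={
            "channel_width": 4e-3,
            "channel_length": 4e-2,
            "grid_spacing": grid_spacing,
            "sacs": [
                {"diameter": 8e-3, "neck_width": 3.2e-3, "position": 1.4e-2,
                 "side": "top", "name": "stagnant"},
                {"diameter": 4.2e-3, "neck_width": 4e-3, "position": 2.8e-2,
                 "side": "top", "name": "washed"},
            ],
        },
        waveform={"q_mean_ml_min": 271.7, "heart_rate_bpm": 63.0,
                  "shape": "ica"},
        rheology={"model": rheology_model},
        numerics={},
        age={"cycles": 5, "scheme": "upwind", "slope_window_cycles": 3},
    )


def straight_channel(grid_spacing: float = 4e-4) -> CaseConfig:
    """A sac-free control channel under the same inlet conditions."""
    return CaseConfig(
        case_id="straight-channel",
        geometry={"channel_width": 4e-3, "channel_length": 2e-2,
                  "grid_spacing": grid_spacing, "sacs": []},
        waveform={"q_mean_ml_min": 271.7, "heart_rate_bpm": 63.0,
                  "shape": "ica"},
    )


def bifurcation_case(grid_spacing: float = 4e-4) -> CaseConfig:
    """A channel with one branch outlet split by Murray's law (2:1 diameters)."""
    return CaseConfig(
        case_id="bifurcation",
        geometry={
            "channel_width": 4e-3, "channel_length": 3e-2,
            "grid_spacing": grid_spacing, "sacs": [],
            "outlet_spec": {"diameters": [4e-3, 2e-3],
                            "branch_position": 2.2e-2},
        },
        waveform={"q_mean_ml_min": 271.7, "heart_rate_bpm": 63.0,
                  "shape": "ica"},
    )
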