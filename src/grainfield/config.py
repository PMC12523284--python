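"""Run configuration: schema, validation, YAML loading.

A single YAML document configures a whole run -- geometry, material
closures, weather forcing, solver controls, campaign source (CSV path or
synthetic generator), initialization and diagnostics settings.  The
parsed configuration is validated before any computation and echoed
verbatim into the run manifest for reproducibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .boundary_forcing import ForcingScenario
from .material_models import MaterialParams
from .pde_core import Mesh, SolverConfig
from .sensor_data import ColdCore, SensorArrayLayout, TruthField

__all__ = ["RunConfig", "load_config", "default_config_dict"]

_SECTION_KEYS = {"geometry", "material", "forcing", "solver", "campaign",
                 "initialization", "diagnostics", "run"}


def default_config_dict() -> dict:
    """The packaged synthetic-twin configuration (August campaign,
    three-cold-core truth, XOZ plane)."""
    return {
        "geometry": {"plane": "XOZ", "width": 24.0, "height": 6.0,
                     "spacing": 0.1},
        "material": {},
        "forcing": {"mean_C": 24.0, "amplitude_C": 6.0},
        "solver": {"dt": 600.0},
        "campaign": {
            "synthetic": {
                "days": 31, "noise_sd": 0.1, "outlier_rate": 0.0,
                "start": "2020-08-01",
                "truth": {
                    "background_C": 16.8, "trend_C_per_day": 0.05,
                    "cores": [
                        {"center": [0.9, 2.0], "sigma": 1.1, "depth": 3.0},
                        {"center": [12.0, 3.0], "sigma": 2.2, "depth": 3.5},
                        {"center": [23.1, 4.0], "sigma": 1.1, "depth": 3.0},
                    ],
                },
            },
        },
        "initialization": {"tol": 0.1, "max_iter": 25, "nudge_lambda": 0.5,
                           "plane_offset": 7.5, "slab_halfwidth": 1.0,
                           "sampling_moisture_wb": 14.0},
        "diagnostics": {"threshold_C": 15.0, "min_zone_area": 0.05},
        "run": {"start_date": "2020-08-01", "days": 31, "seed": 0,
                "mode": "model"},
    }


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration plus the raw document it came from."""

    raw: dict = field(default_factory=default_config_dict)

    def __post_init__(self) -> None:
        unknown = set(self.raw) - _SECTION_KEYS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        # construct everything eagerly so schema errors surface before
        # any computation starts
        self.mesh()
        self.material()
        self.forcing()
        self.solver()
        self.truth_field()
        self.layout()
        run = self.raw.get("run", {})
        if run.get("days", 31) < 1:
            raise ValueError("run.days must be at least 1")
        if run.get("mode", "model") not in ("model", "truth"):
            raise ValueError("run.mode must be 'model' or 'truth'")

    def _sec(self, name: str) -> dict:
        return dict(self.raw.get(name, {}))

    def mesh(self) -> Mesh:
        return Mesh(**self._sec("geometry"))

    def material(self) -> MaterialParams:
        sec = self._sec("material")
        tup = {k: tuple(v) for k, v in sec.items() if isinstance(v, list)}
        return MaterialParams(**{**sec, **tup})

    def forcing(self) -> ForcingScenario:
        sec = self._sec("forcing")
        if "series" in sec and sec["series"] is not None:
            sec["series"] = tuple(tuple(p) for p in sec["series"])
        return ForcingScenario(**sec)

    def solver(self) -> SolverConfig:
        sec = self._sec("solver")
        sec.setdefault("seed", self.seed)
        return SolverConfig(**sec)

    def layout(self) -> SensorArrayLayout:
        sec = self._sec("campaign").get("layout", {})
        if "layer_heights" in sec:
            sec["layer_heights"] = tuple(sec["layer_heights"])
        return SensorArrayLayout(**sec)

    def truth_field(self) -> TruthField:
        synth = self._sec("campaign").get("synthetic", {})
        t = dict(synth.get("truth", {}))
        cores = t.pop("cores", None)
        if cores is not None:
            t["cores"] = tuple(
                ColdCore(center=tuple(c["center"]), sigma=c["sigma"],
                         depth=c["depth"]) for c in cores)
        return TruthField(**t)

    @property
    def seed(self) -> int:
        return int(self.raw.get("run", {}).get("seed", 0))

    @property
    def run(self) -> dict:
        return self._sec("run")

    @property
    def campaign(self) -> dict:
        return self._sec("campaign")

    @property
    def initialization(self) -> dict:
        return self._sec("initialization")

    @property
    def diagnostics(self) -> dict:
        return self._sec("diagnostics")

    def with_overrides(self, **updates) -> "RunConfig":
        """New config with dotted-path overrides, e.g.
        ``with_overrides(**{"run.seed": 3})``."""
        import copy
        raw = copy.deepcopy(self.raw)
        for key, value in updates.items():
            parts = key.split(".")
            node = raw
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = value
        return RunConfig(raw=raw)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (packaged default when ``path`` is None)."""
    if path is None:
        raw = default_config_dict()
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = default_config_dict()
        for k, v in raw.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                base[k].update(v)
            else:
                base[k] = v
        raw = base
    cfg = RunConfig(raw=raw)
    if overrides:
        cfg = cfg.with_overrides(**overrides)
    return cfg
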