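"""Run configuration: serializable bundle of every module's parameters.

A RunConfig owns one parameter group per module (network weights and unit
constants, plant constants, integrator settings, learning-rule constants)
plus the configuration name and seed.  YAML (or JSON) files hold only the
keys that differ from the defaults; unknown keys are rejected with the
offending name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .biomech import (ArmParams, GTOParams, Geometry, MuscleParams,
                      PlanarArm, SpindleParams)
from .engine import Engine, IntegratorConfig
from .network import AgonistMap, Network, NetworkParams, default_params
from .plasticity import DiffHebbParams, InputCorrParams
from .units import ACTParams, AdaptationParams

_GROUPS = {
    "network": NetworkParams,
    "arm": ArmParams,
    "muscles": MuscleParams,
    "spindles": SpindleParams,
    "gto": GTOParams,
    "integrator": IntegratorConfig,
    "diff_hebb": DiffHebbParams,
    "diff_hebb_alpha": DiffHebbParams,
    "input_corr": InputCorrParams,
    "act": ACTParams,
    "adaptation": AdaptationParams,
}


@dataclass
class RunConfig:
    configuration: str = "static"
    seed: int = 0
    network: NetworkParams = None
    arm: ArmParams = None
    muscles: MuscleParams = None
    spindles: SpindleParams = None
    gto: GTOParams = None
    integrator: IntegratorConfig = None
    diff_hebb: DiffHebbParams = None
    diff_hebb_alpha: DiffHebbParams = None
    input_corr: InputCorrParams = None
    act: ACTParams = None
    adaptation: AdaptationParams = None

    def __post_init__(self):
        if self.network is None:
            self.network = default_params(self.configuration)
        for name, cls in _GROUPS.items():
            if name == "network":
                continue
            if getattr(self, name) is None:
                setattr(self, name, cls())
        if self.diff_hebb_alpha is not None and \
                dataclasses.asdict(self.diff_hebb_alpha) == \
                dataclasses.asdict(DiffHebbParams()):
            # the direct cortico-motoneuronal group defaults to a smaller
            # outgoing-sum target than the interneuron group
            self.diff_hebb_alpha = DiffHebbParams(w_sa=0.5)
        self.integrator.seed = self.seed

    # ------------------------------------------------------------------
    def to_dict(self):
        d = {"configuration": self.configuration, "seed": self.seed}
        for name in _GROUPS:
            d[name] = dataclasses.asdict(getattr(self, name))
        return d

    def save(self, path):
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=True) \
            if path.suffix in (".yml", ".yaml") \
            else json.dumps(self.to_dict(), indent=1, sort_keys=True)
        path.write_text(text)

    def hash(self):
        """Stable hash of the full parameter set (key order independent)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    # ------------------------------------------------------------------
    def build_plant(self) -> PlanarArm:
        return PlanarArm(arm=self.arm, muscles=self.muscles,
                         spindles=self.spindles, gto=self.gto,
                         geometry=Geometry(L1=self.arm.L1,
                                           rest_q=tuple(self.arm.rest_q)))

    def build_network(self) -> Network:
        return Network(self.configuration, self.network, self.build_plant(),
                       AgonistMap(), seed=self.seed)

    def build_engine(self) -> Engine:
        return Engine(self.build_network(), self.integrator,
                      dh=self.diff_hebb, dh_alpha=self.diff_hebb_alpha,
                      ic=self.input_corr, act_params=self.act,
                      adapt_params=self.adaptation)


def _apply(obj, data, prefix):
    valid = {f.name for f in dataclasses.fields(obj)}
    for k, v in data.items():
        if k not in valid:
            raise ValueError(f"unknown configuration key {prefix}{k}")
        setattr(obj, k, tuple(v) if isinstance(getattr(obj, k), tuple) else v)


def load_config(path) -> RunConfig:
    """Load a YAML/JSON config; missing keys fall back to defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")

    top = {k: v for k, v in data.items() if k in ("configuration", "seed")}
    cfg = RunConfig(**top)
    for key, sub in data.items():
        if key in ("configuration", "seed"):
            continue
        if key not in _GROUPS:
            raise ValueError(f"unknown configuration key {key}")
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise ValueError(f"configuration group {key} must be a mapping")
        _apply(getattr(cfg, key), sub, f"{key}.")
    # re-validate
    for name in _GROUPS:
        grp = getattr(cfg, name)
        if hasattr(grp, "__post_init__"):
            grp.__post_init__()
    cfg.integrator.seed = cfg.seed
    return cfg
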