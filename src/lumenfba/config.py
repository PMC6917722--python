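"""Run configuration: one YAML file describing models, diet, prebiotic,
dose grid, solver/experiment settings and outputs.

Model references are either file paths (SBML-FBC / COBRA-JSON) or the
names of bundled synthetic fixtures (``toy-host``, ``toy-host-cofactor``,
``toy-fp``, ``toy-bt``, ``toy-null``), so every bundled workflow runs
without downloads.  Each run writes the fully resolved configuration and
its hash next to the outputs for reproducibility.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .comodel import CoMetabolismModel, JoinPolicy, merge_into_comodel
from .conditions import (
    DietSpec,
    PrebioticSpec,
    load_diet_preset,
    load_prebiotic_preset,
)
from .io import read_model
from .model import MetabolicModel
from .synthetic import (
    BT_LIKE,
    FP_LIKE,
    NULL_SECRETOR,
    make_cofactor_host,
    make_toy_host,
    make_toy_microbe,
)

__all__ = ["RunConfig", "load_config"]

_TOY_HOSTS = {
    "toy-host": make_toy_host,
    "toy-host-cofactor": make_cofactor_host,
}
_TOY_MICROBES = {
    "toy-fp": FP_LIKE,
    "toy-bt": BT_LIKE,
    "toy-null": NULL_SECRETOR,
}


@dataclass
class RunConfig:
    host_model: str = "toy-host"
    microbe_model: str = "toy-fp"
    collection: str | None = None  # directory of model files, for `screen`
    collection_n: int = 50  # synthetic collection size when no directory
    collection_seed: int = 20190406
    diet: str = "western-toy"
    diet_file: str | None = None
    prebiotic: str = "fructan-toy"
    prebiotic_file: str | None = None
    # 21 evenly spaced doses over 0-10 g (the commonly accepted safe range)
    doses: list[float] = field(default_factory=lambda: [0.5 * i for i in range(21)])
    dose: float = 1.0  # single-dose experiments (knock-off, subsystems)
    objective: str | None = None  # None = host model objective
    tracked_reactions: list[str] = field(default_factory=list)
    candidates: list[str] | None = None
    pathway: list[str] = field(default_factory=list)
    control: bool = False
    control_cap: float = 0.0
    screen_mode: str = "potential"
    percentile_cut: float = 0.9
    min_biomass: float = 0.01
    host_open_uptake: list[str] = field(default_factory=lambda: ["lac", "ac", "pyr"])
    output_dir: str = "lumenfba_out"

    # -- resolution -------------------------------------------------------
    def load_host(self) -> MetabolicModel:
        if self.host_model in _TOY_HOSTS:
            return _TOY_HOSTS[self.host_model]()
        return read_model(self.host_model)

    def load_microbe(self, ref: str | None = None) -> MetabolicModel:
        ref = ref or self.microbe_model
        if ref in _TOY_MICROBES:
            return make_toy_microbe(_TOY_MICROBES[ref])
        return read_model(ref)

    def join_policy(self) -> JoinPolicy:
        return JoinPolicy(
            host_open_uptake=frozenset(self.host_open_uptake),
            min_biomass=self.min_biomass,
        )

    def build_comodel(self) -> CoMetabolismModel:
        return merge_into_comodel(
            self.load_host(), self.load_microbe(), self.join_policy()
        )

    def load_diet(self) -> DietSpec:
        return load_diet_preset(self.diet, self.diet_file)

    def load_prebiotic(self) -> PrebioticSpec:
        return load_prebiotic_preset(self.prebiotic, self.prebiotic_file)

    def collection_paths(self) -> list[Path] | None:
        if self.collection is None:
            return None
        root = Path(self.collection)
        if not root.is_dir():
            raise FileNotFoundError(f"collection directory {root} not found")
        paths = sorted(
            p for p in root.iterdir()
            if p.suffix in (".json", ".xml", ".sbml", ".gz")
        )
        if not paths:
            raise FileNotFoundError(f"no model files under {root}")
        return paths

    # -- provenance -------------------------------------------------------
    def resolved_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:16]

    def write_resolved(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "resolved_config.yaml").write_text(
            f"# config hash: {self.config_hash()}\n" + self.resolved_yaml()
        )


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (flags override file values)."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
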