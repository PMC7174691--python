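"""Pipeline configuration: YAML in, validated dataclasses out.

Every published threshold is surfaced with its published value as the
default (200 nt minimum length, 3 reads, |log2FC| > 1, p < 0.05, 3-5 nt
central bulge, <= 4 weighted mismatches, <= 2 consecutive mismatches).
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping

import yaml

from .diffexpr import DEParams, GENOTYPES
from .identify import IdentifyParams
from .mimic import CleavageParams, MimicRuleParams
from .network import NetworkParams
from .synthetic import SimulationConfig


@dataclass
class Contrast:
    genotype: str
    condition_a: str = "control"
    condition_b: str = "salt"

    @property
    def name(self) -> str:
        return f"{self.genotype}_{self.condition_b}_vs_{self.condition_a}"


def _default_contrasts() -> List[Contrast]:
    return [Contrast(g) for g in GENOTYPES]


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    identify: IdentifyParams = field(default_factory=IdentifyParams)
    de: DEParams = field(default_factory=DEParams)
    mimic: MimicRuleParams = field(default_factory=MimicRuleParams)
    cleavage: CleavageParams = field(default_factory=CleavageParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    contrasts: List[Contrast] = field(default_factory=_default_contrasts)

    def __post_init__(self) -> None:
        # keep the simulation seed slaved to the pipeline seed unless the
        # user explicitly set one in the simulate block
        if self.simulate.seed == 0 and self.seed != 0:
            self.simulate = dataclasses.replace(self.simulate, seed=self.seed)


def _build(cls, data: Mapping[str, Any], where: str):
    if not isinstance(data, Mapping):
        raise ValueError(f"{where}: expected a mapping, got {type(data)}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"{where}: unknown configuration keys {sorted(unknown)} "
            f"(known: {sorted(known)})"
        )
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if isinstance(value, list) and f.name in (
                "bulge_length_range",
                "planted_mismatch_counts",
                "central_positions",
            ):
                value = tuple(value)
            kwargs[f.name] = value
    return cls(**kwargs)


_SECTIONS = {
    "simulate": SimulationConfig,
    "identify": IdentifyParams,
    "de": DEParams,
    "mimic": MimicRuleParams,
    "cleavage": CleavageParams,
    "network": NetworkParams,
}


def config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    known = {"seed", "contrasts", *_SECTIONS}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown top-level configuration keys {sorted(unknown)} "
            f"(known: {sorted(known)})"
        )
    kwargs: Dict[str, Any] = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name], name)
    if "contrasts" in data:
        kwargs["contrasts"] = [
            _build(Contrast, c, "contrasts") for c in data["contrasts"]
        ]
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
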