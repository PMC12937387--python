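"""Run configuration: a YAML-serializable bundle of model, estimation,
simulation and PTA settings with explicit seeds."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .cohort import StudyDesign
from .estimate import ModelStructure
from .pkmodel import FINAL_MODEL, PopulationParameters
from .pta import PTAConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Settings for a full pipeline run.  All randomness is seeded here."""

    structure: ModelStructure = field(default_factory=ModelStructure.final)
    parameters: PopulationParameters = FINAL_MODEL
    design: StudyDesign = field(default_factory=StudyDesign)
    pta: PTAConfig = field(default_factory=PTAConfig)
    init: dict[str, float] = field(default_factory=dict)
    estimation_options: dict = field(default_factory=dict)
    seed: int = 0
    n_bootstrap: int = 1000
    n_vpc: int = 1000
    output_dir: str = "."

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("covariate_terms", "eval_times", "channels", "surgery_duration_range",
                "incision_window", "removal_window"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in kwargs[key]
            )
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (missing sections use defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "structure" in raw:
        kwargs["structure"] = _build(ModelStructure, raw.pop("structure"))
    if "parameters" in raw:
        kwargs["parameters"] = _build(PopulationParameters, raw.pop("parameters"))
    if "design" in raw:
        design = raw.pop("design")
        if "covariate_quartiles" in design:
            design["covariate_quartiles"] = {
                k: tuple(v) for k, v in design["covariate_quartiles"].items()
            }
        kwargs["design"] = _build(StudyDesign, design)
    if "pta" in raw:
        kwargs["pta"] = _build(PTAConfig, raw.pop("pta"))
    names = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(raw)
    return RunConfig(**kwargs)
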