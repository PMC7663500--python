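"""Run-configuration files (YAML) for the exploration tool.

Schema::

    design_space:
      functionalities:          # ordered; one entry per functionality
        - id: algorithm
          components:
            - id: wpd           # component id
              parameters:       # finite value grids, ordered
                m: [1.0]
                d: [20]
    requirements:               # all optional; defaults mirror the study
      min_precision: 0.7
      min_recall: 0.8
      energy_budget_mwh: null   # null -> derived from the battery (BC/RT*phi)
      latency_tolerance_s: null # null -> latency outside feasibility
    sampler:                    # context-adaptive sampling operating point
      d_low: 0.1
      d_high: 1.0
      d_threshold: 0.6
      theta_low: 10.0
      theta_high: 180.0
      n_shots: 4
      tau: 3.0
      period: 1.0
    generator:                  # synthetic participants (generate command)
      n_participants: 5
      duration: 7200.0
      ...                       # any GeneratorParams field
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from . import cost_models as cm
from .design_space import DesignSpace, RequirementSet, build_design_space
from .sampling import SamplerParams
from .synthetic_emg import GeneratorParams

__all__ = ["RunConfig", "load_run_config"]


class RunConfig:
    """Parsed run configuration."""

    def __init__(self, space: DesignSpace, requirements: RequirementSet,
                 sampler: SamplerParams, generator: dict):
        self.space = space
        self.requirements = requirements
        self.sampler = sampler
        self.generator = generator


def _pick(d: dict, cls) -> dict:
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return d


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    space = build_design_space(raw.get("design_space", {}))
    req_raw = dict(raw.get("requirements", {}))
    if req_raw.get("energy_budget_mwh") is None:
        req_raw["energy_budget_mwh"] = cm.energy_requirement(
            cm.load_profiles().battery)
    req = RequirementSet(**_pick(req_raw, RequirementSet))
    sampler = SamplerParams(**_pick(dict(raw.get("sampler", {})), SamplerParams))
    generator = dict(raw.get("generator", {}))
    return RunConfig(space=space, requirements=req, sampler=sampler,
                     generator=generator)


def generator_params_list(generator: dict) -> list[GeneratorParams]:
    """Expand the generator block into per-participant parameter sets."""
    g = dict(generator)
    n = int(g.pop("n_participants", 5))
    base_seed = int(g.pop("seed", 0))
    return [GeneratorParams(seed=base_seed + i, **g) for i in range(n)]
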