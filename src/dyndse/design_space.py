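"""Formal design-space representation and constrained selection.

A design space is a set of *functionalities* (event-retrieval
algorithm, data sampling strategy, microcontroller, runtime mode, ...),
each realised by one of several *components*, each component carrying
finite grids of *parameters*.  A configuration picks exactly one
component per functionality and binds every parameter to a value from
its grid.  Candidate configurations are scored by a metric vector of
benefits (precision P, recall R — maximised) and costs (execution time
ET, energy EC, memory demand MD, latency CL — minimised), compared by
Pareto dominance, and selected against a requirement set by maximising
the benefit sum over the feasible region.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence

__all__ = [
    "ComponentSpec",
    "Functionality",
    "DesignSpace",
    "Configuration",
    "MetricVector",
    "RequirementSet",
    "build_design_space",
    "enumerate_configurations",
    "dominates",
    "pareto_front",
    "select_optimal",
    "select_optimal_index",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One realisation of a functionality, with finite parameter grids."""

    id: str
    name: str = ""
    parameter_domains: tuple[tuple[str, tuple], ...] = ()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.parameter_domains]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate parameter names in component {self.id!r}")
        for pname, domain in self.parameter_domains:
            if len(domain) == 0:
                raise ValueError(
                    f"empty parameter domain {pname!r} in component {self.id!r}")

    @property
    def n_variants(self) -> int:
        return math.prod(len(dom) for _, dom in self.parameter_domains)


@dataclass(frozen=True)
class Functionality:
    id: str
    components: tuple[ComponentSpec, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(f"functionality {self.id!r} has no components")
        ids = [c.id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate component ids in functionality {self.id!r}")

    @property
    def n_variants(self) -> int:
        return sum(c.n_variants for c in self.components)


@dataclass(frozen=True)
class DesignSpace:
    functionalities: tuple[Functionality, ...]

    def __post_init__(self) -> None:
        if not self.functionalities:
            raise ValueError("design space needs at least one functionality")
        ids = [f.id for f in self.functionalities]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate functionality ids")

    @property
    def size(self) -> int:
        """Total configuration count: Π_ξ Σ_q Π_w |domain|."""
        return math.prod(f.n_variants for f in self.functionalities)

    def functionality(self, fid: str) -> Functionality:
        for f in self.functionalities:
            if f.id == fid:
                return f
        raise KeyError(fid)


@dataclass(frozen=True)
class Configuration:
    """One component choice per functionality plus bound parameter values."""

    choices: tuple[tuple[str, str, tuple[tuple[str, object], ...]], ...]
    # (functionality_id, component_id, ((param, value), ...))

    def component(self, functionality_id: str) -> str:
        for fid, cid, _ in self.choices:
            if fid == functionality_id:
                return cid
        raise KeyError(functionality_id)

    def parameters(self, functionality_id: str) -> dict:
        for fid, _, params in self.choices:
            if fid == functionality_id:
                return dict(params)
        raise KeyError(functionality_id)

    def as_dict(self) -> dict:
        return {fid: {"component": cid, "parameters": dict(params)}
                for fid, cid, params in self.choices}


BENEFIT_AXES = ("P", "R")
COST_AXES = ("ET", "EC", "MD", "CL")


@dataclass(frozen=True)
class MetricVector:
    """(P, R, ET, EC, MD, CL) for one configuration.

    P and R are fractions in [0, 1]; ET and CL seconds; EC mWh; MD
    bytes.  CL is optional (None when latency is not evaluated).
    """

    P: float
    R: float
    ET: float
    EC: float
    MD: float
    CL: Optional[float] = None

    def __post_init__(self) -> None:
        for axis in BENEFIT_AXES:
            v = getattr(self, axis)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{axis} must lie in [0, 1], got {v}")
        for axis in ("ET", "EC", "MD"):
            if getattr(self, axis) < 0:
                raise ValueError(f"{axis} must be >= 0")
        if self.CL is not None and self.CL < 0:
            raise ValueError("CL must be >= 0")

    def axes(self) -> tuple[str, ...]:
        base = BENEFIT_AXES + ("ET", "EC", "MD")
        return base + (("CL",) if self.CL is not None else ())


@dataclass(frozen=True)
class RequirementSet:
    """Requirement bounds the metric vector is normalised against.

    ``et_bound_s`` is the frame length m for real-time mode or the
    runtime T for online mode; ``energy_budget_mwh`` the battery-derived
    budget; ``memory_capacity_bytes`` the target microcontroller's RAM.
    The latency tolerance is optional and, when None, latency is
    excluded from the feasibility conjunction.
    """

    min_precision: float = 0.7
    min_recall: float = 0.8
    et_bound_s: float = 1.0
    energy_budget_mwh: float = 52.03125
    memory_capacity_bytes: float = 96_000
    latency_tolerance_s: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.min_precision <= 1 and 0 < self.min_recall <= 1):
            raise ValueError("benefit thresholds must lie in (0, 1]")
        for f in ("et_bound_s", "energy_budget_mwh", "memory_capacity_bytes"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.latency_tolerance_s is not None and self.latency_tolerance_s <= 0:
            raise ValueError("latency tolerance must be positive")

    def normalized(self, mv: MetricVector) -> dict[str, float]:
        """Value ÷ requirement per axis (benefits ÷ threshold)."""
        out = {
            "P": mv.P / self.min_precision,
            "R": mv.R / self.min_recall,
            "ET": mv.ET / self.et_bound_s,
            "EC": mv.EC / self.energy_budget_mwh,
            "MD": mv.MD / self.memory_capacity_bytes,
        }
        if self.latency_tolerance_s is not None and mv.CL is not None:
            out["CL"] = mv.CL / self.latency_tolerance_s
        return out

    def feasible(self, mv: MetricVector) -> bool:
        """All normalised costs <= 1 and all normalised benefits >= 1."""
        norm = self.normalized(mv)
        costs_ok = all(norm[a] <= 1.0 for a in norm if a not in BENEFIT_AXES)
        benefits_ok = all(norm[a] >= 1.0 for a in BENEFIT_AXES)
        return costs_ok and benefits_ok


# ---------------------------------------------------------------------------
# construction and enumeration
# ---------------------------------------------------------------------------

def build_design_space(spec_table: Mapping | Sequence) -> DesignSpace:
    """Build a validated DesignSpace from a structured description.

    Accepts either ``{"functionalities": [...]}`` or the bare list,
    where each entry is ``{"id": ..., "name": ..., "components":
    [{"id": ..., "parameters": {name: [values...]}}, ...]}``.
    """
    if isinstance(spec_table, Mapping):
        entries = spec_table.get("functionalities", [])
    else:
        entries = list(spec_table)
    if not entries:
        raise ValueError("design space description lists no functionalities")
    functionalities = []
    for entry in entries:
        comps = []
        for c in entry.get("components", []):
            domains = tuple(
                (pname, tuple(vals))
                for pname, vals in (c.get("parameters") or {}).items()
            )
            comps.append(ComponentSpec(id=str(c["id"]), name=c.get("name", ""),
                                       parameter_domains=domains))
        functionalities.append(
            Functionality(id=str(entry["id"]), name=entry.get("name", ""),
                          components=tuple(comps)))
    return DesignSpace(functionalities=tuple(functionalities))


def enumerate_configurations(space: DesignSpace) -> Iterator[Configuration]:
    """Yield every configuration exactly once, in lexicographic order
    over declared functionality → component → parameter-value indices."""
    per_functionality: list[list[tuple[str, str, tuple]]] = []
    for f in space.functionalities:
        options = []
        for comp in f.components:
            names = [n for n, _ in comp.parameter_domains]
            domains = [dom for _, dom in comp.parameter_domains]
            for values in itertools.product(*domains):
                options.append((f.id, comp.id, tuple(zip(names, values))))
        per_functionality.append(options)
    for combo in itertools.product(*per_functionality):
        yield Configuration(choices=tuple(combo))


# ---------------------------------------------------------------------------
# dominance and selection
# ---------------------------------------------------------------------------

def dominates(a: MetricVector, b: MetricVector) -> bool:
    """True iff ``a`` Pareto-dominates ``b``: at least as good on every
    objective (benefits up, costs down) and strictly better on one."""
    if a.axes() != b.axes():
        raise ValueError("metric vectors carry different objective sets")
    at_least_as_good = True
    strictly_better = False
    for axis in a.axes():
        va, vb = getattr(a, axis), getattr(b, axis)
        if axis in BENEFIT_AXES:
            if va < vb:
                at_least_as_good = False
                break
            if va > vb:
                strictly_better = True
        else:
            if va > vb:
                at_least_as_good = False
                break
            if va < vb:
                strictly_better = True
    return at_least_as_good and strictly_better


def pareto_front(vectors: Sequence[MetricVector]) -> list[MetricVector]:
    """The non-dominated subset, in stable input order."""
    if not vectors:
        raise ValueError("pareto_front needs a non-empty list")
    return [v for v in vectors
            if not any(dominates(u, v) for u in vectors if u is not v)]


def select_optimal_index(evaluated: Sequence[tuple[Configuration, MetricVector]],
                         req: RequirementSet) -> Optional[int]:
    """Index of the feasible configuration maximising P + R.

    Ties are broken by lower EC, then by enumeration order.  Returns
    None when no configuration is feasible (an expected outcome, not an
    error).
    """
    best: Optional[int] = None
    best_key: Optional[tuple[float, float]] = None
    for i, (_, mv) in enumerate(evaluated):
        if not req.feasible(mv):
            continue
        key = (-(mv.P + mv.R), mv.EC)  # maximise benefit sum, then lower EC
        if best_key is None or key < best_key:
            best, best_key = i, key
    return best


def select_optimal(evaluated: Sequence[tuple[Configuration, MetricVector]],
                   req: RequirementSet) -> Optional[Configuration]:
    """The feasible configuration maximising the benefit sum, or None."""
    idx = select_optimal_index(evaluated, req)
    return None if idx is None else evaluated[idx][0]
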