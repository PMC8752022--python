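"""DEA scenarios: named combinations of resource (input) and utilization (output) variables.

A scenario is one analytical "view" of the care ecosystem: which resources
(professional rates, service availability, workforce headcount) are treated
as DEA inputs, and which utilization variables (outpatient visits, inpatient
discharges) as DEA outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

#: Resource (input) variables available in the standard area table.
RESOURCE_VARIABLES: tuple[str, ...] = (
    "psychiatrists_per_100k",
    "psychologists_per_100k",
    "nurses_per_100k",
    "total_professionals_per_100k",
    "availability_per_100k",
    "total_professionals_fte",
)

#: Utilization (output) variables.
UTILIZATION_VARIABLES: tuple[str, ...] = (
    "frequentation_visits",
    "discharges",
)


@dataclass(frozen=True)
class Scenario:
    """One input/output variable combination for a DEA run."""

    id: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError(f"scenario {self.id!r}: needs at least one input variable")
        if not self.outputs:
            raise ValueError(f"scenario {self.id!r}: needs at least one output variable")
        overlap = set(self.inputs) & set(self.outputs)
        if overlap:
            raise ValueError(
                f"scenario {self.id!r}: input/output sets overlap on {sorted(overlap)}"
            )


@dataclass
class ScenarioSet:
    """Ordered collection of scenarios with unique ids."""

    scenarios: list[Scenario] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.scenarios]
        if len(ids) != len(set(ids)):
            raise ValueError("scenario ids must be unique")
        if not self.scenarios:
            raise ValueError("a ScenarioSet needs at least one scenario")

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self) -> Iterator[Scenario]:
        return iter(self.scenarios)

    def variables(self) -> set[str]:
        out: set[str] = set()
        for s in self.scenarios:
            out.update(s.inputs)
            out.update(s.outputs)
        return out


# Curated stand-ins for the expert panel's scenario designs: outpatient-only,
# inpatient-only and mixed views, listed in a fixed order. The first entry is
# the all-resources / all-utilization view.
_CURATED: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("S01_global", RESOURCE_VARIABLES, UTILIZATION_VARIABLES),
    ("S02_psychiatrists_outpatient", ("psychiatrists_per_100k",), ("frequentation_visits",)),
    ("S03_workforce_outpatient", ("total_professionals_per_100k",), ("frequentation_visits",)),
    ("S04_nursing_psychology_outpatient", ("psychologists_per_100k", "nurses_per_100k"), ("frequentation_visits",)),
    ("S05_availability_outpatient", ("availability_per_100k",), ("frequentation_visits",)),
    ("S06_availability_inpatient", ("availability_per_100k",), ("discharges",)),
    ("S07_workforce_inpatient", ("total_professionals_per_100k",), ("discharges",)),
    ("S08_psychiatrists_inpatient", ("psychiatrists_per_100k",), ("discharges",)),
    ("S09_headcount_outpatient", ("total_professionals_fte",), ("frequentation_visits",)),
    ("S10_headcount_inpatient", ("total_professionals_fte",), ("discharges",)),
    ("S11_psychiatry_availability_outpatient", ("psychiatrists_per_100k", "availability_per_100k"), ("frequentation_visits",)),
    ("S12_workforce_availability_mixed", ("total_professionals_per_100k", "availability_per_100k"), UTILIZATION_VARIABLES),
    ("S13_clinical_team_mixed", ("psychiatrists_per_100k", "nurses_per_100k"), UTILIZATION_VARIABLES),
    ("S14_structure_mixed", ("availability_per_100k", "total_professionals_fte"), UTILIZATION_VARIABLES),
    ("S15_professional_mix_outpatient", ("psychiatrists_per_100k", "psychologists_per_100k", "nurses_per_100k"), ("frequentation_visits",)),
)


def _all_combinations() -> Iterator[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Deterministic enumeration of every nonempty (inputs, outputs) pair."""
    in_subsets = [
        c
        for r in range(1, len(RESOURCE_VARIABLES) + 1)
        for c in itertools.combinations(RESOURCE_VARIABLES, r)
    ]
    out_subsets = [
        c
        for r in range(1, len(UTILIZATION_VARIABLES) + 1)
        for c in itertools.combinations(UTILIZATION_VARIABLES, r)
    ]
    for ins in in_subsets:
        for outs in out_subsets:
            yield ins, outs


def default_scenarios(columns: Sequence[str], n_scenarios: int = 15) -> ScenarioSet:
    """Build ``n_scenarios`` deterministic input/output combinations.

    Parameters
    ----------
    columns
        Variable names available in the area table; every scenario variable
        must be among them.
    n_scenarios
        Number of scenarios. ``n_scenarios=1`` returns the single global view
        (all resources as inputs, all utilization variables as outputs).
    """
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be >= 1")
    missing = (set(RESOURCE_VARIABLES) | set(UTILIZATION_VARIABLES)) - set(columns)
    if missing:
        raise ValueError(f"table lacks scenario variables: {sorted(missing)}")

    combos: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = list(_CURATED)
    if n_scenarios > len(combos):
        seen = {(c[1], c[2]) for c in combos}
        k = len(combos) + 1
        for ins, outs in _all_combinations():
            if (ins, outs) in seen:
                continue
            combos.append((f"S{k:02d}_auto", ins, outs))
            seen.add((ins, outs))
            k += 1
            if len(combos) >= n_scenarios:
                break
        if n_scenarios > len(combos):
            raise ValueError(
                f"n_scenarios={n_scenarios} exceeds the {len(combos)} distinct "
                "input/output combinations available"
            )
    return ScenarioSet([Scenario(i, ins, outs) for i, ins, outs in combos[:n_scenarios]])
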