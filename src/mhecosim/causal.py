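"""Causal policy propagation.

A time-layered directed acyclic graph captures the expert causal structure of
the care ecosystem: workforce decisions at time t change outpatient
frequentation after a short lag (t+t1) and inpatient stay, discharges and
readmissions after a longer one (t+t1+t2). Fitted base-function models are
attached to downstream nodes; a workforce policy (FTE deltas per area) is
applied to the area table, and propagation turns the updated decision values
into per-(area, variable) uniform uncertainty bounds whose limits are the
models' prediction intervals.

Layers are ordinal (the lags are qualitative, not calibrated durations).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .basefunc import BaseFunctionModel
from .ecosystem import AreaRecord, EcosystemTable

__all__ = [
    "LAYER_T",
    "LAYER_T1",
    "LAYER_T2",
    "CausalNode",
    "CausalNetwork",
    "Intervention",
    "Policy",
    "DEFAULT_POLICY",
    "DistributionTable",
    "build_default_network",
    "apply_policy",
    "propagate",
]

LAYER_T = 0       # decision / exogenous variables (time t)
LAYER_T1 = 1      # short-lag consequences (time t+t1)
LAYER_T2 = 2      # long-lag consequences (time t+t1+t2)

#: Root decision variables a policy may modify.
DECISION_VARIABLES = ("psychiatrists", "total_professionals")


@dataclass
class CausalNode:
    """One ecosystem variable in the causal graph."""

    name: str
    layer: int
    model: BaseFunctionModel | None = None

    def __post_init__(self) -> None:
        if self.layer not in (LAYER_T, LAYER_T1, LAYER_T2):
            raise ValueError(f"node {self.name!r}: unknown time layer {self.layer}")
        if self.layer == LAYER_T and self.model is not None:
            raise ValueError(f"node {self.name!r}: layer-t (root) nodes carry no model")


class CausalNetwork:
    """Time-layered DAG of ecosystem variables with attached models."""

    def __init__(self, nodes: Iterable[CausalNode], edges: Iterable[tuple[str, str]]):
        self._graph = nx.DiGraph()
        for node in nodes:
            self._graph.add_node(node.name, layer=node.layer, model=node.model)
        for u, v in edges:
            self.add_edge(u, v, _validate=False)
        self.validate()

    # -- structure -------------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    def add_edge(self, u: str, v: str, _validate: bool = True) -> None:
        for name in (u, v):
            if name not in self._graph:
                raise ValueError(f"unknown node {name!r}")
        if self._graph.nodes[u]["layer"] > self._graph.nodes[v]["layer"]:
            raise ValueError(
                f"edge {u!r}->{v!r} runs from a later time layer to an earlier one"
            )
        self._graph.add_edge(u, v)
        if _validate:
            self.validate()

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._graph):
            raise ValueError("causal network must be acyclic")
        for u, v in self._graph.edges:
            if self._graph.nodes[u]["layer"] > self._graph.nodes[v]["layer"]:
                raise ValueError(f"edge {u!r}->{v!r} violates time-layer ordering")

    def layer(self, name: str) -> int:
        return self._graph.nodes[name]["layer"]

    def model(self, name: str) -> BaseFunctionModel | None:
        return self._graph.nodes[name]["model"]

    def parents(self, name: str) -> list[str]:
        return sorted(self._graph.predecessors(name))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._graph))

    @property
    def node_names(self) -> list[str]:
        return list(self._graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._graph.edges)


@dataclass(frozen=True)
class Intervention:
    """A signed FTE change of one decision variable in one area."""

    area_id: str
    variable: str
    delta: float

    def __post_init__(self) -> None:
        if self.variable not in DECISION_VARIABLES:
            raise ValueError(
                f"intervention variable must be a layer-t decision variable "
                f"({', '.join(DECISION_VARIABLES)}), got {self.variable!r}"
            )


@dataclass(frozen=True)
class Policy:
    """A labelled set of workforce interventions."""

    label: str
    interventions: tuple[Intervention, ...]

    @property
    def total_delta(self) -> float:
        return sum(i.delta for i in self.interventions)


#: The reference rebalancing policy: half an FTE psychiatrist reassigned from
#: Tolosa to Azpeitia, plus one newly hired FTE psychiatrist in Andoain.
DEFAULT_POLICY = Policy(
    "gipuzkoa-outpatient-rebalance",
    (
        Intervention("Tolosa", "psychiatrists", -0.5),
        Intervention("Azpeitia", "psychiatrists", +0.5),
        Intervention("Andoain", "psychiatrists", +1.0),
    ),
)


@dataclass
class DistributionTable:
    """Per-(area, variable) uniform uncertainty bounds [lo, hi]."""

    area_ids: list[str]
    variables: list[str]
    lo: np.ndarray  # (n_areas, n_variables)
    hi: np.ndarray
    label: str = "pre"

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        shape = (len(self.area_ids), len(self.variables))
        if self.lo.shape != shape or self.hi.shape != shape:
            raise ValueError(f"bounds must have shape {shape}")
        if np.any(self.lo > self.hi + 1e-12):
            raise ValueError("lower bounds exceed upper bounds")
        if np.any(self.lo < 0):
            raise ValueError("care-variable bounds must be >= 0")

    def bounds(self, area_id: str, variable: str) -> tuple[float, float]:
        i = self.area_ids.index(area_id)
        j = self.variables.index(variable)
        return float(self.lo[i, j]), float(self.hi[i, j])

    def midpoints(self) -> pd.DataFrame:
        return pd.DataFrame(
            (self.lo + self.hi) / 2.0, index=self.area_ids, columns=self.variables
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.area_ids):
            for j, v in enumerate(self.variables):
                rows.append({"area_id": a, "variable": v, "lo": self.lo[i, j], "hi": self.hi[i, j]})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "pre") -> "DistributionTable":
        pivot_lo = frame.pivot(index="area_id", columns="variable", values="lo")
        pivot_hi = frame.pivot(index="area_id", columns="variable", values="hi")
        return cls(
            list(pivot_lo.index),
            list(pivot_lo.columns),
            pivot_lo.to_numpy(),
            pivot_hi.to_numpy(),
            label=label,
        )


# --- network construction ------------------------------------------------

def build_default_network(models: Mapping[str, BaseFunctionModel]) -> CausalNetwork:
    """Build the expert causal topology with fitted models attached.

    ``models`` maps node names to fitted models and must contain
    ``frequentation_visits``; ``stay_days`` and ``discharges`` are optional.
    Readmissions stay unmodelled (no statistical relationship exists).
    """
    if "frequentation_visits" not in models:
        raise ValueError("a fitted frequentation model is required")

    nodes = [
        CausalNode("population_adults", LAYER_T),
        CausalNode("total_professionals_fte", LAYER_T),
        CausalNode("availability_per_100k", LAYER_T),
        CausalNode("frequentation_visits", LAYER_T1, models["frequentation_visits"]),
        CausalNode("stay_days", LAYER_T2, models.get("stay_days")),
        CausalNode("discharges", LAYER_T2, models.get("discharges")),
        CausalNode("readmissions", LAYER_T2, None),
    ]
    edges = [
        # population drives workforce sizing (exponential law, structural link)
        ("population_adults", "total_professionals_fte"),
        # frequentation depends on the workforce (and population via composite)
        ("population_adults", "frequentation_visits"),
        ("total_professionals_fte", "frequentation_visits"),
        # stay depends on outpatient availability, visits and workforce
        ("availability_per_100k", "stay_days"),
        ("population_adults", "stay_days"),
        ("total_professionals_fte", "stay_days"),
        # discharges depend on availability, frequentation and workforce
        ("availability_per_100k", "discharges"),
        ("frequentation_visits", "discharges"),
        ("total_professionals_fte", "discharges"),
        # readmissions: expert links from availability, stays and workforce
        ("availability_per_100k", "readmissions"),
        ("stay_days", "readmissions"),
        ("total_professionals_fte", "readmissions"),
    ]
    net = CausalNetwork(nodes, edges)

    node_set = set(net.node_names)
    for name, model in models.items():
        if name not in node_set:
            raise ValueError(f"model attached to unknown variable {name!r}")
        if model.transform is not None:
            missing = set(model.transform.sources) - node_set
            if missing:
                raise ValueError(
                    f"model for {name!r} references variables absent from the "
                    f"network: {sorted(missing)}"
                )
    return net


# --- policy application --------------------------------------------------

def apply_policy(table: EcosystemTable, policy: Policy) -> EcosystemTable:
    """Return a new table with workforce deltas applied; the input is untouched.

    Psychiatrist deltas also move the total-professionals headcount
    one-for-one (a psychiatrist is a professional). Per-100k rates are
    recomputed from the adjusted headcounts.
    """
    records = {a.area_id: copy.deepcopy(a) for a in table.areas}
    for iv in policy.interventions:
        if iv.area_id not in records:
            raise ValueError(f"policy {policy.label!r}: unknown area {iv.area_id!r}")
        rec = records[iv.area_id]
        pop = rec.population_adults
        if iv.variable == "psychiatrists":
            psy_fte = rec.psychiatrists_per_100k * pop / 1e5
            new_psy = psy_fte + iv.delta
            if new_psy < -1e-12:
                raise ValueError(
                    f"policy {policy.label!r}: psychiatrist headcount in "
                    f"{iv.area_id!r} would become negative ({new_psy:.3f})"
                )
            rec.psychiatrists_per_100k = max(new_psy, 0.0) * 1e5 / pop
        new_total = rec.total_professionals_fte + iv.delta
        if new_total < -1e-12:
            raise ValueError(
                f"policy {policy.label!r}: total professionals in {iv.area_id!r} "
                f"would become negative ({new_total:.3f})"
            )
        rec.total_professionals_fte = max(new_total, 0.0)
        rec.total_professionals_per_100k = rec.total_professionals_fte * 1e5 / pop
    out = EcosystemTable([records[a.area_id] for a in table.areas], label=f"{table.label}+{policy.label}")
    for rec in out.areas:
        rec.validate()
    return out


# --- propagation ---------------------------------------------------------

def propagate(
    network: CausalNetwork,
    table: EcosystemTable,
    level: float = 0.95,
    readmission_halfwidth: float = 0.10,
    label: str | None = None,
) -> DistributionTable:
    """Turn the causal network + area table into uniform uncertainty bounds.

    Nodes are visited in topological order. For a modelled node the bounds
    are the model's prediction interval evaluated at the parents' current
    values (interval midpoints for already-propagated parents); for the
    unmodelled readmissions node the observed value +/- a relative half-width;
    decision and exogenous variables get degenerate bounds [v, v]. Table
    columns outside the network (professional rates) are carried over as
    degenerate bounds so downstream DEA scenarios can reference them.
    """
    if readmission_halfwidth < 0:
        raise ValueError("readmission_halfwidth must be >= 0")
    frame = table.to_frame().set_index("area_id")
    variables = [c for c in frame.columns]
    area_ids = list(frame.index)
    lo = np.zeros((len(area_ids), len(variables)))
    hi = np.zeros_like(lo)
    order = network.topological_order()
    net_nodes = set(network.node_names)

    for i, area in enumerate(area_ids):
        current: dict[str, float] = {v: float(frame.loc[area, v]) for v in variables}
        for name in order:
            if name not in variables:
                continue
            model = network.model(name)
            if model is not None:
                if model.transform is None:
                    raise ValueError(f"model for {name!r} has no variable transform")
                missing = [s for s in model.transform.sources if s not in current]
                if missing:
                    raise ValueError(f"node {name!r}: missing parent value(s) {missing}")
                x = model.transform.apply({s: current[s] for s in model.transform.sources})
                if model.form == "product_unit" and np.any(x <= 0):
                    raise ValueError(
                        f"node {name!r} in area {area!r}: nonpositive regressor "
                        "violates the product-unit domain"
                    )
                point, lo_v, hi_v = model.predict_interval(x, level=level)
                scale = model.response_divisor
                lo_v, hi_v = lo_v * scale, hi_v * scale
                current[name] = (lo_v + hi_v) / 2.0
            elif name == "readmissions":
                v = current[name]
                lo_v = v * (1.0 - readmission_halfwidth)
                hi_v = v * (1.0 + readmission_halfwidth)
            else:
                # decision / exogenous: degenerate at the observed value
                lo_v = hi_v = current[name]
            j = variables.index(name)
            lo[i, j], hi[i, j] = lo_v, hi_v
        for v in variables:
            if v not in net_nodes:
                j = variables.index(v)
                lo[i, j] = hi[i, j] = current[v]

    stay_model = network.model("stay_days") if "stay_days" in net_nodes else None
    if stay_model is not None and all(b > 0 for b in stay_model.betas):
        warnings.warn(
            "fitted stay model has a positive exponent: more outpatient activity "
            "propagates into *longer* inpatient stay, contrary to the balance-of-care "
            "expectation; the fitted sign is used as-is",
            stacklevel=2,
        )
    return DistributionTable(area_ids, variables, lo, hi, label=label or table.label)
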