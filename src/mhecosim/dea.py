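"""Data envelopment analysis under variable returns to scale (BCC model).

Each catchment area is a decision-making unit (DMU). The input-oriented
envelopment program contracts a DMU's inputs as far as the convex hull of
observed practice allows at unchanged outputs:

    min theta  s.t.  X' lam <= theta x0,  Y' lam >= y0,  sum lam = 1, lam >= 0

and the output-oriented program expands outputs at unchanged inputs
(max phi); output-oriented scores are reported as 1/phi so both orientations
share the (0, 1] scale. Programs are solved with scipy's HiGHS interface;
`rte_all` can batch all DMUs of an instance into one block-diagonal LP, which
is mathematically identical (the blocks share nothing) and much faster than
one solver call per DMU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .ecosystem import EcosystemTable
from .scenarios import Scenario

__all__ = ["DEAInstance", "RTEResult", "rte_input_oriented", "rte_output_oriented", "rte_all"]

logger = logging.getLogger(__name__)

Orientation = Literal["input", "output"]

_PEER_THRESHOLD = 1e-6
_EPS_FLOOR_FACTOR = 1e-6


@dataclass
class DEAInstance:
    """Strictly positive input/output matrices over a common set of DMUs."""

    inputs: np.ndarray   # (n_areas, n_inputs)
    outputs: np.ndarray  # (n_areas, n_outputs)
    area_ids: list[str]

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        n = len(self.area_ids)
        if n < 2:
            raise ValueError("DEA needs at least 2 DMUs")
        if self.inputs.ndim != 2 or self.outputs.ndim != 2:
            raise ValueError("inputs and outputs must be 2-D matrices")
        if self.inputs.shape[0] != n or self.outputs.shape[0] != n:
            raise ValueError("matrix row counts must match the number of areas")
        if self.inputs.shape[1] < 1 or self.outputs.shape[1] < 1:
            raise ValueError("need at least one input and one output variable")
        if np.any(~np.isfinite(self.inputs)) or np.any(~np.isfinite(self.outputs)):
            raise ValueError("non-finite DEA data")
        if np.any(self.inputs <= 0) or np.any(self.outputs <= 0):
            raise ValueError("DEA data must be strictly positive (apply the epsilon floor)")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @classmethod
    def from_table(cls, table: EcosystemTable, scenario: Scenario) -> "DEAInstance":
        """Assemble the instance for one scenario, flooring near-zero cells.

        Zero or near-zero cells (e.g. a zero psychologist rate) make the
        envelopment LP degenerate; they are floored at
        ``1e-6 x column mean`` and the event is logged.
        """
        frame = table.to_frame().set_index("area_id")
        missing = [v for v in (*scenario.inputs, *scenario.outputs) if v not in frame.columns]
        if missing:
            raise ValueError(f"scenario {scenario.id!r}: variables absent from table: {missing}")
        X = frame[list(scenario.inputs)].to_numpy(dtype=float)
        Y = frame[list(scenario.outputs)].to_numpy(dtype=float)
        for M, names in ((X, scenario.inputs), (Y, scenario.outputs)):
            col_mean = M.mean(axis=0)
            floor = _EPS_FLOOR_FACTOR * np.where(col_mean > 0, col_mean, 1.0)
            low = M < floor
            if low.any():
                for j, name in enumerate(names):
                    k = int(low[:, j].sum())
                    if k:
                        logger.info(
                            "scenario %s: floored %d cell(s) of %s at %.3e",
                            scenario.id, k, name, floor[j],
                        )
                np.copyto(M, np.maximum(M, floor))
        return cls(X, Y, list(frame.index))


@dataclass
class RTEResult:
    """Relative technical efficiency of one DMU under one orientation."""

    area_id: str
    orientation: Orientation
    score: float
    lambdas: np.ndarray
    peers: list[str]

    def __post_init__(self) -> None:
        if not (0.0 < self.score <= 1.0):
            raise ValueError(f"score {self.score} outside (0, 1]")
        if abs(float(np.sum(self.lambdas)) - 1.0) > 1e-8:
            raise ValueError("intensity weights must sum to 1")
        if np.any(self.lambdas < -1e-10):
            raise ValueError("negative intensity weight")


def _make_result(
    instance: DEAInstance, idx: int, orientation: Orientation, raw: float, lam: np.ndarray
) -> RTEResult:
    score = 1.0 / raw if orientation == "output" else raw
    if score > 1.0 or score < 0.0:
        if score > 1.0 + 1e-6 or score < -1e-6:
            logger.warning(
                "clipping %s-oriented score %.9f for %s into [0, 1]",
                orientation, score, instance.area_ids[idx],
            )
        score = min(max(score, 0.0), 1.0)
    if score >= 1.0 - 1e-9:
        # efficient DMUs are canonically their own reference (lam = self is
        # always an optimal solution at score 1)
        lam = np.zeros(instance.n_areas)
        lam[idx] = 1.0
    lam = np.maximum(lam, 0.0)
    lam = lam / lam.sum()
    peers = [instance.area_ids[j] for j in np.flatnonzero(lam > _PEER_THRESHOLD)]
    return RTEResult(instance.area_ids[idx], orientation, score, lam, peers)


def _solve_single(instance: DEAInstance, idx: int, orientation: Orientation) -> RTEResult:
    X, Y = instance.inputs, instance.outputs
    n, m = X.shape
    s = Y.shape[1]
    # variables: [t, lam_1..lam_n]; t is theta (min) or phi (max)
    c = np.zeros(n + 1)
    c[0] = 1.0 if orientation == "input" else -1.0
    A_ub = np.zeros((m + s, n + 1))
    b_ub = np.zeros(m + s)
    if orientation == "input":
        A_ub[:m, 0] = -X[idx]
        A_ub[:m, 1:] = X.T
        A_ub[m:, 1:] = -Y.T
        b_ub[m:] = -Y[idx]
    else:
        A_ub[:m, 1:] = X.T
        b_ub[:m] = X[idx]
        A_ub[m:, 0] = Y[idx]
        A_ub[m:, 1:] = -Y.T
    A_eq = np.zeros((1, n + 1))
    A_eq[0, 1:] = 1.0
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
        bounds=[(None, None)] + [(0.0, None)] * n, method="highs",
        options={"primal_feasibility_tolerance": 1e-9, "dual_feasibility_tolerance": 1e-9},
    )
    if res.status != 0:
        raise RuntimeError(
            f"envelopment LP failed for area {instance.area_ids[idx]!r} "
            f"({orientation}-oriented): {res.message} — the self-referencing solution "
            "is always feasible, so this signals malformed data"
        )
    return _make_result(instance, idx, orientation, float(res.x[0]), res.x[1:])


def rte_input_oriented(instance: DEAInstance, area_index: int) -> RTEResult:
    """Input-oriented VRS score (theta) for one DMU."""
    if not 0 <= area_index < instance.n_areas:
        raise IndexError(f"area_index {area_index} out of range")
    return _solve_single(instance, area_index, "input")


def rte_output_oriented(instance: DEAInstance, area_index: int) -> RTEResult:
    """Output-oriented VRS score reported as 1/phi, on the same (0, 1] scale."""
    if not 0 <= area_index < instance.n_areas:
        raise IndexError(f"area_index {area_index} out of range")
    return _solve_single(instance, area_index, "output")


def _solve_batch(instance: DEAInstance, orientation: Orientation) -> list[RTEResult]:
    """Solve all DMUs at once via one block-diagonal LP.

    Each DMU's program occupies an independent variable block, so the joint
    optimum of the summed objective equals the per-DMU optima.
    """
    X, Y = instance.inputs, instance.outputs
    n, m = X.shape
    s = Y.shape[1]
    nb = n + 1  # block width: [t, lam]
    rows_per = m + s
    data, rows, cols, b_ub = [], [], [], []
    lam_cols = np.arange(1, nb)
    for j in range(n):
        off = j * nb
        r0 = j * rows_per
        for i in range(m):
            if orientation == "input":
                rows.append(r0 + i); cols.append(off); data.append(-X[j, i])
                b_ub.append(0.0)
            else:
                b_ub.append(X[j, i])
            rows.extend([r0 + i] * n); cols.extend(off + lam_cols); data.extend(X[:, i])
        for t in range(s):
            r = r0 + m + t
            if orientation == "output":
                rows.append(r); cols.append(off); data.append(Y[j, t])
                b_ub.append(0.0)
            else:
                b_ub.append(-Y[j, t])
            rows.extend([r] * n); cols.extend(off + lam_cols); data.extend(-Y[:, t])
    A_ub = sp.csr_matrix((data, (rows, cols)), shape=(n * rows_per, n * nb))
    eq_rows = np.repeat(np.arange(n), n)
    eq_cols = (np.arange(n)[:, None] * nb + lam_cols[None, :]).ravel()
    A_eq = sp.csr_matrix((np.ones(n * n), (eq_rows, eq_cols)), shape=(n, n * nb))
    c = np.zeros(n * nb)
    c[::nb] = 1.0 if orientation == "input" else -1.0
    lb = np.zeros(n * nb)
    lb[::nb] = -np.inf
    res = linprog(
        c, A_ub=A_ub, b_ub=np.asarray(b_ub), A_eq=A_eq, b_eq=np.ones(n),
        bounds=np.column_stack([lb, np.full(n * nb, np.inf)]), method="highs",
        options={"primal_feasibility_tolerance": 1e-9, "dual_feasibility_tolerance": 1e-9},
    )
    if res.status != 0:
        raise RuntimeError(
            f"batched envelopment LP failed ({orientation}-oriented): {res.message}"
        )
    out = []
    for j in range(n):
        block = res.x[j * nb : (j + 1) * nb]
        out.append(_make_result(instance, j, orientation, float(block[0]), block[1:]))
    return out


def rte_all(
    instance: DEAInstance, orientation: Orientation = "input", batch: bool = True
) -> list[RTEResult]:
    """Scores for every DMU, ordered like ``instance.area_ids``.

    The per-DMU programs are independent; ``batch=True`` solves them in one
    block-diagonal LP call (identical results, far less solver overhead).
    """
    if orientation not in ("input", "output"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if batch:
        return _solve_batch(instance, orientation)
    return [_solve_single(instance, j, orientation) for j in range(instance.n_areas)]
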