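"""Constrained fuzzy-logic simulation of Boolean networks.

Variables carry continuous activities in [0, 1].  Relations evaluate with
Goedel semantics — AND is min, OR is max, negation is 1 - x — and the
combined value passes through the output variable's transfer function
(identity by default, or a normalized Hill curve).  Updates are synchronous:
every variable's next value is computed from the previous global state.  A
variable produced by several relations takes the max (OR) of their values;
a variable with no relation holds its value, which is how clamped root
inputs behave.

The simulation stops when the maximum change between consecutive states
falls below ``convergence_tol`` (default 1e-6) or when the iteration count
reaches the larger of 100 and 1.2x the number of variables.  Restricted to
{0, 1} states with identity transfers, the dynamics coincide exactly with a
two-state synchronous Boolean update.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

import numpy as np

from .boolean_builder import AND, ASSIGN, OR, BooleanNetwork, BooleanRelation
from .errors import AttractorError, ValidationError

PathLike = Union[str, Path]

#: tolerance for matching attractor rows; below convergence_tol, above float noise
ATTRACTOR_TOL = 1e-9


@dataclass(frozen=True)
class TransferFunction:
    """Map applied to a relation's combined value before assignment.

    ``identity`` passes the value through.  ``hill`` is the normalized Hill
    curve f(x) = x**n * (1 + k**n) / (x**n + k**n) with exponent ``hill_n``
    and half-maximal point ``hill_k``; the normalization pins f(1) = 1, and
    f(0) = 0 with f monotone increasing on [0, 1].
    """

    form: str = "identity"
    hill_n: float = 3.0
    hill_k: float = 0.5

    def __post_init__(self) -> None:
        if self.form not in ("identity", "hill"):
            raise ValidationError(f"transfer.form: {self.form!r} not identity/hill")
        if self.form == "hill":
            if not self.hill_n > 0:
                raise ValidationError("transfer.hill_n: must be > 0")
            if not 0 < self.hill_k <= 1:
                raise ValidationError("transfer.hill_k: must be in (0, 1]")

    def __call__(self, x: float) -> float:
        if self.form == "identity":
            return x
        kn = self.hill_k**self.hill_n
        xn = x**self.hill_n
        return min(1.0, max(0.0, xn * (1.0 + kn) / (xn + kn))) if xn + kn > 0 else 0.0


IDENTITY = TransferFunction()

Transfers = Mapping[str, Callable[[float], float]]


@dataclass
class SimulationConfig:
    """Simulation and trace-expansion parameters.

    ``max_iterations=None`` applies the default rule
    max(100, ceil(1.2 * variable count)).  ``initial_values`` overrides the
    network defaults per variable; values must lie in [0, 1].
    """

    convergence_tol: float = 1e-6
    max_iterations: Optional[int] = None
    expansion_step: int = 20
    expansion_tol: float = 0.01
    expansion_cap: int = 1000
    initial_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("convergence_tol", "expansion_tol"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"config.{name}: must be > 0")
        if self.expansion_step <= 0 or self.expansion_cap <= 0:
            raise ValidationError("config.expansion_step/expansion_cap: must be > 0")
        for var, val in self.initial_values.items():
            if not 0.0 <= val <= 1.0:
                raise ValidationError(
                    f"config.initial_values[{var!r}]: {val} outside [0, 1]"
                )


@dataclass
class SimulationTrace:
    """Per-variable fuzzy values over time; row 0 is the initial state."""

    variables: tuple[str, ...]
    values: np.ndarray  # shape (steps, len(variables))
    terminated_by: str  # "converged" | "iteration_cap"
    attractor: Optional[tuple[int, int]] = None  # (start index, period)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.variables):
            raise ValidationError("trace.values: shape must be (steps, variables)")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValidationError("trace.values: outside [0, 1]")

    def __len__(self) -> int:
        return self.values.shape[0]

    def column(self, var: str) -> np.ndarray:
        return self.values[:, self.variables.index(var)]

    def state(self, row: int) -> dict[str, float]:
        return dict(zip(self.variables, self.values[row]))

    def to_tsv(self, path: PathLike) -> None:
        """Export as TSV: a step column plus one column per variable."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("step\t" + "\t".join(self.variables) + "\n")
            for i, row in enumerate(self.values):
                fh.write(str(i) + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def default_initial_values(network: BooleanNetwork) -> dict[str, float]:
    """Default setup: 1.0 for root inputs (and, transitively, the components
    they are built from), 0.0 for every other variable."""
    hot = network.root_inputs | network.root_components
    return {v: (1.0 if v in hot else 0.0) for v in network.variables}


def eval_relation(
    relation: BooleanRelation,
    state: Mapping[str, float],
    transfers: Optional[Transfers] = None,
) -> float:
    """Evaluate one relation against a state; min/max/1-x semantics, then the
    output's transfer function.  A missing variable raises KeyError."""
    vals = [1.0 - state[l.var] if l.negated else state[l.var] for l in relation.literals]
    if relation.op == AND:
        combined = min(vals)
    elif relation.op == OR:
        combined = max(vals)
    else:  # ASSIGN
        combined = vals[0]
    tf = transfers.get(relation.output, IDENTITY) if transfers else IDENTITY
    return float(tf(combined))


def step(
    network: BooleanNetwork,
    state: Mapping[str, float],
    transfers: Optional[Transfers] = None,
) -> dict[str, float]:
    """One synchronous update: relation outputs take the OR (max) over their
    relations' values; variables with no relation hold."""
    new = dict(state)
    for out, rels in network.relations_by_output().items():
        new[out] = max(eval_relation(r, state, transfers) for r in rels)
    return new


def simulate(
    network: BooleanNetwork,
    config: Optional[SimulationConfig] = None,
    transfers: Optional[Transfers] = None,
) -> SimulationTrace:
    """Run the synchronous fuzzy simulation under the stopping rule.

    Initial values come from the network defaults overridden by
    ``config.initial_values``.  On convergence the attractor is the final
    fixed point; otherwise a cycle attractor is searched for in the trace.
    """
    config = config or SimulationConfig()
    variables = tuple(sorted(network.variables))
    init = default_initial_values(network)
    for var, val in config.initial_values.items():
        if var not in network.variables:
            raise ValidationError(f"initial value for unknown variable {var!r}")
        init[var] = val

    grouped = network.relations_by_output()
    cap = config.max_iterations if config.max_iterations is not None else network.iteration_cap()

    state = init
    rows = [np.array([state[v] for v in variables], dtype=float)]
    terminated = "iteration_cap"
    for _ in range(cap):
        new = dict(state)
        for out, rels in grouped.items():
            new[out] = max(eval_relation(r, state, transfers) for r in rels)
        row = np.array([new[v] for v in variables], dtype=float)
        delta = float(np.max(np.abs(row - rows[-1]))) if len(row) else 0.0
        rows.append(row)
        state = new
        if delta < config.convergence_tol:
            terminated = "converged"
            break

    trace = SimulationTrace(variables, np.vstack(rows), terminated)
    if terminated == "converged":
        trace.attractor = (len(trace) - 1, 1)
    else:
        trace.attractor = detect_attractor(trace)
    return trace


def detect_attractor(
    trace: SimulationTrace, tol: float = ATTRACTOR_TOL
) -> Optional[tuple[int, int]]:
    """Smallest period p and earliest start s such that rows repeat with
    period p (within ``tol``, max norm) from s to the end; None if no repeat."""
    n = len(trace)
    if n < 2:
        return None
    v = trace.values
    for p in range(1, n):
        diffs = np.abs(v[p:] - v[:-p]).max(axis=1) if v.shape[1] else np.zeros(n - p)
        ok = diffs <= tol
        # earliest s with ok[s:] all true and at least one comparison
        bad = np.nonzero(~ok)[0]
        s = int(bad[-1]) + 1 if bad.size else 0
        if s <= n - 1 - p:
            return (s, p)
    return None


def replay_attractor(trace: SimulationTrace, target_len: int) -> np.ndarray:
    """Rows of the trace extended to ``target_len`` by replaying the attractor
    cycle in phase with the existing tail."""
    if trace.attractor is None:
        raise AttractorError(
            "trace has no detected attractor; raise the iteration cap and re-simulate"
        )
    s, p = trace.attractor
    n = len(trace)
    if target_len <= n:
        return trace.values[:target_len]
    cycle = trace.values[s : s + p]
    extra = np.array([cycle[(j - s) % p] for j in range(n, target_len)])
    return np.vstack([trace.values, extra])


def expand_trace(trace: SimulationTrace, config: Optional[SimulationConfig] = None) -> SimulationTrace:
    """Extend a trace along its attractor in blocks of ``expansion_step``.

    After each block the per-variable mean activity (AUC per step) is
    compared with the previous expansion; expansion stops when the largest
    change drops below ``expansion_tol`` or the trace reaches
    ``expansion_cap`` rows.  For the two-trace perturbation workflow the
    analogous lockstep expansion with relative-impact stopping lives in
    :mod:`boolpath.drug_perturbation`.
    """
    config = config or SimulationConfig()
    if trace.attractor is None:
        raise AttractorError(
            "trace has no detected attractor; raise the iteration cap and re-simulate"
        )
    values = trace.values
    metric = values.mean(axis=0)
    n = len(trace)
    while n < config.expansion_cap:
        target = min(n + config.expansion_step, config.expansion_cap)
        values = replay_attractor(
            SimulationTrace(trace.variables, values, trace.terminated_by, trace.attractor),
            target,
        )
        n = values.shape[0]
        new_metric = values.mean(axis=0)
        done = bool(np.max(np.abs(new_metric - metric)) < config.expansion_tol)
        metric = new_metric
        if done:
            break
    return SimulationTrace(trace.variables, values, trace.terminated_by, trace.attractor)
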