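"""Drug perturbation of fuzzy-logic pathway models.

A drug-target interaction's minimum supporting assay value (in nM) maps to a
perturbation strength through a hard-coded piecewise function::

    0.999                              if value < 1 nM
    0.99                               if value < 10 nM
    0.99 - 0.196 * (log10(value) - 1)  if value < 1e6 nM
    0                                  otherwise

clipped to [0, 0.999].  The log base is 10: the third branch equals 0.99 at
10 nM, so the function is continuous there and non-increasing throughout.

Inhibition with strength s multiplies a target's post-transfer value by
(1 - s) at every step; activation moves it toward 1 by v + s*(1 - v).  Both
preserve [0, 1] and reduce to no-ops at s = 0.  A targeted variable that has
no relation (a clamped root input) is never re-derived, so the drug is
applied to its initial value instead.

Impact is quantified per entity by the relative impact score

    score = (perturbation_AUC - reference_AUC) / (perturbation_AUC + reference_AUC)

where AUC is the sum of a variable's fuzzy values over the (expanded) trace,
one unit per step.  Scores lie in [-1, 1]; 0/0 is defined as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .boolean_builder import BooleanNetwork, build_network
from .errors import AttractorError, ContractError, EmptyTargetError, ResolutionError
from .evidence import DrugTargetInteraction
from .fuzzy_sim import (
    IDENTITY,
    SimulationConfig,
    SimulationTrace,
    Transfers,
    default_initial_values,
    replay_attractor,
    simulate,
)
from .pathway_model import Pathway

PathLike = Union[str, Path]

MECHANISMS = ("inhibition", "activation")


def strength_from_assay(min_assay_nM: float) -> float:
    """Map a minimum supporting assay value (nM) to a strength in [0, 0.999]."""
    if not min_assay_nM > 0:
        raise ValueError(f"assay value must be positive (nM), got {min_assay_nM}")
    if min_assay_nM < 1:
        return 0.999
    if min_assay_nM < 10:
        return 0.99
    if min_assay_nM < 1e6:
        return min(0.999, max(0.0, 0.99 - 0.196 * (math.log10(min_assay_nM) - 1.0)))
    return 0.0


def min_assay(
    interactions: Iterable[DrugTargetInteraction], drug: str, target: str
) -> Optional[float]:
    """Minimum assay value in nM across all assay types for a (drug, target)
    pair; None when no records match.  Drug names match case-insensitively,
    targets by their (uppercased) gene symbol."""
    drug_l, target_u = drug.lower(), target.upper()
    vals = [
        r.assay_value_nM
        for r in interactions
        if r.drug.lower() == drug_l and r.target.upper() == target_u
    ]
    return min(vals) if vals else None


@dataclass(frozen=True)
class DrugAction:
    """A drug applied to one or more network variables with one strength."""

    drug: str
    targets: tuple[str, ...]
    mechanism: str = "inhibition"
    strength: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism {self.mechanism!r} not one of {MECHANISMS}")
        if not 0.0 <= self.strength <= 0.999:
            raise ValueError(f"strength {self.strength} outside [0, 0.999]")

    def modify(self, value: float) -> float:
        if self.mechanism == "inhibition":
            return value * (1.0 - self.strength)
        return value + self.strength * (1.0 - value)


@dataclass(frozen=True)
class _DruggedTransfer:
    """A variable's own transfer function composed with a drug effect."""

    base: object  # Callable[[float], float]
    action: DrugAction

    def __call__(self, x: float) -> float:
        return self.action.modify(self.base(x))


def apply_drug(
    network: BooleanNetwork,
    transfers: Optional[Transfers],
    action: DrugAction,
) -> dict:
    """Return a transfer map where each target's post-transfer value passes
    through the drug effect; untargeted variables are unchanged."""
    new = dict(transfers) if transfers else {}
    for t in action.targets:
        if t not in network.variables:
            raise ResolutionError(f"drug target {t!r} is not a network variable")
        new[t] = _DruggedTransfer(new.get(t, IDENTITY), action)
    return new


@dataclass(frozen=True)
class ImpactScore:
    variable: str
    reference_auc: float
    perturbation_auc: float
    score: float


def relative_impact(
    reference: SimulationTrace, perturbed: SimulationTrace
) -> list[ImpactScore]:
    """Per-variable relative impact scores from two equal-shape traces."""
    if reference.variables != perturbed.variables:
        raise ContractError("traces cover different variables")
    if len(reference) != len(perturbed):
        raise ContractError(
            f"traces have different lengths ({len(reference)} vs {len(perturbed)}); "
            "expand them in lockstep first"
        )
    ref_auc = reference.values.sum(axis=0)
    per_auc = perturbed.values.sum(axis=0)
    denom = per_auc + ref_auc
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, (per_auc - ref_auc) / np.where(denom > 0, denom, 1.0), 0.0)
    return [
        ImpactScore(v, float(r), float(p), float(s))
        for v, r, p, s in zip(reference.variables, ref_auc, per_auc, scores)
    ]


def expand_pair(
    reference: SimulationTrace,
    perturbed: SimulationTrace,
    config: Optional[SimulationConfig] = None,
) -> tuple[SimulationTrace, SimulationTrace, list[ImpactScore]]:
    """Expand two traces in lockstep along their attractors.

    Both traces are first brought to a common length, then extended in
    blocks of ``expansion_step``; after each block the relative impact
    scores are recomputed, and expansion stops when the largest score change
    since the previous expansion drops below ``expansion_tol`` or the traces
    reach ``expansion_cap`` rows.  The returned traces always have equal
    lengths.
    """
    config = config or SimulationConfig()
    if reference.attractor is None or perturbed.attractor is None:
        raise AttractorError(
            "both traces need a detected attractor; raise the iteration cap"
        )

    def _ext(trace: SimulationTrace, target: int) -> SimulationTrace:
        return SimulationTrace(
            trace.variables,
            replay_attractor(trace, target),
            trace.terminated_by,
            trace.attractor,
        )

    n = min(max(len(reference), len(perturbed)), config.expansion_cap)
    ref, per = _ext(reference, n), _ext(perturbed, n)
    scores = relative_impact(ref, per)
    while n < config.expansion_cap:
        n = min(n + config.expansion_step, config.expansion_cap)
        ref, per = _ext(ref, n), _ext(per, n)
        new_scores = relative_impact(ref, per)
        delta = max(
            (abs(a.score - b.score) for a, b in zip(new_scores, scores)), default=0.0
        )
        scores = new_scores
        if delta < config.expansion_tol:
            break
    return ref, per, scores


@dataclass
class PerturbationStudy:
    reference: SimulationTrace
    perturbed: SimulationTrace
    scores: list[ImpactScore]
    actions: list[DrugAction]

    def score_for(self, variable: str) -> ImpactScore:
        for s in self.scores:
            if s.variable == variable:
                return s
        raise KeyError(variable)


def run_perturbation_study(
    pathway: Pathway,
    interactions: Sequence[DrugTargetInteraction],
    drug: str,
    mechanism: str = "inhibition",
    config: Optional[SimulationConfig] = None,
    initial_overrides: Optional[dict[str, float]] = None,
    transfers: Optional[Transfers] = None,
) -> PerturbationStudy:
    """Reference vs drug-perturbed simulation of a pathway, with scores.

    The drug's targets are the interaction-table gene symbols that resolve
    to entity variables of the compiled network; each target gets its own
    strength from its minimum supporting assay value.  Both simulations use
    identical initial values (plus the drug effect on targeted clamped
    inputs) and are expanded in lockstep before scoring.
    """
    network = build_network(pathway)
    drug_l = drug.lower()
    targets = sorted(
        {
            r.target
            for r in interactions
            if r.drug.lower() == drug_l and r.target in network.variables
        }
    )
    if not targets:
        raise EmptyTargetError(
            f"drug {drug!r} has no target mapping to a pathway entity"
        )
    actions = [
        DrugAction(
            drug,
            (t,),
            mechanism,
            strength_from_assay(min_assay(interactions, drug, t)),
        )
        for t in targets
    ]

    config = config or SimulationConfig()
    init = default_initial_values(network)
    init.update(initial_overrides or {})
    init.update(config.initial_values)

    ref_config = SimulationConfig(
        convergence_tol=config.convergence_tol,
        max_iterations=config.max_iterations,
        expansion_step=config.expansion_step,
        expansion_tol=config.expansion_tol,
        expansion_cap=config.expansion_cap,
        initial_values=init,
    )
    reference = simulate(network, ref_config, transfers)

    drugged = dict(transfers) if transfers else {}
    init_pert = dict(init)
    relation_outputs = {rel.output for rel in network.relations}
    for action in actions:
        drugged = apply_drug(network, drugged, action)
        for t in action.targets:
            # clamped targets are never re-derived; drug acts on the held value
            if t not in relation_outputs:
                init_pert[t] = action.modify(init_pert[t])
    pert_config = SimulationConfig(
        convergence_tol=config.convergence_tol,
        max_iterations=config.max_iterations,
        expansion_step=config.expansion_step,
        expansion_tol=config.expansion_tol,
        expansion_cap=config.expansion_cap,
        initial_values=init_pert,
    )
    perturbed = simulate(network, pert_config, drugged)

    reference, perturbed, scores = expand_pair(reference, perturbed, config)
    return PerturbationStudy(reference, perturbed, scores, actions)


def write_scores(scores: Sequence[ImpactScore], path: PathLike) -> int:
    """Export scores as TSV (variable, reference_auc, perturbation_auc, score)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variable\treference_auc\tperturbation_auc\tscore\n")
        for s in scores:
            fh.write(
                f"{s.variable}\t{s.reference_auc:.10g}\t"
                f"{s.perturbation_auc:.10g}\t{s.score:.10g}\n"
            )
    return len(scores)
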