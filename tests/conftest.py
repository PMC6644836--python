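"""Shared fixtures and independent oracles.

The oracle functions here re-derive expected behavior by brute force
(truth-table enumeration, a pure two-state Boolean simulator, closed-form
multiple-testing arithmetic) and are deliberately written without reusing
the library's evaluation code paths.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from boolpath.boolean_builder import BooleanNetwork, build_network
from boolpath.fixtures import (
    make_feedback_loop_pathway,
    make_kinase_inhibitor_table,
    make_typical_reaction,
)
from boolpath.pathway_model import Pathway, Reaction


@pytest.fixture
def typical_pathway() -> Pathway:
    return make_typical_reaction()


@pytest.fixture
def loop_pathway() -> Pathway:
    return make_feedback_loop_pathway(4)


@pytest.fixture
def loop_network(loop_pathway) -> BooleanNetwork:
    return build_network(loop_pathway)


@pytest.fixture
def kinase_table():
    return make_kinase_inhibitor_table()


# ---------------------------------------------------------------------------
# oracles


def reaction_truth(reaction: Reaction, assignment: dict[str, int]) -> int:
    """Direct Boolean semantics of a reaction: all inputs and catalysts, at
    least one activator (when any are annotated), and no inhibitor."""
    drive = all(assignment[e] for e in reaction.inputs + reaction.catalysts)
    act = any(assignment[e] for e in reaction.activators) if reaction.activators else True
    inh = any(assignment[e] for e in reaction.inhibitors)
    return int(drive and act and not inh)


def eval_compiled(relations, base: dict[str, int]) -> dict[str, int]:
    """Evaluate compiled relations over a base assignment by repeated passes
    (single-reaction compilations are acyclic, so this reaches a fixpoint)."""
    vals: dict[str, int] = dict(base)
    for _ in range(len(relations) + 1):
        for rel in relations:
            try:
                lits = [(1 - vals[l.var]) if l.negated else vals[l.var] for l in rel.literals]
            except KeyError:
                continue
            if rel.op == "AND":
                vals[rel.output] = min(lits)
            elif rel.op == "OR":
                vals[rel.output] = max(lits)
            else:
                vals[rel.output] = lits[0]
    return vals


def boolean_step(network: BooleanNetwork, state: dict[str, int]) -> dict[str, int]:
    """Pure two-state synchronous Boolean update, independent of the fuzzy
    evaluator: AND=all, OR=any, NOT=logical complement, relations sharing an
    output combine by any()."""
    new = dict(state)
    for out, rels in network.relations_by_output().items():
        votes = []
        for rel in rels:
            bits = [
                (not state[l.var]) if l.negated else bool(state[l.var])
                for l in rel.literals
            ]
            if rel.op == "AND":
                votes.append(all(bits))
            elif rel.op == "OR":
                votes.append(any(bits))
            else:
                votes.append(bits[0])
        new[out] = int(any(votes))
    return new


def binomial_upper_tail_enum(k: int, n: int, p: float) -> float:
    """P(X >= k) by exhaustive summation of the binomial pmf."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def bh_stepup_closed_form(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j, mapped
    back to input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * m / rank)
        q[idx] = running
    return q


def all_assignments(names: list[str]):
    for bits in range(2 ** len(names)):
        yield {name: (bits >> i) & 1 for i, name in enumerate(names)}
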