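"""Compile a reaction-based pathway into a Boolean network.

Conversion scheme:

* A reaction becomes an AND over its inputs, catalysts, an activator term and
  a negated inhibitor term, assigned to its output term.  When a role
  (activators, inhibitors, outputs) has two or more members an accessory
  variable is introduced: activators/inhibitors combine by OR into their
  accessory; a multi-output reaction drives an output accessory that is then
  assigned to every output.  A role with exactly one member is wired
  directly, with no accessory — the semantics are identical.
* A complex requires every subunit: AND over components.
* An entity set is satisfied by any member: OR over components.

Component AND/OR relations are emitted only for containers that are not
produced by any reaction; a produced container's formation is modeled by its
producing reaction(s), and an unconditional subunit relation would override
reaction-driven dynamics.

An entity produced by several reactions has several relations with the same
output variable; they combine by OR at evaluation time.

Root inputs are the entities the default simulation setup clamps to 1.0:
entities in an upstream role of some reaction that either never appear as a
reaction output, or feed a reaction lying on a directed cycle of the
entity-reaction graph.  ``root_components`` is the transitive component
closure of root-input containers, needed so a clamped complex is not zeroed
by its own subunit relation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Union
from pathlib import Path

import networkx as nx

from .errors import IntegrityError, ValidationError
from .pathway_model import CONTAINER_CLASSES, Entity, Pathway, Reaction

AND, OR, ASSIGN = "AND", "OR", "ASSIGN"

ENTITY = "entity"
ACCESSORY_OUTPUT = "accessory_output"
ACCESSORY_ACTIVATOR = "accessory_activator"
ACCESSORY_INHIBITOR = "accessory_inhibitor"

PathLike = Union[str, Path]


def output_accessory_id(reaction_id: str) -> str:
    return f"{reaction_id}:output_acc"


def activator_accessory_id(reaction_id: str) -> str:
    return f"{reaction_id}:activator_acc"


def inhibitor_accessory_id(reaction_id: str) -> str:
    return f"{reaction_id}:inhibitor_acc"


@dataclass(frozen=True)
class Literal:
    var: str
    negated: bool = False


@dataclass(frozen=True)
class BooleanVariable:
    id: str
    kind: str = ENTITY


@dataclass(frozen=True)
class BooleanRelation:
    """One logic rule with a single output variable.

    ``AND``/``OR`` combine two or more literals; ``ASSIGN`` copies exactly
    one.  Negation is only legal on inhibitor literals inside an AND.
    """

    output: str
    op: str
    literals: tuple[Literal, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "literals", tuple(self.literals))
        if self.op not in (AND, OR, ASSIGN):
            raise ValidationError(f"relation.op: {self.op!r} not one of AND/OR/ASSIGN")
        if not self.literals:
            raise ValidationError(f"relation {self.output!r}: literals must be nonempty")
        if self.op == ASSIGN and len(self.literals) != 1:
            raise ValidationError(
                f"relation {self.output!r}: ASSIGN requires exactly one literal"
            )
        if self.op != AND and any(l.negated for l in self.literals):
            raise ValidationError(
                f"relation {self.output!r}: negation only allowed within AND relations"
            )


@dataclass
class BooleanNetwork:
    variables: dict[str, BooleanVariable]
    relations: tuple[BooleanRelation, ...]
    root_inputs: frozenset[str] = frozenset()
    root_components: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.relations = tuple(self.relations)
        self.validate()

    def validate(self) -> None:
        for rel in self.relations:
            if rel.output not in self.variables:
                raise IntegrityError(f"relation output {rel.output!r} is not declared")
            for lit in rel.literals:
                if lit.var not in self.variables:
                    raise IntegrityError(
                        f"literal {lit.var!r} in relation for {rel.output!r} "
                        "is not declared"
                    )
        bad = [v for v in self.root_inputs if self.variables.get(v, BooleanVariable("", "")).kind != ENTITY]
        if bad or not self.root_inputs <= set(self.variables):
            raise IntegrityError(
                "root_inputs must be declared entity variables; offending: "
                + ", ".join(sorted(set(bad) | (self.root_inputs - set(self.variables))))
            )

    def relations_by_output(self) -> dict[str, tuple[BooleanRelation, ...]]:
        grouped: dict[str, list[BooleanRelation]] = {}
        for rel in self.relations:
            grouped.setdefault(rel.output, []).append(rel)
        return {k: tuple(v) for k, v in grouped.items()}

    def iteration_cap(self) -> int:
        """Iteration bound for simulation: larger of 100 and 1.2x variable count."""
        return max(100, math.ceil(1.2 * len(self.variables)))


def _dedup(literals: Iterable[Literal]) -> tuple[Literal, ...]:
    # AND/OR are idempotent: keep one copy per (variable, polarity), first wins;
    # x and !x both survive (their AND is constant 0 at the Boolean corners)
    seen: set[tuple[str, bool]] = set()
    out = []
    for lit in literals:
        key = (lit.var, lit.negated)
        if key not in seen:
            seen.add(key)
            out.append(lit)
    return tuple(out)


def _combine(output: str, literals: tuple[Literal, ...], op: str) -> BooleanRelation:
    if len(literals) == 1 and not literals[0].negated:
        return BooleanRelation(output, ASSIGN, literals)
    return BooleanRelation(output, op, literals)


def convert_reaction(reaction: Reaction) -> list[BooleanRelation]:
    """Compile one reaction into its Boolean relations.

    The main relation ANDs inputs, catalysts, the activator term and the
    negated inhibitor term into the output term; accessory OR relations
    define multi-member activator/inhibitor terms and ASSIGN relations fan a
    multi-output accessory out to each product.
    """
    relations: list[BooleanRelation] = []
    literals = [Literal(v) for v in reaction.inputs + reaction.catalysts]

    accessory_rels: list[BooleanRelation] = []
    if reaction.activators:
        if len(reaction.activators) == 1:
            literals.append(Literal(reaction.activators[0]))
        else:
            acc = activator_accessory_id(reaction.id)
            literals.append(Literal(acc))
            accessory_rels.append(
                BooleanRelation(acc, OR, _dedup(Literal(v) for v in reaction.activators))
            )
    if reaction.inhibitors:
        if len(reaction.inhibitors) == 1:
            literals.append(Literal(reaction.inhibitors[0], negated=True))
        else:
            acc = inhibitor_accessory_id(reaction.id)
            literals.append(Literal(acc, negated=True))
            accessory_rels.append(
                BooleanRelation(acc, OR, _dedup(Literal(v) for v in reaction.inhibitors))
            )

    lits = _dedup(literals)
    if len(reaction.outputs) == 1:
        out_term = reaction.outputs[0]
    else:
        out_term = output_accessory_id(reaction.id)
    relations.append(_combine(out_term, lits, AND))
    relations.extend(accessory_rels)
    if len(reaction.outputs) > 1:
        for out in reaction.outputs:
            relations.append(BooleanRelation(out, ASSIGN, (Literal(out_term),)))
    return relations


def expand_complex(entity: Entity) -> BooleanRelation:
    """A complex requires all subunits: AND over components."""
    if entity.entity_class != "complex":
        raise ValidationError(f"entity {entity.id!r} is not a complex")
    if not entity.components:
        raise IntegrityError(f"complex {entity.id!r} has no components")
    return _combine(entity.id, _dedup(Literal(c) for c in entity.components), AND)


def expand_entity_set(entity: Entity) -> BooleanRelation:
    """An entity set is satisfied by any member: OR over components."""
    if entity.entity_class != "entity_set":
        raise ValidationError(f"entity {entity.id!r} is not an entity_set")
    if not entity.components:
        raise IntegrityError(f"entity_set {entity.id!r} has no members")
    return _combine(entity.id, _dedup(Literal(c) for c in entity.components), OR)


def _accessory_variables(reaction: Reaction) -> list[BooleanVariable]:
    out = []
    if len(reaction.outputs) > 1:
        out.append(BooleanVariable(output_accessory_id(reaction.id), ACCESSORY_OUTPUT))
    if len(reaction.activators) > 1:
        out.append(BooleanVariable(activator_accessory_id(reaction.id), ACCESSORY_ACTIVATOR))
    if len(reaction.inhibitors) > 1:
        out.append(BooleanVariable(inhibitor_accessory_id(reaction.id), ACCESSORY_INHIBITOR))
    return out


def _cyclic_reaction_ids(pathway: Pathway) -> frozenset[str]:
    """Reactions lying on a directed cycle of the entity->reaction->entity graph."""
    g = nx.DiGraph()
    for rid, r in pathway.reactions.items():
        rnode = ("r", rid)
        for e in r.upstream():
            g.add_edge(("e", e), rnode)
        for o in r.outputs:
            g.add_edge(rnode, ("e", o))
    cyclic: set[str] = set()
    for scc in nx.strongly_connected_components(g):
        if len(scc) > 1:
            cyclic.update(rid for kind, rid in scc if kind == "r")
    return frozenset(cyclic)


def compute_root_inputs(pathway: Pathway) -> frozenset[str]:
    """Entities in an upstream role that never appear as outputs, or that feed
    a reaction on a directed cycle."""
    produced = pathway.produced_entity_ids()
    cyclic = _cyclic_reaction_ids(pathway)
    roots: set[str] = set()
    for rid, r in pathway.reactions.items():
        for e in r.upstream():
            if e not in produced or rid in cyclic:
                roots.add(e)
    return frozenset(roots)


def _component_closure(pathway: Pathway, seeds: Iterable[str]) -> frozenset[str]:
    out: set[str] = set()
    stack = list(seeds)
    while stack:
        eid = stack.pop()
        for c in pathway.entities[eid].components:
            if c not in out:
                out.add(c)
                stack.append(c)
    return frozenset(out)


def build_network(pathway: Pathway) -> BooleanNetwork:
    """Compile a pathway into a deterministic Boolean network.

    All iteration is in lexicographic id order, so the same pathway always
    yields a byte-identical serialized network.
    """
    variables: dict[str, BooleanVariable] = {}
    for eid in sorted(pathway.entities):
        variables[eid] = BooleanVariable(eid, ENTITY)
    relations: list[BooleanRelation] = []
    for rid in sorted(pathway.reactions):
        r = pathway.reactions[rid]
        for var in _accessory_variables(r):
            variables[var.id] = var
        relations.extend(convert_reaction(r))

    produced = pathway.produced_entity_ids()
    for eid in sorted(pathway.entities):
        e = pathway.entities[eid]
        if e.is_container and eid not in produced:
            if e.entity_class == "complex":
                relations.append(expand_complex(e))
            else:
                relations.append(expand_entity_set(e))

    roots = compute_root_inputs(pathway)
    return BooleanNetwork(
        variables=dict(sorted(variables.items())),
        relations=tuple(relations),
        root_inputs=roots,
        root_components=_component_closure(pathway, roots),
    )


# ---------------------------------------------------------------------------
# serialization


def relation_to_rule(rel: BooleanRelation) -> str:
    """Render one relation in the human-readable rule syntax (AND as a middle
    dot, OR as +, negation as !)."""
    sep = {AND: " · ", OR: " + ", ASSIGN: ""}[rel.op]
    lhs = sep.join(("!" if l.negated else "") + l.var for l in rel.literals)
    return f"{lhs} = {rel.output}"


def network_to_rules(network: BooleanNetwork) -> str:
    return "".join(relation_to_rule(rel) + "\n" for rel in network.relations)


def network_to_dict(network: BooleanNetwork) -> dict:
    return {
        "variables": [
            {"id": v.id, "kind": v.kind} for v in network.variables.values()
        ],
        "relations": [
            {
                "output": rel.output,
                "op": rel.op,
                "literals": [{"var": l.var, "negated": l.negated} for l in rel.literals],
            }
            for rel in network.relations
        ],
        "root_inputs": sorted(network.root_inputs),
        "root_components": sorted(network.root_components),
    }


def network_from_dict(data: dict) -> BooleanNetwork:
    return BooleanNetwork(
        variables={v["id"]: BooleanVariable(v["id"], v["kind"]) for v in data["variables"]},
        relations=tuple(
            BooleanRelation(
                r["output"],
                r["op"],
                tuple(Literal(l["var"], l["negated"]) for l in r["literals"]),
            )
            for r in data["relations"]
        ),
        root_inputs=frozenset(data.get("root_inputs", ())),
        root_components=frozenset(data.get("root_components", ())),
    )


def write_network_json(network: BooleanNetwork, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(network_to_dict(network), fh, indent=1)
        fh.write("\n")


def write_rules(network: BooleanNetwork, path: PathLike) -> int:
    """Write the rule file (one relation per line); returns the line count."""
    text = network_to_rules(network)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return len(network.relations)
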