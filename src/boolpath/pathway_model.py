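"""Reaction-centric pathway model: domain types, JSON I/O and SIF export.

A pathway is a set of biochemical reactions linked together.  Each reaction
has one or more inputs, zero or more catalysts, activators and inhibitors,
and one or more outputs, all referring to entities by id.  Entities are
proteins, small molecules, complexes (require every subunit), entity sets
(interchangeable members) or "other".  Entity ids are opaque: joins happen
on ids only, never on display names.

JSON dialect (version 1.0), UTF-8::

    {
      "schema_version": "1.0",
      "id": "...", "name": "...",
      "entities": [
        {"id": "...", "name": "...", "entity_class": "protein",
         "components": ["..."]}          # components only for complex/entity_set
      ],
      "reactions": [
        {"id": "...", "inputs": ["..."], "outputs": ["..."],
         "catalysts": [...], "activators": [...], "inhibitors": [...]}
      ]
    }

SIF export writes one tab-separated ``source  relation  target`` row per
reaction-role edge (``input``/``catalyst``/``activator``/``inhibitor`` point
at the reaction id, ``output`` points from it) and one ``component`` row per
container membership.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from .errors import IntegrityError, ValidationError

SCHEMA_VERSION = "1.0"
ENTITY_CLASSES = ("protein", "small_molecule", "complex", "entity_set", "other")
CONTAINER_CLASSES = frozenset({"complex", "entity_set"})
#: fixed SIF relation vocabulary
SIF_RELATIONS = ("input", "catalyst", "activator", "inhibitor", "output", "component")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class Entity:
    """A pathway participant.  ``components`` is nonempty iff the entity is a
    complex or an entity set."""

    id: str
    name: str = ""
    entity_class: str = "protein"
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("entity.id: must be a nonempty string")
        if self.entity_class not in ENTITY_CLASSES:
            raise ValidationError(
                f"entity {self.id!r}.entity_class: {self.entity_class!r} "
                f"not one of {ENTITY_CLASSES}"
            )
        object.__setattr__(self, "components", tuple(self.components))
        is_container = self.entity_class in CONTAINER_CLASSES
        if is_container and not self.components:
            raise IntegrityError(
                f"entity {self.id!r}: {self.entity_class} requires nonempty components"
            )
        if not is_container and self.components:
            raise ValidationError(
                f"entity {self.id!r}.components: only complex/entity_set entities "
                "may declare components"
            )

    @property
    def is_container(self) -> bool:
        return self.entity_class in CONTAINER_CLASSES


@dataclass(frozen=True)
class Reaction:
    """A biochemical reaction.  Inputs and outputs are mandatory; catalysts,
    activators and inhibitors are optional roles.  Multiple catalysts are
    allowed and all enter the AND like inputs."""

    id: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    catalysts: tuple[str, ...] = ()
    activators: tuple[str, ...] = ()
    inhibitors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction.id: must be a nonempty string")
        for role in ("inputs", "outputs", "catalysts", "activators", "inhibitors"):
            object.__setattr__(self, role, tuple(getattr(self, role)))
        if not self.inputs:
            raise ValidationError(f"reaction {self.id!r}.inputs: must be nonempty")
        if not self.outputs:
            raise ValidationError(f"reaction {self.id!r}.outputs: must be nonempty")

    def upstream(self) -> tuple[str, ...]:
        """Entity ids in any upstream role (input, catalyst, activator, inhibitor)."""
        return self.inputs + self.catalysts + self.activators + self.inhibitors


@dataclass
class Pathway:
    """A validated collection of entities and reactions."""

    id: str
    name: str = ""
    entities: dict[str, Entity] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)

    @classmethod
    def from_parts(
        cls,
        id: str,
        entities: Iterable[Entity],
        reactions: Iterable[Reaction] = (),
        name: str = "",
    ) -> "Pathway":
        pw = cls(id=id, name=name)
        for e in entities:
            if e.id in pw.entities:
                raise IntegrityError(f"duplicate entity id {e.id!r}")
            pw.entities[e.id] = e
        for r in reactions:
            if r.id in pw.reactions:
                raise IntegrityError(f"duplicate reaction id {r.id!r}")
            pw.reactions[r.id] = r
        pw.validate()
        return pw

    def validate(self) -> None:
        """Check referential integrity and acyclic containment."""
        dangling: list[str] = []
        for e in self.entities.values():
            dangling += [c for c in e.components if c not in self.entities]
        for r in self.reactions.values():
            dangling += [x for x in r.upstream() + r.outputs if x not in self.entities]
        if dangling:
            raise IntegrityError(
                "unresolved entity references: " + ", ".join(sorted(set(dangling)))
            )
        # no complex/set may contain itself transitively
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(eid: str, chain: tuple[str, ...]) -> None:
            if state.get(eid) == 1:
                return
            if state.get(eid) == 0:
                raise IntegrityError(
                    "cyclic containment: " + " -> ".join(chain + (eid,))
                )
            state[eid] = 0
            for c in self.entities[eid].components:
                visit(c, chain + (eid,))
            state[eid] = 1

        for eid in self.entities:
            visit(eid, ())

    def produced_entity_ids(self) -> frozenset[str]:
        """Ids of entities appearing as an output of at least one reaction."""
        return frozenset(o for r in self.reactions.values() for o in r.outputs)


# ---------------------------------------------------------------------------
# JSON I/O


def _require(obj: dict, key: str, typ, where: str):
    if key not in obj:
        raise ValidationError(f"{where}.{key}: missing required field")
    val = obj[key]
    if not isinstance(val, typ):
        raise ValidationError(
            f"{where}.{key}: expected {typ.__name__}, got {type(val).__name__}"
        )
    return val


def _id_list(obj: dict, key: str, where: str, required: bool = False) -> tuple[str, ...]:
    if key not in obj:
        if required:
            raise ValidationError(f"{where}.{key}: missing required field")
        return ()
    val = obj[key]
    if not isinstance(val, list) or not all(isinstance(x, str) for x in val):
        raise ValidationError(f"{where}.{key}: expected a list of strings")
    return tuple(val)


def pathway_from_dict(data: dict) -> Pathway:
    if not isinstance(data, dict):
        raise ValidationError("pathway: top-level JSON value must be an object")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"pathway.schema_version: unsupported version {version!r} "
            f"(this reader supports {SCHEMA_VERSION})"
        )
    pid = _require(data, "id", str, "pathway")
    name = data.get("name", "")
    entities = []
    for i, ed in enumerate(_require(data, "entities", list, "pathway")):
        where = f"pathway.entities[{i}]"
        if not isinstance(ed, dict):
            raise ValidationError(f"{where}: expected an object")
        entities.append(
            Entity(
                id=_require(ed, "id", str, where),
                name=ed.get("name", ""),
                entity_class=ed.get("entity_class", "protein"),
                components=_id_list(ed, "components", where),
            )
        )
    reactions = []
    for i, rd in enumerate(data.get("reactions", [])):
        where = f"pathway.reactions[{i}]"
        if not isinstance(rd, dict):
            raise ValidationError(f"{where}: expected an object")
        reactions.append(
            Reaction(
                id=_require(rd, "id", str, where),
                inputs=_id_list(rd, "inputs", where, required=True),
                outputs=_id_list(rd, "outputs", where, required=True),
                catalysts=_id_list(rd, "catalysts", where),
                activators=_id_list(rd, "activators", where),
                inhibitors=_id_list(rd, "inhibitors", where),
            )
        )
    return Pathway.from_parts(pid, entities, reactions, name=name)


def pathway_to_dict(pathway: Pathway) -> dict:
    def ent(e: Entity) -> dict:
        d = {"id": e.id, "name": e.name, "entity_class": e.entity_class}
        if e.components:
            d["components"] = list(e.components)
        return d

    def rxn(r: Reaction) -> dict:
        d = {"id": r.id, "inputs": list(r.inputs), "outputs": list(r.outputs)}
        for role in ("catalysts", "activators", "inhibitors"):
            vals = getattr(r, role)
            if vals:
                d[role] = list(vals)
        return d

    return {
        "schema_version": SCHEMA_VERSION,
        "id": pathway.id,
        "name": pathway.name,
        "entities": [ent(e) for _, e in sorted(pathway.entities.items())],
        "reactions": [rxn(r) for _, r in sorted(pathway.reactions.items())],
    }


def read_pathway(path: PathLike) -> Pathway:
    """Read and validate a pathway JSON file."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"pathway: invalid JSON in {path}: {exc}") from exc
    return pathway_from_dict(data)


def write_pathway(pathway: Pathway, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(pathway_to_dict(pathway), fh, indent=1, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SIF export


def sif_rows(pathway: Pathway) -> list[tuple[str, str, str]]:
    """Derive (source, relation, target) triples from reaction roles and
    container membership, in deterministic id order."""
    rows: list[tuple[str, str, str]] = []
    for rid, r in sorted(pathway.reactions.items()):
        for e in r.inputs:
            rows.append((e, "input", rid))
        for e in r.catalysts:
            rows.append((e, "catalyst", rid))
        for e in r.activators:
            rows.append((e, "activator", rid))
        for e in r.inhibitors:
            rows.append((e, "inhibitor", rid))
        for e in r.outputs:
            rows.append((rid, "output", e))
    for eid, e in sorted(pathway.entities.items()):
        for c in e.components:
            rows.append((c, "component", eid))
    return rows


def write_sif(pathway: Pathway, path: PathLike) -> int:
    """Write the derived wiring as SIF; returns the number of rows written."""
    rows = sif_rows(pathway)
    with open(path, "w", encoding="utf-8") as fh:
        for src, rel, dst in rows:
            fh.write(f"{src}\t{rel}\t{dst}\n")
    return len(rows)
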