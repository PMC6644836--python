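"""Deterministic generators for every input format the package consumes.

Everything here is synthetic and seeded: the same arguments always produce
byte-identical artifacts, so the whole pipeline is testable without any
download.  The generators emulate the *shape* of the real resources (a
receptor-kinase pathway with a product-recycling loop, multi-assay drug
tables, enrichment gene sets, a mutation-count FI overlay), not their
statistical texture.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .enrichment import GeneSet
from .evidence import ASSAY_TYPES, DrugTargetInteraction, InteractionList
from .fi_network import FIEdge
from .pathway_model import Entity, Pathway, Reaction

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# pathways


def make_typical_reaction() -> Pathway:
    """One reaction with 2 inputs, 1 catalyst, 2 activators, 2 inhibitors and
    2 outputs — the shape that exercises every accessory-node rule."""
    ids = [
        "activator1", "activator2", "catalyst", "inhibitor1", "inhibitor2",
        "input1", "input2", "output1", "output2",
    ]
    entities = [Entity(i, name=i) for i in ids]
    reaction = Reaction(
        id="R1",
        inputs=("input1", "input2"),
        catalysts=("catalyst",),
        activators=("activator1", "activator2"),
        inhibitors=("inhibitor1", "inhibitor2"),
        outputs=("output1", "output2"),
    )
    return Pathway.from_parts("typical", entities, [reaction], name="typical reaction")


def make_feedback_loop_pathway(loop_reactions: int = 4, seed: int = 0) -> Pathway:
    """A receptor-kinase pathway whose output complex is produced by a
    product-recycling loop.

    Structure: a ligand (SCF) and a receptor kinase (KIT, the druggable
    target) sit upstream.  KIT is activated into pKIT by a reaction that is
    inhibited by the kinase-regulator complex IC = pKIT:PKC — a negative
    feedback that makes pKIT (and everything downstream) oscillate under the
    default all-active setup.  pKIT catalyzes the entry reaction forming the
    loop entry complex LOOP_0, which runs through ``loop_reactions``
    reactions; the final one regenerates LOOP_0 and emits the output complex
    OUT (built from two transcription-factor subunits STATA/STATB).

    Reducing PKC's initial value from 1.0 raises the floor of the
    oscillation (the inhibitor complex can never exceed PKC's level), and
    inhibiting KIT collapses the loop's activity — the two behaviors the
    perturbation workflow is designed to expose.  ``seed`` is accepted for
    interface uniformity; the topology is fully determined by
    ``loop_reactions``.
    """
    if loop_reactions < 2:
        raise ValueError(f"loop_reactions must be >= 2, got {loop_reactions}")
    m = loop_reactions
    loop_ids = [f"LOOP_{i}" for i in range(m)]
    entities = [
        Entity("SCF", name="ligand"),
        Entity("KIT", name="receptor kinase"),
        Entity("PKC", name="kinase regulator"),
        Entity("STATA", name="TF subunit A"),
        Entity("STATB", name="TF subunit B"),
        Entity("pKIT", name="active kinase"),
        Entity("IC", name="kinase:regulator complex", entity_class="complex",
               components=("PKC", "pKIT")),
        Entity("OUT", name="output TF dimer", entity_class="complex",
               components=("STATA", "STATB")),
    ] + [
        Entity(lid, name=f"loop intermediate {i}", entity_class="complex",
               components=("SCF", "pKIT"))
        for i, lid in enumerate(loop_ids)
    ]
    reactions = [
        Reaction("R_activate", inputs=("KIT",), inhibitors=("IC",), outputs=("pKIT",)),
        Reaction("R_regulate", inputs=("pKIT", "PKC"), outputs=("IC",)),
        Reaction("R_entry", inputs=("SCF",), catalysts=("pKIT",), outputs=(loop_ids[0],)),
    ]
    for i in range(1, m):
        reactions.append(
            Reaction(f"R_loop_{i}", inputs=(loop_ids[i - 1],), outputs=(loop_ids[i],))
        )
    reactions.append(
        Reaction(
            f"R_loop_{m}",
            inputs=(loop_ids[m - 1], "STATA", "STATB"),
            catalysts=("pKIT",),
            outputs=(loop_ids[0], "OUT"),
        )
    )
    return Pathway.from_parts(
        f"loop{m}", entities, reactions, name=f"{m}-reaction recycling loop"
    )


def make_random_pathway(
    seed: int, n_entities: int = 10, n_reactions: int = 6
) -> Pathway:
    """A random reaction wiring over a shared entity pool; used for
    oracle-equivalence property testing."""
    rng = np.random.default_rng(seed)
    pool = [f"P{i:02d}" for i in range(n_entities)]
    entities = [Entity(p) for p in pool]
    reactions = []
    for i in range(n_reactions):
        pick = lambda lo, hi: list(
            rng.choice(pool, size=int(rng.integers(lo, hi + 1)), replace=False)
        )
        reactions.append(
            Reaction(
                id=f"R{i:02d}",
                inputs=tuple(pick(1, 2)),
                outputs=tuple(pick(1, 2)),
                catalysts=tuple(pick(0, 1)),
                activators=tuple(pick(0, 2)),
                inhibitors=tuple(pick(0, 2)),
            )
        )
    return Pathway.from_parts(f"random{seed}", entities, reactions)


def make_random_reaction(seed: int, max_vars: int = 12) -> Reaction:
    """A random single reaction whose base variables number at most
    ``max_vars``; roles may share entities."""
    rng = np.random.default_rng(seed)
    pool = [f"E{i:02d}" for i in range(max_vars)]
    n_in = int(rng.integers(1, 4))
    n_cat = int(rng.integers(0, 3))
    n_act = int(rng.integers(0, 4))
    n_inh = int(rng.integers(0, 4))
    n_out = int(rng.integers(1, 4))
    base = list(rng.permutation(pool))
    take = lambda n: tuple(
        rng.choice(base[: max_vars - n_out], size=n, replace=False)
    ) if n else ()
    outputs = tuple(base[max_vars - n_out :])
    return Reaction(
        id=f"RX{seed}",
        inputs=take(n_in),
        catalysts=take(n_cat),
        activators=take(n_act),
        inhibitors=take(n_inh),
        outputs=outputs,
    )


def reaction_pathway(reaction: Reaction) -> Pathway:
    """Wrap a single reaction into a pathway declaring every referenced entity."""
    ids = sorted(set(reaction.upstream() + reaction.outputs))
    return Pathway.from_parts(f"pw_{reaction.id}", [Entity(i) for i in ids], [reaction])


# ---------------------------------------------------------------------------
# drug tables


def make_drug_table(n_drugs: int = 4, n_targets: int = 6, seed: int = 0) -> InteractionList:
    """A reproducible interaction table.

    Every drug-target pair gets 2-4 assay rows; assay values are log-uniform
    over [0.1, 1e6] nM, and four pinned rows (0.5, 5, 1e3 and 1e6 nM) on the
    first pair guarantee the table spans all four branches of the
    affinity-to-strength map.
    """
    if n_drugs < 1 or n_targets < 1:
        raise ValueError("n_drugs and n_targets must be >= 1")
    rng = np.random.default_rng(seed)
    drugs = [f"DRUG{i + 1:02d}" for i in range(n_drugs)]
    targets = [f"GENE{i + 1:02d}" for i in range(n_targets)]
    records = []
    pinned = [0.5, 5.0, 1.0e3, 1.0e6]
    for j, value in enumerate(pinned):
        records.append(
            DrugTargetInteraction(
                drugs[0], targets[0], ASSAY_TYPES[j % 4], value,
                source="synthetic", pubmed_id=str(10_000_000 + j),
            )
        )
    for drug in drugs:
        for target in targets:
            for _ in range(int(rng.integers(2, 5))):
                value = float(10.0 ** rng.uniform(-1.0, 6.0))
                records.append(
                    DrugTargetInteraction(
                        drug, target,
                        ASSAY_TYPES[int(rng.integers(0, 4))], value,
                        source="synthetic",
                        pubmed_id=str(int(rng.integers(20_000_000, 30_000_000))),
                    )
                )
    return InteractionList(records)


def make_kinase_inhibitor_table() -> InteractionList:
    """Drug evidence for the loop fixture: KINI binds KIT with a 16 nM KD as
    its minimum (plus a weaker IC50), and NOOP01 binds KIT only at 1e6 nM
    (strength 0)."""
    return InteractionList(
        [
            DrugTargetInteraction("KINI", "KIT", "KD", 16.0, source="synthetic"),
            DrugTargetInteraction("KINI", "KIT", "IC50", 40.0, source="synthetic"),
            DrugTargetInteraction("NOOP01", "KIT", "KD", 1.0e6, source="synthetic"),
        ]
    )


def write_interactions_tsv(records: InteractionList, path: PathLike) -> int:
    """Write records in the targetome dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\ttarget\tassay_type\tassay_value_nM\tsource\tpubmed_id\n")
        for r in records:
            fh.write(
                f"{r.drug}\t{r.target}\t{r.assay_type}\t{r.assay_value_nM:.10g}\t"
                f"{r.source}\t{r.pubmed_id or ''}\n"
            )
    return len(records)


# ---------------------------------------------------------------------------
# enrichment fixtures


#: (pathway name, printed size, member genes of the 12-gene kinase-inhibitor query)
MULTIKINASE_PATHWAYS: tuple[tuple[str, int, tuple[str, ...]], ...] = (
    ("Signaling by Receptor Tyrosine Kinases", 406,
     ("FLT1", "FLT3", "FLT4", "KDR", "PDGFRB", "PDGFRA", "BRAF", "MAPK14", "KIT", "FGFR3")),
    ("RAF/MAP kinase cascade", 202,
     ("RET", "FLT3", "PDGFRB", "PDGFRA", "BRAF", "KIT", "RAF1", "FGFR3")),
    ("MAPK1/MAPK3 signaling", 207,
     ("RET", "FLT3", "PDGFRB", "PDGFRA", "BRAF", "KIT", "RAF1", "FGFR3")),
    ("MAPK family signaling cascades", 246,
     ("RET", "FLT3", "PDGFRB", "PDGFRA", "BRAF", "KIT", "RAF1", "FGFR3")),
    ("VEGF ligand-receptor interactions", 8, ("FLT1", "FLT4", "KDR")),
    ("VEGF binds to VEGFR leading to receptor dimerization", 8, ("FLT1", "FLT4", "KDR")),
    ("Neurophilin interactions with VEGF and VEGFR", 4, ("FLT1", "KDR")),
    ("PI5P, PP2A and IER3 Regulate PI3K/AKT Signaling", 90,
     ("PDGFRB", "PDGFRA", "KIT", "FGFR3")),
    ("Signaling by VEGF", 94, ("FLT1", "FLT4", "KDR", "MAPK14")),
    ("Negative regulation of the PI3K/AKT network", 95,
     ("PDGFRB", "PDGFRA", "KIT", "FGFR3")),
    ("Negative feedback regulation of MAPK pathway", 6, ("BRAF", "RAF1")),
    ("RAF activation", 12, ("BRAF", "RAF1")),
)

#: the 12 query genes (union of the pathway memberships above)
MULTIKINASE_TARGETS: tuple[str, ...] = (
    "FLT1", "FLT3", "FLT4", "KDR", "PDGFRB", "PDGFRA",
    "BRAF", "MAPK14", "KIT", "FGFR3", "RET", "RAF1",
)


def make_multikinase_genesets() -> tuple[list[GeneSet], list[str]]:
    """Gene sets shaped like the enrichment of a promiscuous kinase
    inhibitor's target list: 12 pathways with fixed sizes and fixed query
    memberships, padded with unique synthetic filler genes."""
    sets = []
    for i, (name, size, members) in enumerate(MULTIKINASE_PATHWAYS):
        filler = [f"SYN{i:02d}_{j:04d}" for j in range(size - len(members))]
        sets.append(GeneSet(name, frozenset(members) | frozenset(filler),
                            description="synthetic fixture"))
    return sets, list(MULTIKINASE_TARGETS)


# ---------------------------------------------------------------------------
# FI network fixtures


def make_fi_fixture() -> tuple[list[FIEdge], dict[str, int], InteractionList]:
    """An FI overlay fixture mirroring a hub-drug pattern: 18 drugs interact
    with network genes at <= 100 nM, 14 of them bind the hub (EGFR), and one
    (SUNIM) bridges two disjoint-pathway kinases (TNIK, PAK3)."""
    counts = {
        "EGFR": 12, "TNIK": 7, "PAK3": 6, "NF1": 9, "CSMD3": 5,
        "FAT3": 8, "LOWG": 4,  # below the default 5-sample threshold
    }
    edges = [
        FIEdge("EGFR", "NF1", "activation", curated=True),
        FIEdge("EGFR", "TNIK", "predicted", curated=False),
        FIEdge("EGFR", "CSMD3", "complex_or_input", curated=True),
        FIEdge("TNIK", "FAT3", "catalysis", curated=True),
        FIEdge("PAK3", "NF1", "inhibition", curated=True),
        FIEdge("EGFR", "LOWG", "activation", curated=True),  # dropped with LOWG
        FIEdge("FAT3", "NF1", "predicted", curated=False),
    ]
    records = []
    for i in range(14):  # the 14 hub binders
        records.append(
            DrugTargetInteraction(f"HUBDRUG{i + 1:02d}", "EGFR", "KD",
                                  5.0 + 6.0 * i, source="synthetic")
        )
    records.append(DrugTargetInteraction("SUNIM", "TNIK", "KD", 50.0, source="synthetic"))
    records.append(DrugTargetInteraction("SUNIM", "PAK3", "Ki", 80.0, source="synthetic"))
    records.append(DrugTargetInteraction("DRUG_NF1", "NF1", "IC50", 90.0, source="synthetic"))
    records.append(DrugTargetInteraction("DRUG_FAT3", "FAT3", "EC50", 70.0, source="synthetic"))
    records.append(DrugTargetInteraction("DRUG_CSMD3", "CSMD3", "KD", 33.0, source="synthetic"))
    # above-threshold noise that must never produce an edge
    records.append(DrugTargetInteraction("WEAK01", "EGFR", "KD", 5000.0, source="synthetic"))
    return edges, counts, InteractionList(records)


def write_fi_edges_tsv(edges: list[FIEdge], path: PathLike) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tannotation\tcurated\n")
        for e in edges:
            flag = "curated" if e.curated else "predicted"
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.annotation}\t{flag}\n")
    return len(edges)


def write_mutation_counts_tsv(counts: dict[str, int], path: PathLike) -> int:
    pd.DataFrame(
        {"gene": list(counts), "samples": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)
    return len(counts)
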