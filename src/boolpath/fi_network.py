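"""Functional-interaction subnetworks with drug overlays.

Builds a gene-gene network from a functional-interaction (FI) edge list
restricted to genes mutated in at least a minimum number of samples, then
overlays drug nodes connected to genes they bind with supporting assay
values at or below a nanomolar threshold.  Drug nodes are a distinct node
class (``node_type`` attribute) so downstream renderers can style them;
this module does not render.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import pandas as pd

from .errors import FormatError
from .evidence import DrugTargetInteraction

PathLike = Union[str, Path]

ANNOTATIONS = (
    "activation",
    "catalysis",
    "inhibition",
    "complex_or_input",
    "predicted",
    "other",
)
#: annotations where edge direction is meaningful and endpoint order is kept
DIRECTIONAL = frozenset({"activation", "catalysis", "inhibition"})


@dataclass(frozen=True)
class FIEdge:
    """A functional interaction between two genes.

    Non-directional annotations are stored with endpoints in canonical
    (sorted) order; directional ones keep gene_a -> gene_b.
    """

    gene_a: str
    gene_b: str
    annotation: str = "other"
    curated: bool = False

    def __post_init__(self) -> None:
        a, b = self.gene_a.upper(), self.gene_b.upper()
        if a == b:
            raise ValueError(f"self-interaction {a!r} is not a valid FI edge")
        if self.annotation not in ANNOTATIONS:
            raise ValueError(f"annotation {self.annotation!r} not in {ANNOTATIONS}")
        if self.annotation not in DIRECTIONAL and a > b:
            a, b = b, a
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)


def read_fi_edges(path: PathLike) -> list[FIEdge]:
    """Read an FI edge list TSV: gene_a, gene_b, annotation, curated
    (curated/predicted or true/false)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene_a", "gene_b", "annotation", "curated"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing FI columns: {', '.join(missing)}")
    flags = {"curated": True, "true": True, "predicted": False, "false": False}
    edges = []
    for idx, row in frame.iterrows():
        flag = flags.get(row["curated"].strip().lower())
        if flag is None:
            raise FormatError(f"{path} row {idx}: bad curated flag {row['curated']!r}")
        edges.append(
            FIEdge(row["gene_a"], row["gene_b"], row["annotation"].strip(), flag)
        )
    return edges


def read_mutation_counts(path: PathLike) -> dict[str, int]:
    """Read a gene -> mutated-sample-count TSV (columns gene, samples)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "samples": int})
    if "gene" not in frame.columns or "samples" not in frame.columns:
        raise FormatError(f"{path}: expected columns gene, samples")
    counts = {str(g).upper(): int(s) for g, s in zip(frame["gene"], frame["samples"])}
    if any(c < 0 for c in counts.values()):
        raise FormatError(f"{path}: negative sample counts")
    return counts


def build_subnetwork(
    edges: Iterable[FIEdge],
    counts: Mapping[str, int],
    min_samples: int = 5,
) -> nx.Graph:
    """Network of genes mutated in at least ``min_samples`` samples.

    Nodes carry ``sample_count`` and ``node_type='gene'``; only FI edges with
    both endpoints retained survive.
    """
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    g = nx.Graph()
    for gene, count in counts.items():
        if count >= min_samples:
            g.add_node(gene.upper(), sample_count=int(count), node_type="gene")
    for e in edges:
        if g.has_node(e.gene_a) and g.has_node(e.gene_b):
            g.add_edge(e.gene_a, e.gene_b, annotation=e.annotation, curated=e.curated)
    return g


def overlay_drugs(
    network: nx.Graph,
    interactions: Sequence[DrugTargetInteraction],
    max_nM: float = 100.0,
) -> nx.Graph:
    """Add drug nodes and drug-gene edges where the gene is in the network
    and the minimum supporting assay value is <= max_nM (inclusive).  Edges
    carry that minimum as ``min_assay_nM``."""
    out = network.copy()
    genes = {n for n, d in network.nodes(data=True) if d.get("node_type") == "gene"}
    minima: dict[tuple[str, str], float] = {}
    for r in interactions:
        target = r.target.upper()
        if target in genes:
            key = (r.drug, target)
            minima[key] = min(minima.get(key, float("inf")), r.assay_value_nM)
    for (drug, gene), value in sorted(minima.items()):
        if value <= max_nM:
            if not out.has_node(drug):
                out.add_node(drug, node_type="drug")
            out.add_edge(drug, gene, annotation="drug_target", min_assay_nM=value)
    return out


def drug_degree(network: nx.Graph, gene: str) -> int:
    """Number of distinct drugs attached to a gene node."""
    return sum(
        1
        for nb in network.neighbors(gene.upper())
        if network.nodes[nb].get("node_type") == "drug"
    )


def write_sif(network: nx.Graph, path: PathLike) -> int:
    """SIF export: one ``source  annotation  target`` row per edge."""
    rows = 0
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, data in sorted(network.edges(data=True)):
            fh.write(f"{a}\t{data.get('annotation', 'other')}\t{b}\n")
            rows += 1
    return rows


def write_node_attributes(network: nx.Graph, path: PathLike) -> int:
    """Node attribute TSV: node, node_type, sample_count (empty for drugs)."""
    rows = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tnode_type\tsample_count\n")
        for node, data in sorted(network.nodes(data=True)):
            count = data.get("sample_count", "")
            fh.write(f"{node}\t{data.get('node_type', 'gene')}\t{count}\n")
            rows += 1
    return rows
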