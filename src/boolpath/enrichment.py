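"""Pathway enrichment by binomial test with Benjamini-Hochberg FDR.

For a query of n genes tested against a pathway of size s drawn from a
background of N genes, the enrichment p-value is the upper tail
P(X >= k) for X ~ Binomial(n, s/N), where k is the number of query genes in
the pathway.  P-values across pathways are corrected by the
Benjamini-Hochberg step-up procedure.  The background size N is an explicit
parameter: the result depends on it, and no universally right value exists
(20000 is a common, arbitrary choice for human protein-coding genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError

PathLike = Union[str, Path]

DEFAULT_BACKGROUND_SIZE = 20000


@dataclass(frozen=True)
class GeneSet:
    """A named set of uppercase gene symbols."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    pathway_size: int
    hits: int
    p_value: float
    fdr: float
    hit_genes: tuple[str, ...]


def binomial_pvalue(hits: int, query_size: int, pathway_size: int, background_size: int) -> float:
    """Upper-tail binomial p-value P(X >= k), X ~ Binomial(n, s/N)."""
    if not 0 <= hits <= query_size:
        raise ValueError(f"need 0 <= hits <= query_size, got {hits}, {query_size}")
    if not 0 < pathway_size <= background_size:
        raise ValueError(
            f"need 0 < pathway_size <= background_size, got {pathway_size}, {background_size}"
        )
    if hits == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy computes this stably in log space internally
    return float(stats.binom.sf(hits - 1, query_size, pathway_size / background_size))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def read_gmt(path: PathLike) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g), parts[1]))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: PathLike) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description] + sorted(gs.genes)) + "\n")
            n += 1
    return n


def read_gene_list(path: PathLike) -> list[str]:
    """Newline-delimited gene symbols; blank lines and '#' comments skipped."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return genes


def enrich(
    query_genes: Sequence[str],
    gene_sets: Sequence[GeneSet],
    background_size: int = DEFAULT_BACKGROUND_SIZE,
    fdr_cutoff: float = 1.0,
    background_genes: Optional[Iterable[str]] = None,
) -> list[EnrichmentResult]:
    """Rank gene sets by binomial enrichment of the query.

    Query genes are uppercased and deduplicated (order preserved).  When a
    background gene list is given, query genes outside it are dropped with a
    warning so n stays consistent with the model.  Results are sorted by
    p-value ascending (ties by pathway name) and filtered at the FDR cutoff;
    hit genes are listed in query order.
    """
    seen: set[str] = set()
    query: list[str] = []
    for g in query_genes:
        gu = g.upper()
        if gu not in seen:
            seen.add(gu)
            query.append(gu)
    if background_genes is not None:
        bg = {g.upper() for g in background_genes}
        dropped = [g for g in query if g not in bg]
        if dropped:
            warnings.warn(
                f"{len(dropped)} query gene(s) absent from the background were "
                f"dropped: {', '.join(dropped)}",
                stacklevel=2,
            )
        query = [g for g in query if g in bg]
    if not query:
        warnings.warn("empty query after normalization; no tests run", stacklevel=2)
        return []

    union = set().union(*(gs.genes for gs in gene_sets)) if gene_sets else set()
    if background_size < len(union):
        raise ValueError(
            f"background_size {background_size} smaller than the union of the "
            f"gene sets ({len(union)})"
        )

    rows = []
    for gs in gene_sets:
        hit_genes = tuple(g for g in query if g in gs.genes)
        p = binomial_pvalue(len(hit_genes), len(query), len(gs.genes), background_size)
        rows.append((gs, hit_genes, p))
    fdrs = bh_fdr([p for _, _, p in rows])
    results = [
        EnrichmentResult(gs.name, len(gs.genes), len(hits), p, q, hits)
        for (gs, hits, p), q in zip(rows, fdrs)
        if q <= fdr_cutoff
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def write_results(results: Sequence[EnrichmentResult], path: PathLike) -> int:
    """TSV export with one row per pathway: name, size, hit count, p, FDR, hits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "Pathway\tPathway Size\tNumber of Targets in Pathway\t"
            "P-value\tFDR\tTargets in Pathway\n"
        )
        for r in results:
            fh.write(
                f"{r.pathway}\t{r.pathway_size}\t{r.hits}\t{r.p_value:.6g}\t"
                f"{r.fdr:.6g}\t{','.join(r.hit_genes)}\n"
            )
    return len(results)
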