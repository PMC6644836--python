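"""Drug-target interaction evidence: reading, filtering, summarizing.

Two TSV dialects are supported.  The ``targetome`` dialect uses columns
``drug, target, assay_type, assay_value_nM, source, pubmed_id`` with assay
values already in nM.  The ``drugcentral`` dialect uses columns
``DRUG_NAME, GENE, ACT_TYPE, ACT_VALUE, ACT_SOURCE, ACT_PMID``; its native
activity scale is configuration, so when the activity column is on a
p-scale (-log10 molar, e.g. pKi) pass ``pscale=True`` to convert via
10**(9 - p) nM.  The conversion is never auto-detected: silent unit
guessing corrupts thresholds.

Malformed rows are never silently dropped; they are collected into the
returned list's ``rejects`` attribute with row index and reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError

PathLike = Union[str, Path]

ASSAY_TYPES = ("KD", "Ki", "IC50", "EC50")
_ASSAY_CANON = {t.upper(): t for t in ASSAY_TYPES}

DIALECTS = {
    "targetome": {
        "drug": "drug",
        "target": "target",
        "assay_type": "assay_type",
        "assay_value": "assay_value_nM",
        "source": "source",
        "pubmed_id": "pubmed_id",
    },
    "drugcentral": {
        "drug": "DRUG_NAME",
        "target": "GENE",
        "assay_type": "ACT_TYPE",
        "assay_value": "ACT_VALUE",
        "source": "ACT_SOURCE",
        "pubmed_id": "ACT_PMID",
    },
}


@dataclass(frozen=True)
class DrugTargetInteraction:
    """One supporting assay record for a drug-target interaction."""

    drug: str
    target: str
    assay_type: str
    assay_value_nM: float
    source: str = ""
    pubmed_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"assay_type {self.assay_type!r} not in {ASSAY_TYPES}")
        if not self.assay_value_nM > 0:
            raise ValueError(f"assay_value_nM must be positive, got {self.assay_value_nM}")


@dataclass(frozen=True)
class RejectedRow:
    index: int
    reason: str


class InteractionList(list):
    """A list of DrugTargetInteraction with a ``rejects`` report attached."""

    def __init__(self, records: Iterable[DrugTargetInteraction] = (), rejects=()):
        super().__init__(records)
        self.rejects: list[RejectedRow] = list(rejects)


def read_interactions(
    path: PathLike, dialect: str = "targetome", pscale: bool = False
) -> InteractionList:
    """Read a drug-target TSV under the named dialect's column map.

    Returns normalized records (values in nM); malformed rows go to the
    result's ``rejects``.  Raises FormatError when no row parses, ValueError
    for an unknown dialect.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    cols = DIALECTS[dialect]
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # unreadable / not a table at all
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    missing = [c for c in (cols["drug"], cols["target"], cols["assay_type"], cols["assay_value"]) if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required {dialect} columns: {', '.join(missing)}"
        )

    records: list[DrugTargetInteraction] = []
    rejects: list[RejectedRow] = []
    for idx, row in frame.iterrows():
        drug = row[cols["drug"]].strip()
        target = row[cols["target"]].strip()
        raw_type = row[cols["assay_type"]].strip()
        raw_val = row[cols["assay_value"]].strip()
        if not drug or not target:
            rejects.append(RejectedRow(int(idx), "empty drug or target"))
            continue
        assay_type = _ASSAY_CANON.get(raw_type.upper())
        if assay_type is None:
            rejects.append(RejectedRow(int(idx), f"unknown assay type {raw_type!r}"))
            continue
        try:
            value = float(raw_val)
        except ValueError:
            rejects.append(RejectedRow(int(idx), f"non-numeric assay value {raw_val!r}"))
            continue
        if pscale:
            value = 10.0 ** (9.0 - value)
        if not value > 0:
            rejects.append(RejectedRow(int(idx), f"non-positive assay value {value}"))
            continue
        records.append(
            DrugTargetInteraction(
                drug=drug,
                target=target.upper(),
                assay_type=assay_type,
                assay_value_nM=value,
                source=str(row.get(cols["source"], "")).strip(),
                pubmed_id=(str(row[cols["pubmed_id"]]).strip() or None)
                if cols["pubmed_id"] in frame.columns
                else None,
            )
        )
    if not records:
        raise FormatError(
            f"{path}: zero parseable rows under dialect {dialect!r} "
            f"({len(rejects)} rejected)"
        )
    return InteractionList(records, rejects)


def filter_by_assay(
    records: Sequence[DrugTargetInteraction],
    max_nM: float,
    assay_types: Optional[Iterable[str]] = None,
) -> InteractionList:
    """Retain records with assay value <= max_nM (inclusive) and assay type in
    the given subset (all four by default); order is stable."""
    if not max_nM > 0:
        raise ValueError(f"max_nM must be positive, got {max_nM}")
    allowed = frozenset(assay_types) if assay_types is not None else frozenset(ASSAY_TYPES)
    if not allowed:
        raise ValueError("assay_types subset must be nonempty")
    unknown = allowed - frozenset(ASSAY_TYPES)
    if unknown:
        raise ValueError(f"unknown assay types: {sorted(unknown)}")
    return InteractionList(
        r for r in records if r.assay_value_nM <= max_nM and r.assay_type in allowed
    )


@dataclass
class EvidenceSummary:
    """Per-target minima and a histogram of assay values for one drug.

    Histogram bins are half-open [lo, hi) with the final bin closed; counts
    sum to the number of records whose value falls within the bin range.
    ``multi_assay_targets`` are targets supported by two or more distinct
    assay types among the summarized records.
    """

    drug: str
    target_min_nM: dict[str, float] = field(default_factory=dict)
    bin_edges: tuple[float, ...] = ()
    bin_counts: tuple[int, ...] = ()
    multi_assay_targets: frozenset[str] = frozenset()

    def to_tsv(self, path: PathLike) -> int:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("target\tmin_assay_nM\tmulti_assay\n")
            for target, val in sorted(self.target_min_nM.items()):
                flag = "yes" if target in self.multi_assay_targets else "no"
                fh.write(f"{target}\t{val:.10g}\t{flag}\n")
        return len(self.target_min_nM)


def summarize(
    records: Sequence[DrugTargetInteraction],
    drug: str,
    bin_edges: Sequence[float],
) -> EvidenceSummary:
    """Summarize one drug's evidence: per-target minima, histogram, flags."""
    edges = tuple(float(e) for e in bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or len(edges) < 2:
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    drug_l = drug.lower()
    mine = [r for r in records if r.drug.lower() == drug_l]
    if not mine:
        warnings.warn(f"no interaction records for drug {drug!r}", stacklevel=2)
        return EvidenceSummary(drug, {}, edges, (0,) * (len(edges) - 1))
    minima: dict[str, float] = {}
    types: dict[str, set[str]] = {}
    for r in mine:
        minima[r.target] = min(minima.get(r.target, float("inf")), r.assay_value_nM)
        types.setdefault(r.target, set()).add(r.assay_type)
    counts, _ = np.histogram([r.assay_value_nM for r in mine], bins=np.asarray(edges))
    return EvidenceSummary(
        drug=drug,
        target_min_nM=minima,
        bin_edges=edges,
        bin_counts=tuple(int(c) for c in counts),
        multi_assay_targets=frozenset(t for t, s in types.items() if len(s) >= 2),
    )


def plot_histogram(summary: EvidenceSummary, path: PathLike) -> None:
    """Optional histogram image of a drug's assay-value evidence."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    edges = np.asarray(summary.bin_edges)
    ax.bar(
        range(len(summary.bin_counts)),
        summary.bin_counts,
        width=0.9,
        tick_label=[f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])],
    )
    ax.set_xlabel("assay value (nM)")
    ax.set_ylabel("interaction count")
    ax.set_title(f"Assay evidence for {summary.drug}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
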