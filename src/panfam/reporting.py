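"""Population-level summaries: copy-number matrix, size histogram, tallies."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptySummaryError
from .nomenclature import AccessionAssignment


@dataclass(frozen=True)
class CopyNumberMatrix:
    """Accession x core-index copy counts, with per-accession totals."""

    counts: pd.DataFrame  # index: accession id, columns: 1..K
    margin: pd.Series  # per-accession totals

    @property
    def k(self) -> int:
        return self.counts.shape[1]


def copy_matrix(
    assignments: Sequence[AccessionAssignment], k: int | None = None
) -> CopyNumberMatrix:
    """Count members per (accession, core index); rows sorted by accession.

    ``k`` defaults to the largest core index seen across all names; pass it
    explicitly when trailing clades could be absent from every accession.
    """
    if k is None:
        k = max(
            (nm.core_index for a in assignments for nm in a.names), default=0
        )
    rows = {}
    for a in sorted(assignments, key=lambda a: a.accession_id):
        row = [0] * k
        for nm in a.names:
            row[nm.core_index - 1] += 1
        rows[a.accession_id] = row
    counts = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(range(1, k + 1))
    )
    return CopyNumberMatrix(counts=counts, margin=counts.sum(axis=1))


@dataclass(frozen=True)
class FamilySummary:
    """Population-level membership statistics.

    ``n_all_core_single`` counts accessions carrying exactly one copy of
    every core clade and nothing else — the operational reading of
    "harboring all K core genes" that makes the per-size histogram and the
    duplicate/loss tallies partition the accession set.
    """

    n_accessions: int
    n_core: int
    total_members: int
    size_histogram: dict[int, int]
    n_all_core_single: int
    n_with_duplicates: int
    n_with_losses: int
    n_with_translocations: int
    n_with_unplaced: int
    n_unassigned_members: int
    group_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_accessions": self.n_accessions,
            "n_core": self.n_core,
            "total_members": self.total_members,
            "size_histogram": {
                str(k): v for k, v in sorted(self.size_histogram.items())
            },
            "n_all_core_single": self.n_all_core_single,
            "n_with_duplicates": self.n_with_duplicates,
            "n_with_losses": self.n_with_losses,
            "n_with_translocations": self.n_with_translocations,
            "n_with_unplaced": self.n_with_unplaced,
            "n_unassigned_members": self.n_unassigned_members,
            "group_counts": dict(sorted(self.group_counts.items())),
        }

    def to_text(self) -> str:
        lines = [
            f"accessions: {self.n_accessions}",
            f"core clades (K): {self.n_core}",
            f"total named members: {self.total_members}",
            "members per accession: "
            + ", ".join(
                f"{size}: {count}"
                for size, count in sorted(self.size_histogram.items())
            ),
            f"all-core single-copy accessions: {self.n_all_core_single}",
            f"accessions with >=1 additional copy: {self.n_with_duplicates}",
            f"accessions with >=1 loss: {self.n_with_losses}",
            f"accessions with >=1 translocation: {self.n_with_translocations}",
            f"accessions with >=1 unplaced member: {self.n_with_unplaced}",
            f"unassigned members: {self.n_unassigned_members}",
            "accession groups: "
            + ", ".join(
                f"{g}: {c}" for g, c in sorted(self.group_counts.items())
            ),
        ]
        return "\n".join(lines)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def summarize(
    assignments: Sequence[AccessionAssignment], k: int | None = None
) -> FamilySummary:
    """Summarise a full assignment set; raises on empty input."""
    if not assignments:
        raise EmptySummaryError("no accession assignments to summarise")
    if k is None:
        k = max(
            (nm.core_index for a in assignments for nm in a.names), default=0
        )
    from .family_io import UNPLACED, NameStatus

    histogram: dict[int, int] = {}
    n_all_core = n_dup = n_loss = n_transloc = n_unplaced = 0
    total = 0
    unassigned = 0
    groups: dict[str, int] = {}
    for a in assignments:
        size = len(a.names)
        histogram[size] = histogram.get(size, 0) + 1
        total += size
        unassigned += len(a.unassigned)
        group = a.accession_id[:1]
        groups[group] = groups.get(group, 0) + 1
        has_dup = any(nm.copy_ordinal >= 1 for nm in a.names)
        has_loss = bool(a.missing_core)
        if has_dup:
            n_dup += 1
        if has_loss:
            n_loss += 1
        if any(
            nm.status is NameStatus.CORE_TRANSLOCATED for nm in a.names
        ):
            n_transloc += 1
        if any(nm.actual_chrom == UNPLACED for nm in a.names):
            n_unplaced += 1
        if not has_dup and not has_loss and size == k:
            n_all_core += 1
    return FamilySummary(
        n_accessions=len(assignments),
        n_core=k,
        total_members=total,
        size_histogram=histogram,
        n_all_core_single=n_all_core,
        n_with_duplicates=n_dup,
        n_with_losses=n_loss,
        n_with_translocations=n_transloc,
        n_with_unplaced=n_unplaced,
        n_unassigned_members=unassigned,
        group_counts=groups,
    )


def write_matrix(matrix: CopyNumberMatrix, path: str | Path) -> None:
    """Write the copy-number matrix as TSV with a trailing total column."""
    out = matrix.counts.copy()
    out.columns = [str(c) for c in out.columns]
    out["total"] = matrix.margin
    out.to_csv(path, sep="\t", index_label="accession")
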