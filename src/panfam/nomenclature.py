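"""Per-accession classification against the core profile.

For each accession and core clade the classifier picks the *core instance*
(the member standing for the species-level core gene), labels it in-place /
translocated / unplaced, numbers every remaining member of the clade as an
additional copy in chromosomal order, and records clades with no member at
all as losses. Aggregated over accessions this yields a machine-readable
ledger of presence/absence, copy-number and translocation variation.

Core-instance selection, in order:

1. members on the expected chromosome x, nearest the clade's cross-accession
   median start (then lowest start) — so a tandem duplicate beside the
   canonical locus does not displace the resident copy;
2. otherwise, among placed members (unplaced members are never preferred
   over placed ones), the member with highest identity to the clade
   representative when sequences are available;
3. otherwise lowest (chromosome, start), unplaced last.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .core_inference import (
    DEFAULT_SCORING,
    AlignmentScoring,
    FamilyProfile,
    global_identity,
)
from .errors import ProfileMismatchError, UnassignableError
from .family_io import (
    UNASSIGNED,
    UNPLACED,
    AssignedName,
    MemberRecord,
    NameStatus,
)


class EventKind(str, Enum):
    TRANSLOCATION = "TRANSLOCATION"
    DUPLICATION = "DUPLICATION"
    LOSS = "LOSS"
    UNPLACED = "UNPLACED"


@dataclass(frozen=True)
class VariationEvent:
    """One atomic presence/position deviation from the core profile."""

    kind: EventKind
    accession_id: str
    core_index: int
    from_chrom: int
    to_chrom: int | None

    def __post_init__(self) -> None:
        if self.kind is EventKind.TRANSLOCATION and self.to_chrom in (
            self.from_chrom,
            UNPLACED,
            None,
        ):
            raise ProfileMismatchError(
                "translocation must move to a different, placed chromosome"
            )
        if self.kind is EventKind.LOSS and self.to_chrom is not None:
            raise ProfileMismatchError("loss carries no destination")


@dataclass(frozen=True)
class AccessionAssignment:
    """All names for one accession, plus its missing core indices."""

    accession_id: str
    names: tuple[AssignedName, ...]
    missing_core: frozenset[int]
    unassigned: tuple[MemberRecord, ...] = ()


def _positional_key(m: MemberRecord) -> tuple[bool, int, int, str]:
    # chromosome ascending with unplaced last, then start, then gene id
    return (not m.placed, m.chromosome, m.start_bp, m.gene_id)


def _core_status(chromosome: int, x: int) -> NameStatus:
    if chromosome == x:
        return NameStatus.CORE_IN_PLACE
    if chromosome == UNPLACED:
        return NameStatus.UNPLACED_CORE
    return NameStatus.CORE_TRANSLOCATED


def classify_accession(
    members: Sequence[MemberRecord],
    profile: FamilyProfile,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> AccessionAssignment:
    """Classify one accession's labeled members against the profile.

    Members must carry a clade label (a profile source label) or the
    unassigned sentinel; unassigned members are reported separately and
    receive no name. Numbering of the remaining clades is unaffected by
    losses, so a member keeps its core index even when another clade is
    absent from the accession.
    """
    members = list(members)
    accessions = {m.accession_id for m in members}
    if len(accessions) != 1:
        raise ProfileMismatchError(
            f"classify_accession expects one accession, got {sorted(accessions)}"
        )
    accession = accessions.pop()

    by_index: dict[int, list[MemberRecord]] = defaultdict(list)
    unassigned: list[MemberRecord] = []
    for m in members:
        if m.clade_label is None:
            raise UnassignableError(
                f"{m.gene_id}: member must be labeled before classification"
            )
        if m.clade_label == UNASSIGNED:
            unassigned.append(m)
            continue
        try:
            by_index[profile.index_for_label(m.clade_label)].append(m)
        except KeyError:
            raise ProfileMismatchError(
                f"{m.gene_id}: clade label {m.clade_label} is not in the "
                f"{profile.family_symbol} profile"
            ) from None

    names: list[AssignedName] = []
    missing: set[int] = set()
    for index in profile.indices:
        group = by_index.get(index)
        if not group:
            missing.add(index)
            continue
        clade = profile.clade(index)
        x = clade.expected_chrom
        core = _pick_core_instance(group, clade, scoring)
        names.append(
            AssignedName(
                accession_id=accession,
                family_symbol=profile.family_symbol,
                core_index=index,
                copy_ordinal=0,
                expected_chrom=x,
                actual_chrom=core.chromosome,
                status=_core_status(core.chromosome, x),
                gene_id=core.gene_id,
            )
        )
        rest = sorted(
            (m for m in group if m is not core), key=_positional_key
        )
        for ordinal, m in enumerate(rest, start=1):
            names.append(
                AssignedName(
                    accession_id=accession,
                    family_symbol=profile.family_symbol,
                    core_index=index,
                    copy_ordinal=ordinal,
                    expected_chrom=x,
                    actual_chrom=m.chromosome,
                    status=(
                        NameStatus.DUPLICATE
                        if m.placed
                        else NameStatus.UNPLACED_DUPLICATE
                    ),
                    gene_id=m.gene_id,
                )
            )

    return AccessionAssignment(
        accession_id=accession,
        names=tuple(names),
        missing_core=frozenset(missing),
        unassigned=tuple(unassigned),
    )


def _pick_core_instance(group, clade, scoring):
    if len(group) == 1:
        return group[0]
    on_x = [m for m in group if m.chromosome == clade.expected_chrom]
    if on_x:
        return min(
            on_x,
            key=lambda m: (
                abs(m.start_bp - clade.median_start),
                m.start_bp,
                m.gene_id,
            ),
        )
    placed = [m for m in group if m.placed]
    candidates = placed if placed else group
    rep = clade.representative_sequence
    if rep and all(m.sequence for m in candidates):
        best, best_ident = None, -1.0
        for m in sorted(candidates, key=_positional_key):
            ident = global_identity(m.sequence, rep, scoring)
            if ident > best_ident:
                best, best_ident = m, ident
        return best
    return min(candidates, key=_positional_key)


def classify_all(
    members: Iterable[MemberRecord],
    profile: FamilyProfile,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[AccessionAssignment]:
    """Classify every accession in the input, sorted by accession id."""
    by_acc: dict[str, list[MemberRecord]] = defaultdict(list)
    for m in members:
        by_acc[m.accession_id].append(m)
    return [
        classify_accession(by_acc[acc], profile, scoring)
        for acc in sorted(by_acc)
    ]


_KIND_ORDER = {
    EventKind.LOSS: 0,
    EventKind.TRANSLOCATION: 1,
    EventKind.DUPLICATION: 2,
    EventKind.UNPLACED: 3,
}


def detect_events(
    assignments: Iterable[AccessionAssignment], profile: FamilyProfile
) -> list[VariationEvent]:
    """Aggregate assignments into a deterministic variation-event ledger.

    One TRANSLOCATION per translocated core instance, one DUPLICATION per
    additional copy, one LOSS per missing core index and one UNPLACED per
    name on the unplaced sentinel (an unplaced additional copy therefore
    yields both a DUPLICATION and an UNPLACED event). Ordered by
    (accession, core index, copy ordinal, kind).
    """
    events: list[VariationEvent] = []
    for a in sorted(assignments, key=lambda a: a.accession_id):
        keyed: list[tuple[int, int, int, VariationEvent]] = []
        for nm in a.names:
            x, y = nm.expected_chrom, nm.actual_chrom
            if nm.status is NameStatus.CORE_TRANSLOCATED:
                keyed.append(
                    (
                        nm.core_index,
                        0,
                        _KIND_ORDER[EventKind.TRANSLOCATION],
                        VariationEvent(
                            EventKind.TRANSLOCATION, a.accession_id,
                            nm.core_index, x, y,
                        ),
                    )
                )
            if nm.copy_ordinal >= 1:
                keyed.append(
                    (
                        nm.core_index,
                        nm.copy_ordinal,
                        _KIND_ORDER[EventKind.DUPLICATION],
                        VariationEvent(
                            EventKind.DUPLICATION, a.accession_id,
                            nm.core_index, x, y,
                        ),
                    )
                )
            if y == UNPLACED:
                keyed.append(
                    (
                        nm.core_index,
                        nm.copy_ordinal,
                        _KIND_ORDER[EventKind.UNPLACED],
                        VariationEvent(
                            EventKind.UNPLACED, a.accession_id,
                            nm.core_index, x, UNPLACED,
                        ),
                    )
                )
        for index in a.missing_core:
            keyed.append(
                (
                    index,
                    0,
                    _KIND_ORDER[EventKind.LOSS],
                    VariationEvent(
                        EventKind.LOSS, a.accession_id, index,
                        profile.expected_chrom(index), None,
                    ),
                )
            )
        keyed.sort(key=lambda t: t[:3])
        events.extend(e for *_, e in keyed)
    return events


def write_events(
    events: Iterable[VariationEvent], path
) -> None:
    """Write the event ledger as 'kind\\taccession\\tN\\tfrom\\tto'."""
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        fh.write("kind\taccession\tN\tfrom\tto\n")
        for e in events:
            to = "" if e.to_chrom is None else e.to_chrom
            fh.write(
                f"{e.kind.value}\t{e.accession_id}\t{e.core_index}\t"
                f"{e.from_chrom}\t{to}\n"
            )
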