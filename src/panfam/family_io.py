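"""Membership records, table/FASTA I/O, and the member-name grammar codec.

The naming grammar assigns every gene-family member across a pan-genome a
single, structured identifier::

    Accession_SYMBOLN[.n]_x        core member N at its expected chromosome x
    Accession_SYMBOLN[.n]_xDy      n-th additional copy of core member N;
                                   x = expected chromosome of the core gene,
                                   y = actual chromosome of the copy
    Accession_SYMBOLN_xTy          core member N transferred from its expected
                                   chromosome x to chromosome y

``SYMBOL`` is the family symbol (e.g. ``SiSRS`` for the foxtail-millet SRS
family), ``N`` the core index (1..K), and the optional ``.n`` the ordinal of
an additional copy in chromosomal order. ``y = 0`` encodes a member on an
unanchored scaffold ("unplaced"); the published grammar prints no name for
unplaced copies, so the ``0`` token is this package's extension and is kept
round-trippable. Underscore is the grammar's only delimiter, which is why
accession identifiers may not contain one.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from Bio import SeqIO

from .errors import (
    MembershipFormatError,
    NameFormatError,
    NameGrammarError,
    UnknownMemberError,
)

#: Chromosome sentinel for members not anchored to a numbered chromosome.
UNPLACED = 0

#: Clade-label sentinel for members that could not be assigned to any core
#: clade (identity below threshold). Distinct from ``None`` (= never labeled).
UNASSIGNED = 0

MEMBERSHIP_COLUMNS = (
    "accession",
    "gene_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "clade",
)
_REQUIRED_COLUMNS = ("accession", "gene_id", "chromosome", "start", "end")

_UNPLACED_TOKENS = {"", "0", "un", "unplaced", "na", "."}


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MemberRecord:
    """One gene-family member observed in one accession.

    Coordinates are 1-based and inclusive on both ends; only the relative
    order of ``start_bp`` values is ever used downstream. ``chromosome`` is a
    positive integer or :data:`UNPLACED` (0) for unanchored scaffolds.
    ``clade_label`` is ``None`` until a clade has been assigned, a positive
    integer for a clade, or :data:`UNASSIGNED` (0) after assignment failed.
    """

    accession_id: str
    gene_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    strand: str = ""
    clade_label: int | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.accession_id:
            raise MembershipFormatError("accession id must be non-empty")
        if "_" in self.accession_id:
            raise MembershipFormatError(
                f"accession id {self.accession_id!r} contains '_', the name "
                "grammar delimiter; underscore-free ids are required"
            )
        if self.chromosome < 0:
            raise MembershipFormatError(
                f"{self.gene_id}: chromosome must be >= 1 or 0 (unplaced)"
            )
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise MembershipFormatError(
                f"{self.gene_id}: need 1 <= start <= end, "
                f"got {self.start_bp}..{self.end_bp}"
            )
        if self.clade_label is not None and self.clade_label < 0:
            raise MembershipFormatError(
                f"{self.gene_id}: clade label must be >= 1 (or 0 = unassigned)"
            )

    @property
    def placed(self) -> bool:
        return self.chromosome != UNPLACED

    def with_clade(self, label: int) -> "MemberRecord":
        return replace(self, clade_label=label)

    def with_sequence(self, sequence: str) -> "MemberRecord":
        return replace(self, sequence=sequence)


def _parse_chromosome(token: str) -> int:
    tok = token.strip()
    low = tok.lower()
    if low.startswith("chr"):
        low = low[3:]
        tok = tok[3:]
    if low in _UNPLACED_TOKENS:
        return UNPLACED
    try:
        value = int(tok)
    except ValueError:
        raise MembershipFormatError(
            f"chromosome token {token!r} is neither an integer nor an "
            "unplaced token ('0', 'Un', empty)"
        ) from None
    if value < 0:
        raise MembershipFormatError(f"negative chromosome {token!r}")
    return value


def read_membership(path: str | Path) -> list[MemberRecord]:
    """Read a tab-separated membership table into records, preserving order.

    The header must name at least ``accession``, ``gene_id``, ``chromosome``,
    ``start`` and ``end``; ``strand`` and ``clade`` are optional. Unplaced
    chromosome tokens (``0``, ``Un``, empty) are normalised to the sentinel.
    Row-level problems are reported with their 1-based line number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise MembershipFormatError(f"{path}: empty file, no header row")
        header = [h.strip() for h in reader.fieldnames]
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise MembershipFormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        records: list[MemberRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                clade_tok = (row.get("clade") or "").strip()
                if not clade_tok:
                    clade: int | None = None
                elif clade_tok.lower() == "unassigned":
                    clade = UNASSIGNED
                else:
                    clade = int(clade_tok)
                records.append(
                    MemberRecord(
                        accession_id=row["accession"].strip(),
                        gene_id=row["gene_id"].strip(),
                        chromosome=_parse_chromosome(row["chromosome"]),
                        start_bp=int(row["start"]),
                        end_bp=int(row["end"]),
                        strand=(row.get("strand") or "").strip(),
                        clade_label=clade,
                    )
                )
            except (MembershipFormatError, ValueError, TypeError) as exc:
                raise MembershipFormatError(
                    f"{path}, line {lineno}: {exc}"
                ) from None
    return records


def write_membership(records: Iterable[MemberRecord], path: str | Path) -> None:
    """Write records as a tab-separated membership table (standard header)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MEMBERSHIP_COLUMNS)
        for r in records:
            if r.clade_label is None:
                clade = ""
            elif r.clade_label == UNASSIGNED:
                clade = "unassigned"
            else:
                clade = str(r.clade_label)
            writer.writerow(
                [
                    r.accession_id,
                    r.gene_id,
                    r.chromosome,
                    r.start_bp,
                    r.end_bp,
                    r.strand,
                    clade,
                ]
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a ``{record id: sequence}`` mapping."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def attach_sequences(
    records: Iterable[MemberRecord], sequences: Mapping[str, str]
) -> list[MemberRecord]:
    """Return records with sequences attached where the gene id is known."""
    return [
        r.with_sequence(sequences[r.gene_id]) if r.gene_id in sequences else r
        for r in records
    ]


# ---------------------------------------------------------------------------
# Assigned names
# ---------------------------------------------------------------------------


class NameStatus(str, Enum):
    """Classification of a member relative to its core clade's locus."""

    CORE_IN_PLACE = "CORE_IN_PLACE"
    CORE_TRANSLOCATED = "CORE_TRANSLOCATED"
    DUPLICATE = "DUPLICATE"
    UNPLACED_CORE = "UNPLACED_CORE"
    UNPLACED_DUPLICATE = "UNPLACED_DUPLICATE"


class NameStyle(str, Enum):
    """How much positional suffix a rendered name carries.

    FULL always emits the suffix; SHORT drops ``Dy`` when the copy sits on the
    expected chromosome (``y = x``); MINIMAL drops the suffix entirely, which
    is only unambiguous when ``y = x``.
    """

    FULL = "full"
    SHORT = "short"
    MINIMAL = "minimal"


@dataclass(frozen=True)
class AssignedName:
    """Structured form of one standardized member name.

    ``copy_ordinal`` 0 denotes the core instance itself; additional copies
    are numbered 1.. in chromosomal order. ``expected_chrom`` (x) is a
    species-level constant of the core clade; ``actual_chrom`` (y) is where
    this member actually sits, 0 meaning unplaced.
    """

    accession_id: str
    family_symbol: str
    core_index: int
    copy_ordinal: int
    expected_chrom: int
    actual_chrom: int
    status: NameStatus
    gene_id: str = ""

    def __post_init__(self) -> None:
        n, x, y = self.copy_ordinal, self.expected_chrom, self.actual_chrom
        if self.core_index < 1 or x < 1 or n < 0 or y < 0:
            raise NameFormatError(
                f"invalid name fields N={self.core_index} n={n} x={x} y={y}"
            )
        s = self.status
        ok = {
            NameStatus.CORE_IN_PLACE: n == 0 and y == x,
            NameStatus.CORE_TRANSLOCATED: n == 0 and y not in (0, x),
            NameStatus.UNPLACED_CORE: n == 0 and y == 0,
            NameStatus.DUPLICATE: n >= 1 and y >= 1,
            NameStatus.UNPLACED_DUPLICATE: n >= 1 and y == 0,
        }[s]
        if not ok:
            raise NameFormatError(
                f"fields n={n}, x={x}, y={y} violate status {s.value}"
            )

    @property
    def is_core_instance(self) -> bool:
        return self.copy_ordinal == 0


def format_name(name: AssignedName, style: NameStyle = NameStyle.FULL) -> str:
    """Render an :class:`AssignedName` in the requested style."""
    base = f"{name.accession_id}_{name.family_symbol}{name.core_index}"
    if name.copy_ordinal:
        base += f".{name.copy_ordinal}"
    x, y = name.expected_chrom, name.actual_chrom
    s = name.status

    if s in (NameStatus.CORE_TRANSLOCATED, NameStatus.UNPLACED_CORE):
        if style is NameStyle.MINIMAL:
            raise NameFormatError(
                f"{base}: a core member away from its expected chromosome "
                "has no suffix-free form (the suffix carries the location)"
            )
        return f"{base}_{x}T{y}"

    if s in (NameStatus.DUPLICATE, NameStatus.UNPLACED_DUPLICATE):
        if style is NameStyle.FULL or y != x:
            if style is NameStyle.MINIMAL:
                raise NameFormatError(
                    f"{base}: a copy on chromosome {y} (expected {x}) has "
                    "no unambiguous suffix-free form"
                )
            return f"{base}_{x}D{y}"
        if style is NameStyle.SHORT:
            return f"{base}_{x}"
        return base

    # CORE_IN_PLACE
    if style is NameStyle.MINIMAL:
        return base
    return f"{base}_{x}"


class _ProfileLike(Protocol):
    """What :func:`parse_name` needs from a family profile."""

    family_symbol: str

    @property
    def k(self) -> int: ...

    def expected_chrom(self, core_index: int) -> int: ...


def parse_name(text: str, profile: _ProfileLike) -> AssignedName:
    """Parse a member name against a family profile.

    The profile supplies the family symbol, the valid core-index range 1..K,
    and the expected chromosome per core index — required both to resolve
    omitted suffixes and to reject names whose printed ``x`` contradicts the
    species-level locus.
    """
    parts = text.split("_")
    if len(parts) not in (2, 3) or not all(parts):
        raise NameGrammarError(
            f"{text!r}: expected Accession_{profile.family_symbol}N[.n][_suffix]"
        )
    accession, body = parts[0], parts[1]
    m = re.fullmatch(
        re.escape(profile.family_symbol) + r"(\d+)(?:\.(\d+))?", body
    )
    if not m:
        raise NameGrammarError(
            f"{text!r}: body {body!r} does not match "
            f"{profile.family_symbol}N[.n]"
        )
    core_index = int(m.group(1))
    copy_ordinal = int(m.group(2)) if m.group(2) else 0
    if m.group(2) and copy_ordinal == 0:
        raise NameGrammarError(f"{text!r}: copy ordinal must be >= 1")
    if not 1 <= core_index <= profile.k:
        raise UnknownMemberError(
            f"{text!r}: core index {core_index} outside 1..{profile.k}"
        )
    x_expected = profile.expected_chrom(core_index)

    if len(parts) == 2:
        # Suffix omitted: by the grammar's omission rule the member sits on
        # the expected chromosome.
        y = x_expected
    else:
        sm = re.fullmatch(r"(\d+)(?:([DT])(\d+))?", parts[2])
        if not sm:
            raise NameGrammarError(
                f"{text!r}: suffix {parts[2]!r} matches none of x, xDy, xTy"
            )
        x = int(sm.group(1))
        if x != x_expected:
            raise NameGrammarError(
                f"{text!r}: printed expected chromosome {x} contradicts the "
                f"profile ({profile.family_symbol}{core_index} maps to "
                f"chromosome {x_expected})"
            )
        if sm.group(2) is None:
            y = x
        elif sm.group(2) == "D":
            if copy_ordinal == 0:
                raise NameGrammarError(
                    f"{text!r}: 'D' suffix on a core instance (no .n ordinal)"
                )
            y = int(sm.group(3))
        else:  # T
            if copy_ordinal != 0:
                raise NameGrammarError(
                    f"{text!r}: 'T' suffix is reserved for core instances"
                )
            y = int(sm.group(3))
            if y == x:
                raise NameGrammarError(
                    f"{text!r}: transfer to the expected chromosome itself"
                )

    if copy_ordinal >= 1:
        status = (
            NameStatus.DUPLICATE if y >= 1 else NameStatus.UNPLACED_DUPLICATE
        )
    elif y == x_expected:
        status = NameStatus.CORE_IN_PLACE
    elif y == 0:
        status = NameStatus.UNPLACED_CORE
    else:
        status = NameStatus.CORE_TRANSLOCATED

    return AssignedName(
        accession_id=accession,
        family_symbol=profile.family_symbol,
        core_index=core_index,
        copy_ordinal=copy_ordinal,
        expected_chrom=x_expected,
        actual_chrom=y,
        status=status,
    )


# ---------------------------------------------------------------------------
# Names table
# ---------------------------------------------------------------------------

NAMES_COLUMNS = (
    "accession",
    "gene_id",
    "name_full",
    "name_short",
    "status",
    "N",
    "n",
    "x",
    "y",
)


def write_names(names: Iterable[AssignedName], path: str | Path) -> None:
    """Write assigned names as the standard tab-separated names table."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(NAMES_COLUMNS)
        for nm in names:
            writer.writerow(
                [
                    nm.accession_id,
                    nm.gene_id,
                    format_name(nm, NameStyle.FULL),
                    format_name(nm, NameStyle.SHORT),
                    nm.status.value,
                    nm.core_index,
                    nm.copy_ordinal,
                    nm.expected_chrom,
                    nm.actual_chrom,
                ]
            )


def read_names(path: str | Path) -> list[AssignedName]:
    """Read a names table written by :func:`write_names`."""
    names: list[AssignedName] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [
            c for c in NAMES_COLUMNS if c not in (reader.fieldnames or [])
        ]
        if missing:
            raise MembershipFormatError(
                f"{path}: missing column(s): {', '.join(missing)}"
            )
        for row in reader:
            full = row["name_full"]
            symbol_body = full.split("_")[1]
            symbol = re.match(r"\D+", symbol_body).group(0)  # type: ignore[union-attr]
            names.append(
                AssignedName(
                    accession_id=row["accession"],
                    family_symbol=symbol,
                    core_index=int(row["N"]),
                    copy_ordinal=int(row["n"]),
                    expected_chrom=int(row["x"]),
                    actual_chrom=int(row["y"]),
                    status=NameStatus(row["status"]),
                    gene_id=row["gene_id"],
                )
            )
    return names
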