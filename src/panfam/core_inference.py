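"""Clade assignment by global-alignment identity and core-profile inference.

A pan-genome gene family is summarised by its *core profile*: the set of
clades present in at least a threshold fraction of accessions, each with a
species-level expected chromosome (the modal chromosome of its single-copy
placed instances) and a canonical locus (the cross-accession median start).
Core indices 1..K are assigned in ascending (expected chromosome, median
start) order, so two core genes co-located on one chromosome are numbered by
position along it.

Members lacking a clade label are assigned to the core clade whose
representative sequence they match best under global (Needleman–Wunsch)
alignment, with identity defined as matches / alignment columns — gaps count
against identity, which penalises length variants instead of silently
matching them.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .errors import (
    DegenerateInputError,
    EmptyProfileError,
    MembershipFormatError,
    UnassignableError,
    UnresolvedLocusError,
)
from .family_io import UNASSIGNED, UNPLACED, MemberRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Global alignment identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentScoring:
    """Linear-gap global alignment scoring plus the assignment threshold."""

    match_score: float = 1.0
    mismatch_score: float = 0.0
    gap_score: float = -1.0
    min_identity: float = 0.6

    def __post_init__(self) -> None:
        if not self.match_score > self.mismatch_score:
            raise DegenerateInputError("match score must exceed mismatch score")
        if not self.gap_score < self.match_score:
            raise DegenerateInputError("gap score must be below match score")
        if not 0.0 <= self.min_identity <= 1.0:
            raise DegenerateInputError("min_identity must lie in [0, 1]")


DEFAULT_SCORING = AlignmentScoring()


@njit(cache=False)
def _nw_best(a, b, match, mismatch, gap):  # pragma: no cover - numba kernel
    """Needleman–Wunsch DP maximising (score, matches, -columns).

    The lexicographic secondary objectives make the reported identity of a
    co-optimal alignment deterministic: among maximum-score alignments the
    one with most matches, then fewest columns, is reported. Additivity of
    all three components keeps the greedy cell-wise choice exact.
    """
    n, m = len(a), len(b)
    S = np.empty((n + 1, m + 1), np.float64)
    M = np.empty((n + 1, m + 1), np.int64)
    C = np.empty((n + 1, m + 1), np.int64)
    S[0, 0] = 0.0
    M[0, 0] = 0
    C[0, 0] = 0
    for i in range(1, n + 1):
        S[i, 0] = i * gap
        M[i, 0] = 0
        C[i, 0] = i
    for j in range(1, m + 1):
        S[0, j] = j * gap
        M[0, j] = 0
        C[0, j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eq = 1 if a[i - 1] == b[j - 1] else 0
            bs = S[i - 1, j - 1] + (match if eq == 1 else mismatch)
            bm = M[i - 1, j - 1] + eq
            bc = C[i - 1, j - 1] + 1
            # gap in b (consume a[i-1])
            s2 = S[i - 1, j] + gap
            if s2 > bs or (
                s2 == bs
                and (
                    M[i - 1, j] > bm
                    or (M[i - 1, j] == bm and C[i - 1, j] + 1 < bc)
                )
            ):
                bs, bm, bc = s2, M[i - 1, j], C[i - 1, j] + 1
            # gap in a (consume b[j-1])
            s3 = S[i, j - 1] + gap
            if s3 > bs or (
                s3 == bs
                and (
                    M[i, j - 1] > bm
                    or (M[i, j - 1] == bm and C[i, j - 1] + 1 < bc)
                )
            ):
                bs, bm, bc = s3, M[i, j - 1], C[i, j - 1] + 1
            S[i, j] = bs
            M[i, j] = bm
            C[i, j] = bc
    return S[n, m], M[n, m], C[n, m]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def global_alignment_stats(
    seq_a: str, seq_b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> tuple[float, int, int]:
    """Return (score, matches, columns) of the optimal global alignment."""
    if not seq_a or not seq_b:
        raise DegenerateInputError("cannot align an empty sequence")
    score, matches, columns = _nw_best(
        _encode(seq_a),
        _encode(seq_b),
        float(scoring.match_score),
        float(scoring.mismatch_score),
        float(scoring.gap_score),
    )
    return float(score), int(matches), int(columns)


def global_identity(
    seq_a: str, seq_b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> float:
    """Fraction of matching columns in one optimal global alignment.

    Symmetric in its arguments and always in [0, 1]; gap columns are part of
    the denominator.
    """
    _, matches, columns = global_alignment_stats(seq_a, seq_b, scoring)
    return matches / columns


# ---------------------------------------------------------------------------
# Clade assignment
# ---------------------------------------------------------------------------


def assign_clades(
    members: Iterable[MemberRecord],
    representatives: Mapping[int, str],
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[MemberRecord]:
    """Fill missing clade labels by nearest-representative identity.

    Each unlabeled member receives the clade label of its highest-identity
    representative, provided that identity reaches ``scoring.min_identity``;
    otherwise it is marked :data:`UNASSIGNED`. Already-labeled members pass
    through unchanged. Ties between representatives resolve to the lowest
    clade label and are logged.
    """
    members = list(members)
    no_evidence = [
        m.gene_id
        for m in members
        if m.clade_label is None and not m.sequence
    ]
    if no_evidence:
        raise UnassignableError(
            "members carry neither clade label nor sequence: "
            + ", ".join(no_evidence)
        )
    labels = sorted(representatives)
    out: list[MemberRecord] = []
    for m in members:
        if m.clade_label is not None:
            out.append(m)
            continue
        best_label, best_identity = UNASSIGNED, -1.0
        tied = False
        for label in labels:
            ident = global_identity(m.sequence, representatives[label], scoring)
            if ident > best_identity:
                best_label, best_identity, tied = label, ident, False
            elif ident == best_identity:
                tied = True
        if tied:
            logger.info(
                "gene %s: identity tie between representatives, "
                "assigning lowest clade label %d",
                m.gene_id,
                best_label,
            )
        if best_identity >= scoring.min_identity:
            out.append(m.with_clade(best_label))
        else:
            out.append(m.with_clade(UNASSIGNED))
    return out


# ---------------------------------------------------------------------------
# Core profile inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoreClade:
    """One core clade of the inferred species-level profile."""

    index: int
    expected_chrom: int
    representative: str
    presence_fraction: float
    source_label: int
    median_start: float
    representative_sequence: str | None = None


@dataclass(frozen=True)
class FamilyProfile:
    """The species-level core set: K clades with expected loci."""

    family_symbol: str
    presence_threshold: float
    core_clades: tuple[CoreClade, ...]

    def __post_init__(self) -> None:
        indices = [c.index for c in self.core_clades]
        if indices != list(range(1, len(indices) + 1)):
            raise EmptyProfileError(
                f"core indices must be 1..K consecutive, got {indices}"
            )

    @property
    def k(self) -> int:
        return len(self.core_clades)

    @property
    def indices(self) -> range:
        return range(1, self.k + 1)

    def clade(self, core_index: int) -> CoreClade:
        return self.core_clades[core_index - 1]

    def expected_chrom(self, core_index: int) -> int:
        return self.clade(core_index).expected_chrom

    def median_start(self, core_index: int) -> float:
        return self.clade(core_index).median_start

    def index_for_label(self, label: int) -> int:
        for c in self.core_clades:
            if c.source_label == label:
                return c.index
        raise KeyError(label)


def infer_core_profile(
    members: Iterable[MemberRecord],
    presence_threshold: float = 0.8,
    family_symbol: str = "SiSRS",
) -> FamilyProfile:
    """Infer the core profile from labeled members of all accessions.

    A clade is core iff it is present in at least ``presence_threshold`` of
    the accessions. Its expected chromosome is the modal chromosome among
    *single-copy placed* instances (so widespread duplication cannot shift
    the canonical locus), its canonical start the median start of those
    instances on that chromosome, and its representative the gene nearest
    that median. Members marked unassigned are ignored.
    """
    members = list(members)
    accessions = {m.accession_id for m in members}
    if not accessions:
        raise EmptyProfileError("no members supplied")
    unlabeled = [m.gene_id for m in members if m.clade_label is None]
    if unlabeled:
        raise UnassignableError(
            "profile inference needs fully labeled members; unlabeled: "
            + ", ".join(unlabeled[:10])
        )

    by_label: dict[int, list[MemberRecord]] = defaultdict(list)
    for m in members:
        if m.clade_label != UNASSIGNED:
            by_label[m.clade_label].append(m)

    n_acc = len(accessions)
    core: list[tuple[int, int, float, str, float, str | None]] = []
    for label, group in sorted(by_label.items()):
        presence = len({m.accession_id for m in group}) / n_acc
        if presence < presence_threshold:
            continue
        per_acc = Counter(m.accession_id for m in group)
        singles = [
            m
            for m in group
            if per_acc[m.accession_id] == 1 and m.placed
        ]
        if not singles:
            raise UnresolvedLocusError(
                f"clade {label}: no placed single-copy instance to anchor "
                "the expected chromosome"
            )
        counts = Counter(m.chromosome for m in singles).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            raise UnresolvedLocusError(
                f"clade {label}: modal chromosome tied between "
                f"{counts[0][0]} and {counts[1][0]}"
            )
        chrom = counts[0][0]
        on_chrom = [m for m in singles if m.chromosome == chrom]
        med = float(median(m.start_bp for m in on_chrom))
        rep = min(
            on_chrom, key=lambda m: (abs(m.start_bp - med), m.gene_id)
        )
        core.append((chrom, label, presence, rep.gene_id, med, rep.sequence))

    if not core:
        raise EmptyProfileError(
            f"no clade reaches presence threshold {presence_threshold}"
        )
    core.sort(key=lambda t: (t[0], t[4], t[1]))
    clades = tuple(
        CoreClade(
            index=i,
            expected_chrom=chrom,
            representative=rep_id,
            presence_fraction=presence,
            source_label=label,
            median_start=med,
            representative_sequence=seq,
        )
        for i, (chrom, label, presence, rep_id, med, seq) in enumerate(
            core, start=1
        )
    )
    return FamilyProfile(
        family_symbol=family_symbol,
        presence_threshold=presence_threshold,
        core_clades=clades,
    )


# ---------------------------------------------------------------------------
# Profile (de)serialization
# ---------------------------------------------------------------------------

_PROFILE_HEADER = (
    "index",
    "expected_chrom",
    "source_label",
    "representative",
    "presence_fraction",
    "median_start",
)


def write_profile(profile: FamilyProfile, path: str | Path) -> None:
    """Serialize a profile as a small key-value + table text file."""
    with Path(path).open("w", newline="") as fh:
        fh.write(f"family_symbol\t{profile.family_symbol}\n")
        fh.write(f"presence_threshold\t{profile.presence_threshold}\n")
        fh.write(f"n_core\t{profile.k}\n")
        fh.write("\t".join(_PROFILE_HEADER) + "\n")
        for c in profile.core_clades:
            fh.write(
                f"{c.index}\t{c.expected_chrom}\t{c.source_label}\t"
                f"{c.representative}\t{c.presence_fraction}\t{c.median_start}\n"
            )


def read_profile(path: str | Path) -> FamilyProfile:
    """Read a profile written by :func:`write_profile` (sequences excluded)."""
    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    i = 0
    while i < len(lines) and not lines[i].startswith("index\t"):
        key, _, value = lines[i].partition("\t")
        meta[key] = value
        i += 1
    if i == len(lines):
        raise MembershipFormatError(f"{path}: no core-clade table found")
    clades = []
    for line in lines[i + 1 :]:
        if not line.strip():
            continue
        idx, chrom, label, rep, presence, med = line.split("\t")
        clades.append(
            CoreClade(
                index=int(idx),
                expected_chrom=int(chrom),
                representative=rep,
                presence_fraction=float(presence),
                source_label=int(label),
                median_start=float(med),
            )
        )
    try:
        return FamilyProfile(
            family_symbol=meta["family_symbol"],
            presence_threshold=float(meta["presence_threshold"]),
            core_clades=tuple(clades),
        )
    except KeyError as exc:
        raise MembershipFormatError(f"{path}: missing key {exc}") from None


def with_representative_sequences(
    profile: FamilyProfile, sequences: Mapping[str, str]
) -> FamilyProfile:
    """Attach representative sequences (by gene id) to a loaded profile."""
    clades = tuple(
        CoreClade(
            index=c.index,
            expected_chrom=c.expected_chrom,
            representative=c.representative,
            presence_fraction=c.presence_fraction,
            source_label=c.source_label,
            median_start=c.median_start,
            representative_sequence=sequences.get(
                c.representative, c.representative_sequence
            ),
        )
        for c in profile.core_clades
    )
    return FamilyProfile(
        family_symbol=profile.family_symbol,
        presence_threshold=profile.presence_threshold,
        core_clades=clades,
    )
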