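"""Synthetic pan-genome families with planted ground truth.

Two generators live here. :func:`simulate` plants a configurable pan-genome
gene family — every accession starts with one copy of each core clade at a
clade-canonical locus, then per-clade loss, translocation, unplacement and
duplication events are drawn at the configured rates — and records every
applied event, so classifier output can be compared against exact truth.
:func:`sisrs_pangenome_fixture` deterministically reconstructs the published
112-accession foxtail-millet SiSRS composition (six core clades on
chromosomes 2,2,3,4,5,6; twelve seven-member accessions; one eight-member
accession, Q13; eight five-member accessions; twelve core translocations).

Event semantics in :func:`simulate`:

* per clade instance one categorical draw among loss / translocation /
  unplacement / none, so those three are mutually exclusive;
* loss preempts everything — a lost clade cannot duplicate;
* a surviving clade may additionally duplicate (independent draw). A
  duplicate of a parent still at its canonical chromosome x is tandem
  (same chromosome) with probability 1/2, unplaced with probability
  ``unplaced_rate``, and otherwise dispersed to a uniformly random other
  chromosome. A duplicate of a parent that has *left* x is always tandem:
  with a dispersed duplicate of a relocated parent, gene content alone
  cannot tell which copy translocated and which duplicated, so such
  configurations would make the planted truth unidentifiable rather than
  test the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import ConfigError
from .family_io import UNPLACED, MemberRecord
from .nomenclature import EventKind, VariationEvent

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical start of clade c is ``c * CANONICAL_SPACING``; additional
#: copies sit :data:`COPY_OFFSET` downstream. Only relative order matters.
CANONICAL_SPACING = 1_000_000
COPY_OFFSET = 100_000
GENE_LENGTH = 3_000


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Rates are per accession x clade instance. Defaults mirror a sparse but
    realistic pan-genome survey of a small transcription-factor family:
    ~5% of clade instances lost, ~10% translocated, ~10% duplicated, ~5%
    on unanchored scaffolds, and 2% per-residue divergence from the clade
    representative (protein identity ~0.96–0.98, far above the 0.6
    assignment threshold).
    """

    n_accessions: int = 100
    n_core: int = 6
    loss_rate: float = 0.05
    dup_rate: float = 0.10
    transloc_rate: float = 0.10
    unplaced_rate: float = 0.05
    mutation_rate: float = 0.02
    n_chromosomes: int = 9
    rep_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.n_core < 1:
            raise ConfigError("need >= 1 accession and >= 1 core clade")
        rates = (
            self.loss_rate,
            self.dup_rate,
            self.transloc_rate,
            self.unplaced_rate,
            self.mutation_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigError("all rates must lie in [0, 1]")
        if self.loss_rate + self.transloc_rate + self.unplaced_rate > 1.0:
            raise ConfigError(
                "loss + translocation + unplacement rates exceed 1 "
                "(they are drawn as one categorical event per clade instance)"
            )
        if self.n_chromosomes < self.n_core:
            raise ConfigError(
                f"n_chromosomes ({self.n_chromosomes}) must be >= n_core "
                f"({self.n_core})"
            )
        if self.transloc_rate > 0 and self.n_chromosomes < 2:
            raise ConfigError("translocation needs >= 2 chromosomes")
        if self.rep_length < 1:
            raise ConfigError("rep_length must be >= 1")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth: core loci, events, member origins."""

    core_chromosomes: dict[int, int]
    events: tuple[VariationEvent, ...]
    member_sources: dict[str, int]
    representatives: dict[int, str]


@dataclass(frozen=True)
class SimResult:
    members: tuple[MemberRecord, ...]
    sequences: dict[str, str]
    truth: SimTruth


def _mutate(seq_codes: np.ndarray, rate: float, rng) -> np.ndarray:
    """Substitute each residue with probability ``rate`` (never to itself)."""
    hits = np.nonzero(rng.random(seq_codes.size) < rate)[0]
    if hits.size == 0:
        return seq_codes
    out = seq_codes.copy()
    # draw from the 19 other residues by skipping the current one
    draws = rng.integers(0, len(AMINO_ACIDS) - 1, size=hits.size)
    current = out[hits]
    out[hits] = np.where(draws >= current, draws + 1, draws)
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[c] for c in codes)


def simulate(config: SimConfig) -> SimResult:
    """Generate one pan-genome family dataset; bit-reproducible per seed.

    Clade ``c`` (1..K) is planted on chromosome ``c`` at canonical start
    ``c * CANONICAL_SPACING`` with a small per-accession jitter. Returned
    members carry sequences but no clade labels, so the full pipeline
    (assign -> infer -> classify -> detect) can be exercised against
    ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_core
    rep_codes = {
        c: rng.integers(0, len(AMINO_ACIDS), size=config.rep_length)
        for c in range(1, K + 1)
    }
    representatives = {c: _decode(codes) for c, codes in rep_codes.items()}

    p_loss = config.loss_rate
    p_transloc = p_loss + config.transloc_rate
    p_unplaced = p_transloc + config.unplaced_rate
    other_chroms = {
        x: [c for c in range(1, config.n_chromosomes + 1) if c != x]
        for x in range(1, K + 1)
    }

    members: list[MemberRecord] = []
    sequences: dict[str, str] = {}
    sources: dict[str, int] = {}
    events: list[VariationEvent] = []
    width = max(3, len(str(config.n_accessions)))
    for i in range(1, config.n_accessions + 1):
        acc = f"S{i:0{width}d}"
        gene_no = 0
        for c in range(1, K + 1):
            x = c
            u = rng.random()
            if u < p_loss:
                events.append(
                    VariationEvent(EventKind.LOSS, acc, c, x, None)
                )
                continue
            if u < p_transloc:
                chrom = int(rng.choice(other_chroms[x]))
                events.append(
                    VariationEvent(EventKind.TRANSLOCATION, acc, c, x, chrom)
                )
            elif u < p_unplaced:
                chrom = UNPLACED
                events.append(
                    VariationEvent(EventKind.UNPLACED, acc, c, x, UNPLACED)
                )
            else:
                chrom = x
            start = c * CANONICAL_SPACING + int(rng.integers(0, 1000))
            gene_no += 1
            gene = f"{acc}.g{gene_no}"
            core_codes = _mutate(rep_codes[c], config.mutation_rate, rng)
            seq = _decode(core_codes)
            members.append(
                MemberRecord(
                    accession_id=acc,
                    gene_id=gene,
                    chromosome=chrom,
                    start_bp=start,
                    end_bp=start + GENE_LENGTH - 1,
                    sequence=seq,
                )
            )
            sequences[gene] = seq
            sources[gene] = c

            if rng.random() < config.dup_rate:
                if chrom == x:
                    r = rng.random()
                    if r < 0.5:
                        dup_chrom = x
                    elif r < 0.5 + config.unplaced_rate:
                        dup_chrom = UNPLACED
                    else:
                        dup_chrom = int(rng.choice(other_chroms[x]))
                else:
                    # parent left its canonical locus: tandem only (see
                    # module docstring for the identifiability argument)
                    dup_chrom = chrom
                events.append(
                    VariationEvent(
                        EventKind.DUPLICATION, acc, c, x, dup_chrom
                    )
                )
                if dup_chrom == UNPLACED:
                    events.append(
                        VariationEvent(EventKind.UNPLACED, acc, c, x, UNPLACED)
                    )
                gene_no += 1
                dup_gene = f"{acc}.g{gene_no}"
                dup_codes = _mutate(core_codes, config.mutation_rate, rng)
                dup_seq = _decode(dup_codes)
                members.append(
                    MemberRecord(
                        accession_id=acc,
                        gene_id=dup_gene,
                        chromosome=dup_chrom,
                        start_bp=start + COPY_OFFSET,
                        end_bp=start + COPY_OFFSET + GENE_LENGTH - 1,
                        sequence=dup_seq,
                    )
                )
                sequences[dup_gene] = dup_seq
                sources[dup_gene] = c

    truth = SimTruth(
        core_chromosomes={c: c for c in range(1, K + 1)},
        events=tuple(events),
        member_sources=sources,
        representatives=representatives,
    )
    return SimResult(
        members=tuple(members), sequences=sequences, truth=truth
    )


# ---------------------------------------------------------------------------
# SiSRS 112-accession fixture
# ---------------------------------------------------------------------------

#: Clade -> expected chromosome of the foxtail-millet SiSRS core genes
#: (SiSRS1 and SiSRS2 co-localise on chromosome 2, SiSRS3-6 on 3-6).
SISRS_CLADE_CHROM = {1: 2, 2: 2, 3: 3, 4: 4, 5: 5, 6: 6}

#: Five-member accessions and the core clade each one lacks.
SISRS_LOSSES = {
    "L7": 1,
    "L34": 2,
    "L20": 3,
    "L24": 4,
    "L35": 4,
    "C4": 5,
    "Q33": 5,
    "Q24": 6,
}

#: Seven-member accessions: clade of the extra copy and its chromosome
#: (0 = unanchored scaffold).
SISRS_EXTRA_COPIES = {
    "C16": (2, 0),
    "Q14": (2, 9),
    "Q35": (2, 0),
    "L10": (3, 8),
    "Q15": (3, 9),
    "L3": (4, 0),
    "Q1": (4, 0),
    "Q4": (5, 5),
    "Q9": (5, 5),
    "Q12": (5, 5),
    "Q31": (5, 5),
    "Q3": (6, 0),
}

#: Q13, the single eight-member accession: extra copies of clades 3 and 6
#: on their own core chromosomes.
SISRS_Q13_EXTRAS = ((3, 3), (6, 6))

#: Core translocations: accession -> {clade: actual chromosome}.
SISRS_TRANSLOCATIONS = {
    "L23": {1: 5},
    "Q25": {1: 7},
    "L14": {2: 4},
    "Q1": {3: 8},
    "Q28": {3: 5},
    "Q30": {3: 2},
    "C27": {4: 7},
    "L11": {4: 2, 6: 5},
    "C15": {6: 3},
    "C26": {6: 1},
    "C29": {6: 5},
}

#: Number of unremarkable six-member background accessions (P001..).
#: Together with the ten six-member translocation accessions they make the
#: 91 accessions carrying exactly the six single-copy core genes.
SISRS_N_BACKGROUND = 81


def sisrs_accession_ids() -> list[str]:
    """The 112 fixture accession ids, special accessions first."""
    named = sorted(
        set(SISRS_LOSSES)
        | set(SISRS_EXTRA_COPIES)
        | set(SISRS_TRANSLOCATIONS)
        | {"Q13"}
    )
    background = [f"P{i:03d}" for i in range(1, SISRS_N_BACKGROUND + 1)]
    return named + background


def sisrs_pangenome_fixture() -> list[MemberRecord]:
    """Deterministic 112-accession / 678-member SiSRS membership table.

    Coordinates are synthetic (clade c's canonical start is
    ``c * CANONICAL_SPACING``; extra copies sit ``COPY_OFFSET`` downstream);
    only their relative order is used downstream. Records carry clade
    labels and no sequences.

    Known inconsistency of the source composition: accession Me34V is
    described as lacking clade 2 while carrying an extra clade-6 copy,
    which cannot be reconciled with the printed 91/12/1/8 accession-size
    partition; the fixture follows the partition and omits Me34V.
    """
    members: list[MemberRecord] = []
    for acc in sisrs_accession_ids():
        gene_no = 0
        lost = SISRS_LOSSES.get(acc)
        moved = SISRS_TRANSLOCATIONS.get(acc, {})
        for clade in range(1, 7):
            if clade == lost:
                continue
            chrom = moved.get(clade, SISRS_CLADE_CHROM[clade])
            start = clade * CANONICAL_SPACING
            gene_no += 1
            members.append(
                MemberRecord(
                    accession_id=acc,
                    gene_id=f"{acc}.g{gene_no}",
                    chromosome=chrom,
                    start_bp=start,
                    end_bp=start + GENE_LENGTH - 1,
                    clade_label=clade,
                )
            )
        extras: list[tuple[int, int]] = []
        if acc in SISRS_EXTRA_COPIES:
            extras.append(SISRS_EXTRA_COPIES[acc])
        if acc == "Q13":
            extras.extend(SISRS_Q13_EXTRAS)
        for clade, chrom in extras:
            start = clade * CANONICAL_SPACING + COPY_OFFSET
            gene_no += 1
            members.append(
                MemberRecord(
                    accession_id=acc,
                    gene_id=f"{acc}.g{gene_no}",
                    chromosome=chrom,
                    start_bp=start,
                    end_bp=start + GENE_LENGTH - 1,
                    clade_label=clade,
                )
            )
    return members


def sisrs_translocation_events() -> list[VariationEvent]:
    """The twelve planted core translocations of the fixture."""
    events = []
    for acc, moves in SISRS_TRANSLOCATIONS.items():
        for clade, to in moves.items():
            events.append(
                VariationEvent(
                    EventKind.TRANSLOCATION,
                    acc,
                    clade,
                    SISRS_CLADE_CHROM[clade],
                    to,
                )
            )
    return sorted(
        events, key=lambda e: (e.accession_id, e.core_index)
    )
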