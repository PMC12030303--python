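"""Nei–Gojobori (1986) Ka/Ks for codon-aligned coding-sequence pairs.

The NG86 method counts, per codon, the fraction of the three possible
single-nucleotide changes at each position that are synonymous (site
counting), averages synonymous/nonsynonymous classifications over all
mutational pathways between two codons (difference counting), and corrects
the resulting proportions p with the Jukes–Cantor distance
d = -(3/4) ln(1 - 4p/3). Pathways passing through a stop codon are excluded
with renormalisation over the surviving pathways; single-base changes to a
stop codon are likewise excluded from the site-count denominator. All
mutational pathways are weighted equally (pure NG86). Ka/Ks < 1 indicates
purifying selection, > 1 positive selection.

Only the standard genetic code is wired up; the code table is data-driven
(taken from Biopython's table 1), so alternates could be added if needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import NamedTuple

from Bio.Data import CodonTable

from .errors import DegenerateInputError, FrameError, InvalidCodonError

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD: dict[str, str] = dict(_TABLE.forward_table)
_STOPS: frozenset[str] = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"
GAP_CHARS = "-."


def _translate(codon: str) -> str:
    """Amino acid for a valid non-stop codon; raises InvalidCodonError."""
    if len(codon) != 3:
        raise InvalidCodonError(f"{codon!r}: codon must be 3 nt")
    if codon in _STOPS:
        raise InvalidCodonError(f"{codon!r} is a stop codon")
    try:
        return _FORWARD[codon]
    except KeyError:
        raise InvalidCodonError(
            f"{codon!r}: ambiguous or non-DNA base"
        ) from None


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon.

    Per position, the synonymous fraction is the number of the three
    single-base changes that preserve the amino acid divided by the number
    of changes not producing a stop codon; the nonsynonymous fraction is its
    complement. Summed over the three positions the two fractions add to 3
    exactly.
    """
    aa = _translate(codon)
    syn_total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            non_stop += 1
            if _FORWARD[alt] == aa:
                syn += 1
        if non_stop:
            syn_total += syn / non_stop
    return syn_total, 3.0 - syn_total


class PathwayDiff(NamedTuple):
    """Pathway-averaged substitution counts between two codons."""

    sd: float
    nd: float
    blocked: bool  # True when every pathway crossed a stop codon


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> PathwayDiff:
    """Average (synonymous, nonsynonymous) steps over all mutational pathways.

    For k differing positions all k! orderings of the single-base steps are
    enumerated; a pathway whose intermediate codon is a stop is discarded and
    the average renormalised over the survivors, so sd + nd = k whenever at
    least one pathway survives. If every pathway is blocked the pair
    contributes k nonsynonymous differences by convention (flagged).
    """
    _translate(codon_a)
    _translate(codon_b)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_positions)
    if k == 0:
        return PathwayDiff(0.0, 0.0, False)
    syn_sum = nsyn_sum = 0.0
    n_paths = 0
    for order in permutations(diff_positions):
        current = codon_a
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _FORWARD[nxt] == _FORWARD[current]:
                syn += 1
            else:
                nsyn += 1
            current = nxt
        if ok:
            syn_sum += syn
            nsyn_sum += nsyn
            n_paths += 1
    if n_paths == 0:
        logger.warning(
            "codon pair %s/%s: every mutational pathway crosses a stop; "
            "counting %d nonsynonymous differences by convention",
            codon_a,
            codon_b,
            k,
        )
        return PathwayDiff(0.0, float(k), True)
    return PathwayDiff(syn_sum / n_paths, nsyn_sum / n_paths, False)


@dataclass(frozen=True)
class CodonPairCounts:
    """Summed NG86 site and difference counts for one sequence pair."""

    n_codons: int
    s_sites: float
    n_sites: float
    sd: float
    nd: float


@dataclass(frozen=True)
class KaKsResult:
    """NG86 outputs; Ka/Ks are None when the proportion saturates (>= 3/4)."""

    counts: CodonPairCounts
    pn: float | None
    ps: float | None
    ka: float | None
    ks: float | None
    ratio: float | None
    flags: tuple[str, ...] = ()


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """NG86 Ka/Ks for a codon-aligned pair of coding sequences.

    The two sequences must be equal-length and a multiple of 3; codon
    columns containing a gap character in either sequence are removed
    pairwise before counting. Site counts are averaged over the two
    sequences. Saturation (p >= 3/4) and Ks = 0 are reported as undefined
    values, not exceptions.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise FrameError(
            f"sequence lengths differ ({len(a)} vs {len(b)}); "
            "a codon alignment is required"
        )
    if len(a) % 3:
        raise FrameError(f"length {len(a)} is not a multiple of 3")

    codons: list[tuple[str, str]] = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(g in ca or g in cb for g in GAP_CHARS):
            continue
        codons.append((ca, cb))
    if not codons:
        raise DegenerateInputError("no ungapped codon columns to compare")

    flags: list[str] = []
    s_a = s_b = sd = nd = 0.0
    blocked = 0
    for pos, (ca, cb) in enumerate(codons, start=1):
        try:
            fa, _ = codon_site_fractions(ca)
            fb, _ = codon_site_fractions(cb)
        except InvalidCodonError as exc:
            raise InvalidCodonError(f"codon {pos}: {exc}") from None
        s_a += fa
        s_b += fb
        diff = codon_pair_differences(ca, cb)
        sd += diff.sd
        nd += diff.nd
        if diff.blocked:
            blocked += 1
    if blocked:
        flags.append(f"degenerate_pairs={blocked}")

    n_codons = len(codons)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    counts = CodonPairCounts(
        n_codons=n_codons, s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd
    )

    ps = sd / s_sites if s_sites > 0 else None
    pn = nd / n_sites if n_sites > 0 else None
    ks = _jukes_cantor(ps) if ps is not None else None
    ka = _jukes_cantor(pn) if pn is not None else None
    if ps is None:
        flags.append("no_synonymous_sites")
    elif ks is None:
        flags.append("saturated_ps")
    if pn is not None and ka is None:
        flags.append("saturated_pn")

    if ks is None or ks == 0.0 or ka is None:
        ratio = None
        if ks == 0.0:
            flags.append("ks_zero")
    else:
        ratio = ka / ks
    return KaKsResult(
        counts=counts,
        pn=pn,
        ps=ps,
        ka=ka,
        ks=ks,
        ratio=ratio,
        flags=tuple(flags),
    )
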