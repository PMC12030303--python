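"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately self-contained: the genetic code is spelled
out as the classic 64-letter string (TCAG order) rather than taken from the
package or Biopython, alignments are enumerated recursively instead of by
dynamic programming, and the NG86 arithmetic is a straight-line transcription
of the counting rules.
"""

from __future__ import annotations

import math
from itertools import permutations, product

# ---------------------------------------------------------------------------
# Global alignment by exhaustive enumeration
# ---------------------------------------------------------------------------


def enumerate_alignments(a: str, b: str, match, mismatch, gap):
    """Yield (score, matches, columns) of every global alignment of a and b."""

    def rec(i: int, j: int):
        if i == len(a) and j == len(b):
            yield (0.0, 0, 0)
            return
        if i < len(a):
            for s, m, c in rec(i + 1, j):
                yield (s + gap, m, c + 1)
        if j < len(b):
            for s, m, c in rec(i, j + 1):
                yield (s + gap, m, c + 1)
        if i < len(a) and j < len(b):
            eq = a[i] == b[j]
            step = match if eq else mismatch
            for s, m, c in rec(i + 1, j + 1):
                yield (s + step, m + (1 if eq else 0), c + 1)

    yield from rec(0, 0)


def oracle_alignment_best(a, b, match, mismatch, gap):
    """Best (score, matches, columns), maximising (score, matches, -columns)."""
    best = max(
        enumerate_alignments(a, b, match, mismatch, gap),
        key=lambda t: (t[0], t[1], -t[2]),
    )
    return best


def oracle_identity(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    _, matches, columns = oracle_alignment_best(a, b, match, mismatch, gap)
    return matches / columns


# ---------------------------------------------------------------------------
# Standard genetic code, spelled out
# ---------------------------------------------------------------------------

_BASES_TCAG = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

CODE: dict[str, str] = {}
for i1, b1 in enumerate(_BASES_TCAG):
    for i2, b2 in enumerate(_BASES_TCAG):
        for i3, b3 in enumerate(_BASES_TCAG):
            CODE[b1 + b2 + b3] = _AA64[16 * i1 + 4 * i2 + i3]

NONSTOP_CODONS = sorted(c for c, aa in CODE.items() if aa != "*")


def oracle_site_fractions(codon: str):
    """(syn, nonsyn) site fractions by enumerating all 9 single-base variants."""
    aa = CODE[codon]
    assert aa != "*"
    syn_total = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if CODE[alt] == "*":
                continue
            nonstop += 1
            if CODE[alt] == aa:
                syn += 1
        if nonstop:
            syn_total += syn / nonstop
    return syn_total, 3.0 - syn_total


def oracle_pair_diff(codon_a: str, codon_b: str):
    """Pathway-averaged (sd, nd) by enumerating every mutation ordering."""
    positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    k = len(positions)
    if k == 0:
        return 0.0, 0.0
    totals = []
    for order in permutations(positions):
        cur = codon_a
        sd = nd = 0
        alive = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if CODE[nxt] == "*":
                alive = False
                break
            if CODE[nxt] == CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if alive:
            totals.append((sd, nd))
    if not totals:
        return 0.0, float(k)
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


def oracle_ng86(cds_a: str, cds_b: str):
    """Straight-line NG86: returns dict with S, N, Sd, Nd, pS, pN, Ks, Ka."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    s_a = s_b = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        n_codons += 1
        s_a += oracle_site_fractions(ca)[0]
        s_b += oracle_site_fractions(cb)[0]
        d = oracle_pair_diff(ca, cb)
        sd += d[0]
        nd += d[1]
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    ps = sd / S if S > 0 else None
    pn = nd / N if N > 0 else None

    def jc(p):
        if p is None or p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    return {
        "n_codons": n_codons,
        "S": S,
        "N": N,
        "Sd": sd,
        "Nd": nd,
        "pS": ps,
        "pN": pn,
        "Ks": jc(ps),
        "Ka": jc(pn),
    }


def random_cds(rng, n_codons: int) -> str:
    """Random stop-free CDS of the given codon count."""
    return "".join(
        NONSTOP_CODONS[rng.integers(0, len(NONSTOP_CODONS))]
        for _ in range(n_codons)
    )


def mutate_cds(rng, cds: str, rate: float) -> str:
    """Point-mutate a CDS, rejecting mutations that create stop codons."""
    seq = list(cds)
    for i in range(len(seq)):
        if rng.random() < rate:
            codon_start = 3 * (i // 3)
            for base in rng.permutation(list("ACGT")):
                if base == seq[i]:
                    continue
                trial = seq[:]
                trial[i] = base
                if CODE["".join(trial[codon_start : codon_start + 3])] != "*":
                    seq[i] = base
                    break
    return "".join(seq)
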