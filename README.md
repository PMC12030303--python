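# panfam

Pan-genome gene-family nomenclature and variation analysis.

When a gene family is surveyed across the many accessions of one species
(a pan-genome), the classical one-genome naming habit — number the members
of the reference genome and hope — breaks down: the same ancestral gene may
be present, absent, duplicated, translocated to another chromosome, or
stranded on an unanchored scaffold depending on the accession. `panfam`
turns such a survey into a consistent species-level nomenclature and a
machine-readable ledger of the variation. It was built around the SRS
(SHI-related sequence) transcription-factor family of foxtail millet
(*Setaria italica*), whose 112-accession pan-genome survey is shipped as a
built-in dataset, but the machinery is generic over any family symbol.

## What it computes

**Core profile.** Members are grouped into clades (labels supplied, or
assigned by global-alignment identity to one representative sequence per
clade; identity = matches / alignment columns, so gaps count against). A
clade is *core* when present in ≥ a threshold fraction of accessions
(default 0.8). Its expected chromosome *x* is the modal chromosome of its
single-copy placed instances; core indices *N* = 1..K follow ascending
(*x*, median start) order.

**Names.** Every member then gets one identifier under the grammar

```
Accession_SYMBOLN[.n]_x      core member N at its expected chromosome x
Accession_SYMBOLN[.n]_xDy    n-th additional copy of N; "D" = duplicate of,
                             y = the copy's actual chromosome
Accession_SYMBOLN_xTy        core member N transferred from x to y
```

with `y = 0` for unanchored scaffolds. Short forms drop `Dy` when `y = x`;
the suffix may be dropped entirely when unambiguous. Numbering is stable
under loss: an accession missing core member 2 still names the others
`..._SYMBOL1`, `..._SYMBOL3`, … The codec is bidirectional (parse ↔ format).

**Variation ledger and summaries.** Per accession, classification yields
one TRANSLOCATION / DUPLICATION / LOSS / UNPLACED event per deviation from
the profile, plus a copy-number matrix and population summary statistics.

**Selection.** `panfam.ng86` scores codon-aligned CDS pairs with the
Nei–Gojobori (1986) method: fractional synonymous/nonsynonymous site
counts per codon, equal-weight averaging over all mutational pathways
between codons (pathways through stop codons excluded, with
renormalisation), and Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3) of each proportion, giving Ka, Ks and Ka/Ks.

**Simulation.** `panfam.simulate` plants pan-genome families with known
loss/duplication/translocation/unplacement events and exact recorded
truth, for validating the whole pipeline.

## Worked example

```python
from panfam import *

members = sisrs_pangenome_fixture()          # 112 accessions, 678 members
profile = infer_core_profile(members)        # six core clades
assignments = classify_all(members, profile)
print(summarize(assignments).to_text())
```

prints

```
accessions: 112
core clades (K): 6
total named members: 678
members per accession: 5: 8, 6: 91, 7: 12, 8: 1
all-core single-copy accessions: 91
accessions with >=1 additional copy: 13
accessions with >=1 loss: 8
accessions with >=1 translocation: 11
accessions with >=1 unplaced member: 5
unassigned members: 0
accession groups: C: 6, L: 10, P: 81, Q: 15
```

i.e. 91 accessions carry exactly the six single-copy core genes
(SiSRS1–2 on chromosome 2, SiSRS3–6 on chromosomes 3–6), twelve carry one
extra copy, Q13 carries two, and eight lack one core member. The extra
copies of accession Q13 come out as

```python
>>> q13 = next(a for a in assignments if a.accession_id == "Q13")
>>> [format_name(nm) for nm in q13.names if nm.copy_ordinal]
['Q13_SiSRS3.1_3D3', 'Q13_SiSRS6.1_6D6']
```

and a Ka/Ks call on a 40-codon pair with four synonymous and four
nonsynonymous differences:

```python
>>> r = ng86(cds_a, cds_b)
>>> print(f"Ka={r.ka:.4f} Ks={r.ks:.4f} Ka/Ks={r.ratio:.3f}")
Ka=0.0435 Ks=0.1773 Ka/Ks=0.245
```

(Ka/Ks < 1: purifying selection.)

The same pipeline is available from the shell:

```
panfam fixture --out-prefix sisrs
panfam infer   --members sisrs.members.tsv --out profile.tsv
panfam name    --members sisrs.members.tsv --profile profile.tsv \
               --out names.tsv --events events.tsv
panfam report  --names names.tsv --out summary.json --matrix matrix.tsv
panfam kaks    --pairs pairs.tsv --fasta cds.fasta --out kaks.tsv
panfam simulate --seed 1 --out-prefix sim
```

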