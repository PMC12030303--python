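# Methods

## The problem and the model

A pan-genome survey of a gene family observes, for each of many accessions
of one species, a set of family members with chromosomal locations (or an
"unplaced" flag for unanchored scaffolds) and optionally protein/CDS
sequences. `panfam` models the species-level family as K *core clades*,
each descending from one ancestral core gene with a conserved chromosomal
locus, and explains every observed member as the core instance of a clade,
an additional copy of it, or (by absence) a loss. The assumptions are:

* clade membership is meaningful across accessions (members of one clade
  are orthologous/recently paralogous, not a grab-bag);
* the canonical locus of a core gene is the location shared by the
  majority of accessions — deviation from it in one accession is the
  event, not a redefinition of the locus;
* copy number, presence and location per (accession, clade) are the
  observables; promoter content, expression and domain architecture are
  out of scope here.

## Pipeline

1. **Clade assignment** (`assign_clades`) — only for members without a
   clade label. Each is aligned globally against one representative
   sequence per clade; it takes the clade of the best representative if
   identity ≥ `min_identity`, else it is marked *unassigned* and excluded
   from naming (reported separately rather than force-fitted).
2. **Core-profile inference** (`infer_core_profile`) — a clade is core iff
   present in ≥ `presence_threshold` of accessions. Its expected
   chromosome x is the modal chromosome among its *single-copy, placed*
   instances (duplicated accessions are excluded so widespread duplication
   cannot shift the canonical locus); its canonical start is the median
   start of those instances on x. Core indices 1..K follow ascending
   (x, median start), so co-localised core genes are numbered along the
   chromosome.
3. **Per-accession classification** (`classify_accession`) — per clade:
   the *core instance* is the member on x nearest the canonical start
   (then lowest start); if no member is on x, the placed member with
   highest identity to the representative (positional order as fallback
   and tie-break); unplaced members are never preferred over placed ones.
   The core instance is in-place / translocated / unplaced by its
   chromosome; all other members become copies numbered 1.. in
   (chromosome, start) order with unplaced last. Absent clades are
   recorded as losses and do not renumber the rest.
4. **Ledger and summaries** (`detect_events`, `copy_matrix`, `summarize`)
   — one event per deviation; "harbouring all K core genes" is
   operationalised as *exactly one copy of every core clade and nothing
   else*, the only reading under which the per-size accession histogram
   partitions the accession set.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `presence_threshold` | 0.8 | fraction of accessions required for core status. Real core clades sit near 1.0 (the shipped SiSRS composition has ≥ 110/112 ≈ 0.98 per clade); 0.8 leaves headroom for sparser families while excluding accessory clades. |
| `match/mismatch/gap` | 1 / 0 / −1 | linear-gap global alignment scores; only relative order of candidate identities matters for assignment. |
| `min_identity` | 0.6 | members below this identity to every representative stay unassigned; within-clade identities in practice sit far above it, cross-clade far below. |
| name grammar `y = 0` | — | token for unplaced members (e.g. `C16_SiSRS2.1_2D0`); the published grammar prints no unplaced form, so this is a package extension, kept round-trippable. |

## Numerical and tie-break choices

* Identity = matches / alignment columns of one optimal alignment. Among
  co-optimal alignments the reported one maximises (score, matches,
  −columns) lexicographically — additive components, so the dynamic
  program is exact and the result is deterministic and matches an
  exhaustive-enumeration oracle.
* Representative ties in clade assignment go to the lowest clade label
  (logged). Modal-chromosome ties in profile inference are a hard error
  (`UnresolvedLocusError`): silently picking one would misname every
  translocation of that clade.
* Coordinates are 1-based, both ends inclusive (GFF-style convention);
  only relative order is ever used.
* NG86: site fractions exclude single-base changes to stop codons from
  the denominator; pathway averaging drops pathways through stop codons
  and renormalises over survivors (if none survive the pair counts as all
  nonsynonymous, flagged). Site counts are averaged over the two
  sequences; gapped codon columns are removed pairwise before counting.
  Saturation (p ≥ 3/4) and Ks = 0 yield `None` fields plus a flag, not
  exceptions. Only the standard genetic code is wired up (data-driven
  table, so alternates could be added).

## The simulator

`simulate(SimConfig(...))` plants clade c of K on chromosome c at
canonical start c·10⁶ (per-accession jitter < 10³), then per (accession,
clade) draws **one** categorical event — loss (0.05), translocation
(0.10, uniform over other chromosomes), unplacement (0.05) or none — and,
for surviving instances, an independent duplication (0.10). Loss preempts
everything: a lost gene cannot duplicate, so the duplication rate is a
per-surviving-instance rate. Sequences are per-clade random proteins of
length 250 (mid-range for SRS proteins, 226–411 aa) mutated at 2% per
residue; duplicates are re-mutated copies of their parent. All
randomness flows from one seed; output is bit-reproducible.

Duplicate placement: a duplicate of a parent still at its canonical
chromosome x is tandem with probability 1/2, unplaced with probability
`unplaced_rate`, otherwise dispersed to a random other chromosome. A
duplicate of a parent that has *left* x is always tandem. This is an
identifiability rule, not cosmetics: when neither copy of a clade sits on
x and the two sit on different chromosomes, gene content alone cannot
tell which copy translocated and which duplicated, so planting such
configurations would make "exact recovery of the truth" an ill-posed
target rather than a test of the classifier.

What the simulator does **not** emulate: assembly and annotation error
(fragmented gene models, split scaffolds), segmental duplications moving
several clades at once, gene conversion between paralogs, indel
divergence (mutations are substitutions only), and clade gain (new
accessory clades). Passing recovery tests therefore shows the
classification logic is exact under the stated event model — not that
real annotations are this clean.

## Built-in SiSRS composition

`sisrs_pangenome_fixture()` reconstructs the 112-accession foxtail-millet
SiSRS survey: 91 accessions with the six single-copy core genes
(including ten accessions carrying the twelve core translocations),
twelve accessions with one extra copy, Q13 with two, and eight accessions
each lacking one core member — 678 members in total. Coordinates are
synthetic (the survey reports none): clade c starts at c·10⁶, extra
copies +10⁵; only order matters downstream. One documented inconsistency
of the source composition: accession Me34V (described as lacking clade 2
while carrying an extra clade-6 copy) cannot be reconciled with the
printed accession-size partition, and is omitted.

## Problem sizes in the test suite

Unit tests use 10–50 accession simulations with 40–120-residue
representatives; the end-to-end recovery check runs 50 datasets of 100
accessions × 6 clades at the default rates (~1.5 s per dataset, dominated
by ~3700 alignments of 250-residue proteins in the numba kernel). The
alignment oracle comparison enumerates all two-letter pairs to length 4
exhaustively and samples lengths 5–6, where exhaustive alignment
enumeration is still cheap.

## Known limitations

* Nearest-representative identity is a deliberate, self-contained
  substitute for phylogeny/HMM-based clade definition; on real families
  with recent inter-clade gene conversion the two can disagree.
* The loss ledger is neutral: it cannot distinguish biological loss from
  sequencing-depth or annotation artefacts.
* When a clade's only members are unplaced in every accession, no
  expected chromosome exists and profile inference fails loudly rather
  than guessing.
* Ka/Ks requires a codon alignment as input; the package strips gapped
  codon columns but does not align.
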