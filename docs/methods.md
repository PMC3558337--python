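# Methods

This note documents the conventions, models, and design choices behind
`mitocomp`, in the order a user meets them.

## Coordinate model and the tiling identity

All coordinates are 1-based inclusive on a circular sequence; a feature with
`end < start` wraps through the origin. This matches how mitogenome
organization tables are conventionally printed and keeps the packaged
template transcriptions literal. BED-style 0-based half-open conversion, if
ever needed, happens at an export boundary, never internally.

The gap/overlap census walks consecutive genes around the circle, including
the junction between the last and the first gene. Non-coding regions
(NCR-class features) are retained in tables but excluded from the gene ring:
they are intergenic intervals, and their spans appear inside the flanking
positive gap. This is the only reading under which the packaged templates'
interval counts and intergenic grand totals reconcile exactly, including the
circular-junction gap after the last gene. The partition report then checks

    Σ(ring spans) + Σ(positive gaps) − Σ(overlaps) = genome length.

Given internally consistent coordinates this identity is arithmetic, so its
practical role is diagnostic: duplicated genes, features extending past the
declared genome length, or corrupted tables surface as a structured
diagnostic rather than an exception or silence.

## Stop-codon accounting

Termination codons are excluded from the protein-coding partition and from
all codon counts: a complete stop contributes 3 bp, an incomplete stop 1 bp
(`T`) or 2 bp (`TA`). The stop kind is forced by the span's reading-frame
remainder (0 → complete, 1 → `T`, 2 → `TA`), and incomplete stops are
understood as completed to UAA by polyadenylation. Under this convention
coding length equals exactly 3 × codon count, and the per-codon-position
partitions each have length equal to the codon total. An `include_stops`
switch supports the other convention; with it the codon-position split is
taken per gene, since an incomplete stop would otherwise shift downstream
genes out of frame.

Overlapping genes are never trimmed: each gene contributes its full span to
its class partition, so per-class sums may double-count a few shared bases.
The tiling identity above, not the class sums, is the conservation check.

## Genetic code

NCBI translation table 5 (invertebrate mitochondrial) is the default
throughout: AGA/AGG = Ser, TGA = Trp, stops = TAA/TAG. The code object is
table-driven, so other NCBI tables or custom reassignments (some lineages
reassign TAA) can be substituted without touching any algorithm. The ORF
scanner's start set defaults to {ATT, ATA, ATG, TTG, TTA, GTG} — the union
of starts observed in nematode mitogenomes plus the canonical forms — and is
overridable.

## tRNA structural model and folding

Most nematode mitochondrial tRNAs replace the T-arm and variable loop with a
single unpaired "TV replacement" loop; the serine tRNAs instead lack the DHU
arm but keep a T-arm stem-loop. The model fixes stem sizes (acceptor 7 bp,
DHU 4 bp, anticodon 5 bp with a 7-nt loop, anticodon central) and gives
length ranges for the flexible elements: DHU loop 4–9 nt, TV loop 4–12 nt,
serine T-stem 3–5 bp with a 3–8 nt loop, inter-arm spacers of 0–2 and 0–1
nt. The 7-nt anticodon loop and the loop/spacer ranges are conventions of
the field's tRNA models, not measured values; all are overridable in
`TrnaModel`.

Folding is an exhaustive search over every arm placement consistent with the
model and the sequence length (sequences are ≤ 75 nt, so this is a few dozen
placements). Scoring counts paired stem positions — Watson–Crick plus G·U at
full weight — minus one per mismatch, with at most one mismatch per stem. No
thermodynamic energy model is used; structures of this size are accepted by
inspection in practice, and a pairing count reproduces that judgement
deterministically. Ties break by fewest mismatches, then the TV variant,
then the smallest trailing loop, then the leftmost placement, making the
fold a pure function of the sequence. N residues never pair.

Isoacceptor labels follow anticodon families: L1 = anticodon UAG (CUN
leucine), L2 = UAA (UUR leucine), S1 = UCU (AGN serine), S2 = UGA (UCN
serine); classification translates the reverse complement of the anticodon.

## Tandem-repeat detection

For every candidate period, runs are extended greedily left to right: the
next window is accepted while its Hamming distance to the running
column-majority consensus stays within the per-copy budget. Reported
mismatches are recounted against the final whole-array consensus, so a
deviant first copy is charged its own mismatches rather than polluting the
reference — matching how such arrays are described (e.g. "identical units
with a single mismatch in the first repeat"). An adjacent-window Hamming
prefilter (safe by the triangle inequality) vectorizes the scan; the O(L×P)
cost is trivial at mitogenome scale. Overlapping candidates are reduced to
maximal reports: longest array span, then fewest mismatches, then smaller
unit, then leftmost. Note that when flanking background happens to continue
the periodic pattern, the maximal run genuinely begins before the "planted"
or annotated boundary; the detector reports the maximal description.

## Gene-order comparison

Adjacencies are directed gene pairs, because in these genomes all genes are
co-oriented; an order of n genes has exactly n adjacencies on the circle.
The breakpoint distance `n − |shared adjacencies|` is a metric (symmetry and
the triangle inequality are property-tested), zero exactly on circular-order
identity; all comparisons are rotation-invariant. NCRs are excluded from
orders. Neighbor joining is the classical agglomeration with a
lexicographic tie-break on the Q criterion and non-negative clamping of
branch lengths; on additive matrices it recovers the generating tree
exactly (tested against an independent implementation).

## Alignment preparation

The built-in aligner is intentionally simple and fully deterministic:
pairwise global alignment with affine gaps (Gotoh; defaults match +2,
mismatch −1, gap open −3, extend −1; diagonal-preferring traceback),
extended to multiple sequences by center-star merging under "once a gap,
always a gap". It exists so the pipeline and its tests need no external
aligner — it does not try to emulate any particular MSA program, and
externally produced protein alignments can be imported and are treated
identically. Pairwise scores are verified against exhaustive enumeration of
all alignments on short inputs.

Back-translation maps each residue column to its source codon and each gap
to `---`, after verifying that the degapped row equals the translation of
the stop-stripped CDS; incomplete stops contribute no residue. Genes
concatenate in alphanumeric order (atp6, cob, cox1–3, nad1–6, nad4L) — the
partition table makes the choice immaterial. Third-position exclusion drops
every third column per partition, so it commutes with concatenation.

## The synthetic-data generator

`GenomeSpec` fixes everything the analysis measures: the layout (the two
packaged templates transcribe published annotation tables verbatim), a
64-entry codon distribution (the templates use the published per-codon
counts, stops zero), per-class A+T targets (templates: rRNA 85.3%/69.4%,
NCR 98.7%/72.9%, tRNA 84.7%/77.2% for the two species), the tRNA model, and
per-NCR repeat plans (templates: 4×147 + 4×101 + 3×56 with one first-copy
mismatch; 3×494 with two mismatches). Layout numbers — spans, gaps,
overlaps, codon totals, start/stop codons — are therefore reproduced
exactly by construction, while composition and codon usage are reproduced up
to multinomial sampling noise. What the generator does *not* emulate:
codon-level linkage (sites are i.i.d. given the distribution), realistic
rRNA secondary structure, within-NCR repeat spacing (families are placed
contiguously from the 5' end, an assumption), and evolutionary covariation
between genomes. Passing tests demonstrate the pipeline's correctness on
genomes with the published marginal statistics, not distributional realism
beyond those marginals.

Generation is deterministic given the seed, with a single generator per
call. Features are generated downstream-first so that a downstream
feature's bases take precedence in overlaps; upstream codons are then
sampled conditioned on the shared bases, and the hard base requirements of
all planned start/stop codons are checked for joint consistency up front —
an infeasible plan (contradictory shared bases) raises immediately rather
than silently mutating the layout. tRNA generation uses seeded rejection
sampling: a draw is accepted only when the folder returns exactly the
planted structure, which makes the generator/folder round trip an invariant
by construction rather than a statistical hope.

Background sequence (rRNA, NCR, intergenic) is i.i.d. with the class A+T
target split evenly between A and T (and between G and C), since published
compositions report A+T jointly per partition.

## Numeric conventions

Percentages are computed over non-N residues and rounded half-up — one
decimal for composition, two for codon usage — matching how such tables are
printed. The top-k codon summary sums unrounded frequencies before
rounding; summing individually rounded percentages can differ in the last
digit (the packaged counts give 31.43 unrounded vs 31.44 rounded-components
for one genome's top three), and the tests document both.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: two
full template genomes (14.8 and 21.7 kb) plus hundreds of randomized ~11 kb
layouts, 100-seed tRNA round trips (2,200 folds), 200-seed repeat
plantings, and 1,000 random gene-order pairs. The whole suite completes in
well under a minute of CPU.

## Known limitations

* rRNA gene boundaries are taken from the annotation table; no rRNA
  inference is attempted.
* Homology-based gene identification (protein similarity search) is out of
  scope; the ORF scanner is positional, not comparative.
* The repeat detector reports tandem (head-to-tail) arrays only; dispersed
  repeats and length-variant heteroplasmy are not modeled.
* Gene-order comparison treats translocations only (directed adjacencies,
  one strand); inversion-aware (signed/DCJ) distances are not implemented.
* Tree building stops at neighbor joining on breakpoint distances;
  likelihood/Bayesian inference belongs to external engines, for which this
  package prepares inputs.
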