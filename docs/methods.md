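# Methods

This note records the models, defaults and numerical choices behind
`trbannot`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the underlying procedure left
latitude.

## Motif model

Recombination signals are matched against the canonical V(D)J consensus
heptamer `CACAGTG` and nonamer `ACAAAAACC` by mismatch count, with the
recombinationally critical `CAC` core required exact. Two threshold
tiers are used throughout:

| tier | heptamer mm | nonamer mm | spacer slack | meaning |
|---|---|---|---|---|
| strict (calling) | ≤ 2 | ≤ 3 | ±1 | RS intact |
| relaxed (rescue) | ≤ 3 | ≤ 5 | ±1 | RS present but defective |

An RS found at strict thresholds is intact; one found only at relaxed
thresholds, within ±40 bp of the coding end, is *defective* (an ORF
call); none at all is *missing* (a pseudogene call). These tiers are
explicit, configurable defaults — curation practice distinguishes the
outcomes without publishing thresholds. Scoring is mismatch-count only,
not a PWM, so hit sets are exactly reproducible and checkable against an
exhaustive position-by-position scan (a property the test suite
enforces on random kilobase sequences). Per-gene spacer classes follow
the 12/23 rule: V 3'RS = 23, J RS = 12, D flanked by a 12-spacer 5'D-RS
and a 23-spacer 3'D-RS.

Splice donors are GT dinucleotides scored by agreement with the full
`GTAAGT` hexamer (J donors are only clean when the full hexamer is
present, matching its strong conservation at TRB J 3' ends); acceptors
are AG preceded by a pyrimidine-rich tract (≥5 of 8 pyrimidines — a
heuristic, configurable, since only the AG itself is universal).

## Gene calling

Calling is similarity-seeded: reference coding sequences (one exemplar
per V subgroup, one CDS per C subgroup) locate candidate regions via
exact k-mer seeds (k = 12) grouped into ungapped diagonal segments;
per-segment identity is the match fraction over the segment (≥70%
identity to seed discovery, deliberately below the 75% subgroup
threshold so cross-subgroup references still seed hits). A 12-column
tab-separated hit table from an external search engine can be imported
in place of the internal search.

Within each candidate window a spliced alignment places exon boundaries:
seed segments are chained, indel-separated segments merged, and each
junction refined over a ±6 bp shift window to maximize local agreement
with the reference while preferring GT..AG boundaries (full `GTAAGT`
preferred among ties). Two guards make this robust: a putative intron
whose gap the reference also bridges *ungapped* at clearly sub-random
mismatch density (<35%, against ~75% expected across a real intron) is
collapsed as a chance seed match; and a junction that fits badly
(penalty > 4) *and* bridges ungapped below 50% mismatches is likewise
collapsed. A junction with no GT/AG solution keeps the best-agreement
boundary and is flagged defective. Splicing frames are checked from
cumulative coding length (C exons must splice 1, 1, 0).

The V coding 3' end is fixed by a strict 23-spacer RS whose heptamer
begins within 3 bp of the aligned end; failing that, the ±40 bp window
is rescanned at relaxed thresholds, and candidates with neither RS nor
strong similarity are dropped. Multi-intron V-EXON models (the
four-exon TRBV6 configuration) are attempted when enabled; with the
mode off such genes collapse to the two-exon model and are flagged. J
genes are called where a strict 12-spacer RS is followed within 21–72 bp
by an open J-REGION ending at the best donor hexamer (≥4/6 agreement;
not-quite-`GTAAGT` donors are flagged defective); the germline J-REGION
is read in frame 0 from the base after the heptamer, with F-G-X-G
located by scanning all three frames. D genes are one per 12/23-paired
RS (head-to-tail, 8–25 bp apart, closest-pair-first greedy — the
~12 bp G-rich salmonid D sits comfortably inside the configurable 8–25
window).

Loci are assembled C-first: each C gene seeds a locus, the nearest
upstream same-strand D joins it, J genes between D and C join it, and V
genes join the locus whose D is nearest upstream on their own strand
with no intervening C. Contig-level patterns: two complete
opposite-orientation loci with V genes between the C genes =
head-to-head pair; a lone locus with inverted orphan V genes = remnant;
an extra D-J-C cluster with no upstream V adjacent to a complete locus =
tandem D-J-C duplication.

## Functionality

"Incorrect folding" is operationalized strictly as anchor-residue
change: CYS-23 / TRP-41 / CYS-104 for V domains (transferred by global
BLOSUM62 alignment to a numbering profile — the gene's own subgroup
exemplar where known, since a generic profile can drop below the 30%
alignability floor at high divergence), the same positions plus a
hydrophobic residue at 89 (set {A,V,L,I,M,F,W,C,Y}, configurable) for C
domains, and the F-G-X-G J-MOTIF for J genes. Frameshift = coding
length not ≡ 0 mod 3 after exon assembly. A coding span containing N
cannot be certified functional and is reported ORF with a `contains_N`
flag. Precedence: stop codon / frameshift / missing RS ⇒ P; else
defective RS / defective splice / anchor change / N ⇒ ORF; else F.

## Subgroups and names

Subgroup identity is computed over V-REGION nucleotides only (the
coding sequence minus the 20 leader codons), by global alignment
(match +1, mismatch −1, gap open −4, extend −1), as matches over aligned
columns excluding terminal-gap columns. Clustering is single linkage
over edges with identity **strictly** greater than 75% — the subgroup
definition is a connectivity criterion — with complete linkage
available. Clusters take the label of their best reference exemplar
above 75%, else the next free integer (flagged novel). Ranks run 5'→3'
along the locus transcriptional orientation within (locus, subgroup);
J genes are numbered positionally; C genes are ranked across loci
within their C subgroup. Locus numbers follow contig order and C-gene
position (user-overridable): they are positional by design, so
reversing an assembly contig can swap locus digits while every
subgroup and rank is orientation-invariant.

## Phylogenetics

Distances: p-distance (nucleotide default), Poisson-corrected
(−ln(1−p), protein default) and Kimura-2-parameter, with pairwise
deletion (default) or complete deletion of gapped sites; saturated
entries are set to a ceiling of 10 substitutions/site and flagged. The
tree-building protocol being emulated pairs a JTT model label with
nucleotide inputs, which is contradictory, so topology-level agreement
is the comparison standard and the distance model is explicit. NJ is
the Saitou–Nei algorithm with the standard Q-criterion and a
deterministic tie-break (lowest index pair joins first); negative
branch-length estimates are clamped to zero with the raw value kept.
NJ provably recovers additive matrices, which the suite exercises on 50
random trees. Bootstrap resamples alignment columns with replacement;
supports are the percentage of replicates containing each bipartition
of the full-data tree (mapped onto that tree, not a majority-rule
consensus), bit-reproducible for a fixed seed.

## Expression

Each read is aligned to every C reference on both strands by infix
(semiglobal) edit distance; indels count toward the mismatch total, the
best reference wins if its distance is ≤2, and reads tying between
different references are discarded as ambiguous (counted, so either
convention is auditable). RPKM uses **total input reads** as depth, not
mapped reads. Reported ratios round half away from zero to one decimal;
raw values are retained. A SAM/BAM path (primary alignments, NM ≤ 2)
serves externally mapped data.

## The synthetic generator

The generator plants the full architecture with exact truth
coordinates: V genes as a 49 bp L-PART1 (splice frame 1) + intron +
323 bp V-EXON ending at the 2nd-CYS codon + 23-spacer RS; a TRBV6-style
variant splits the V-EXON with two frame-0 introns; J genes as
12-spacer RS + 48 bp J-REGION with F-G-X-G + `GTAAGT` donor; D as the
G-rich 12-mer between 12- and 23-spacer RS; C as four exons
(286/108/71/45 bp, frames 1, 1, 0) encoding 169 residues with anchors
C23/W41/V89/C104. Subgroup structure: per-subgroup ancestors diverge
from a root at the between-subgroup rate (default 0.35
substitutions/site), members from their ancestor at the within-subgroup
rate (default 0.10); with >75% within-subgroup and ~55–60%
between-subgroup identity, single-linkage clustering separates
subgroups cleanly. Substitutions are i.i.d., never create in-frame
stops, and spare anchors, splice-proximal codons (±6 bp of each
junction, emulating purifying selection at splice sites) and — within a
subgroup — the leader, which is strongly conserved in real repertoires
and guarantees seedability. Coding indels occur only through the
explicit frameshift operation, so truth coordinates stay exact.

The labeled mutant panel plants one V gene per operation: none (F),
stop / frameshift / ablated RS (P), degraded RS (3 heptamer
mismatches), broken donor (GT→AT), broken acceptor (AG→AC) and
2nd-CYS→GLY (ORF).

**What the generator does not emulate.** Intergenic and intron filler
is uniform random DNA *rejection-sampled to contain no chance RS motif
at calling thresholds and no stray `GTAAGT`*; an assembled contig gets
a final pass that rewrites mutable bases under any residual chance
motif, and ablated-RS neighbourhoods are additionally kept clean at the
relaxed thresholds so "missing RS" is well defined. Real genomes
contain cryptic RS and decoy splice sites, plus repeats, indel
polymorphism and assembly gaps, none of which are simulated (an
optional N-run is the only gap model). Exact precision/recall = 1.0 on
synthetic data therefore certifies the pipeline's logic — coordinate
arithmetic, motif geometry, exon chaining, classification — not its
false-positive rate on real chromosomes, where similarity seeding and
the strict RS tier carry the discrimination burden. Default genome
scale (~180 kb head-to-head contig with 100 V genes, plus a ~35 kb
single-locus contig) is a deliberate desk-scale rendition of the real
loci, whose largest locus carries 130 V genes over 521 kb; counts per
subgroup echo the real distribution at reduced size.

Read simulation allocates counts proportionally to target RPKM ratio ×
transcript length with largest-remainder rounding (exact for small
tests; a multinomial option exists in spirit via the error channel),
uniform positions, random strands and i.i.d. substitution errors.

## Reproducibility and problem sizes

All randomness flows from `numpy.random.default_rng(seed)`; the same
seed yields byte-identical genomes and FASTQ. The acceptance script
runs, per invocation: one default genome (~215 kb total) annotated end
to end; 20 mutant-panel genomes (~18 kb each); 20 subgroup-recovery
replicates (8 subgroups × 4 members); 50 random additive trees (n ≤
10); 100 scanner-oracle kilobases; and 3 × 50,000 simulated reads.
These sizes were chosen so a complete verification runs in about a
minute on one CPU while keeping every statistical check comfortably
powered (e.g. ratio recovery is tested against 3 binomial-delta-method
standard errors, ~0.1 at ratio 7 with 50 k reads).

## Known limitations

* The similarity search is substitution-oriented (ungapped segments
  with indel merging); highly indel-divergent references would need an
  external search via the hit-table import.
* Numbering is profile-transfer, not a full gap-insertion numbering
  algorithm; insertions relative to the profile carry no position.
* The C-subgroup bootstrap projects sequences onto the first sequence's
  columns instead of building a true multiple alignment — adequate for
  the near-equal-length C proteins it serves.
* Locus numbering cannot be derived from sequence alone; defaults are
  positional and meant to be overridden where historical names exist.
* 12/23-rule *pairing compatibility* beyond motif integrity (e.g.
  whether a defective RS could still recombine) is not modeled.
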