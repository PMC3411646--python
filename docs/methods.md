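# Methods

## Scope and data model

The pipeline operates on a master multiple alignment of complete plastomes
(one row per taxon, gap character `-`, uppercase A/C/G/T/N), per-taxon
region tables partitioning each linearized genome into LSC, IRb, SSC and
IRa, a gene-feature table (GFF3 subset, converted to 0-based half-open
coordinates on read), and a fixed rooted species tree whose taxa are
labelled A-genome diploid, D-genome diploid, allotetraploid, or outgroup
(exactly one outgroup). All internal coordinates are 0-based half-open;
1-based inclusive appears only at the GFF3 file boundary. Columns
containing N in a compared taxon contribute to neither the numerator nor
the denominator of any rate.

## Pairwise divergence

For a pair of taxa the master alignment is projected by dropping columns
gapped in both; substitution events are columns where both carry distinct
A/C/G/T bases (A↔G and C↔T are transitions), and indel events are maximal
runs of gap in exactly one taxon. Alignment-terminal gap runs are excluded
(they are artifacts of linearizing a circular molecule), substitution
columns adjacent to indels still count, and events inherit the region of
their left flank in the reference taxon (the pair's first taxon carrying a
region table). Reported quantities follow the comparative-genomics
conventions: divergence percent = 100·bp/alignment length; S/I =
substitution events / indel events; per-kb rates divide region counts by
region length, with the two IR copies pooled and reported once (counts
summed and halved, lengths averaged). Rounding for report tables is
round-half-even at the printed precision.

## Indel polarization

`multi_taxon_indel_loci` splits the alignment into maximal column spans
with a constant set of gapped taxa, so ragged or nested gaps become
separate loci and "shared" always means identical span boundaries. At each
locus the derived taxa are those whose state (gap vs sequence) differs
from the outgroup's; the locus polarizes iff the derived set matches one
staged configuration — both D genomes (D stage 1), one D genome (D stage
2), A plus all allotetraploids (A stage 1, before tetraploid formation),
both A genomes (A stage 2), one A genome (A stage 3), all allotetraploids
(AD stage 1), or a proper tetraploid subset (AD stage 2). A derived gap is
a deletion, derived sequence an insertion. Branch assignment maps the
derived set to the tree edge above its subtending node; AD-stage-2 subsets
that are not clades are flagged as homoplasy candidates rather than
assigned. Patterns matching no rule — including the whole-ingroup pattern,
whose event could lie on either root edge — stay unpolarized with the
reason recorded. Loci overlapping detected SSR spans are flagged
`ssr_associated`; they polarize only when a stage rule matches, which is
the dominant failure mode for slippage-generated gaps in real panels.

A note on the outgroup-flip property: flipping the outgroup's state at a
root-adjacent stage-1 locus converts a D-stage-1 pattern into an A-stage-1
pattern (and vice versa) with inverted polarity, because those derived
sets are the two children of the ingroup root. Flipping at an
allotetraploid-crown stage-1 locus instead yields derived set A∪D, which
is not a clade — two equally parsimonious event placements exist — and the
locus is correctly left unpolarized. The recovery experiments assert both
behaviours.

## cpSSR analysis

The scanner reports maximal perfect tandem repeats of primitive motifs
(unit 1–5 bp): for each unit length u, positions with `seq[j] == seq[j-u]`
form match runs, each run yields the repeat region, and a trailing partial
unit is truncated (consequently a repeat with a partial unit maps to
positions that differ by up to u−1 between the two strands). A run is
reported at the smallest unit generating it (poly-A is never a "AA"
dinucleotide) and motifs are canonicalized to their smallest rotation
without collapsing reverse complements. Threshold presets follow the two
definitions used for plastome SSR surveys: set A (mono ≥8, di ≥8, tri ≥9,
tetra ≥12, penta ≥15 bp) and set B (mono ≥10, di ≥10, tri ≥12, tetra ≥16,
penta ≥20 bp); set-B loci are by construction a subset of set-A loci.
Homology across genomes is by overlap of alignment-column spans plus
canonical-motif equality (single linkage); a group is polymorphic for a
pair iff the two repeat lengths differ, with absence scored as length 0,
and conserved iff all taxa carry identical nonzero length. 1–3 bp pairwise
indels are attributed to slippage when their span intersects a group
polymorphic for that pair. Two genuine leakage modes keep the attributed
fraction below 1.0 even under slippage-only evolution: both taxa may carry
equal repeat lengths via different unit losses (the locus is then not
"polymorphic for the pair" although a gap run exists), and deep-path
contractions can drop both copies below the detection threshold.

## Ka/Ks, calibration, dating

The Nei–Gojobori (1986) estimator is implemented directly: per-codon
synonymous site fractions (changes to stop codons count as nonsynonymous)
averaged over both sequences; observed differences per codon averaged over
all substitution orderings, with paths through stop codons excluded and
weights renormalized (equal weighting as fallback when all paths are
blocked); Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3), with p ≥ 3/4
flagged as saturated. Codons containing a gap or N in either sequence are
dropped pairwise; internal stops raise by default and can be masked for
bulk whole-genome summaries. The genetic code is the bacterial/plastid
table (NCBI 11). Values from this estimator differ slightly, by method,
from ML codon-model estimates published for the same data.

Calibration and dating are the estimator-agnostic identities
r_s = Ks/(2·t_cal) and T = Ks/(2·r_s); they invert each other exactly, and
with the study's rate r_s = 1.162×10⁻⁹ /site/year the Ks implied by the
A/D split dates it to 3.89 MY. When dating *simulated* panels the rate
must be calibrated from the simulation itself (driver 05 calibrates on the
planted A/D split): the generator's uniform per-site rate makes its
synonymous rate equal to its genome-wide rate, unlike real plastomes where
synonymous sites evolve faster than the constrained average.

Tajima's relative rate test counts, over gap-free N-free columns of a
taxon trio, sites where only lineage A differs (n_A) and only lineage B
differs (n_B); χ² = (n_A−n_B)²/(n_A+n_B) on 1 df, undefined (reported as
p = 1 with a flag) when n_A+n_B = 0. No multiple-testing correction is
applied; significance stars mark p < 0.05 / p < 0.01. Caveat for
whole-genome mode on IR-mirrored data: every concerted IR event is counted
in both repeat copies, which roughly doubles the variance contribution of
~19% of events and inflates the statistic (empirically ~7/18 nominal
rejections on a clock-simulated panel versus 0/18 when IR columns are
excluded); trios sharing tree branches are also strongly correlated. The
type-I calibration experiment therefore simulates unduplicated sequence,
where the empirical rejection rate sits at the nominal 5%.

## Synthetic plastome generator

The ancestral genome is assembled region by region with per-region AT
fractions (defaults 64.8/57.0/68.3% for LSC/IR/SSC, overall ≈63%), sizes
defaulting to the observed architecture (LSC 88.8 kb, SSC 20.3 kb, IR
25.6 kb per copy, ≈160.3 kb total), a seeded SSR repertoire (≈70 loci,
mostly A/T mononucleotide runs of 9–14 units with exact flank-broken unit
counts), boundary genes for junction analysis (rps19 ending 11 bp before
LSC/IRb; ycf1 crossing SSC/IRa by 55 bp, annotation only), and a
plus-strand CDS complement rewritten to be free of in-frame stops so codon
analyses are well posed.

Evolution proceeds by preorder traversal of the rooted tree. Branch
lengths are in millions of years; per branch, substitution and indel
counts are Poisson with means rate·length·sites, positions uniform.
Defaults: substitution rate 6.8×10⁻⁴ /site/MY of path (giving ≈0.53%
divergence across the 2×3.89 MY A/D path), Si/Sv target 0.45
(transversion-rich, as observed), indel rate = substitution rate / 3.2,
an indel size law over 1–15 bp with mass 0.32 at 1 bp and 0.20 at 5 bp,
insertion:deletion odds 0.8 (deletion bias), 30% of insertions generated
as adjacent-segment duplications (the slipped-strand signature; targeted
duplicate-adjacent deletions are deliberately not generated because
finding a matching site is size-dependent and would bend the realized
spectrum away from the nominal law), and per-locus slippage probability
0.04·branch-length with ±1 unit per event. Indels are redrawn (≤100
tries) if they would cross a region boundary, overlap a same-branch indel,
or touch the linearization origin (a 10-site margin at both genome ends).

Concerted IR evolution: events are sampled over LSC+IRb+SSC only and IRa
is rebuilt each branch as the reverse complement of IRb, so the two copies
stay exact mirrors (a flag disables this, decoupling the copies). The
mirroring model is an idealization — how tightly real IRs are homogenized
per generation is not quantified — and note that it mirrors *events*, not
rates: the IR is not intrinsically slower in the generator, whereas real
plastome IRs are; per-region rate multipliers are not modelled.

Column identity uses order keys: tuples whose lexicographic order equals
sequence order in every lineage. Ancestral sites are `(i,)`; an insertion
(event id e) after the site keyed K creates `K + (−e, m)`, which places
later insertions closer to their flank — exactly sequential-application
semantics — and keeps the global column order consistent across lineages.
IRa keys are an order-reversing involution of their IRb partners' keys, so
mirroring needs no bookkeeping. The truth alignment is the key-sorted
union of all tip sites; the event log stores keys, so replaying it from
the ancestor reproduces every tip byte-for-byte (tested), and identical
seeds reproduce identical files.

What the generator does not emulate: realistic gene content and intron
structure, codon-aware selection, per-region or per-site rate
heterogeneity, recombination, and base-compositional drift. Recovery
results on synthetic panels therefore demonstrate the correctness of the
accounting, polarization, SSR and dating machinery under known truth, not
the biological fidelity of any particular published value.

## Experiment design and problem sizes

The recovery experiments run the generator at its full study-condition
genome size (~160 kb, 14 taxa). Polarization/spectrum recovery pools three
seeded replicates (~890 planted ingroup indels) with SSR slippage disabled
so that every gap locus stems from the indel process and the planted size
law is exact; recovery denominators are planted insertions/deletions on
branches strictly inside the ingroup crown (single-outgroup polarization
cannot, in principle, place events on the two root edges) that survive in
the alignment and fall outside detected SSR spans. The size-spectrum χ²
test uses one replicate (~750 loci, all expected bin counts > 10) and
counts each concerted-IR event once. The slippage-attribution experiment
evolves under slippage only (≈150 tree events, >2000 pairwise 1–3 bp
events). The relative-rate type-I experiment uses 800 trios of 2-kb
sequences at 4% ingroup and 8% outgroup divergence. Dating identities use
100 random (Ks, T) pairs. The small-alignment oracle check enumerates all
4-taxon alignments of one and two columns over {A, C, −} exhaustively plus
4000 seeded longer cases against a column-by-column reference.

## Degenerate inputs and tie-breaks

Empty alignments, ragged rows, duplicate taxon ids, `.` gaps and non-ACGTN
characters are format errors; lowercase is read as uppercase with a
warning. Si/Sv and S/I with zero denominators report NaN. Identical
sequences give zero events everywhere. An SSR run at exactly the threshold
is included; compound (adjacent different-motif) repeats are separate
loci. Junction distances are signed: negative means the gene crosses the
junction, with magnitude equal to the overlap. The pairwise matrix writes
indel counts above and substitution totals below the diagonal, so cell
meaning follows the supplied taxon order while per-pair values are
order-invariant.
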