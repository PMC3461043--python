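# Methods

This note records the models, conventions and numerical choices behind
`mitocomp`, in the order the pipeline runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, strands and the genome model

A mitogenome is a circular A/C/G/T/N string with typed, stranded features.
Internally all coordinates are 0-based half-open on the J-strand; report
output is 1-based inclusive (GenBank convention). The J-strand is defined
operationally as the strand carrying *cox1* (falling back to the majority
strand when *cox1* is absent); a GenBank record stored in the opposite
orientation is reverse-complemented on input so the stored sequence *is* the
J-strand. Features crossing the origin carry a wrap flag and occupy
[start, L) ∪ [0, end). Unknown gene names are kept as non-coding features
with a warning rather than rejected, to tolerate annotation dialects; the
synonym table mapping dialect names (COI, 16S, tRNA-Leu(UUR), …) to
canonical labels is caller-extensible. Leucine/serine isoacceptors are
numbered L1: UUR, L2: CUN, S1: AGN, S2: UCN.

## Architecture

Gene overlaps are computed pairwise between features adjacent in J-strand
order (regardless of strand), including the pair that closes the circle. A
three-gene pileup would thus count as its adjacent pairwise intersections;
the generator never creates one, and real mitogenomes essentially never do.
Non-coding regions are the complement of the PCG/tRNA/rRNA union on the
circle — an annotated control region is deliberately ignored in the union
and rediscovered, so annotated and unannotated inputs give the same
inventory. The region flanked by *rrnS* and *trnI* is labelled CR. Regions
longer than 100 bp are flagged "large" (configurable).

A stop is called truncated (T or TA) only when the CDS length modulo 3
leaves that remainder *and* a tRNA starts at 0 bp distance downstream in
coding orientation — the configuration in which polyadenylation of the
transcript can complete the terminator. Any other ragged end is reported
with an anomaly note instead of being silently accepted.

## Composition

Skews are (A−T)/(A+T) and (G−C)/(G+C); an empty denominator yields a
missing value, never zero. N residues are excluded from all counts, so
partial genomes are summarised over their available sequence. Partition
statistics are computed on the J-strand (the convention in which published
mitogenome composition tables are reported), with a flag for per-gene
coding-strand statistics. Third-codon-position statistics default to the
coding strand of each gene — the frame exists only there — with the
J-strand projection (complementing the thirds of minority-strand genes)
available behind the same flag, since the choice flips skew signs for
N-strand genes. Sliding-window profiles wrap the origin and report
deviations from the genome-wide mean.

## Codon usage

Codon counting drops a truncated terminal T/TA, excludes the final stop
codon, raises on internal stops (naming the gene and codon) and skips
N-containing codons into a separate tally. The degeneracy layout is derived
from the genetic code actually in force, not assumed: under table 5 the 62
sense codons form 12 two-fold families, 6 four-fold, one six-fold (Leu) and
one eight-fold (Ser = TCN + AGN), so

    ENC = 12/F̄₂ + 6/F̄₄ + 1/F₆ + 1/F₈ ,   F = (nΣp² − 1)/(n − 1)

ranges from 20 to 62 — not Wright's universal-code 61, which programs
assuming the universal layout report. Families with fewer than two counted
codons contribute no F; a class with no estimable F is imputed at its
no-bias floor 1/k, and a non-positive class mean (all-singleton usage) falls
back to the same floor. The result is clamped at 62, which also makes the
exactly-uniform table evaluate to exactly 62 despite the finite-n bias of F.

CBI uses one preferred codon per family, defaulting to the modal codon of
the analysed table (the classical definition leaves the preferred set to
the analyst); an explicit set can be supplied, e.g. dataset-wide modal
codons when comparing species. ENC per species is computed on the
concatenated PCGs (one value per genome); per-gene tables are available by
calling `count_codons` on single genes.

## Nei–Gojobori Ka/Ks

Site counts: per codon position, the synonymous fraction is the share of
the single-nucleotide changes at that position that preserve the amino
acid, with changes into stop codons removed from both numerator and
denominator; synonymous + nonsynonymous sites sum to exactly 3 per codon.
Differences: observed substitutions between a codon pair are averaged with
equal weight over all minimal substitution pathways (original 1986
weighting, no transition/transversion weighting); pathways crossing a stop
codon are excluded and the remainder renormalised — the test suite verifies
by exhaustive enumeration that every sense–sense pair retains at least one
pathway under table 5. Proportions are corrected with Jukes–Cantor
d = −(3/4)·ln(1 − 4p/3); saturation (p ≥ 3/4) yields a missing value that
propagates as such, never a clamp. Codon sites containing a gap, an N, or a
stop codon in either sequence are treated as missing data and skipped
pairwise — the stop case matters for clade-simulated genomes, where
evolution inside a 7 bp gene overlap is controlled by one of the two
reading frames and can occasionally write a stop into the other. Per-gene
summaries average Ka, Ks and their ratio over all unordered sequence pairs;
the GC covariate of the rate regression is total gene GC by default, GC3 by
flag.

## Non-coding structure

*Tandem repeats.* For each candidate period p, positions with
seq[i] == seq[i+p] are scored; windows of width p with matching fraction ≥
the identity threshold (default 0.8) are merged into runs, tolerating gaps
shorter than one period (a locally divergent stretch knocks out up to a
unit's worth of windows without ending the array). Edges are trimmed until
a 5 bp runway reaches the threshold, which removes the flank bleed that
window-level detection produces. An array of period p also scores at 2p,
3p, …, with comparable identity; such harmonic calls are dropped when a
smaller-period call of similar identity covers ≥ 60% of their span, and the
survivors are accepted greedily by span, then identity. Copy number is
span/period and may be fractional. Defaults (min unit 10, min copies 2,
min identity 0.8) are calibration values, configurable throughout.

*Control-region blocks.* Sliding-window composition (default window 20 bp)
with thresholds G+A ≥ 0.80, C ≥ 0.60, A+T ≥ 0.90 — calibration values. The
CR is taken on the J-strand with position 0 at the rrnS-proximal (3') end,
its natural orientation when extracted from a genome in the ancestral gene
order. The G+A-rich block is the qualifying run nearest that end; the
C-rich block is the first qualifying run beyond it, and the A+T-rich block
the first beyond that, mirroring the canonical layout; runs may start up to
one window inside the previous block (edge windows blend compositions) and
are clamped to non-overlap. Because the CR background is itself A+T-rich,
spurious A+T windows are common; when no C block anchors the search the
A+T block falls back to the run with the best excess-composition × length
score. Block edges are resolution-limited to roughly half a window.

*Stem-loops.* Exhaustive scan for inverted repeats: equal arms of length ≥
min_stem (default 6, capped at 30) separated by a loop in the configured
range (default 3–20), pairing Watson–Crick plus G·U when enabled (default),
with at most `max_mismatch` internal non-pairing positions (default 1) and
both terminal pairs required to pair. Candidates rank by stem length, then
fewest mismatches, and are accepted without overlap. The CR annotation
searches from one window before the end of the composition blocks (detected
block edges can overrun an abutting hairpin by a few positions).

## RNA conservation

Alignment columns are classified disjointly: any gap ⇒ indel; else
identical ⇒ conserved; else substitution — so the three counts always sum
to the alignment length. tRNA structures are dot-bracket strings with arm
assignments (acceptor, DHU, anticodon, TψC, extra); a stem mismatch is a
paired position failing Watson–Crick (and G·U when allowed), attributed to
the arm of its 5' partner. DHU loss is the absence of any paired position
in the DHU arm; a single surviving pair counts as present.

## Phylogeny

Per-gene alignments are inputs (the package does not align); missing taxa
are gap-filled with a warning, and partition column ranges are recorded.
Distances use pairwise deletion of columns gapped or ambiguous in either
member (complete deletion by flag); K2P uses the standard log correction
and returns a missing value, with a warning, when saturated. Neighbor
joining is delegated to scikit-bio and the tree is rooted on the branch to
the outgroup clade; with no outgroup the unrooted tree is returned with a
warning. NJ is a deliberate desk-scale surrogate for ML/Bayesian inference:
topology agreement is reported, not asserted, for real data.

## Synthetic data

The generator emits a circular genome in the ancestral arthropod gene order
(37 genes + CR). Protein genes sample amino acids from frequencies typical
of AT-rich insect mitochondrial proteomes, then codons within each family.
The within-family distribution starts from per-base AT-weighted
probabilities, is concentrated by a single genome-wide Dirichlet draw whose
concentration (`codon_bias`, default 0.5) steers ENC — small values give
strong bias — and is then exponentially tilted so the expected coding AT,
combined with an explicit AT budget for every non-coding part (tRNA/rRNA
filler at 0.93, CR blocks at their block compositions, variable domain at
0.80), hits the whole-genome AT target; the tilt removes the genome-level
AT variance the single Dirichlet draw would otherwise add. Measured AT
lands within ±0.02 of the target at 16 kb.

Plantings: atp8–atp6 and nad4–nad4L overlap by 7 bp sharing ATGATAA on the
coding strand, built by fixing the flanking codons of both genes so the
shared region is consistent in both frames (requesting any other motif is
rejected as infeasible); *cox1* starts with TTG; *cox2* and *nad5* end on
truncated T/TA stops with a zero-gap downstream tRNA; the trnI–trnQ spacer
carries a tandem repeat and the trnS2–nad1 spacer a plain insertion by
default; the CR is laid out GA block → C block → AT block → stem-loop →
variable domain from its rrnS-proximal end, with coordinates of every
planting returned as ground truth. tRNAs are random cloverleaves with
exact-complement stems, real anticodons, and a D-armless trnS1; their
dot-bracket structures are part of the ground truth.

The codon-evolution simulator uses a reversible 62-state codon process:
single-nucleotide exchanges at rate 1 (synonymous) or ω (nonsynonymous),
optionally κ-weighted transitions, stop codons unreachable; the symmetric
rate matrix is scaled to unit mean rate and exponentiated by
eigendecomposition, so branch lengths are expected substitutions per codon.
`simulate_cds_pair` evolves two descendants half a branch length each from
a uniform ancestor. `generate_clade` evolves a root genome down a Newick
tree — codon model on PCG positions (each overlap position owned by the
first gene in genome order), Jukes–Cantor elsewhere, with nucleotide-site
branch lengths (codon branch lengths are 3×).

What the generator does *not* emulate, and what passing tests therefore do
not show about real data: strand-asymmetric mutational spectra (real skews
arise from replication asymmetry; the generator's skews are planted
compositionally), indel evolution, among-site rate variation, realistic
rRNA/tRNA sequence homology across genomes (clade simulation provides
homology; independent generation does not), and base-composition
heterogeneity along genes.

## Problem sizes and numerical conventions

The acceptance experiments run at desk scale: 50 replicates of ~10 kb
(3,334 codons) per ω for rate recovery, 100 plantings each for
repeat/block/stem-loop recovery (repeat plantings are redrawn until their
realised adjacent-copy identity is ≥ 0.9, the condition under which
recovery is claimed), 100 six-taxon clades of 2 kb for NJ recovery, and a
six-genome batch spanning 72–77% A+T for the composition/architecture
closure. All random streams derive from a single integer seed; no global
random state is used or mutated. Missing statistics (undefined skew,
saturated distances, 0/0 rate ratios) are represented as `None`/`NA` and
propagate explicitly — nothing is clamped to a numeric sentinel.

## Known limitations

Gene-order rearrangement analysis is limited to adjacency and
presence/absence (no breakpoint distances). The repeat detector reports the
fundamental period of near-periodic arrays but is not a full
alignment-based repeat finder; heavily diverged arrays (adjacent-copy
identity below ~0.85) fragment. CR block segmentation assumes the canonical
block order and is resolution-limited by its window. ML/Bayesian tree
inference, model selection and bootstrap support are out of scope by
design.
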