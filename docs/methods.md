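# Methods

This note records the models implemented in `myxoedit`, the conventions and
parameter choices behind them, what the synthetic data do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Coordinates, canonicalization, ambiguity

An editing site is an insertion *before* a 0-based index of the unedited
genomic sequence. Inserting a C anywhere inside a run of genomic Cs yields
the same edited sequence, so sites are canonicalized to the **leftmost**
equivalent placement; this is a convention, not a biological claim, chosen
because it is deterministic and order-preserving. A site is *ambiguous* when
the inserted base is flanked in the edited sequence by an equal base
(templated or inserted); for isolated single insertions this coincides with
the usual definition (a genomic C neighbour). Several insertions may share
one canonical slot (a CC insertion parses to two sites at the same position);
this is required for edited-FASTA round-trip fidelity and for the predictor's
search space, which permits codons of fewer than three genomic nucleotides.
Codon positions are always measured in the edited reading frame starting at
the transcript's first base.

Non-C insertions (U/dinucleotide editing types) are parsed and retained but
excluded from all C-site statistics; the accuracy scorer additionally
excludes predictions within 1 nt of a non-C true site (the exclusion radius
is not fixed by any published number; 1 nt is the minimal "close vicinity").

## The insertion-aware aligner

`predict.predict_sites` maximizes, over all insertion sets and alignments,

  alignment score − insertion_penalty × (#inserted Cs),

where each aligned codon draws k ∈ {0,1,2,3} genomic nucleotides (in order)
plus 3−k Cs in any within-codon arrangement, a model position may be skipped
(protein-side gap) and a 3-nt genomic codon may be skipped (codon-side gap),
both with affine cost `gap_open + (L−1)·gap_extend` for a gap of L units
(defaults 11/1, the BLOSUM convention). Matrix mode scores codon translations
against a reference protein with BLOSUM62/75/90; PSSM mode uses per-position
log-odds read from PSI-BLAST ASCII output. The DP is exact over this space —
the test suite checks score equality with an independent exhaustive
enumeration on hundreds of random instances — and deterministic: ties prefer
transitions consuming more genomic nucleotides (fewer insertions), then a
fixed arrangement order, and predicted sites are canonicalized leftmost.

`insertion_penalty` defaults to 0 (the plain maximum-similarity criterion).
Note that with a zero penalty the aligner will freely spend insertions to
locally repair diverged regions, typically in frame-preserving triples; a
penalty of a few score units suppresses this and is recommended when the
homolog is distant. Stop codons are scored through the matrix ('*' column),
never forbidden; gene location (`locate_gene`) uses the same program with
free leading/trailing genomic sequence, scans both strands, and reports the
better one.

## Conservation analysis

For each gene the two edited mRNAs are aligned globally (match 2, mismatch
−1, gap open 5, extend 1 — generic nucleotide scoring; the DNA rows of the
four-way view are derived by gapping the inserted characters, so no separate
DNA alignment is needed). Shared sites are C insertions edited at the same
alignment column in both organisms; a shared site is unambiguous when at
least one organism's insertion has no equal neighbour. Backgrounds f1, f2, f3
are the fractions of gap-free columns per codon position at which both
organisms carry the same base, pooled over genes.

Offsets d ∈ [−9, +9] \ {0} from each shared site are compared at the same
relative position of each organism's own mRNA (not through alignment
columns), matching how flanking patterns are defined; the offset's codon
position is ((site_cp − 1 + d) mod 3) + 1. Significance uses exact binomial
tails — upper when observed ≥ background, lower otherwise — at a
Bonferroni-style cutoff of 0.05/36 (18 offsets × 2 strata) by default; the
cutoff is a parameter and raw p-values are always reported. Beyond the 9-nt
window, sites with another editing site between the probed position and the
site are discarded, which keeps codon phase clean at the cost of sample size
(N_d is non-increasing in |d|).

## Motif uniqueness

The negative set ("definitely not edited") is conservative: every position or
junction at which an inserted base could lie under an equivalent placement
within its homopolymer run is excluded. Single-sided scans ask for the
largest k such that some k-mer flanks both an unambiguous C site and a
non-edited locus; straddling m+n scans ask whether a site's m-upstream plus
n-downstream context (C removed, at the edited level) occurs contiguously
across a non-edited junction. Non-uniqueness is monotone in (m, n) by
substring closure, so the result is summarized as the maximal antichain of
non-unique combinations plus its complement's minimal elements (the smallest
sufficient recognition regions). Indexing is plain k-mer set intersection;
transcriptomes of a few hundred kilobases are handled in seconds.

## Recognition information

With GC fraction g, two random nucleotides agree with probability
p = 2(g/2)² + 2((1−g)/2)² (0.3125 at g = 0.25). A 19-nt motif with f fixed
positions recurs in expectation G·p^f times in a G-nt genome; the smallest f
with G·p^f ≤ 2 ("close to one per genome") is 9 at G = 62,862 — a strict
threshold of 1 expected hit would give 10, and the threshold is exposed as a
parameter. Mixing 9 fixed positions with 10 positions drifting at the lowest
observed background (63.3%) gives the minimum average conservation
(9 + 10·0.633)/19 = 80.7%. `detectability_check` turns that bound into the
binomial p-value it would have produced at a given sample size, implementing
the argument that a null scan outcome at N ≈ 148 sites is informative.

## Codon-position bias

R = N3/N2 over unambiguous C sites with σ_R = R·√(1/N2 + 1/N3), the
first-order propagation of independent √N counting errors. Genes are grouped
by second-codon-position conservation over [0.60, 1.00] in 2 or 4 equal
intervals; a gene exactly on an interior boundary goes to the upper group.
Empty groups are reported as missing rather than zero, and the 2-group table
is exactly the 4-group table with groups pooled pairwise.

## The synthetic-data generator

The generator is the package's stand-in for paired GenBank gene sets and
encodes the study conditions as defaults: 25% GC, one insertion per 25 nt,
second-position identity targets spanning 0.60–1.00, and proposal weights
(0.45, 0.25, 0.30) over codon positions which, after selection at mid-range
conservation, realize roughly the observed 34/10/56 site split.

One ancestral in-frame ORF is drawn codon-wise from a base distribution
tilted so that stop-codon rejection still realizes the requested composition.
Editing sites arise by the mutation-selection mechanism: a proposed position
has its base replaced by C; synonymous replacements are always accepted,
amino-acid-changing ones with probability (1 − conservation target), and
stop-creating ones never. This coupling — not a hand-placed bias — is what
makes R = N3/N2 grow with conservation, so recovering that trend is a genuine
test of the analysis. At most one site is allowed per C-run (two sites in one
run would collapse onto a single canonical slot). Each site is retained in
both descendants with probability `shared_site_fraction` (default 0.7),
otherwise in one of them; a lost site's C remains genome-templated in the
other descendant, so the two mRNAs stay column-aligned in ancestral
coordinates (true indels between organisms are deliberately not modelled).

Divergence assigns each codon position an exact mismatch count,
round((1−f_c)·n_c), at uniformly chosen columns, mutating one lineage per
column with a composition-stationary kernel (a single π-weighted draw;
unusable draws move to another column). Exact counts rather than per-site
Bernoulli rates were chosen because the generator's contract promises
realized second-position identity within ±5 points of target even for single
genes, which rate-based calibration cannot guarantee at a few hundred codons.
First/third-position targets are slaved to the second by the observed
divergence ratios (d1/d2 ≈ 1.52, d3/d2 ≈ 2.30), floored at 30% identity.
Columns around sites never gain or lose Cs, keeping run structure — and
hence canonical site placement — identical across organisms. `motif_spec`
embeds a recognition signal by pinning columns at chosen offsets from shared
sites to a chosen conservation level, again by exact count, so an embedded
80.7% offset reproduces the detectability bound deterministically.

What the generator does **not** emulate: conservative (BLOSUM-like) amino
acid replacement — substitutions draw uniformly from the composition, which
makes proteins at a given nucleotide identity look more diverged than real
homolog pairs, and accounts for the predictor's over-insertion on low-
conservation synthetic genes; indel divergence; transition/transversion bias;
rate variation along genes; and any real recognition signal. Passing tests
therefore certify the algorithms and their statistical calibration, not
predictor accuracy on real sequence pairs.

## Problem sizes and determinism

The test suite runs its statistical checks at the scales the analyses are
about: conservation-scan power uses ~148 third-position shared sites per
replicate (two genes of 800–900 codons, 200 replicates), type-I control uses
200 null replicates, DP-oracle equivalence uses 200 instances of up to 30 nt
against exhaustive enumeration, and the bias trend uses 12 genes of 400–450
codons per seed across 20 seeds — enough for N2 ≈ 40 in the conserved group
so the 1σ comparison is meaningful. All randomness flows from explicit seeds
(NumPy `SeedSequence` spawning per gene); pipeline reruns are byte-identical.

## Known limitations

* The predictor's search space ties genomic-side gaps to whole codons; a
  gapped codon cannot itself contain insertions. This matches the documented
  operation grammar but means rare edge optima mixing insertions into
  unaligned codons are not represented.
* Offsets are profiled in each organism's own mRNA coordinates; alignment
  columns are used only to decide sharedness.
* Canonical leftmost placement can shift an ambiguous site's codon position;
  analyses therefore restrict to unambiguous sites, and shared pairs whose
  codon positions disagree between organisms are excluded with a warning.
* `group_and_trend` judges the trend only between the extreme occupied
  groups; intermediate non-monotonicity is visible in the table but not
  summarized.
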