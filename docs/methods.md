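# Methods

## Coordinate conventions

All reference coordinates are 0-based and half-open. Cut sites are
*between-base* integers: cut `c` lies between reference positions `c-1`
and `c`. For a `+`-strand protospacer at `[s, s+20)` with PAM at
`[s+20, s+23)`, the blunt SpCas9 cut between the 3rd and 4th nucleotide
upstream of the PAM gives `c = s + 17`; the `-` strand is the mirror
image, `c = s + 3`. Reverse-complementing an amplicon maps `c` to
`len(amplicon) - c`, which the test suite asserts on random fixtures.

## Quantification window

Indels are attributed to nuclease activity when they touch the window
`[c - w, c + w)` with half-width `w = 5` by default (10 reference
positions). A deletion is in-window iff it removes at least one base of
the window; an insertion iff its between-base anchor lies in the closed
range `[c - w, c + w]`. The phrase "a window of five nucleotides around
the cut" is ambiguous between 5 total and 5 per side; we adopt the ±w
convention common in amplicon-editing quantification tools and expose
`window_halfwidth` so either reading can be configured. Only NGG PAMs
are supported.

## Alignment and event calling

Reads are designed to span the amplicon, so we use global end-to-end
pairwise alignment (Biopython `PairwiseAligner`) with affine gap
penalties: match +2, mismatch −4, gap open −10, gap extend −1, where a
length-L gap scores `open + (L−1)·extend`. These scores are this
package's declared defaults (configurable via `AlignmentScoring`); no
published parameter set exists for this assay class. Maximal gap runs
become single insertion/deletion events; mismatch columns become
length-1 substitution events; adjacent distinct events are never merged.
Every indel is then left-normalized (shifted to its leftmost equivalent
placement, VCF-style) so event coordinates are deterministic in
homopolymer and microhomology contexts. Reads whose alignment identity
(matching columns over all columns) falls below 0.60 are flagged
unalignable and excluded from all denominators. Terminal gap runs are
treated as missing coverage, not deletions: a read enters a target's
denominator only if its aligned span covers the whole window.
Identical read sequences share one alignment (mosaic amplicon data is
dominated by a handful of alleles), which is what makes 10⁶-read cohorts
quantify in seconds.

## Classification rules

Per read and target: status is `mutated` iff ≥1 in-window indel exists;
substitutions never change status (single-nucleotide substitutions are
characteristic bridge-PCR sequencing and PCR errors, so they are treated
as noise). The net coding shift sums, over in-window indels, +length for
insertions anchored strictly inside a coding interval and −overlap with
coding intervals for deletions. Category: `frameshift` if the net shift
is not a multiple of 3; `inframe` if it is a multiple of 3 and some
in-window indel touches coding sequence; `noncoding` otherwise. A large
deletion intersecting the windows of two targets on one amplicon counts
as mutated for both. `q`, `fs`, `im`, `nm` are all fractions of
window-covering reads, so they conserve to 1 exactly; `im`/`nm` are
deliberately *not* renormalized to mutated reads, because the
loss-of-function formula needs per-allele (per-read) fractions with
`q + im + nm ≤ 1`. Targets with fewer than `min_reads` (default 100)
covering reads are marked insufficient-coverage rather than divided by
small denominators.

## The biallelic loss-of-function model

The embryo's allele pool is treated as well mixed, read fractions as
allele fractions, and the two alleles of a cell as independent draws
from that pool (no PCR-duplicate correction). With per-sgRNA wildtype
fractions `q_r` for a pool of `R` co-injected sgRNAs,

    P(M) = (1 − ∏_r q_r)²        P(F) = (1 − ∏_r (q_r + im_r + nm_r))²

are the probabilities of at least one mutation / frameshift mutation on
each allele; `R = 1` gives the single-sgRNA forms `(1−q)²` and
`(1−(q+im+nm))²`. `p_fs ≤ p_mut` always, and pooled `p_mut` dominates
every single-sgRNA `p_mut` of the same animal. Cohort medians use the
midpoint-of-central-pair convention for even n and are computed over
*per-animal* probabilities. Because squaring is nonlinear, the median of
`(1−q)²` is not `(1−median q)²` in general (with an even cohort the
median averages two animals); the two coincide when the median animal is
shared, e.g. at a 100% mutagenesis rate. Reported percentages are
rounded to one decimal; full precision is kept internally.

## Indel spectra

Per animal, each indel size (negative = deletion length, positive =
insertion length) is reported as the fraction of that target's mutated
reads carrying an in-window event of the size; a read with several
distinct indels contributes to each size, so per-animal fractions can
sum above 1 while each single fraction stays ≤ 1. The cohort profile is
the mean over animals with ≥1 mutated read (a fraction of zero mutated
reads is undefined, so such animals are excluded from the denominator).
The deletion/insertion split is event-level over all mutated reads. The
most frequent indel is the argmax of the mean frequency, ties broken
toward smaller |size| with deletions before insertions. Event size is
the event's own length, not the read's net shift, and a deletion
spanning two targets' windows contributes to both targets' profiles.
Substitutions never enter profiles.

## Synthetic cohorts

The generator models mosaicism as a small founder-allele pool per animal
and amplicon (default K = 4 founders, Dirichlet(1) frequencies),
reflecting that editing at early cleavage stages creates few distinct
alleles. Per animal and target, an editing rate θ is drawn from
Beta(5, 2) (broad, high-mean mutagenesis as observed in injected
cohorts; a fixed rate can be configured); each founder is edited at each
target independently with probability θ. An edited site receives either
the target's recurrent locus-specific deletion — fixed size (default
6 nt) straddling the cut, chosen with a per-animal weight drawn as
0.78·Beta(0.7, 1.3), reproducing a recurrent deletion that averages
roughly a quarter of mutations but ranges from 0 to ~78% between
animals — or a random indel: deletion with probability 0.8, sizes from
truncated geometric distributions (deletions p = 0.25 on 1..30,
insertions p = 0.7 on 1..10, mode 1), deletions placed uniformly across
the cut, insertions anchored at the cut with uniform ACGT bases. Reads
sample a founder by frequency and receive i.i.d. substitution errors
(default 2×10⁻³ per base, never indels), emulating the dominant
Illumina/PCR error mode; qualities are constant Q40.

Exact expected fractions are computed by classifying each error-free
allele sequence with the production classifier and weighting by allele
frequency, and exact P(M)/P(F) follow from the closed forms — the truth
tables are therefore a recovery oracle for the entire pipeline. Given
the same configuration and seed, pools, truth tables and FASTQ files are
byte-identical (gzip members are written with a fixed mtime).

Features of real data the generator does not emulate — and which passing
recovery tests therefore do not certify: PCR duplicates and chimeric
reads, read-quality structure, paired-end merging artefacts, and single
large deletions spanning two sgRNA windows (founders receive independent
edits per target, so double-window events arise only from two separate
indels).

## Phenotype metric

The microcephaly index of an animal is its head-diameter to body-length
ratio divided by the mean ratio of the designated control group; the
control group has mean index 1 by construction and the index is
invariant to uniform magnification. Only the index and descriptive group
medians are computed here; hypothesis testing is left to standard tools.

## Problem sizes and numerical choices

The recovery acceptance tests run a 96-animal cohort at 10,000
error-free reads per animal and amplicon (per-animal `q` recovered
within ±0.02, about a 4σ binomial bound; cohort-median pooled P(M)
within ±0.05), and a 400-animal, 8-founder cohort for the
deletion/insertion split (±0.02 around the generator's 0.8 at >5,000
events). Read collapsing makes these cohorts cheap: the whole suite runs
in well under a minute. Fraction conservation is asserted to 1e−9;
probability-domain checks use a 1e−9 tolerance for rounding at the
boundaries. The classification rules are cross-checked exhaustively
against an independent per-position oracle on a 60-nt amplicon for all
single events and all compatible pairs of small indels.

## Known limitations

* Paired-end merging, UMI handling and quality filtering beyond an
  optional mean-Q threshold are out of scope; inputs are assumed to be
  amplicon-spanning single (or pre-merged) reads.
* The model ignores PCR amplification bias: read fractions stand in for
  allele fractions.
* Cohort medians of recomputed published per-animal tables can only be
  verified when those tables are supplied locally (see
  `tests/test_acceptance.py`); the raw reads behind them have no public
  accession.
* Microhomology out-of-frame scoring is intentionally not implemented;
  it is an external predictor whose lack of correlation with observed
  frameshift rates motivates direct measurement, which is this package's
  job.
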