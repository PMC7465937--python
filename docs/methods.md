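# Methods

## Motif model

HP1 chromoshadow-domain (CSD) dimers bind short linear motifs across their
dimer interface. The canonical motif is the pentapeptide P-x-V-x-L; the
degenerate variants L-x-V-x-L and C-x-V-x-L keep the conserved V (pattern
position 3) and L (position 5) anchors and substitute the first anchor.
The scanner tests every length-5 window of a sequence against each
requested class: anchor positions match only the literal residue, and the
wildcard positions x match any of the 20 standard amino acids but **not**
the ambiguity codes X/B/Z/U — counting unknown residues as matches would
inflate hit rates, and even B (D-or-N) is never allowed to satisfy an
anchor. All matches are reported, including overlapping windows and
multiple motifs per protein; the three classes have distinct position-1
anchors, so no window can match two classes and no tie-break is needed.
The −1/+1 flanking residues are recorded with each hit because they are
candidate modifiers of CSD-binding affinity.

Cohort summaries count a protein once regardless of hit multiplicity and
report `round(100 · n_with_motif / n_total)` with ties away from zero,
the convention under which 9/13 prints as 69% and 30/86 as 35%.

## Co-localization and its null

A query peak "co-localizes" with a reference set when it shares at least
one base pair with any reference peak; coordinates are 0-based half-open
throughout, so touching endpoints do not overlap. This is the weakest
standard overlap criterion; the statistic counts each query peak once.
The direction of the comparison (which set is the query) is an explicit
choice — the percentage of A peaks on B generally differs from the
percentage of B peaks on A.

The null holds the query fixed and re-places every reference peak
uniformly at random on its own chromosome, keeping its length (new start
uniform on `[0, chrom_len − length]`, placements independent, overlaps
among randomized peaks allowed). Keeping chromosome assignment preserves
chromosome-level peak density. No assembly-gap or blacklist masking is
applied; users of real genomes can pre-filter their inputs, which keeps
the null exactly as stated and exactly testable.

With `b` the number of null draws at least as extreme as the observation,
the empirical p is `(1 + b)/(n_perm + 1)` — never exactly zero. The
default alternative is two-sided (extremeness is distance from the null
mean), since both enrichment and depletion are scientifically meaningful;
`greater`/`less` are available. The z-score standardizes the observed
count by the null mean and the sample (ddof = 1) standard deviation; when
the null is degenerate (sd = 0) the z-score is reported as undefined while
the p-value is still computed from counts. Defaults: `n_perm = 1000`,
seed mandatory in all reports.

## Border calling

The heterochromatin/euchromatin "epigenomic border" of a chromosome arm is
called from peak summit heights (arbitrary units; the source tracks are
log2 enrichment, treated as opaque):

1. The **global median** of peak heights is taken over the whole set
   (even counts: mean of the two central values).
2. Summits are binned every `bin_size` (default 0.5 Mb) from an origin —
   the centromeric end of the arm, a user input since centromere
   coordinates are assembly-specific — toward the telomere. Bins are
   half-open on the scan axis: a summit exactly on a boundary belongs to
   the higher-index bin; in the decreasing direction this mirrors to the
   origin-distal side. Peaks without explicit summits (BED input) use the
   interval midpoint. Empty bins get median 0: a stretch with no peaks
   cannot be heterochromatic under this statistic.
3. Scanning bins in order from the origin, the border is the first bin
   whose median is **strictly below** the global median (a bin exactly at
   the median does not trigger). No smoothing is applied by default; a
   `min_run` parameter can require several consecutive below-median bins.

The reported coordinate is the origin-proximal boundary of the triggering
bin — the last coordinate known to be heterochromatin-adjacent — with
`report ∈ {start, end, midpoint}` available; borders are also printed in
Mb at one decimal. A consensus over several tracks agrees when every
track calls a border and the positions span at most a tolerance (default
one bin); the consensus coordinate is their median.

## Synthetic data

The generators emulate the statistical structure of the study inputs, not
their biology:

* **Proteomes** — background residues uniform over the 20 standard amino
  acids (default length Poisson with mean 500, floor 20); planted motifs
  have fixed anchors and uniform wildcards. Any window that incidentally
  matches a motif class is rejection-resampled (only non-anchor positions
  are redrawn, so planted motifs survive), making the planted set the
  *exact* ground truth and scanner tests equality assertions. If a
  planted motif would not fit the drawn length, the protein is extended to
  fit rather than erroring on a random draw. Real proteomes have biased
  composition and homology structure; passing these tests shows scanner
  correctness, not anything about real motif prevalence.
* **Peak pairs** — reference peaks uniform (chromosomes weighted by
  length; lengths Poisson, default mean 300 bp); `round(f · n_query)`
  query peaks are forced to intersect a reference peak by ≥ 1 bp and the
  rest are rejection-placed to intersect none, so the observed overlap
  count is exact by construction (defaults n_query = n_ref = 200,
  f = 0.4). With `overlap_frac=None` the query is placed independently —
  the null configuration used for type-I calibration. Real peak sets
  have non-uniform placement (mappability, chromatin state), which the
  null deliberately ignores.
* **Landscapes** — Poisson peak counts per 0.5-Mb bin (default mean 20),
  summits uniform within the bin, heights normal with mean 3.0 a.u.
  before the planted border and 0.4 a.u. after (sd 0.3, truncated at a
  0.05 floor), matching the high/low levels of the motivating decay
  pattern. Peaks are emitted as ±100 bp intervals around their summit.

All generators consume a single explicit numpy RNG stream per call and
are byte-reproducible under a fixed seed; a TruthRecord with the planted
parameters is serialized next to each dataset.

## Numerical and design choices

* In a **noiseless** step landscape the height distribution has two atoms,
  so the global median equals whichever block holds the majority of
  peaks; exact-recovery demonstrations therefore place the border past
  the arm midpoint (heterochromatic majority). With noise and a border
  near the midpoint the global median falls between the blocks and
  recovery is within one bin essentially always.
* Type-I calibration uses 200 null pairs of 100 + 100 peaks (mean length
  400 bp) on a 2 × 200 kb genome with 500 permutations each, sized so the
  null overlap count has a rich discrete support (mean ≈ 20) and the
  empirical p is close to uniform; the one-sided (`greater`) p is used
  for the calibration check because the two-sided p on a discrete
  statistic is more conservative.
* The exhaustive oracle for the permutation null enumerates every
  reference placement on a ≤ 1 kb chromosome; the Monte-Carlo mean is
  required to sit within three standard errors.
* Peak files on chromosomes missing from the chrom.sizes table raise
  errors rather than dropping silently, because silent drops bias the
  randomization null.

## Limitations

* The permutation null does not model mappability, blacklist regions or
  clustering of real peaks; p-values on real data inherit those caveats.
* The border caller assumes a single heterochromatin→euchromatin
  transition per scan; interspersed domains need a changepoint/HMM
  approach, which is out of scope.
* Motif scanning is pattern matching only — no position-weight scoring,
  no structural validation of CSD binding, and no variants beyond the
  three named classes.
* Cohort membership (which proteins constitute a "direct binder" set) is
  a user input; the package computes the summary, not the curation.
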