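# Methods

## Model and assumptions

Integrations of one vector on one analysis unit — a (chromosome arm,
strand) pair — are treated as an i.i.d. sample from an unknown density on
that unit. Arms are analysed separately because the centromere is a giant
blind region; strands separately because restriction-digest blind regions
are strand specific. Independence between integrations is assumed; clonal
expansion or shared-fragment artefacts upstream of the site list would
violate it and are not modelled.

Comparing two vectors is cast as comparing two unknown densities on the
same domain from two independent samples of possibly different size. The
method is deliberately two-stage: data-adaptive *candidate* segments from
band disjointness, then a familywise-error-controlled exact test per
candidate. The second stage is not independent of the first (candidates
are selected where the samples already differ), so raw Fisher p-values at
the candidate stage are anti-conservative; this is mitigated, not removed,
by the strict 0.99 band level and the joint Holm family, and the residual
effect is visible in the pipeline's own null studies (a few percent of
label-shuffled replicates confirm one short spurious hotspot).

## Blind regions and the collapsed coordinate

A position is detectable only if its distance to the flanking restriction
site lies in `[min_read, max_frag)` — below `min_read` (20 bp) the
junction read is unalignably short, at or above `max_frag` (500 bp) the
fragment is removed by size selection. Within each gap between
consecutive motif starts `(p, q)` the blind set is
`[p, min(p+min_read, q)) ∪ [min(p+max_frag, q), q)` on the + strand and
its mirror image on the − strand (the half-open boundary mirrors with the
rule). Design choices where the protocol description is silent:

* the spans of a unit before the first and after the last restriction
  site are fully blind on both strands (no complete flanked fragment
  exists there) — the conservative reading;
* the motif footprint itself is inside the first blind piece by
  construction;
* runs of N of ≥ 1,000 bp (assembly gaps) are added to the blind set: N
  cannot contain a motif and long N runs are unmappable, and leaving them
  "detectable" would create artificial density valleys;
* gaps shorter than `min_read` are entirely blind; rule intervals are
  clipped to their gap;
* TTAA is its own reverse complement, so one scan serves both strands; a
  flag scans both orientations for non-palindromic enzymes.

Collapsing deletes blind intervals and concatenates detectable segments;
the map is stored as segment offset arrays giving O(log k)
collapse/expand. Expansion of a candidate interval re-inserts any blind
stretches interior to it, so genomic length ≥ collapsed length.

Coordinates are 0-based half-open (BED) everywhere.

## Density estimation and variability bands

The Gaussian-kernel estimator is evaluated on 2¹⁴ equally spaced grid
points per unit by default (≈ 15 kb resolution on the largest human arm,
much finer than any reported hotspot; large simulation studies in the
test-suite use 2¹¹–2¹² points, still ≥ 40 grid cells per planted signal).
Between grid points the estimate is a natural cubic spline clipped at
zero; band edges at off-grid points are recomputed from the interpolated
density, not interpolated separately, which preserves the ordering
lower ≤ f̂ ≤ upper. No boundary correction is applied at unit edges. The
discreteness of the base-pair domain is ignored (the grid spacing already
exceeds 1 bp by orders of magnitude).

The variability band uses the variance-stabilising square-root transform:
on the √f̂ scale the asymptotic variance R(K)/(4nh) does not involve the
unknown density, so a constant half width
`w = z_{(1+α)/2} √(R(K)/(4nh))` applies across the unit; edges are
back-transformed and the lower edge clipped at zero. The band accounts
for variance only — smoothing bias (which flattens modes and fills
valleys) is ignored, so there is no nominal coverage probability. The
test-suite measures empirical pointwise coverage ≥ 90% at a low-curvature
point under cross-validated bandwidths.

## Bandwidth selection

`h` is chosen per vector by unbiased cross-validation: minimise
`UCV(h) = ∫f̂² − (2/n) Σᵢ f̂₋ᵢ(xᵢ)`, whose two terms have closed forms in
the pairwise distances for the Gaussian kernel. Numerical scheme (an open
choice, disclosed here): a log-spaced grid of 200 evaluations over
`[2 × median nearest-neighbour spacing, L/4]` followed by bounded
golden-section refinement around the grid minimum; a numerically flat
objective (spread < 1e-12) falls back to Silverman's rule with a warning.
For n > 600 the pair sums are evaluated on an FFT autocorrelation of
positions binned at 2¹⁷ resolution (bin width ≪ any admissible h); the
exact closed form remains the definition and the small-n path, and the
two agree to ~1e-4 relative in the tests. Replicated simulation studies
pass a coarser 32–64-point search grid; the refinement step keeps the
located minimum within a few percent of the exhaustive one.

## Detection, sensitivity, confirmation

Candidates are maximal runs of grid points with strictly disjoint bands;
endpoints stay at grid resolution (reported hotspots are ≥ 200 kb, the
grid spacing far below that), single-point runs are kept, and no minimum
length is imposed — the exact-test stage prunes weak candidates. + and −
strand candidates are never merged. Ids are the winner label plus
discovery order (`hiv_3`). The sensitivity scan multiplies both vectors'
cross-validated bandwidths by the same factor s (admissible range
[0.05, 20]); the s = 1 entry is by construction the main output.

Confirmation counts the winner's and loser's sites inside the genomic
hotspot on its strand; the outside count is the vector's genome-wide
total minus the inside count — a single genome-wide propensity per
vector, keeping table margins constant across candidates (whether
"outside" should instead be per-strand is undecidable from the protocol
description; this choice is recorded here). The odds ratio is oriented
≥ 1 (∞ when the loser has no inside sites). p-values come from the
two-sided Fisher exact test; the 95% CI is conditional-exact when any
cell ≤ 5 and logit-Wald with Haldane–Anscombe 0.5 correction otherwise,
and is reporting-only. All candidates of one genome-wide run form a
single Holm family; ties in p are broken by stable sort then candidate
id.

## Annotation

Gene counting is strand-agnostic (≥ 1 bp overlap counts once); site
counting is strand-aware. Expression enrichment uses genes outside *all*
confirmed hotspots as the background (not just outside the hotspot under
test); gene-free hotspots are reported as NA and excluded from the Holm
family. Group comparisons of per-hotspot track densities use the Welch t
statistic by default (it does not assume equal variances) and
Mann–Whitney for hotspot lengths; either is selectable. Permutation
p-values are `(1 + #{|T*| ≥ |T|})/(n_perm + 1)` under label shuffling
(default n_perm = 100,000, seed recorded in output metadata), or the
exact proportion when all label partitions are enumerable
(`C(n, n₁) ≤ n_perm`). A size-1 group demotes Welch to Mann–Whitney with
a warning.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
sequence realism. The genome is ACG filler (motif-free by construction)
with TTAA motifs at `4 + Geometric` gaps; the default mean gap of 350 bp
yields ~29–30% blind under the 20/500 bp rule, matching the regime of
real single-enzyme libraries. Sites are drawn by inverse-CDF sampling on
a fine collapsed-coordinate grid from a mixture of a uniform background
over detectable positions plus Gaussian-shaped bumps (FWHM = declared
width); the bump amplitude is solved numerically so that the in-window
integration odds of the bumped vector versus a uniform one equals the
declared odds ratio, and the half-maximum window is emitted as truth.
The default scenario mirrors the real study's scale: one 1e8 bp arm,
~1,500 sites per vector per strand, three planted bumps of odds ratio 8
spanning 2% of the arm. All randomness flows from one recorded seed.

What passing tests on these data do *not* show: robustness to
non-independent sites (clonal amplification), to mappability artefacts,
to non-Gaussian-shaped true signal, or to density features sharper than
the grid; the uniform background is also far smoother than real genomic
covariates such as gene density.

## Numerical conventions and degenerate inputs

Units where either vector has fewer than 10 sites are skipped with a
warning (bands there overlap for lack of data, not equality of
densities). Fully blind units are flagged degenerate and skipped. An
empty site file produces empty outputs and exit code 0. Output tables
carry version, config hash (analysis parameters only, so identical
settings are byte-comparable across directories) and seed; no timestamps
are written, making re-runs byte-identical.

## Known limitations

* Candidate selection and testing use the same data (see above); the
  confirmed list is a ranked shortlist for validation, not a set of
  calibrated discoveries.
* The variability band's bias blindness can hide a true difference where
  both densities curve strongly in the same direction.
* Single-enzyme blind-region modelling only; multi-enzyme digestion
  unions are out of scope, as is genome mappability (which cancels in a
  two-vector comparison restricted to uniquely mapped reads).
* Holm across candidates controls FWER given the candidate list; no
  spatial correlation between neighbouring candidates is modelled.
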