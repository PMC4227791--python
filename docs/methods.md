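# Methods

This note documents the models, statistics and numerical choices behind
`gcckit`, and what the synthetic data do and do not establish about real
genome conformation capture (GCC) experiments.

## Interaction networks

A GCC experiment reduces to a weighted graph: nodes are restriction
fragments (AseI, AT^TAAT, cut offset 2 on the forward strand), edges carry
the number of times a fragment pair was captured.  All coordinates are
0-based half-open; fragments tile each chromosome, which gives O(log n)
position lookups and makes linear adjacency well defined (rank difference
of 1 within a chromosome).  Analyses run on networks filtered to
significant (frequency at or above the FDR cut-off), uniquely positioned
(an input flag per fragment — mappability is not re-derived here) and
non-adjacent interactions.  Pairs whose two reads fall in the same
fragment are self-ligations, not interactions, and are dropped with a
count kept.

### FDR cut-off

The cut-off is the smallest integer frequency f at which

    E[# pairs with frequency >= f under a ligation-noise model]
    -----------------------------------------------------------  <= target FDR
            # observed pairs with frequency >= f

The noise model is an endpoint permutation: the multiset of fragment
endpoints of all captured events is randomly re-paired (default 100
permutations), which preserves per-fragment coverage while destroying
pair identity.  The empirical tail is Poisson-smoothed beyond the largest
frequency any permutation produced, using the mean per-pair event rate.
This is a design choice — the statistical method this replaces is not
restated in the sources available to us — and is validated only through
its own calibration behaviour: the cut-off is non-decreasing as the
target FDR tightens, a noise-free background gives cut-off 1, and a
constructed network with noise at frequency <= 2 and signal at >= 5
returns a cut-off between the bands.  One practical property worth
knowing: because the null preserves coverage, concentrated signal (a few
fragments absorbing a large share of events) inflates the null tail and
pushes the cut-off up.  At desk scale the cut-off therefore depends
strongly on the ratio of sequencing depth to the size of the fragment-pair
space.

### Collector's curve and random networks

The rarefaction (collector's) curve expands a network into an event list,
adds one artificial interaction at exactly the cut-off frequency, samples
increasing fractions of events without replacement, and reports the mean
percentage of the full network's significant interactions sampled
*strictly more often* than the artificial one (ties are not significant).
The random-network comparison pools the events of all three phase
networks, redraws per-phase networks of the original event counts (with
or without replacement), applies the real cut-off, and compares the
observed seven-region Venn counts with the replicate means by chi-square;
cells with expectation below 1 are pooled before the test and df is the
remaining cell count minus 1.

### Loop lengths

For an intrachromosomal pair ordered so that F1 precedes F2 along the
chromosome, the loop length is L = |F2_start − F1_end|; adjacent
fragments (if not filtered) give L = 0.  Histograms use half-open bins of
100 bp or 10 kb.

## Colocalization testing

The colocalization frequency of a locus set is the number of filtered
interactions whose two fragments each overlap (>= 1 bp) a locus of the
set, excluding interactions whose two fragments overlap only one and the
same locus — a region folding onto itself is not colocalization of two
regions.  Two empirical nulls are built from 1000 random locus sets
matched in number and lengths: conserved random (CR) keeps each locus on
its own chromosome; random (R) redraws the chromosome proportional to
chromosome length among chromosomes that can host the locus (a locus as
long as a chromosome is allowed, with a single admissible start).
Empirical p-values use the add-one form p = (1 + #{null >= obs}) /
(n + 1), which cannot reach zero under finite resampling; random sets are
drawn once per test and reused for both tails.  A verdict is
significant-high (or -low) only when both CR and R agree at the per-test
level (default 5%); an observed frequency of zero is "not detected".  The
result also reports the inter/intra split of the colocalizing
interactions and, within intra, the fraction spanning more than 50 kb
(configurable).  For a family of tests the expected FDR is reconstructed
as n_tests × alpha / n_significant with not-detected tests excluded — the
simplest estimate consistent with a per-test alpha, and a reconstruction
rather than a quoted procedure.

## Transcript sets

Genes with no detectable transcript (level 0) are removed per phase
before quantiles.  High/low sets take the top and bottom 5% with
inclusive boundaries (ties enter the set; a degenerate all-equal table
returns everything, with a warning).  Differential sets across the
transitions G1→G2, G2→M, M→G1 use ratio = (to + pc)/(from + pc) with a
pseudocount pc = 0.1 FPKM to keep zeros finite; up at ratio >= fold
(default 2), down at <= 1/fold, so up(A→B) equals down(B→A) exactly.
Note the pseudocount makes an exactly 2-fold change fall marginally below
threshold; pass pc = 0 when exact boundary behaviour matters.  Linear
distribution uses gene central positions floor-assigned into 50-kb
half-open bins, and a one-sample Kolmogorov–Smirnov test against
Uniform(0, chromosome length); chromosomes with fewer than three set
members are flagged not-tested.

## Coarse-grained polymer models

Chromosomes are chains of spherical granules (default 10 kb per granule)
inside a spherical nucleus; the spindle pole body (SPB) sits at the −z
pole of the envelope and the nucleolus, a sphere of radius R/3, at the +z
pole, diametrically opposite.  Defaults for the full-scale geometry are
R = 1330 nm with 30 nm granules (G1) and R = 1710 nm with 60 nm granules
(G2) — radii read off the density-map grids (266 and 342 pixels at
10 nm), the only printed geometry anchor; the larger G2 granule stands in
for the replicated fiber.

Three nested regimes: *confined* (hard constraints only), *constrained*
(adds tethers: all centromeres to the SPB; telomeres of the first two
chromosomes to envelope points 55° off the nucleolar pole; the
rDNA-flanking ends of the third chromosome to the nucleolar surface — the
Rabl configuration), and *interactions* (adds attractive restraints from
a 10% frequency-weighted sample of the captured interactions, resampled
per structure by default).

Energies (units of kT, Metropolis at kT = 1):

* harmonic bonds k_b (d − d0)² with d0 one granule diameter and
  k_b = 10/d0²;
* hard terms by move rejection: containment (center within R − r_g),
  nucleolar exclusion, bond-length band [0.5, 1.5] d0, excluded volume
  0.8 d0 between non-bonded granules;
* flat-bottom tethers k_t max(0, |x − anchor| − tol)², default
  k_t = 1 kT/(100 nm)², tol = 200 nm;
* flat-bottom pair restraints k_i max(0, d − d_c)² with d_c two granule
  diameters.

Moves are single-granule Gaussian displacements (σ = 0.5 d0; acceptance
around 20% in the default systems).  The initial configuration is a
guided self-avoiding walk: each chain is grown at bond length d0 with
steps biased toward guide points interpolated through its tether anchors,
so tethered chains start near their Rabl arrangement and the Monte Carlo
performs local relaxation; the default 5000 sweeps (a sweep is n
attempted moves) is ample for that relaxation, and the test systems use
400–2000 sweeps.  On a free 3-granule chain the sampled bond-length
distribution matches the closed-form Boltzmann density
d² exp(−k_b(d − d0)²) on the allowed band (KS check), a direct
detailed-balance diagnostic of the kernel.

**Scaling to small genomes.**  The real fission-yeast geometry pairs a
~38 µm chromatin contour with a 1330 nm radius (ratio ≈ 30).  A 1.2 Mb
synthetic genome at the same granule size cannot span a full-scale
nucleus — no Rabl arrangement would be geometrically possible — so
`ModelSpec.for_genome` scales the nuclear radius to preserve the
contour-to-radius ratio and stiffens tethers so thermal excursions stay a
fixed fraction of the nucleus.  Test ensembles use 300 granules
(4 kb/granule, R = 300 nm, 50 structures) for constraint and
pair-distance contracts, and 500 granules (2.4 kb/granule, R = 500 nm,
20 structures per model) for the DDF model contrast, where the
three-diameter start distance must stay small relative to the nucleus;
these sizes are the package's choice of a desk-scale system that
preserves the full-scale geometry's proportions.

## Spatial statistics

### Density distribution function (DDF)

For a granule subset, DDF(R, R+dR) = (n(R,R+dR)/v(R,R+dR)) / (N/V):
ordered pair counts per distance shell over the summed per-center shell
volumes, normalized by the overall subset density.  Where a shell spills
over the nuclear border, the volume is the exact analytic sphere–sphere
lens intersection of the shell with the nucleus — without this correction
the pair-density ratio of even a uniform point set decays well below 1 at
large R.  Uniform points give DDF = 1 (to (N−1)/N); the acceptance anchor
measures 0.999 at N = 1000.  Shell width defaults to one granule
diameter; curves run to the nuclear diameter, and shells with no
available volume are NaN.  The comparison statistic is the signed area
between each structure's DDF and 1, accumulated from three granule
diameters outward (90 nm G1, 180 nm G2 at full scale) to exclude
short-range linear clustering, compared across ensembles by a two-tailed
unpaired t-test.  Signed (not absolute) area is the default because
clustering manifests as DDF > 1; absolute area is available.

### Rotationally symmetric density maps

Because tethers and restraints are invariant to rotation about the
SPB–nucleolus axis, structures project losslessly onto (z, r): z the
scalar projection onto the SPB→nucleolus unit axis (origin at the nuclear
center, SPB at −R), r the distance to the axis.  Granules spread onto a
square grid (Δz = Δr = 10 nm; 266² pixels for G1, 342² for G2 at full
scale) with kernel

    Frequency(z_p, r_p) = (1/N_structures) Σ_structures Σ_granules
                          1/(2πσ²) exp(−((z_p−z_g)² + (r_p−r_g)²)/(2σ))

with σ the granule radius (15 nm G1, 45 nm G2).  The exponent denominator
2σ follows the printed definition this package reproduces even though the
prefactor is the standard 2D Gaussian normalizer — the kernel then
integrates to 1/σ per granule rather than 1; `exponent="gaussian"`
switches to the conventional 2σ² form, and the peak value 1/(2πσ²) of a
granule on a pixel coordinate is identical under both.  The kernel is
truncated at 4σ (truncated mass is negligible under either convention).
Density divides Frequency by the cylindrical-ring volume
πΔz((r_p+Δr)² − r_p²); Relative Density divides the element density by
the total chromatin density plus Dempf, the peak density of a single
granule placed at (z = 0, r = R) — a small regularizer that keeps ratios
stable where absolute density is low near the envelope.  Pixels where
both densities vanish report 0.  An interactions-control map uses a
random granule subset of the same size as the element set.

A note on the G2 constants: the DDF start distance of 180 nm corresponds
to three 60 nm granules, while the map σ of 45 nm is described as the
granule radius (implying 90 nm); both constants are honored verbatim in
their own operations and the tension is left visible here rather than
silently reconciled.

## Synthetic data: what it emulates and what it does not

The generator draws a three-chromosome genome (500/400/300 kb) with
restriction sites at Poisson positions (density 1/2000 bp, ~625
fragments; accidental site occurrences in the random sequence are
scrubbed so the restriction map is exactly the planted one), annotations
(telomeric 20-kb windows, mid-chromosome centromeres, rDNA-flanking
windows inside the third chromosome's ends, LTR-like elements with half
placed on the third chromosome, two repeat tracks that clear the
fragment-uniqueness flag, 400 genes), per-phase networks, and expression
tables.  All generators are pure functions of (spec, seed) through named
RNG substreams.

Networks are one multinomial draw of 30 000 captured pairs over all
fragment pairs, weighted (L + 20 kb)^−1 within chromosomes and constant
between, calibrated so 85% of the expected mass is intrachromosomal;
pairs whose two fragments overlap a planted locus set active in the phase
have their weight multiplied by the planted effect (default: LTR and
telomere sets, multiplier 20, all phases).  Expression is log-normal
(log-sd 0.8, clipped at 3 sd) with planted top/bottom genes far outside
the bulk, planted 2.5-fold transitions arranged cyclically, and per-phase
log-noise of 0.04 clipped at 2.5 sd — chosen so planted extreme and
differential sets are recovered *exactly* by construction, making
recovery tests sharp rather than probabilistic.

What passing tests show: the statistics are calibrated (type-I error at
alpha, uniform null p-values, DDF of 1 for uniform arrangements), the
bookkeeping is exact (brute-force oracles), and planted effects of
realistic direction are recovered with high power.  What they do not
show: real GCC data have mappability artifacts, coverage biases,
replicate structure and ligation chemistry that the single-multinomial
background does not model; the desk-scale pair space makes the FDR
cut-off and the inter/intra composition of the significant network scale
differently than in the real data (in particular, interchromosomal pairs
rarely clear the cut-off at this depth, so synthetic LTR colocalization
is intra-dominated, unlike the interchromosomally dominated real
finding).  Headline counts from the real sequencing data are therefore
not reproduced here and are not targets of the test suite.

## Pipeline

`gcckit pipeline` chains the stages on synthetic data with a single
master seed and writes per-stage text outputs plus `summary.json`;
stages are cached by a hash of their parameters so unchanged reruns
resume.  Reduced defaults (depth, 200 colocalization nulls, 6 polymer
structures at 20 kb/granule, 400 sweeps) keep the end-to-end run around a
minute; every knob is a YAML override.
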