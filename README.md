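# gcckit

Genome conformation capture (GCC) network analysis for the fission-yeast
cell cycle: significance-filtered chromosome interaction networks,
permutation tests for spatial colocalization of locus sets,
transcript-defined gene sets, coarse-grained Monte Carlo models of
chromosomes in the nucleus, and the spatial statistics (density
distribution function, rotationally symmetric density maps) that connect
the networks to nuclear architecture.

The package is written for computational biologists studying 3D genome
organization in *Schizosaccharomyces pombe* (or similar small genomes)
across synchronized G1, G2 and M populations.  It ships a first-class
synthetic-data module, so every stage runs and is tested end-to-end
without any external download.

## The statistics at the core

**Interaction networks.**  An AseI digest turns the genome into fragments
that tile each chromosome; captured ligation events become a weighted
graph over unordered fragment pairs.  Analyses use significant
(frequency ≥ FDR cut-off), uniquely positioned, non-adjacent
interactions.  The cut-off is the smallest f with
E[#pairs ≥ f | noise] / #observed pairs ≥ f ≤ target FDR, where the noise
model randomly re-pairs the observed fragment endpoints.

**Colocalization.**  A locus set self-colocalizes when an interaction
joins two fragments that each overlap a locus of the set.  The observed
frequency is compared against 1000 conserved-random (CR: per-chromosome
counts preserved) and 1000 random (R: chromosome drawn ∝ length) locus
sets of identical lengths; p = (1 + #{null ≥ obs})/(n + 1), and a call is
significant only when CR and R agree.

**Polymer models.**  Chromosomes are granule chains (10 kb per granule by
default) confined to a spherical nucleus with a nucleolar exclusion,
simulated by Metropolis Monte Carlo at kT = 1 in three nested regimes:
confined, constrained (Rabl tethers: centromeres at the spindle pole
body, telomeres at the envelope, rDNA-flanking ends at the nucleolus) and
interactions (adds attractive restraints from a frequency-weighted 10%
sample of the captured interactions).

**Spatial statistics.**  The density distribution function
DDF(R,R+dR) = (n/v)/(N/V) with analytic border-corrected shell volumes is
1 for uniform arrangements and > 1 for clustering; ensembles are compared
by the signed area between the DDF and 1 from three granule diameters
outward (two-tailed unpaired t-test).  2D (z, r) density maps project
structures onto the SPB–nucleolus symmetry axis, spread granules with a
Gaussian kernel (σ = granule radius), divide by cylindrical-ring volumes
and normalize by total chromatin density plus the Dempf regularizer.

See `docs/methods.md` for assumptions, parameter defaults and known
limitations.

## Worked example

```python
import gcckit
from gcckit import core, synth, netstats, coloc

spec = gcckit.SyntheticSpec(seed=1)          # 3 chromosomes, 1.2 Mb
genome = synth.generate_genome(spec)
fragments = core.digest_genome(genome)        # AseI (AT^TAAT)
ann = synth.generate_annotations(spec, genome)
fragments = synth.mark_unique_fragments(fragments, ann["repeat"])
net = synth.generate_network(spec, fragments, ann, "G1")
print(len(fragments), len(net), net.total_frequency)

cutoff = netstats.fdr_cutoff(net, target_fdr=0.05, seed=0)
sig = core.filter_network(net, fragments, cutoff,
                          require_unique=True, drop_adjacent=True)
print(cutoff, len(sig))

res = coloc.coloc_test(ann["LTR"], sig, genome, fragments,
                       n_random=1000, seed=3)
print(res.verdict, res.observed, round(res.p_high_cr, 6),
      round(res.long_range_intra_fraction, 2))
```

prints

```
625 17144 30000
6 652
significant-high 299 0.000999 0.3
```

Reading: the 1.2 Mb synthetic genome digests into 625 fragments; 30 000
captured pairs form a network of 17 144 distinct interactions.  The
endpoint-permutation noise model puts the 5% FDR cut-off at frequency 6,
leaving 652 significant, uniquely positioned, non-adjacent interactions.
The LTR set colocalizes in 299 of them — more than every one of the 1000
CR and 1000 R random locus sets (p = 1/1001 by the add-one rule), so the
verdict is significant-high by both methods; 30% of the intrachromosomal
LTR colocalization spans more than 50 kb.

The same analysis runs end-to-end from the shell, including polymer
ensembles and density maps:

```sh
gcckit pipeline --seed 1 --out-dir out/      # writes summary.json + stage files
gcckit --help                                # individual subcommands
```

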