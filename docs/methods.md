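# Methods

This note documents the models behind each stage, the tunable
parameters and their defaults, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design
was genuinely open.

## Data model

The unit of analysis is the **phased haplotype**: an int8 matrix of
haplotypes × sites with alleles 0 (REF), 1 (ALT), −1 (missing). Each
diploid sample contributes exactly two rows; for fully homozygous
(inbred) material the two rows are identical, which is the normal case
for the selfing-crop data this package targets. Positions are 1-based
within the matrix (VCF convention); all interval arithmetic against
BED uses 0-based half-open coordinates. Sites are biallelic SNPs;
multiallelic records and indels are skipped on read with a counted
warning. Per-site population frequencies are complete-case (ALT count
over non-missing haplotypes).

## Synthetic data

The generator produces the statistical structure the inference
assumes, not a demographic simulation.

**Drift model.** Per site, an ancestral frequency p ~ Uniform(0.05,
0.95); each population draws its frequency from the Balding–Nichols
distribution Beta(p(1−F)/F, (1−p)(1−F)/F) and haplotype alleles are
Bernoulli draws from it. Sites monomorphic across the union of panels
are redrawn so every emitted site is biallelic. Default geometry is a
30 Mb pseudo-chromosome at 1 SNP/kb, which puts the 150-SNP painting
windows at ≈150 kb and matches the 100 kb statistic windows.

**Reference pools.** Three pools at F = 0.3 with 60 haplotypes each;
this yields pairwise Hudson Fst around 0.3–0.45, i.e. "strongly
diverged gene pools" on the scale seen between crop subspecies.

**Admixed targets.** Background-pool Bernoulli draws everywhere,
donor-pool draws inside planted tracts. Carrier status is decided per
diploid sample and both haplotypes carry the tract — introgression
blocks in a selfer are homozygous. The default tract is 3.8 Mb
(17.9–21.7 Mb) with carrier fraction 0.5 among 20 targets.

**Quartets.** P1/P2 drift F = 0.05 from a shared internal lineage
(itself F = 0.2 from the ancestral), P3 at F = 0.2, and the outgroup
P4 at F = 0.5 from the same ancestral frequencies — deep enough that
the (1−p4) weights stay informative without a full species tree. Gene
flow is laid down as contiguous blocks of 250 SNPs covering exactly
the requested fraction of sites, with P2 haplotypes drawn from P3's
population frequency inside blocks; contiguity makes the jackknife
blocks non-trivial.

**Sweeps.** Founder-copy model: the site nearest the focal position
must be biallelic; a fraction q of haplotypes take the ALT allele
there and copy one founder haplotype outward for Exponential(mean λ)
bp on each side before reverting to their own alleles. Non-carriers
take REF at the focal site so the swept-allele frequency is q up to
rounding. Defaults: q = 0.5, λ = 150 kb, one population of 200
haplotypes on 5 Mb with a denser 500 kb / 1,000-SNP centre.

**What is not emulated.** Background linkage disequilibrium (sites are
independent outside tracts and sweeps), recombination-map structure,
mutation-rate variation, missing data and genotyping error. Passing
tests therefore demonstrate that the statistics behave correctly under
their own assumptions; they say nothing about robustness to LD-driven
false positives in real data, which is the main caveat for the iHS
scan in particular.

## Chromosome painting

Per chromosome, 150-SNP windows advance by 75 SNPs; a trailing short
window is appended when SNPs would otherwise stay unpainted and at
least 75 SNPs are available for it. Within a window, PCA is fitted on
reference **and** target haplotypes jointly (mean-imputed missing
calls, mean-centred sites, full SVD, deterministic sign convention).
One Gaussian product-kernel density per reference group is fitted on
the first 5 components with per-dimension Scott bandwidths
σ̂·m^(−1/(d+4)), floored at 1e−3 so zero-variance dimensions remain
evaluable. Posteriors are equal-prior normalised densities computed in
log space.

Label rules (configurable in `PaintingConfig`): single label at
posterior ≥ 0.8; the top-two pair when their sum is ≥ 0.8 with each
≥ 0.1; otherwise `unspecific`; `absent` when the window has fewer than
n_pcs+1 polymorphic sites, a group has fewer than 5 haplotypes, or
more than half of a group's calls are missing. These thresholds
reproduce the five-way colour semantics of painted ideograms (pure,
shared, unspecific, absent) and were fixed once, before any recovery
experiment, as round numbers; they are deliberately exposed rather
than tuned.

Overlapping windows are reconciled per 75-SNP slice by keeping the
covering window whose top posterior is larger (ties go to the earlier
window); runs of equal slice labels merge into tracts. Reference
selection from an external ancestry-proportion table uses an inclusive
≥ 0.8 cutoff; cutoffs ≤ 0.5 are rejected because they would allow a
sample to qualify for two clusters.

Measured on the default scenario, per-slice accuracy is ≈0.999 and
planted-tract boundary errors stay within one window step per side.

## ABBA-BABA

Frequency-weighted site patterns (population samples, not single
genomes); the outgroup enters through (1−p4) weights rather than
strict polarisation, so sites polymorphic in P4 are down-weighted
naturally. The jackknife partitions usable sites into contiguous
blocks of equal SNP count (default 379); SE is the standard delete-one
estimate and Z = D/SE with |Z| > 3 as the significance convention. A
zero ABBA+BABA denominator yields an undefined (NaN) D, never 0.

**f̂.** S(P1,P2,P3,P4)/S(P1,P3,P3,P4) with the donor in both
denominator slots. The p3·p3 product uses the unbiased estimator of
the squared frequency, p̂² − p̂(1−p̂)/(n−1): the naive product
overstates the denominator by Var(p̂3), which at 30 haplotypes
depresses f̂ by ≈10% (complete replacement of P2 by donor draws then
recovers f̂ ≈ 1.0 instead of ≈0.88). Recovery at f_true = 0.2 is
unbiased to within 0.01 over seeds.

**fd / fdM.** Windowed; fd substitutes pD = max(p2,p3) into the P2 and
P3 slots of the denominator and is reported only where window D ≥ 0.
fdM extends fd symmetrically (pD = max(p1,p3) into P1/P3 slots, sign
flipped) so positive values mean P3→P2 and negative P3→P1. Windows
with fewer than 20 usable sites are flagged.

## Windowed diversity

π per site uses the unbiased haplotype estimator [n/(n−1)]·2p̂(1−p̂);
Dxy uses p̂A(1−p̂B)+p̂B(1−p̂A); both are divided by the **window bp
span**, treating unobserved positions as monomorphic — the input is a
SNP-only VCF, so these are diversities per bp of span, comparable
across windows but not to sequence-based estimates with explicit
invariant-site counts. Window Fst is Hudson's 1 − π̄w/Dxy as a ratio of
window sums, floored at 0 with a flag; Dxy = 0 gives NaN. Tajima's D
follows the standard 1989 constants with n = haplotype count; S = 0 is
undefined, not 0. Windows are 100 kb advancing by 50 kb, anchored at
bp 1 by default (an `anchor="data"` option starts the grid at the
first SNP, making statistics invariant to a constant position shift);
windows with fewer than 10 SNPs are flagged excluded but kept in the
output. "Fewer than ten" is read strictly: a 10-SNP window is
computed.

The global matrix uses the Weir–Cockerham ANOVA estimator on haploid
(haplotype) data as a ratio of sums over sites, with negative totals
floored at 0 — the estimator's small negative bias terms otherwise
report ≈−1/n for literally identical populations.

## EHH / iHS

EHH(x) = Σ_h C(count_h,2)/C(n_core,2) over distinct extended
haplotypes, computed outward SNP by SNP from the focal site; the curve
keeps points while EHH ≥ 0.05 (`ehh_min`) and records whether each
flank was truncated by decay or ran into the chromosome end. iHH is
the trapezoidal integral over physical bp of both flanks. Sites need
MAF ≥ 0.05; sites whose EHH reaches a chromosome end above threshold
are discarded by default (`discard_edge_truncated`) to avoid
border-biased integrals. Standardisation bins sites by ALT frequency
in 0.025-wide bins, merging bins with fewer than 10 sites into their
nearest populated neighbour; a zero-SD bin maps to 0 with a flag.
These four constants mirror common rehh-style usage and are all
configurable. The p-value transform is the two-sided Gaussian tail on
the −log10 scale; outliers are strictly p > 5, annotated with the
driving allele (ALT when iHS < 0). Candidate genes intersect
[pos − 30 kb, pos + 30 kb] of any outlier, deduplicated, with the
nearest-SNP distance (0 inside a gene).

**Localisation limits.** Under the founder-copy model the
founder-sharing signal extends across the entire swept tract: sites
100–250 kb from the focal position show raw iHS as extreme as the
focal site itself, so the single genome-wide max-|iHS| site lands
essentially uniformly within the swept region (measured median
distance ≈200 kb over seeds), even though the sweep is detected
unambiguously (−log10 p > 5 within the swept region in nearly all
seeds, and neutral genomes yield zero such sites in ≥8/10 seeds).
Single-SNP peak position should not be over-interpreted at λ on the
order of 100 kb; the swept region, not the peak SNP, is the reliable
unit — which is why the demo's recovery check asserts localisation to
the swept-tract footprint (dense half-span + 2λ).

## LD pruning and annotations

`ld_prune` follows the PLINK `--indep-pairwise 50 10 0.2` scheme
(50-SNP windows advancing by 10; drop the later of any pair with
dosage r² > 0.2; monomorphic sites never enter a correlation), with
one deviation: the pass repeats on the surviving set until a fixed
point, making the result idempotent — a single pass is not, because
removals regroup windows and expose unchecked pairs. Gene annotations
come from GFF3 (`gene` features only) or BED (converted to 1-based
inclusive).

## Determinism and problem sizes

Every simulation takes an integer seed and is byte-identical across
runs; painting, ABBA-BABA, window statistics and the scan contain no
randomness after simulation, and tie-breaks (window overlap, dual-label
ordering, LD-prune drops) are all deterministic. The shipped test
suite and the acceptance script run the scenarios at their default
sizes (30 Mb quartets and painting panels, 5 Mb sweep genomes, 10–20
seeds for calibration rates), chosen so the whole pipeline exercises
end-to-end on a single CPU in a few minutes.
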