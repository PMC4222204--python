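# Methods

`microsatpop` re-implements, as one tested pipeline, the population-genetic
workflow used to study the two post-fire resprouting forms of *Banksia
attenuata*: northern lignotuberous populations and southern epicormic
populations genotyped at 11 unlinked microsatellite loci. The original
genotype matrix was never deposited, so the package pairs each analysis
stage with a synthetic-data generator that reproduces the study's design and
its printed summary statistics. This note records the models, the defaults
and why they were chosen, the numerical details, and what the synthetic
fixtures can and cannot demonstrate.

## Data model

A `GenotypeDataset` is an `(n_individuals, n_loci, 2)` integer array of
codominant allele states with population labels and an optional
population-to-phenotype-group mapping. Allele states are fragment lengths
as scored; `0` is missing, and calls are always both-present or
both-missing. A `(population, locus)` cell with no data propagates as
*undefined*, never as zero diversity: statistics average over defined loci
only. GenePop (2- or 3-digit) and a plain TSV dialect are supported;
because GenePop does not standardize population naming, a two-column
`population<TAB>group` sidecar both names the POP blocks (by order, when
names do not already match) and carries the phenotype groups.

## Diversity and differentiation estimators

Per population we report the mean number of alleles per locus `A`, the mean
effective number `Ae = 1 / sum(p_i^2)`, observed heterozygosity `Ho`, and
Nei's unbiased expected heterozygosity `He = (2n/(2n-1)) (1 - sum p_i^2)`.

Differentiation uses the heterozygosity-based family with Nei–Chesser
small-sample corrections. Per locus, with `k` populations, unweighted mean
frequencies and harmonic-mean sample size `n_h`:

    HS = 2 n_h/(2 n_h - 1) * (1 - mean_i sum_a p_ia^2)
    HT = (1 - sum_a pbar_a^2) + HS/(2 n_h k)

- `G_ST = (HT - HS)/HT`, aggregated over loci by summing numerators and
  denominators (ratio of sums);
- Hedrick's standardized `F'_ST` via the closed form
  `G_ST (k - 1 + HS) / ((k - 1)(1 - HS))`, i.e. `G_ST / G_ST(max)` — chosen
  over recoding-based maximization because it is deterministic and directly
  testable against the ratio definition;
- Jost's `D = (k/(k-1)) (HT - HS)/(1 - HS)` per locus; the multi-locus
  summary is the arithmetic mean over defined loci (a harmonic-mean variant
  is available; the choice is cosmetic because per-locus values are what the
  analysis interprets).

Negative estimates are legitimate for undifferentiated populations under
the bias correction and are stored as computed. "Between-group" per-locus
`D` pools each group's allele copies into a single unit (`k = 2`), which is
the scale on which the study reports values near 0.9; within-group `D`
treats member populations as units.

Pairwise significance uses permutation of individuals between the two
populations with the add-one rule `p = (1 + #{perm >= obs})/(1 + n_perm)`,
Bonferroni-corrected across pairs. Bootstrap intervals resample individuals
within populations (2.5/97.5 percentiles by default; min/max available)
because the source analysis reports only "1000 bootstrapping" without a
scheme — resampling individuals is the conservative common choice.

The printed per-population diversity table and pairwise `F'_ST` matrix of
the original study ship as TSV reference data so block summaries and group
means can be recomputed and compared against the quoted values.

## F_ST-outlier scan

The scan follows the FDIST logic. The null is a symmetric island model with
`d = 100` demes (the FDIST default; the study states none); the sampled
demes match the observed populations in number and diploid counts. The
coalescent uses the many-demes two-phase approximation: within each sampled
deme, lineages either coalesce (probability `(j-1)/(j-1+M)` per event,
`M = 4Nm`) or escape ("scattering", treated as instantaneous because the
within-deme timescale is `1/d` of the between-deme one); escaped lineages
then follow a Kingman coalescent with pair rate `1/(d + (d-1)/M)`
("collecting"). Under this model the expected within-deme pair coalescence
time is exactly `d` (in units of `2N`) and `F_ST = 1/(1 + M d/(d-1))`,
which is inverted to choose `M` for a target `F_ST`. Because
heterozygosity-based `F_ST` is mildly deflated by mutational homoplasy, a
pilot round (2 x 2,000 loci) rescales `M` so the realized multi-locus
`F_ST` of the cloud matches the target — the same trial-simulation tuning
the original FDIST used. An exact event-by-event structured coalescent was
rejected on cost grounds: at the migration rates implied by near-zero
within-group `F_ST` it needs of order `M d log n` migration events per
locus, and the approximation error is `O(1/d)`.

Mutation on the cloud is strict stepwise by default (microsatellites), with
an infinite-alleles option; per-locus `theta` is log-uniform on
`(0.05, 20)` so simulated heterozygosity spans the observed range. Each
cloud holds 20,000 loci. Per locus we record bias-corrected mean
within-population gene diversity (`HS`, the conditioning axis) and `G_ST`,
computed with the same estimators as the observed data. The envelope splits
the `HS` axis into 20 equal-occupancy bins (bins under 50 points merge),
takes empirical 0.5%/50%/99.5% quantiles per bin, and interpolates
piecewise-linearly between bin means; loci outside the simulated range are
judged against the nearest bin and flagged as extrapolated.

The null target is the observed multi-locus `F_ST` of the set; following
FDIST practice, flagged loci are removed once and the scan re-run at the
trimmed target. Because allele frequencies of neighbouring populations are
correlated, the scan runs on three sets — all populations, and each
phenotype group separately — and a locus is *selection-associated* when it
is an outlier in the whole set but neutral in both within-group scans.

## Admixture clustering and delta-K

The clustering module is a reduced re-implementation of the classical
admixture Gibbs sampler: latent cluster assignments per allele copy,
conjugate Dirichlet updates for cluster allele frequencies
(`lambda = 1`) and for individual admixture proportions with fixed uniform
`alpha = 1` (no alpha updating, no correlated-frequencies or linkage
models). With `alpha = 1` the posterior-mean membership of a fully assigned
individual is bounded by `(2L + 1)/(2L + 2)` at `L` loci — at 11 loci about
0.96 — so assignment quality is judged on modal memberships, not on
saturation near 1.

Defaults are burn-in 1,000 of 6,000 total sweeps, 5 runs per `K`, scanned
over `K = 1..6`. At roughly 1 ms per sweep on the study-sized fixture this
keeps a full scan in the low minutes; on data as strongly structured as the
study's (`F'_ST ~ 0.27` between groups) the likelihood plateau and the
`K = 2` decision are insensitive to chain length well below these settings,
which is why the very long chains of the original analysis are not the
default. The number of clusters is chosen by Evanno's
`delta_K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K))` over run-mean
log-likelihoods; a zero between-run sd yields `inf` with a warning.

## ABC over divergence scenarios

Three demographic hypotheses relate the two phenotype groups, each group
pooled as one population: (1) population 1 (lignotuberous) ancestral,
population 2 derived through a bottleneck at split time `t1`; (2) the
mirror image; (3) both populations derived from an unsampled ancestor, each
through its own bottleneck — the both-lineage placement is this package's
resolution of an ambiguity in the source description. In scenarios 1 and 2
the ancestral sampled population keeps its present-size prior back in time.

Priors: present sizes and the ancestral size uniform on 10^4–10^5
(diploid); bottleneck size `Nb` uniform on 10–100; bottleneck duration
`db` uniform on 250–750 years (1–3 generations at the 250-year generation
time); `t1` normal(25,000, 5,000) years truncated to `t1 > db` (a
structural necessity, since the bottleneck sits inside the derived-lineage
interval); locus mutation rate uniform on 10^-4–10^-3 per generation,
shared across loci. The generalized stepwise model uses a geometric step
parameter `P ~ U(0.1, 0.3)` and a single-nucleotide-indel rate log-uniform
on 10^-8–10^-5 — standard microsatellite-ABC defaults, since the source
names the model but not its parameters. Motif states are confined to 40
contiguous values by reflecting boundaries, implemented exactly by folding
the free walk (mirror reflection equals folding for symmetric steps);
indels shift fragment length off the dinucleotide ladder by one base and
are tracked separately.

The coalescent runs in continuous time with per-pair rate `1/(2N)` per
generation and piecewise-constant sizes; times convert from years at 250
years per generation, rounded to at least one generation. Simulators are
numba-compiled; a 3 x 20,000-record reference table at 11 loci and 25
diploids per population builds in a few minutes single-threaded.

Summary statistics (12): per population, mean alleles, mean unbiased
expected heterozygosity, mean allele-size variance and mean
Garza–Williamson `M` (alleles over ladder span plus one); pairwise,
multi-locus `G_ST`, Jost's `D`, shared-allele distance
`1 - sum_a min(p1a, p2a)` and the mean squared allele-size difference
(delta-mu)^2. Sizes are expressed in ladder-step units inferred per locus
(gcd of allele gaps). This is a compact version of the conventional
microsatellite-ABC statistic family; the scenario contrast lives mainly in
the bottleneck's asymmetric erosion of `A` and `M`.

Statistics are MAD-standardized over the table (zero-MAD statistics drop
out); distances are Euclidean. Scenario probabilities come from scenario
proportions among the closest records (direct; acceptance count scaled as
the fixed fraction 1,500/6x10^6 of the table) or from a multinomial
logistic regression on the closest records (15,000/6x10^6 fraction),
ridge-stabilized and evaluated at the observation; a single-scenario
neighbourhood falls back to the direct estimate. Parameter posteriors are
Epanechnikov-weighted quantiles of the accepted draws of the chosen
scenario with an optional local-linear adjustment; at desk scale the
acceptance count for *parameters* defaults to 1,000 of a 20,000-record
scenario block, because the scaled scenario-choice fraction (15 records)
is too few for stable weighted quantiles. Confidence evaluation draws
pseudo-observed datasets from each scenario's prior predictive and reports
the confusion matrix, per-scenario type-I/II rates and the probability the
selected scenario is true.

## Synthetic data generator

The generator emulates the study design: 6 + 8 populations, 25–35 diploids
each, 11 loci with an 18-allele support per locus (198 alleles total),
between-group block-mean `F'_ST` on target 0.27 and within-group `F'_ST`
near zero, and one locus carrying the published selection signature (one
allele at 0.87 in the epicormic group, all frequencies below 0.2 in the
lignotuberous group, shared 17-allele support).

Frequencies follow a two-level drift construction. Ancestral spectra are
skewed Dirichlet draws (`alpha = 0.27` per allele) tempered per locus to a
gene diversity drawn uniformly from 0.65–0.85, so that per-population `He`
lands in the study's printed 0.69–0.77 band and `A` near 8 under 25–35
sampled diploids. Group frequencies move in opposite directions along a
fixed random direction by a multiplicative exponential tilt whose magnitude
is bisected per locus so every neutral locus has the *same* parametric
between-group `G_ST`; the common level is then bisected (outer loop) so the
realized sampled block-mean `F'_ST` hits the target. Population frequencies
get the same construction at a small fixed magnitude. Because all noise is
drawn once with fixed shapes and only magnitudes vary, both bisections run
under common random numbers and converge reliably; genotypes are drawn
under Hardy–Weinberg equilibrium, with optional uniform missingness.

Two deliberate idealizations matter for interpreting test results. First,
neutral loci are exchangeable by construction — they share one underlying
divergence level, which is precisely the null hypothesis of the outlier
scan. Real loci add locus-to-locus drift variance (in a two-group split
the between-group contrast has very few effective degrees of freedom), and
an island-model envelope under-covers such hierarchically structured data;
the clean one-locus detection on the fixture therefore demonstrates the
machinery, not the scan's specificity on real hierarchical data. Second,
the generator is a frequency-level emulation, not a coalescent: it has no
mutation model, no linkage, and no shared genealogy, so ABC is never fit to
it (ABC analyses pool the groups and compare against coalescent
simulations).

## Numerical and testing notes

- All stochastic operations take explicit seeds and are bit-reproducible;
  seeds derived internally use `numpy.random.SeedSequence` spawning.
- Undefined statistics (monomorphic `HT = 0`, `HS = 1`, `n = 0`) raise or
  propagate as NaN; nothing is silently clamped.
- The estimator layer is verified to 1e-12 against an independent
  brute-force implementation of the published formulas over an exhaustive
  two-population, two-allele grid.
- Acceptance-scale runs use a 3 x 20,000 ABC table, 20,000-locus null
  clouds, and a `K = 1..5` scan with 5 runs of 3,000 sweeps; these sizes
  were chosen as the smallest at which the recovery properties are stable,
  and they are stated alongside every reported number.
- Known limitations: the island-model null is a two-phase approximation
  (error `O(1/d)`); the admixture sampler is the simplest variant (fixed
  `alpha`, uncorrelated frequencies); scenario 3's confusion with
  scenarios 1/2 is reported, not asserted, because the topologies are
  genuinely similar; real-data numerical identity with the GUI tools used
  in the original study is not claimed.
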