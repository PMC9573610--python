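# Methods

This note documents the models and procedures implemented in `peaheat`,
the defaults chosen where the underlying field protocol leaves the desk
analysis under-determined, and the limits of what the synthetic-data tests
establish.

## Screening model

The screen scores heat tolerance from the grain-weight penalty of late
sowing. Per accession and stage (NS/LS1/LS2), the average grain weight
per plant `W` is the mean over replicates of the per-replicate mean of up
to five weighed plants (`max_plants=5`, configurable). Loss rates are

    LR1 = (1 − W_LS1/W_NS) · 100,   LR2 = (1 − W_LS2/W_NS) · 100,

clamped to [0, 100]. A negative raw loss (a late-sowing yield *gain*)
clamps to 0 rather than erroring: the classification's domain starts at
"no loss", and level 1 is the no-loss class.

**Nine-level standard.** Each loss rate falls into one of five 20-point
bands; ties at 20/40/60/80 go to the lower band (the bands are printed as
`0 ≤ LR ≤ 20`, `20 < LR ≤ 40`, …). The level is the band-index sum plus
one. On band pairs that differ by at most one this reproduces the
published rule table verbatim (checked exhaustively on a 0.5-point grid);
the band-sum rule additionally covers the corner cases the printed table
omits (e.g. LR1 = 15, LR2 = 55, whose difference is ≤ 40 and which is
therefore not excluded), assigning them the natural interpolated level.
Accessions with |LR1 − LR2| > 40 are excluded as inconsistent between the
two late sowings. Levels 1–3 map to HT, 7–9 to HS.

**Survival and filling rates.** FSR = Σ survivors / (n_reps · sown) · 100.
The published formula prints a fixed "/3" while stating n = 1 for the
first screening; dividing by n·sown reconciles both readings (n = 3
reproduces the printed form exactly). GFR = hundred-grain weight divided
by the calendar days from first flowering to maturity; HT-vs-HS contrasts
use one-way ANOVA per stage.

**Iterative screening.** Round r + 1 is expected to re-screen only the HT
and HS accessions of round r; this is validated and reported, not
enforced, so fully simulated rounds can re-screen everything. The last
round's HT/HS sets are the "extremely" tolerant/sensitive sets; the
consistency set holds accessions with the same HT/HS category in every
round they appear.

**KS normality check.** The level values are tested against a normal with
the sample mean and standard deviation; D is the exact ECDF sup-distance
and p the plain asymptotic Kolmogorov-series probability at √n·D, i.e.
the classic SPSS-style one-sample output without Lilliefors correction.
Two caveats are inherent and documented rather than patched: (i) with
estimated parameters the asymptotic p is conservative, and (ii) level
values are integers 1–9, and at panel sizes in the hundreds the
discretisation alone drives D above the rejection threshold — the
calibration checks therefore run at the final-round panel scale
(45 accessions), where the test is conservative-to-nominal (measured null
rejection ≈ 9% at α = 0.05 over 500 replicates). Zero sample variance is
flagged degenerate instead of producing a p-value.

## Synthetic trial generator

The generator emulates the screening design — three sowing dates
(1/16/31 March), single-replicate first round, three replicates
afterwards, ten seeds per row, five weighed plants — with these choices:

* NS per-plant grain weight is log-normal per accession (median 25 g,
  log-sd 0.5, spanning roughly 0–60 g); plant-to-plant weights within an
  accession are log-normal with cv 0.10 (mean-preserving).
* Loss under late sowing: a percent-scale score g = class mean + stage
  shift + N(0, noise_sd) is squashed through 100·expit((g − 50)/25),
  a logistic with unit slope at 50%, so losses always lie in (0, 100).
  Scores leaving [0, 100] before the squash are tallied in a truncation
  counter. The latent classes sit at 50 ∓ effect/2 (HT low), so
  `effect` is directly the class separation in points; LS2 adds a
  5-point shift. Class is binary (HT/HS) by default for crisp recovery
  checks.
* Survivors per row are Binomial(10, p) with p = 0.618/0.474/0.285 for
  NS/LS1/LS2 — the mean field survival rates reported for a large
  first-round screening, so zero-survivor rows (unscoreable stages,
  exclusion-ledger entries) arise at a realistic rate.
* Phenology: flowering ~68 days after sowing (a little earlier per later
  stage), grain filling ~36 days (shorter under heat); dates are ISO
  calendar days and always satisfy sowing < flowering < maturity.
* Temperatures: seasonal cosine (annual mean 14 °C, amplitude 13 °C, peak
  day 196 — a north-China-plain spring) plus optional linear trend and
  Gaussian noise; any late window is warmer than the 15-day-earlier
  normal window in expectation.

With the study conditions used in the tests (effect 60 points, noise sd
5, 200 accessions), the screen recovers ~94–96% of latent labels. What
passing these tests shows is that the classification pipeline is a
faithful, well-calibrated implementation of the standard; it does **not**
show that real pea panels separate this cleanly — real loss
distributions are unimodal with a continuum of intermediate levels,
genotype × year interaction moves accessions between rounds, and weight
measurement error is not log-normal by fiat.

## Genotype generator and diversity statistics

Genotypes follow a Balding–Nichols construction generalised to k alleles:
per locus an ancestral frequency vector (biallelic: uniform on
[0.2, 0.8]; 10% of loci tri-allelic with Dirichlet(2) ancestral
frequencies), then per-group frequencies ~ Dirichlet(p·(1 − F)/F), then
genotypes by within-group random mating. Neutral markers are
differentiated between the two planted subpopulations, heat-tolerance-
related markers between the latent HT/HS classes — the structure the
downstream clustering is supposed to find. Missing calls are masked
i.i.d. at `missing_rate`.

Diversity indices are plug-in estimators from non-missing calls only: NG
and NA are observed distinct genotypes/alleles, MAF the largest allele
frequency, GD = 1 − Σp², PIC Botstein's 1 − Σp² − Σ_{i<j} 2p_i²p_j², all
k-allele general. `He` is the *observed* heterozygosity (fraction of
heterozygous calls): pea is a selfing crop, so observed heterozygosity
sits far below GD, which is why both are reported and the unbiased
expected heterozygosity n/(n − 1)·GD appears separately as `He_exp`.
Informativeness classes: PIC ≥ 0.5 high, 0.25 ≤ PIC < 0.5 moderate,
< 0.25 slight. No call-rate filter is applied by default.

## Distances, UPGMA, PCoA

Individual-level trees and ordinations use the allele-sharing distance
d = 1 − shared/(2·m) over pairwise-complete markers (shared = multiset
intersection of the two allele pairs). Group-level distance is Nei's
(1972) standard D = −ln(J_XY/√(J_X·J_Y)) with J terms averaged over loci;
a zero between-group identity yields an infinite distance, kept and
flagged. The Nei-distance dialect (1972 standard rather than 1983 D_A)
is a deliberate choice where the toolchain being mirrored does not pin
one down.

UPGMA uses size-weighted average linkage with joins at half the
inter-cluster distance; ties break on the smallest pair of original leaf
indices, making output deterministic and permutation-invariant up to
relabelling. Trees serialise to Newick with branch lengths; ultrametricity
holds to 1e−9 by construction and is asserted in tests.

PCoA Gower-centres −½D², eigendecomposes, and scales eigenvectors by
√eigenvalue for eigenvalues above a relative tolerance of 1e−10;
contribution rates are eigenvalue shares of the positive part, in
percent. Negative eigenvalues (non-Euclidean distances) are reported but
carry no coordinates.

## Admixture model

The sampler implements the admixture model with independent allele
frequencies: allele copy c of accession i at locus l originates from
cluster k with probability Q[i, k] and is then drawn from P[k, l, ·].
Gibbs updates cycle origin indicators Z (categorical, ∝ Q·P), cluster
frequencies P (Dirichlet(λ + counts), λ = 1), and admixture rows Q
(Dirichlet(α + counts), α = 1). α is held fixed — no Metropolis update —
which is adequate for K-selection and assignment at this scale and keeps
the sampler simple. Missing calls are skipped. The per-iteration
log-likelihood ln P(X | P, Q) is recorded after burn-in; the run-level
estimate is the deviance-style L_est = mean(lnL) − var(lnL)/2 (the plain
mean is also exposed). Q is reported as the post-burn-in posterior mean,
with clusters in canonical order (by the first accession exceeding 0.5
membership) so runs are comparable despite label switching; within-chain
label switching is not corrected and is not observed at the
well-separated desk scales used here. The inner loop is compiled with
numba; identical seeds give identical traces.

Default MCMC lengths are 2,000 burn-in + 8,000 recorded iterations — a
deliberate desk-scale choice (the mirrored tool's convention is 10,000 +
100,000 with K = 1–10 and 10 runs per K, available as config presets).
At 120 accessions × 40 markers the scaled-down chains are long past
mixing for K ≤ 5.

**Evanno ΔK.** L(K) is the mean of L_est over ≥ 2 runs per K on a
contiguous K range; ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L_est at K),
defined for interior K; the optimum is the interior argmax. A linear
L(K) profile (all second differences zero) or zero spread is flagged
ambiguous/undefined rather than forced to an answer. Because ΔK needs
interior points, K = 1 can never be selected — a known limitation of the
criterion, not of this implementation.

## Primer validation

Rules are applied per role: peripheral primers — length 15–30 nt,
effective length ≤ 38, GC 40–60%, Tm 58–60 °C, bounded
self-complementarity, cross-complementarity ≤ 4 with partners, no
3′-terminal complementary overlap; extension primers — the same
sequence-level rules plus tailed length ≥ 36 nt and 4–6 nt spacing to
adjacent loci (advisory only, since adjacent lengths only *generally*
differ by that much). Tm uses the basic GC formula
64.9 + 41·(GC − 16.4)/L for ≥ 14 nt and the Wallace rule 2(A+T) + 4(G+C)
below, with the method flagged — no thermodynamic nearest-neighbour
tables. "No self-complementary sequences" is not quantified in the
protocol being validated; runs ≥ 4 warn and ≥ 6 fail, both configurable.
Complementarity scans are exhaustive (dynamic-programming longest common
substring against the reverse complement) and are verified against a
quadratic brute force in tests.

## Numerical and degenerate-input policy

* Strict inequality for "days above" thresholds; growing-degree days
  floor at zero per day; base temperature defaults to 0 °C (configurable)
  since the thermal-unit definition referenced by the field protocol does
  not pin one down.
* Accessions missing a scoreable stage are excluded with reason codes
  (`W_NS_MISSING`, `W_NS_NONPOSITIVE`, `MISSING_LATE_STAGE`,
  `LR_DIFF_GT_40`), never silently dropped.
* All-missing markers yield flagged undefined statistics; distance pairs
  with no comparable markers yield flagged NaN distances that refuse to
  enter UPGMA.
* All generators and samplers take explicit integer seeds; equal seeds
  give bit-identical outputs, and the pipeline derives per-stage seeds
  from the single run seed.

## Problem sizes

Test and acceptance runs use deliberately scaled problem sizes chosen as
the smallest that exercise each claim: 200 accessions × 20 seeds for
screening power, 120 accessions × 40 markers with F_ST = 0.15 for
structure recovery (5 replicate panels × K = 1–5 × 5 runs in the
acceptance script; 3 × 5 × 3 at shorter chains in the test suite), 500
replicates for KS calibration. These sizes match the regime where the
corresponding field results live (hundreds of accessions, tens of
markers) while keeping every run deterministic and fast.
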