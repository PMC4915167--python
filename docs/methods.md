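# Methods

## Model and sampler

The association model is a spike-and-slab ("BayesC") linear mixed model

    y_i = mu + sum_j z_ij a_j delta_j + e_i,

with z_ij in {-1, 0, +1} (+1 for the allele-1 homozygote, 0 for the
heterozygote; missing calls must be mean-imputed before fitting), delta_j ~
Bernoulli(pi), a_j | delta_j=1 ~ N(0, sigma2_a), and e_i ~ N(0, sigma2_e /
w_i). Weights implement the weighted analysis of deregressed-EBV
pseudo-phenotypes: a record of reliability r carries w = r/(1-r), so a
reliability-0.5 record counts as one own-performance equivalent. Station
records use w = 1. pi is a fixed constant of the run, not estimated.

Gibbs updates per iteration, in fixed order (part of the determinism
contract): mu from its weighted normal conditional; each marker in map order
— delta_j from its marginalized conditional with the effect integrated out,
then a_j from its normal conditional when included (excluded markers carry
a_j = 0 and do not enter the sigma2_a update); sigma2_a from
scaled-inv-chi2(nu_a + k, (nu_a S_a + sum a_j^2)/(nu_a + k)) over the k
included effects; sigma2_e from the weighted residual sum of squares
analogously. The inclusion log-likelihood ratio is evaluated as

    u = c_j sigma2_a / sigma2_e
    llr = 0.5 * (-log1p(u) + r_j^2/(c_j sigma2_e) * u/(1+u)),

with c_j = z_j' W z_j and r_j = z_j' W (e + z_j a_j delta_j). This form is
algebraically the standard marginal Bernoulli draw but is invariant bit for
bit under jointly doubling all weights and the residual prior scale, which
turns the weight-scale invariance of the posterior into an exactly testable
property. The kernel is numba-compiled; all draws come from one seeded stream,
so chains are bit-reproducible under a fixed seed.

### Priors

sigma2_a and sigma2_e carry scaled-inv-chi2(nu, S) priors with nu = 4 by
default. S is set so the prior expectation nu S/(nu-2) equals the preliminary
variance estimate: residual scale from sigma2_e_prior, and marker-effect
scale from sigma2_u_prior spread over the heterozygosity expected in the
model, S_a proportional to sigma2_u / (pi * sum_j 2 p_j (1-p_j)). The
preliminary estimates are config inputs (a full evaluation would take them
from a polygenic BLUP pre-analysis; the package accepts the simulator's truth
or defaults to an even split of Var(y), a deliberately vague
method-of-moments stand-in). Setting sample_sigma2_a/e = False pins a
variance at its scale, which with pi -> 1 reduces the model to SNP-BLUP /
ridge — the closed-form limit used as a sampler oracle in the tests.

### Posterior summaries

P_j is the post-burn-in frequency of delta_j = 1 (not Rao-Blackwellized — it
is the most direct estimate of "the probability of the SNP having a non-zero
effect"; thinning defaults to 1). Before the Bayes-Factor transform, P is
capped into [1/(2S), 1 - 1/(2S)] for S kept samples: an empirical 0 or 1 only
bounds the event at the chain's resolution, and the cap keeps logBF finite
and sample-size-aware.

The marker-captured genetic variance is sigma2_u_hat = 2 sum_j p_j(1-p_j) *
sigma2_a_uncond, with p_j the allele frequency and sigma2_a_uncond = pi *
E[sigma2_a | chain] the unconditional (mixture) marker-effect variance — each
marker carries a non-zero effect a fraction pi of the time, and the
heterozygosity sum runs over all fitted markers. Using the conditional
variance instead would overstate capture by a factor 1/pi.

## Evidence and region calling

BF = (P/(1-P))/(pi/(1-pi)); logBF = 2 ln BF (so BF 150 -> 10.0, BF 200 ->
10.6). Evidence classes on the peak logBF: major above 12 (BF ~ 400), QTL
above 8 (BF ~ 55), putative in (6, 8]; all thresholds strict, so a peak at
exactly 8.0 is putative.

Candidate peaks (logBF above the peak threshold) are processed in decreasing
logBF (ties broken by position). Each unconsumed peak grows independently in
both directions: the frontier starts at the peak; while at least one marker
with logBF > 3 lies in the 0.5 Mb window beyond the frontier, the frontier
jumps to the outermost such marker and every qualifying marker passed is
absorbed; region bounds are the outermost absorbed positions (the peak alone
when nothing qualifies). The window anchors on the moving frontier — the
published wording is ambiguous about the anchor, and this reading reproduces
"bounds defined by the last marker above the extension threshold that was
integrated". Absorbed markers cannot seed another region, and a lower peak
landing inside an already-called interval merges into it, so each
above-threshold marker belongs to exactly one region. An independent
brute-force window simulation in the test suite encodes the same rule and is
compared on 1,000 random tracks.

Coordinates are 1-based bp internally; Mb values in reports use 6 decimals;
BED exports convert to 0-based half-open at the boundary.

## Cross-trait comparison

Regions from traits of the same performance complex (calving: CS, PO, CSm;
suckling: MY, US, WWm) are compared at evidence >= QTL. Overlap is a
non-empty intersection of closed bp intervals on the same chromosome; a
shared boundary SNP counts (regions are defined by SNP positions, and a
shared boundary SNP is shared evidence). Each overlapping pair yields one
common-region record — no merging, preserving a one-row-per-pair table.
Venn counting is reference-trait oriented (counts of the reference trait's
regions overlapping none / one / both of the other traits); the reference is
a parameter. Gene annotation reports genes overlapping each region and,
failing that, the nearest same-chromosome gene with its distance in Mb
(3 decimals).

## Marker QC

Filters run in fixed order and are idempotent: call rate strictly greater
than 0.90 (a marker called in exactly 90 % of animals is removed), then a
1-df chi-square Hardy-Weinberg goodness-of-fit test on the non-missing calls
with p strictly greater than 1e-4. The chi-square form (not the exact test)
is the standard choice at these sample sizes; monomorphic markers return
p = 1. Allele frequency is (2 n_hom1 + n_het) / (2 n_called), on non-missing
calls only.

## Synthetic populations

The generator emulates a beef progeny-test design: n animals in paternal
half-sib families (default 78 sires, following the progeny-test structure of
the motivating dataset), dense SNP maps over several chromosomes, and a
quantitative trait defaulting to a milk-yield-like scale (mean 5.54 kg, SD
1.39 kg, h2 = 0.35).

Genotypes: markers are laid out in LD blocks (default 20 markers). Per block,
a founder pool of 32 haplotypes is built by copy-with-mutation — a copy
genealogy over the pool, with each site's allele 1 assigned to the descendant
clade of one branch, the branch chosen so the clade size matches the site's
target frequency (drawn uniformly from [maf_min, maf_max], default
[0.05, 0.5]); 1 % site-wise noise softens clade sharing. Nested clades give
adjacent-marker r-squared around 0.3-0.4 within blocks against a ~0.003
background, and pool frequencies track the targets. Each sire receives two
pool haplotypes per block; an animal's paternal gamete picks one of its
sire's haplotypes per block (block-boundary recombination) and the maternal
gamete is a random pool haplotype (unrelated dams). Missing calls are NaN at
the configured rate; downstream stages require explicit mean imputation.

Traits: planted QTL (default 10, drawn among markers with sample MAF >= 0.05
so effects stay finite and detectable; effect-size distribution configurable
— normal by default, since the real effect-size law is unknown) plus a
polygenic background over all remaining markers. Both genetic components are
centered and scaled so the realized heritability tracks h2 and the planted
QTL carry qtl_var_fraction of the genetic variance; residuals are drawn at
the remaining variance. h2 = 1 is rejected (no residual variance).

DEBV pseudo-phenotypes: pseudo = TBV + noise with Var(noise) = sigma2_u
(1-r)/r, so the squared correlation with the true breeding value approaches
r; reliabilities default to U[0.05, 0.33], the range of the motivating field
data. Milk yield combines day-60 and day-120 weigh-suckle-weigh records with
weights 1/3 and 2/3.

What the generator does not emulate: multi-generation pedigrees and dam
relatedness, realistic LD decay within blocks and any LD across blocks,
chip-specific ascertainment, imputation errors, selection, or non-Gaussian
trait scales (ordered categorical calving scores are simulated as Gaussian
liabilities). Passing tests therefore demonstrate correctness of the
machinery and calibration under the assumed model, not performance on real
cattle data.

## Problem sizes and numerical choices

Desk-scale study conditions used by the tests and the acceptance script:
sampler oracle checks on a 20 x 5 ridge instance (60,000 iterations);
pure-noise calibration at n = 500, m = 5,000, pi = 0.0025 (15,000
iterations); planted-QTL recovery at n = 500, m = 2,000, one QTL at 30 % of
phenotypic variance (20,000 iterations); variance capture at n = 2,000,
m = 10,000, h2 = 0.4 (8,000 iterations — sigma2_a mixes quickly and its
posterior mean is stable at that length, sparing the 100,000-iteration
setting of a full analysis). pi = 0.0025 is the package's desk-scale
convention across these runs. The captured fraction at these conditions
falls around 0.4-0.7 across simulation replicates (chain-length checks show
the per-replicate value is converged; the spread is genuine replicate-level
variation), the same under-capture character as a full-scale analysis.

Degenerate inputs: zero-variance phenotypes, non-positive weights, fully
missing markers, burn_in >= n_iter and pi outside (0,1) are rejected rather
than patched. Markers with c_j = 0 (no genotype information under the
weights) fall back to the prior inclusion probability. Logistic overflow is
clamped at |log-odds| > 35. Region-calling ties (equal logBF peaks) break by
position, keeping output invariant to input order.

## Known limitations

- The sampler is single-chain; convergence diagnostics are limited to the
  kept-sample traces returned by fit_bayesc.
- P_i is the raw inclusion frequency; a Rao-Blackwellized estimator would
  have lower Monte-Carlo variance at the same chain length.
- The polygenic-component model variant (fitting a pedigree-based polygenic
  term alongside the markers) is out of scope; the parsimonious
  markers-only model is the one implemented.
- DEBV computation itself (deregression of EBVs) is consumed, not derived;
  only the reliability-to-weight mapping is implemented.
- The exact HWE test and per-animal QC are not implemented.
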