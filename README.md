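# bayesqtl

QTL detection for maternal beef-cattle traits with BayesC variable selection,
Bayes-Factor evidence scoring, sliding-window region calling, and cross-trait
region comparison.

## The problem

Maternal performance in beef cattle — how easily a cow calves and how well she
suckles her calf — is economically central but genetically poorly understood.
Progeny-test populations provide two kinds of records: station phenotypes
(calving difficulty score, pelvic opening, milk yield by weigh-suckle-weigh,
udder swelling score) measured on a limited number of primiparous cows, and
field pseudo-phenotypes (deregressed EBVs, DEBV, for maternal calving score
and maternal weaning weight) whose precision varies strongly with the record's
reliability. With dense SNP genotypes (~7×10^5 markers) and only ~10^3
phenotyped animals, single-marker regression is hopeless; Bayesian variable
selection resolves the n ≪ p problem and yields direct probabilistic evidence
per marker.

## The model

For animal *i* with phenotype *y_i* and genotype codes
*z_ij* ∈ {−1, 0, +1}:

    y_i = μ + Σ_j z_ij a_j δ_j + e_i

Each marker effect *a_j* is in the model (δ_j = 1) with prior probability π
and is then N(0, σ²_a); residuals are N(0, σ²_e / w_i), where *w_i* = 1 for
station records and *w_i* = r_i/(1 − r_i) for DEBV records of reliability
*r_i*. Variances carry scaled-inverse-χ² priors seeded by preliminary
estimates; π is a fixed constant of the run (default 0.025 %, i.e. 177 of
706,791 HD-chip markers in the model at a time). A Gibbs sampler (default
100,000 iterations, 20,000 burn-in) yields per-marker posterior inclusion
probabilities *P_j*, converted to evidence values

    BF_j = (P_j/(1−P_j)) / (π/(1−π)),      logBF = 2 ln BF.

Peaks with logBF > 8 are called QTL (major evidence above 12, putative in
(6, 8]). Around each peak, a 0.5 Mb sliding window absorbs flanking markers
with logBF > 3; the region bounds are the last absorbed markers. Regions
called for different traits of the same performance complex are intersected,
Venn-counted against a reference trait, and annotated with overlapping or
nearest genes. The total genetic variance captured by the markers is
σ̂²_u = 2 Σ_j p_j(1−p_j) σ̂²_a (with σ̂²_a the unconditional marker-effect
variance), reported as a fraction of the preliminary genetic variance.

A synthetic-population generator (half-sib families, block LD via
copy-with-mutation founder haplotypes, planted QTL on a polygenic background,
reliability-stratified DEBV) makes every stage testable without any download.

## Worked example

```python
import numpy as np
import bayesqtl as bq

cfg = bq.SimConfig(n_animals=500, n_snps=2000, n_chromosomes=2,
                   n_qtl=1, h2=0.30, qtl_var_fraction=1.0, seed=55)
G = bq.simulate_genotypes(cfg)
phen, truth = bq.simulate_traits(G, cfg)

mcfg = bq.ModelConfig(pi=0.0025, n_iter=20_000, burn_in=5_000, seed=56,
                      sigma2_u_prior=truth.sigma2_u_true,
                      sigma2_e_prior=truth.sigma2_e_true)
post, summary, diag = bq.fit_bayesc(G, phen, mcfg)

j = int(np.argmax(post.P))
print("planted QTL at marker", truth.qtl_indices[0], "- peak P at", j)
print("peak P =", post.P[j], " logBF =", round(post.logbf[j], 1))
regions = bq.call_regions(post.to_frame())
print([(r.chromosome, r.start_bp, r.end_bp, r.evidence_class) for r in regions])
```

prints

```
planted QTL at marker 814 - peak P at 814
peak P = 1.0  logBF = 32.6
[('1', 80282590, 80282590, 'major')]
```

The sampler puts the inclusion peak exactly on the planted QTL; with the
chain's 15,000 kept samples, P = 1 caps to 1 − 1/(2·15000), giving the finite
logBF of 32.6, and the caller reports one major-evidence point region at that
marker's position.

The same steps run from the shell: `bayesqtl simulate`, `bayesqtl qc`,
`bayesqtl fit`, `bayesqtl call`, `bayesqtl compare`, `bayesqtl annotate`, or
`bayesqtl all` for the full chain; every artifact gets a `.run.json` manifest
with the config hash and seed.

The package also ships the published reference tables for Blonde d'Aquitaine
maternal traits (major QTL intervals, common regions, candidate-gene
footprints, UMD 3.1 coordinates) under `bayesqtl.datasets`, which the
comparison and annotation stages use as worked inputs — e.g. intersecting the
udder-swelling and milk-yield chromosome-6 regions recovers the reported
common interval ending at 88.959 Mb, with the GC (vitamin-D-binding protein)
gene inside it.

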