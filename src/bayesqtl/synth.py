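"""Synthetic genotype/phenotype generator with the structure the analysis assumes.

The generator emulates a progeny-test population of beef cattle: roughly a
thousand animals in paternal half-sib families, dense SNP genotypes with
block-wise linkage disequilibrium, quantitative maternal traits with low to
moderate heritability, and deregressed-EBV style pseudo-phenotypes whose noise
shrinks with record reliability.  Genotypes arise from a haplotype
copy-with-mutation scheme: within each LD block a small founder-haplotype pool
is built by copying earlier haplotypes with a low per-site mutation rate, so
adjacent markers in a block are correlated while blocks are independent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeTable

# founder pool used for the copy-with-mutation haplotypes; the pool size
# bounds within-block diversity, the site-noise rate softens clade sharing
_N_FOUNDER_HAPLOTYPES = 32
_SITE_NOISE_RATE = 0.01


@dataclass
class SimConfig:
    """Knobs of the synthetic population.

    Defaults emulate a station progeny test: ~1,000 daughters of 78 sires,
    dense genotypes, a milk-yield-like trait (mean 5.54 kg, SD 1.39 kg,
    h2 = 0.35) with a handful of medium/large QTL on a polygenic background,
    and field-record reliabilities in the 0.05-0.33 range.
    """

    n_animals: int = 1000
    n_snps: int = 10_000
    n_chromosomes: int = 10
    chrom_length_mb: float = 100.0
    maf_min: float = 0.05
    maf_max: float = 0.5
    ld_block_len: int = 20
    n_sires: int = 78
    n_qtl: int = 10
    h2: float = 0.35
    qtl_var_fraction: float = 0.5
    reliability_min: float = 0.05
    reliability_max: float = 0.33
    missing_rate: float = 0.0
    seed: int = 2016
    trait_mean: float = 5.54
    trait_sd: float = 1.39
    qtl_effect_dist: str = "normal"  # "normal" | "gamma" | "equal"

    def __post_init__(self) -> None:
        for name in ("n_animals", "n_snps", "n_chromosomes", "ld_block_len", "n_sires"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.maf_min <= self.maf_max <= 0.5):
            raise ValueError("require 0 < maf_min <= maf_max <= 0.5")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0 <= self.qtl_var_fraction <= 1:
            raise ValueError("qtl_var_fraction must lie in [0, 1]")
        if self.n_qtl < 0 or self.n_qtl > self.n_snps:
            raise ValueError("need 0 <= n_qtl <= n_snps")
        if not (0 < self.reliability_min <= self.reliability_max < 1):
            raise ValueError("reliabilities must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.chrom_length_mb <= 0:
            raise ValueError("chrom_length_mb must be positive")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        if self.qtl_effect_dist not in {"normal", "gamma", "equal"}:
            raise ValueError("qtl_effect_dist must be 'normal', 'gamma' or 'equal'")


@dataclass
class SimulationTruth:
    """Planted ground truth used by recovery tests."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    sigma2_u_true: float
    sigma2_e_true: float
    true_breeding_values: np.ndarray

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.qtl_effects = np.asarray(self.qtl_effects, dtype=np.float64)
        if len(self.qtl_indices) != len(self.qtl_effects):
            raise ValueError("one effect per planted QTL required")
        if self.sigma2_u_true < 0:
            raise ValueError("genetic variance must be non-negative")
        if self.sigma2_e_true <= 0:
            raise ValueError("residual variance must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"qtl_index": self.qtl_indices, "effect": self.qtl_effects}
        )


def _marker_positions(rng: np.random.Generator, m: int, length_bp: int) -> np.ndarray:
    pos = np.sort(rng.integers(1, length_bp + 1, size=m))
    # enforce strict monotonicity (duplicate draws bumped forward)
    for i in range(1, m):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def _block_haplotype_pool(
    rng: np.random.Generator, blen: int, p_target: np.ndarray
) -> np.ndarray:
    """Founder haplotypes for one LD block by copy-with-mutation.

    A copy genealogy is built over the pool (haplotype k copies a random
    earlier one); each site's allele 1 is carried by the descendant clade of
    one branch, chosen so the clade size matches the site's target frequency.
    Nested clades give correlated adjacent markers; a little site-wise noise
    keeps identical columns rare.  Pool allele frequencies track ``p_target``.
    """
    K = _N_FOUNDER_HAPLOTYPES
    parent = np.zeros(K, dtype=np.int64)
    for k in range(1, K):
        parent[k] = rng.integers(0, k)
    clade = np.zeros((K, K), dtype=bool)  # clade[v, k]: k descends from v
    for k in range(K):
        v = k
        while True:
            clade[v, k] = True
            if v == 0:
                break
            v = parent[v]
    sizes = clade.sum(axis=1)

    pool = np.zeros((K, blen), dtype=np.int8)
    for s in range(blen):
        t = int(np.clip(round(K * p_target[s]), 1, K - 1))
        diffs = np.abs(sizes - t)
        candidates = np.flatnonzero(diffs == diffs.min())
        v = candidates[rng.integers(0, len(candidates))]
        pool[:, s] = clade[v]
    noise = rng.random((K, blen)) < _SITE_NOISE_RATE
    pool[noise] = 1 - pool[noise]
    return pool


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a half-sib genotype matrix with block LD.

    Returns an animals x markers matrix coded {-1, 0, +1} (NaN where missing),
    with a marker map strictly increasing within each chromosome.  Each
    animal's paternal haplotype comes from one of ``n_sires`` sires (block-wise
    recombination between the sire's two haplotypes); the maternal haplotype is
    drawn from the founder pool, emulating unrelated dams.
    """
    rng = np.random.default_rng((cfg.seed, 0))
    n, m = cfg.n_animals, cfg.n_snps

    # distribute markers over chromosomes as evenly as possible
    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes, dtype=int)
    per_chrom[: m % cfg.n_chromosomes] += 1
    length_bp = int(cfg.chrom_length_mb * 1_000_000)

    chroms, positions, marker_ids = [], [], []
    for c, mc in enumerate(per_chrom, start=1):
        pos = _marker_positions(rng, mc, length_bp)
        chroms.extend([str(c)] * mc)
        positions.append(pos)
        marker_ids.extend(f"snp_{c}_{p}" for p in pos)
    positions = np.concatenate(positions)

    sire_of = np.arange(n) % cfg.n_sires  # balanced half-sib families
    Z = np.empty((n, m), dtype=np.float64)

    col = 0
    for mc in per_chrom:
        for start in range(0, mc, cfg.ld_block_len):
            blen = min(cfg.ld_block_len, mc - start)
            p_target = rng.uniform(cfg.maf_min, cfg.maf_max, size=blen)
            pool = _block_haplotype_pool(rng, blen, p_target)

            # two pool haplotypes per sire for this block
            sire_haps = rng.integers(0, _N_FOUNDER_HAPLOTYPES, size=(cfg.n_sires, 2))
            # paternal gamete: pick one of the sire's two haplotypes per block
            gamete_choice = rng.integers(0, 2, size=n)
            pat = pool[sire_haps[sire_of, gamete_choice]]
            # maternal gamete: unrelated dam, random pool haplotype
            mat = pool[rng.integers(0, _N_FOUNDER_HAPLOTYPES, size=n)]

            Z[:, col : col + blen] = pat + mat - 1.0
            col += blen
    assert col == m

    if cfg.missing_rate > 0:
        Z[rng.random((n, m)) < cfg.missing_rate] = np.nan

    marker_map = pd.DataFrame(
        {"marker_id": marker_ids, "chrom": chroms, "pos_bp": positions}
    )
    animal_ids = np.array([f"animal_{i:05d}" for i in range(n)])
    return GenotypeMatrix(genotypes=Z, animal_ids=animal_ids, marker_map=marker_map)


def _draw_effects(rng: np.random.Generator, k: int, dist: str) -> np.ndarray:
    if dist == "normal":
        eff = rng.normal(size=k)
    elif dist == "gamma":
        eff = rng.gamma(0.4, 1.0, size=k) * rng.choice([-1.0, 1.0], size=k)
    else:  # equal
        eff = rng.choice([-1.0, 1.0], size=k)
    return eff


def _scaled(g: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Center g and scale its sample variance to target_var; returns (g, scale)."""
    g = g - g.mean()
    v = g.var()
    if target_var <= 0 or v <= 1e-12:
        return np.zeros_like(g), 0.0
    s = float(np.sqrt(target_var / v))
    return g * s, s


def simulate_traits(
    G: GenotypeMatrix, cfg: SimConfig
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Simulate a quantitative trait from planted QTL plus polygenic background.

    y = mu + z'a(QTL) + z'b(background) + e, with the genetic components scaled
    so the realized heritability Var(TBV)/Var(y) tracks ``cfg.h2`` and the
    planted QTL carry ``cfg.qtl_var_fraction`` of the genetic variance.
    Station-trait weights (all 1) are attached.
    """
    if cfg.h2 >= 1.0:
        raise ValueError("h2 = 1 leaves no residual variance; require h2 < 1")
    rng = np.random.default_rng((cfg.seed, 1))

    Z = G.genotypes
    if np.isnan(Z).any():
        col_mean = np.nanmean(Z, axis=0)
        Z = np.where(np.isnan(Z), col_mean, Z)

    var_total = cfg.trait_sd**2
    sigma2_u = cfg.h2 * var_total
    sigma2_e = (1.0 - cfg.h2) * var_total

    # plant QTL only on reasonably polymorphic markers so the scaled effects
    # stay finite and the signal is detectable
    freq = (Z.mean(axis=0) + 1.0) / 2.0
    eligible = np.flatnonzero((freq >= 0.05) & (freq <= 0.95))
    if len(eligible) < cfg.n_qtl:
        eligible = np.arange(G.n_markers)
    qtl_idx = np.sort(rng.choice(eligible, size=cfg.n_qtl, replace=False))
    raw_eff = _draw_effects(rng, cfg.n_qtl, cfg.qtl_effect_dist)
    g_qtl, qtl_scale = _scaled(
        Z[:, qtl_idx] @ raw_eff, sigma2_u * cfg.qtl_var_fraction
    )
    qtl_effects = raw_eff * qtl_scale

    bg_idx = np.setdiff1d(np.arange(G.n_markers), qtl_idx)
    bg_eff = rng.normal(size=len(bg_idx))
    g_poly, _ = _scaled(Z[:, bg_idx] @ bg_eff, sigma2_u * (1.0 - cfg.qtl_var_fraction))

    tbv = g_qtl + g_poly
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=G.n_animals)
    y = cfg.trait_mean + tbv + e

    phen = PhenotypeTable(
        animal_id=G.animal_ids.copy(),
        value=y,
        weight=np.ones(G.n_animals),
    )
    truth = SimulationTruth(
        qtl_indices=qtl_idx,
        qtl_effects=qtl_effects,
        sigma2_u_true=float(tbv.var()),
        sigma2_e_true=float(sigma2_e),
        true_breeding_values=tbv,
    )
    return phen, truth


def reliability_weight(r: np.ndarray) -> np.ndarray:
    """Residual weight w = r / (1 - r) attached to a record of reliability r."""
    r = np.asarray(r, dtype=np.float64)
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("reliability must lie in (0, 1)")
    return r / (1.0 - r)


def simulate_debv(
    truth: SimulationTruth,
    cfg: SimConfig,
    animal_ids: np.ndarray | None = None,
    reliabilities: np.ndarray | None = None,
) -> PhenotypeTable:
    """Deregressed-EBV style pseudo-phenotypes with reliability-derived weights.

    pseudo_i = TBV_i + noise_i with Var(noise_i) = sigma2_u (1 - r_i) / r_i, so
    the squared correlation with the true breeding value approaches r_i; the
    attached weight is r_i / (1 - r_i).
    """
    rng = np.random.default_rng((cfg.seed, 2))
    n = len(truth.true_breeding_values)
    if reliabilities is None:
        reliabilities = rng.uniform(cfg.reliability_min, cfg.reliability_max, size=n)
    r = np.asarray(reliabilities, dtype=np.float64)
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("reliability must lie in (0, 1)")

    base_var = truth.sigma2_u_true if truth.sigma2_u_true > 0 else 1.0
    noise_sd = np.sqrt(base_var * (1.0 - r) / r)
    pseudo = truth.true_breeding_values + rng.normal(size=n) * noise_sd

    if animal_ids is None:
        animal_ids = np.array([f"animal_{i:05d}" for i in range(n)])
    return PhenotypeTable(
        animal_id=np.asarray(animal_ids), value=pseudo, weight=reliability_weight(r)
    )


def my_combine(m60: float, m120: float) -> float:
    """Milk yield from weigh-suckle-weigh records at days 60 and 120.

    The lactation estimate weights the day-60 measurement by one-third and the
    day-120 measurement by two-thirds.
    """
    m60 = np.asarray(m60, dtype=np.float64)
    m120 = np.asarray(m120, dtype=np.float64)
    if np.any(m60 < 0) or np.any(m120 < 0):
        raise ValueError("milk measurements must be non-negative")
    out = m60 / 3.0 + 2.0 * m120 / 3.0
    return float(out) if out.ndim == 0 else out
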