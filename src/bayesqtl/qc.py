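"""Marker quality control: call-rate and Hardy-Weinberg equilibrium filters.

The editing rules mirror standard chip QC for cattle association studies:
markers are kept when their call rate is strictly above 90 % and when a 1-df
chi-square goodness-of-fit test against Hardy-Weinberg proportions gives
P > 1e-4.  Filters run in that order (call rate first, HWE on the surviving
non-missing calls) and are idempotent.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AlleleFrequencies, GenotypeMatrix

logger = logging.getLogger(__name__)

CALL_RATE_THRESHOLD = 0.90
HWE_P_THRESHOLD = 1e-4


def _genotype_counts(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker counts of (+1 homozygote, heterozygote, -1 homozygote)."""
    Z = G.genotypes
    n_hom1 = np.nansum(Z == 1.0, axis=0).astype(np.int64)
    n_het = np.nansum(Z == 0.0, axis=0).astype(np.int64)
    n_hom2 = np.nansum(Z == -1.0, axis=0).astype(np.int64)
    return n_hom1, n_het, n_hom2


def call_rate(G: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per marker."""
    return 1.0 - G.missing_mask().mean(axis=0)


def call_rate_filter(
    G: GenotypeMatrix, threshold: float = CALL_RATE_THRESHOLD
) -> GenotypeMatrix:
    """Keep markers whose call rate is strictly greater than ``threshold``.

    A marker observed in exactly 90 % of animals is removed at the default
    threshold: the rule is "call rate higher than" the cutoff, not "at least".
    """
    if not 0 < threshold <= 1:
        raise ValueError("call-rate threshold must lie in (0, 1]")
    if G.n_markers == 0 or G.n_animals == 0:
        raise ValueError("empty genotype matrix")
    rate = call_rate(G)
    keep = rate > threshold
    logger.info(
        "call-rate filter (> %.2f): kept %d of %d markers",
        threshold, int(keep.sum()), G.n_markers,
    )
    return G.subset_markers(keep)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square Hardy-Weinberg goodness-of-fit p-value.

    Observed genotype counts are compared with the proportions expected at the
    sample allele frequency (p^2, 2pq, q^2).  Monomorphic markers are in exact
    equilibrium by construction and return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotyped animal required")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=np.float64)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test_markers(G: GenotypeMatrix) -> np.ndarray:
    """Vector of HWE p-values, one per marker, on non-missing calls."""
    n_hom1, n_het, n_hom2 = _genotype_counts(G)
    return np.array(
        [hwe_test(a, h, b) for a, h, b in zip(n_hom1, n_het, n_hom2)]
    )


def hwe_filter(G: GenotypeMatrix, p_threshold: float = HWE_P_THRESHOLD) -> GenotypeMatrix:
    """Keep markers with HWE p-value strictly greater than ``p_threshold``."""
    if not 0 <= p_threshold < 1:
        raise ValueError("p_threshold must lie in [0, 1)")
    if G.n_markers == 0 or G.n_animals == 0:
        raise ValueError("empty genotype matrix")
    pvals = hwe_test_markers(G)
    keep = pvals > p_threshold
    logger.info(
        "HWE filter (p > %g): kept %d of %d markers",
        p_threshold, int(keep.sum()), G.n_markers,
    )
    return G.subset_markers(keep)


def allele_frequencies(G: GenotypeMatrix) -> AlleleFrequencies:
    """Allele-1 frequency per marker: (2 n_hom1 + n_het) / (2 n_called)."""
    n_hom1, n_het, n_hom2 = _genotype_counts(G)
    n_called = n_hom1 + n_het + n_hom2
    if np.any(n_called == 0):
        raise ValueError("marker with no non-missing calls")
    return AlleleFrequencies(p=(2 * n_hom1 + n_het) / (2 * n_called))


def qc_report(
    G: GenotypeMatrix,
    call_rate_threshold: float = CALL_RATE_THRESHOLD,
    hwe_p_threshold: float = HWE_P_THRESHOLD,
) -> pd.DataFrame:
    """Per-marker QC table: call rate, HWE p (post call-rate), kept flag.

    HWE p-values are reported for every marker but the kept flag applies the
    filters in pipeline order: markers failing call rate are dropped before
    the HWE criterion is considered.
    """
    rate = call_rate(G)
    pvals = hwe_test_markers(G)
    kept = (rate > call_rate_threshold) & (pvals > hwe_p_threshold)
    return pd.DataFrame(
        {
            "marker_id": G.marker_map["marker_id"].to_numpy(),
            "call_rate": rate,
            "hwe_p": pvals,
            "kept": kept,
        }
    )


def apply_qc(
    G: GenotypeMatrix,
    call_rate_threshold: float = CALL_RATE_THRESHOLD,
    hwe_p_threshold: float = HWE_P_THRESHOLD,
) -> GenotypeMatrix:
    """Run the full editing pipeline: call-rate filter, then HWE filter."""
    return hwe_filter(
        call_rate_filter(G, call_rate_threshold), hwe_p_threshold
    )
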