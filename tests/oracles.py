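"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively, from the documented rules, without reusing
the package's region caller, HWE test or sampler internals.
"""
from __future__ import annotations

import math

import numpy as np


def oracle_hwe_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Multinomial chi-square HWE p-value by direct hand computation.

    Expected genotype counts at the sample allele frequency, 1-df chi-square,
    and the tail probability via the complementary error function
    (P(X > x) = erfc(sqrt(x/2)) for a 1-df chi-square).
    """
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    e_AA, e_Aa, e_aa = n * p * p, 2 * n * p * q, n * q * q
    chi2 = (
        (n_AA - e_AA) ** 2 / e_AA
        + (n_Aa - e_Aa) ** 2 / e_Aa
        + (n_aa - e_aa) ** 2 / e_aa
    )
    return math.erfc(math.sqrt(chi2 / 2.0))


def oracle_ridge_posterior_mean(Z, y, w, sigma2_a, sigma2_e):
    """Closed-form joint posterior mean of (mu, a) when every marker is in.

    Solves the weighted ridge normal equations with an unpenalized intercept:
    [[1'W1, 1'WZ], [Z'W1, Z'WZ + (sigma2_e/sigma2_a) I]] [mu; a] = [1'Wy; Z'Wy].
    """
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    W = np.diag(np.asarray(w, dtype=float))
    X = np.hstack([np.ones((n, 1)), Z])
    lhs = X.T @ W @ X
    ridge = np.zeros(m + 1)
    ridge[1:] = sigma2_e / sigma2_a
    lhs += np.diag(ridge)
    rhs = X.T @ W @ np.asarray(y, dtype=float)
    sol = np.linalg.solve(lhs, rhs)
    return sol[0], sol[1:]


def oracle_call_regions(rows, peak_threshold=8.0, extension_threshold=3.0,
                        window_mb=0.5):
    """Step-by-step sliding-window region simulation.

    ``rows``: iterable of (chrom, pos_bp, logbf).  Returns a list of dicts
    with chrom, start, end, peak, peak_logbf, members (set of positions with
    logbf above the extension threshold absorbed into the region, plus any
    merged peaks).
    """
    window = window_mb * 1e6
    by_chrom: dict = {}
    for chrom, bp, lbf in rows:
        by_chrom.setdefault(chrom, []).append((bp, lbf))

    all_regions = []
    for chrom, markers in by_chrom.items():
        markers = sorted(markers)
        peaks = sorted(
            [(bp, l) for bp, l in markers if l > peak_threshold],
            key=lambda t: (-t[1], t[0]),
        )
        taken: set = set()
        regions: list[dict] = []
        for bp0, lbf0 in peaks:
            if bp0 in taken:
                for reg in regions:
                    if reg["start"] <= bp0 <= reg["end"]:
                        reg["members"].add(bp0)
                        break
                continue
            host = None
            for reg in regions:
                if reg["start"] <= bp0 <= reg["end"]:
                    host = reg
                    break
            if host is not None:
                host["members"].add(bp0)
                taken.add(bp0)
                continue

            members = {bp0}
            frontier = bp0
            while True:
                qual = [
                    bp for bp, l in markers
                    if frontier < bp <= frontier + window and l > extension_threshold
                ]
                if not qual:
                    break
                members.update(qual)
                frontier = max(qual)
            frontier = bp0
            while True:
                qual = [
                    bp for bp, l in markers
                    if frontier - window <= bp < frontier and l > extension_threshold
                ]
                if not qual:
                    break
                members.update(qual)
                frontier = min(qual)

            taken.update(members)
            regions.append(
                {
                    "chrom": chrom,
                    "start": min(members),
                    "end": max(members),
                    "peak": bp0,
                    "peak_logbf": lbf0,
                    "members": members,
                }
            )
        all_regions.extend(regions)
    all_regions.sort(key=lambda r: (str(r["chrom"]), r["start"]))
    return all_regions


def random_logbf_track(rng: np.random.Generator, max_markers: int = 200):
    """A random synthetic per-marker logBF track for oracle comparisons.

    Mostly near-zero evidence with occasional spikes so that peaks, extension
    markers and merges all occur.
    """
    n = int(rng.integers(5, max_markers + 1))
    n_chrom = int(rng.integers(1, 4))
    rows = []
    for _ in range(n):
        chrom = str(rng.integers(1, n_chrom + 1))
        bp = int(rng.integers(1, 20_000_000))
        u = rng.random()
        if u < 0.6:
            lbf = float(rng.uniform(0, 3))
        elif u < 0.85:
            lbf = float(rng.uniform(3, 8))
        else:
            lbf = float(rng.uniform(8, 18))
        rows.append((chrom, bp, lbf))
    # deduplicate positions per chromosome
    seen = set()
    out = []
    for chrom, bp, lbf in rows:
        if (chrom, bp) in seen:
            continue
        seen.add((chrom, bp))
        out.append((chrom, bp, lbf))
    return out
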