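"""Bayes-Factor evidence scoring and sliding-window QTL region calling.

Evidence for a marker is the Bayes Factor BF = (P/(1-P)) / (pi/(1-pi)), the
posterior odds of inclusion over the prior odds, reported on the logBF =
2 ln(BF) scale so values are comparable to deviance / likelihood-ratio
statistics.  Peaks with logBF above 8 are QTL (above 12, major evidence;
between 6 and 8, putative).  Around each peak the region grows by a sliding
0.5 Mb window: while at least one marker with logBF > 3 lies within 0.5 Mb
beyond the current frontier, the frontier jumps to the outermost such marker
and all qualifying markers passed are absorbed; the region bounds are the
positions of the last absorbed markers.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import QTLRegion, chrom_sort_key

PEAK_LOGBF_THRESHOLD = 8.0
MAJOR_LOGBF_THRESHOLD = 12.0
PUTATIVE_LOGBF_THRESHOLD = 6.0
EXTENSION_LOGBF_THRESHOLD = 3.0
WINDOW_MB = 0.5

_CLASS_ORDER = {"none": 0, "putative": 1, "qtl": 2, "major": 3}


def cap_inclusion_prob(P, n_samples: int):
    """Bound inclusion probabilities away from 0 and 1 before the BF formula.

    With S kept samples an empirical P of exactly 0 or 1 only says the event
    fell outside the chain's resolution; capping to [1/(2S), 1 - 1/(2S)] keeps
    evidence values finite and reflective of the sample size.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    eps = 1.0 / (2.0 * n_samples)
    return np.clip(np.asarray(P, dtype=np.float64), eps, 1.0 - eps)


def bayes_factor(P, pi: float):
    """Posterior odds of inclusion over prior odds."""
    if not 0 < pi < 1:
        raise ValueError("pi must lie in (0, 1)")
    P = np.asarray(P, dtype=np.float64)
    if np.any((P < 0) | (P >= 1)):
        raise ValueError("P must lie in [0, 1); cap P = 1 first")
    out = (P / (1.0 - P)) / (pi / (1.0 - pi))
    return float(out) if out.ndim == 0 else out


def log_bf(bf):
    """logBF = 2 ln(BF); non-positive BF maps to -inf."""
    bf = np.asarray(bf, dtype=np.float64)
    out = np.where(bf > 0, 2.0 * np.log(np.where(bf > 0, bf, 1.0)), -np.inf)
    return float(out) if out.ndim == 0 else out


def bf_from_logbf(logbf):
    """Inverse of :func:`log_bf`: BF = exp(logBF / 2)."""
    out = np.exp(np.asarray(logbf, dtype=np.float64) / 2.0)
    return float(out) if out.ndim == 0 else out


def expected_selected_count(pi: float, n_snps: int) -> int:
    """Number of SNP expected in the model at each iteration: round(pi * n)."""
    if n_snps < 0:
        raise ValueError("n_snps must be non-negative")
    if not 0 <= pi <= 1:
        raise ValueError("pi must lie in [0, 1]")
    return int(np.floor(pi * n_snps + 0.5))


def classify_evidence(peak_logbf: float) -> str:
    """Evidence class of a peak: major (>12), qtl (>8), putative (>6), none.

    All thresholds are strict, so a peak at exactly 8.0 is putative and one at
    exactly 12.0 is qtl.
    """
    if not np.isfinite(peak_logbf):
        if peak_logbf == -np.inf:
            return "none"
        raise ValueError("peak logBF must be finite")
    if peak_logbf > MAJOR_LOGBF_THRESHOLD:
        return "major"
    if peak_logbf > PEAK_LOGBF_THRESHOLD:
        return "qtl"
    if peak_logbf > PUTATIVE_LOGBF_THRESHOLD:
        return "putative"
    return "none"


def _grow(
    pos: np.ndarray,
    qualifies: np.ndarray,
    peak_idx: int,
    window_bp: float,
    direction: int,
) -> list[int]:
    """Absorb qualifying markers by sliding the window beyond the frontier.

    Window is (frontier, frontier + window_bp] downstream or the mirror
    upstream; the frontier jumps to the outermost qualifying marker found and
    every qualifying marker passed on the way is absorbed.
    """
    absorbed: list[int] = []
    frontier = pos[peak_idx]
    n = len(pos)
    j = peak_idx
    while True:
        found: list[int] = []
        if direction > 0:
            k = j + 1
            while k < n and pos[k] <= frontier + window_bp:
                if qualifies[k]:
                    found.append(k)
                k += 1
        else:
            k = j - 1
            while k >= 0 and pos[k] >= frontier - window_bp:
                if qualifies[k]:
                    found.append(k)
                k -= 1
        if not found:
            break
        j = found[-1]  # outermost qualifying marker
        absorbed.extend(found)
        frontier = pos[j]
    return absorbed


def call_regions(
    track: pd.DataFrame,
    peak_threshold: float = PEAK_LOGBF_THRESHOLD,
    extension_threshold: float = EXTENSION_LOGBF_THRESHOLD,
    window_mb: float = WINDOW_MB,
    max_P: np.ndarray | None = None,
) -> list[QTLRegion]:
    """Call QTL regions from a per-marker logBF track.

    ``track`` needs columns ``chrom``, ``pos_bp``, ``logbf`` and optionally
    ``marker_id`` and ``P``.  Markers are sorted internally; duplicate
    (chrom, pos_bp) pairs are an error.  Candidate peaks (logBF above
    ``peak_threshold``) are processed in decreasing logBF order (ties broken
    by position); each unconsumed peak grows independently upstream and
    downstream by the sliding-window rule, absorbing markers with logBF above
    ``extension_threshold``.  Markers absorbed into a region cannot seed
    another one, and a lower peak landing inside an already-called region is
    merged into it.
    """
    if peak_threshold <= 0 or extension_threshold <= 0 or window_mb <= 0:
        raise ValueError("thresholds and window must be positive")
    required = {"chrom", "pos_bp", "logbf"}
    if not required.issubset(track.columns):
        raise ValueError(f"track needs columns {sorted(required)}")
    df = track.copy()
    if "marker_id" not in df.columns:
        df["marker_id"] = [
            f"{c}:{p}" for c, p in zip(df["chrom"], df["pos_bp"])
        ]
    df["_ckey"] = df["chrom"].map(chrom_sort_key)
    df = df.sort_values(["_ckey", "pos_bp"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(subset=["chrom", "pos_bp"]).any():
        raise ValueError("duplicate (chrom, pos_bp) in track")

    window_bp = window_mb * 1e6
    regions: list[QTLRegion] = []

    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        logbf = sub["logbf"].to_numpy(dtype=np.float64)
        ids = sub["marker_id"].to_numpy()
        pvals = sub["P"].to_numpy(dtype=np.float64) if "P" in sub.columns else None
        qualifies = logbf > extension_threshold
        consumed = np.zeros(len(pos), dtype=bool)

        cand = np.flatnonzero(logbf > peak_threshold)
        # decreasing logBF, ties by position
        cand = cand[np.lexsort((pos[cand], -logbf[cand]))]

        chrom_regions: list[dict] = []
        for idx in cand:
            if consumed[idx]:
                for reg in chrom_regions:
                    if reg["start"] <= pos[idx] <= reg["end"]:
                        reg["members"].add(int(idx))
                        break
                continue
            merged = False
            for reg in chrom_regions:
                if reg["start"] <= pos[idx] <= reg["end"]:
                    reg["members"].add(int(idx))
                    consumed[idx] = True
                    merged = True
                    break
            if merged:
                continue

            down = _grow(pos, qualifies, idx, window_bp, +1)
            up = _grow(pos, qualifies, idx, window_bp, -1)
            members = {int(idx), *map(int, down), *map(int, up)}
            for k in members:
                consumed[k] = True
            mpos = [pos[k] for k in members]
            chrom_regions.append(
                {
                    "start": min(mpos),
                    "end": max(mpos),
                    "peak": int(idx),
                    "members": members,
                }
            )

        for reg in chrom_regions:
            members = sorted(reg["members"], key=lambda k: pos[k])
            peak = reg["peak"]
            regions.append(
                QTLRegion(
                    chromosome=str(chrom),
                    start_bp=int(reg["start"]),
                    end_bp=int(reg["end"]),
                    peak_bp=int(pos[peak]),
                    peak_logbf=float(logbf[peak]),
                    evidence_class=classify_evidence(float(logbf[peak])),
                    member_markers=[str(ids[k]) for k in members],
                    max_P=float(np.max(pvals[list(members)]))
                    if pvals is not None
                    else float("nan"),
                )
            )

    regions.sort(key=lambda r: (chrom_sort_key(r.chromosome), r.start_bp))
    return regions


def regions_to_frame(regions: list[QTLRegion], trait: str = "") -> pd.DataFrame:
    """Tabular view of called regions with Mb coordinates to 6 decimals."""
    return pd.DataFrame(
        {
            "trait": trait,
            "chrom": [r.chromosome for r in regions],
            "start_mb": [round(r.start_bp / 1e6, 6) for r in regions],
            "end_mb": [round(r.end_bp / 1e6, 6) for r in regions],
            "peak_mb": [round(r.peak_bp / 1e6, 6) for r in regions],
            "peak_logbf": [r.peak_logbf for r in regions],
            "evidence_class": [r.evidence_class for r in regions],
            "n_members": [len(r.member_markers) for r in regions],
            "max_P": [r.max_P for r in regions],
        }
    )
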