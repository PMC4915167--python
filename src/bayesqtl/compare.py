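"""Cross-trait comparison of QTL regions and gene-interval annotation.

Traits recorded for the same maternal performance (calving or suckling) are
compared by intersecting their called QTL intervals on each chromosome: a
region supported by two or three traits is far less likely to be a false
positive, and the common region narrows the search space for candidate genes.
Overlap is on closed intervals of SNP positions; a shared boundary SNP counts
as overlap.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CommonRegion, GeneInterval, QTLRegion, chrom_sort_key

_CLASS_RANK = {"none": 0, "putative": 1, "qtl": 2, "major": 3}


def filter_by_evidence(regions: list[QTLRegion], min_class: str = "qtl") -> list[QTLRegion]:
    """Keep regions whose evidence class is at least ``min_class``."""
    if min_class not in _CLASS_RANK:
        raise ValueError(f"unknown evidence class {min_class!r}")
    floor = _CLASS_RANK[min_class]
    return [r for r in regions if _CLASS_RANK[r.evidence_class] >= floor]


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def common_regions(
    regions_a: list[QTLRegion],
    regions_b: list[QTLRegion],
    traits: tuple[str, str] = ("trait_a", "trait_b"),
    min_class: str = "qtl",
) -> list[CommonRegion]:
    """Intersect two traits' QTL regions.

    Every pair of same-chromosome regions with a non-empty overlap yields one
    record with the intersection [max(starts), min(ends)] and both peak
    positions; a region overlapping two regions of the other trait yields two
    records.
    """
    ra = filter_by_evidence(regions_a, min_class)
    rb = filter_by_evidence(regions_b, min_class)
    out: list[CommonRegion] = []
    for a in ra:
        for b in rb:
            if a.chromosome != b.chromosome:
                continue
            if not _overlaps(a.start_bp, a.end_bp, b.start_bp, b.end_bp):
                continue
            out.append(
                CommonRegion(
                    traits=traits,
                    chromosome=a.chromosome,
                    start_bp=max(a.start_bp, b.start_bp),
                    end_bp=min(a.end_bp, b.end_bp),
                    peak_bp_by_trait={traits[0]: a.peak_bp, traits[1]: b.peak_bp},
                )
            )
    out.sort(key=lambda r: (chrom_sort_key(r.chromosome), r.start_bp))
    return out


def venn_counts(
    regions_by_trait: dict[str, list[QTLRegion]],
    reference: str | None = None,
    min_class: str = "qtl",
) -> dict[str, int]:
    """Reference-trait oriented Venn cells for three traits.

    Counts how many of the reference trait's regions overlap none of the other
    two traits' regions, exactly one of them (per trait), or both.  Overlap is
    a non-empty closed-interval intersection on the same chromosome.
    """
    if len(regions_by_trait) != 3:
        raise ValueError("exactly three traits required")
    traits = list(regions_by_trait)
    if reference is None:
        reference = traits[0]
    if reference not in regions_by_trait:
        raise ValueError(f"reference trait {reference!r} not among inputs")
    others = [t for t in traits if t != reference]

    ref_regions = filter_by_evidence(regions_by_trait[reference], min_class)
    other_regions = {
        t: filter_by_evidence(regions_by_trait[t], min_class) for t in others
    }

    counts = {
        "reference": 0,
        "none": 0,
        f"with_{others[0]}": 0,
        f"with_{others[1]}": 0,
        "with_both": 0,
    }
    for r in ref_regions:
        counts["reference"] += 1
        hit = [
            any(
                o.chromosome == r.chromosome
                and _overlaps(r.start_bp, r.end_bp, o.start_bp, o.end_bp)
                for o in other_regions[t]
            )
            for t in others
        ]
        if all(hit):
            counts["with_both"] += 1
        elif hit[0]:
            counts[f"with_{others[0]}"] += 1
        elif hit[1]:
            counts[f"with_{others[1]}"] += 1
        else:
            counts["none"] += 1
    return counts


def annotate_genes(
    regions: list[QTLRegion] | list[CommonRegion],
    genes: list[GeneInterval],
) -> list[dict]:
    """Annotate each region with overlapping genes, or the nearest gene.

    Returns one record per region: the genes whose footprint overlaps the
    interval and, when none overlaps, the nearest non-overlapping gene on the
    same chromosome with its distance in Mb (3 decimals).
    """
    records: list[dict] = []
    for region in regions:
        chrom = region.chromosome
        start, end = region.start_bp, region.end_bp
        overlapping = [
            g
            for g in genes
            if g.chromosome == chrom and _overlaps(start, end, g.start_bp, g.end_bp)
        ]
        rec = {
            "chromosome": chrom,
            "start_bp": start,
            "end_bp": end,
            "overlapping_genes": sorted(g.gene_symbol for g in overlapping),
            "nearest_gene": None,
            "nearest_distance_mb": None,
        }
        if not overlapping:
            same_chrom = [g for g in genes if g.chromosome == chrom]
            if same_chrom:
                def gap(g: GeneInterval) -> int:
                    if g.end_bp < start:
                        return start - g.end_bp
                    return g.start_bp - end

                nearest = min(same_chrom, key=gap)
                rec["nearest_gene"] = nearest.gene_symbol
                rec["nearest_distance_mb"] = round(gap(nearest) / 1e6, 3)
        records.append(rec)
    return records


def peak_distance(
    chrom_a: str, peak_bp_a: float, chrom_b: str, peak_bp_b: float
) -> float:
    """Distance in Mb between two peak SNPs on the same chromosome."""
    if str(chrom_a) != str(chrom_b):
        raise ValueError("peaks lie on different chromosomes")
    return abs(float(peak_bp_a) - float(peak_bp_b)) / 1e6


def common_regions_to_frame(commons: list[CommonRegion]) -> pd.DataFrame:
    """Tabular view mirroring a common-QTL table (Mb, 6 decimals)."""
    rows = []
    for c in commons:
        t1, t2 = c.traits
        rows.append(
            {
                "traits": f"{t1} - {t2}",
                "chrom": c.chromosome,
                "start_mb": round(c.start_bp / 1e6, 6),
                "end_mb": round(c.end_bp / 1e6, 6),
                f"peak_mb_{t1}": round(c.peak_bp_by_trait[t1] / 1e6, 6),
                f"peak_mb_{t2}": round(c.peak_bp_by_trait[t2] / 1e6, 6),
            }
        )
    return pd.DataFrame(rows)
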