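"""Published reference coordinates shipped with the package.

Small tables of QTL intervals, common regions and candidate genes reported
for maternal performance traits in Blonde d'Aquitaine beef cattle (UMD 3.1
assembly coordinates).  They serve as worked-example inputs for the interval
comparison and annotation stages and as fixtures for regression tests; they
are printed summaries, not raw data.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .calling import classify_evidence
from .containers import GeneInterval, QTLRegion

#: Analysis constants of the published high-density analysis: prior inclusion
#: fraction and the number of SNP retained after QC on the HD chip.
HD_PI = 0.00025
HD_N_SNPS = 706_791

#: The two distinct peak SNPs (Mb, chromosome 6) jointly integrated by the
#: suckling-trait QTL regions around the GC gene.
SUCKLING_CHR6_DUAL_PEAKS_MB = (88.745, 88.922)


def _read(name: str) -> pd.DataFrame:
    with resources.files("bayesqtl.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_major_qtl_table() -> pd.DataFrame:
    """Major-evidence QTL (logBF > 12) per trait, Mb coordinates."""
    return _read("major_qtl_regions.tsv")


def load_major_qtl_regions(trait: str | None = None) -> list[QTLRegion]:
    """Major QTL as :class:`QTLRegion` objects (positions converted to bp)."""
    df = load_major_qtl_table()
    if trait is not None:
        df = df[df["trait"] == trait]
    return [
        QTLRegion(
            chromosome=str(r.chrom),
            start_bp=int(round(r.start_mb * 1e6)),
            end_bp=int(round(r.end_mb * 1e6)),
            peak_bp=int(round(r.peak_mb * 1e6)),
            peak_logbf=float(r.peak_logbf),
            evidence_class=classify_evidence(float(r.peak_logbf)),
        )
        for r in df.itertuples(index=False)
    ]


def load_common_region_table() -> pd.DataFrame:
    """Reported common QTL regions for trait pairs, with both peak positions."""
    return _read("common_qtl_regions.tsv")


def load_candidate_genes() -> list[GeneInterval]:
    """Candidate gene footprints proposed within the reported QTL regions."""
    df = _read("candidate_genes.tsv")
    return [
        GeneInterval(
            gene_symbol=str(r.gene_symbol),
            chromosome=str(r.chrom),
            start_bp=int(round(r.start_mb * 1e6)),
            end_bp=int(round(r.end_mb * 1e6)),
            strand=str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]
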