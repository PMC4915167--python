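"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as a TSV matrix (header = marker ids, first column = animal
id, cells in dosage coding 0/1/2 with NA for missing) or as PLINK-RAW style
dosages; the marker map as a PLINK .map-like 4-column TSV.  Internally the
dosage d is converted to the association coding z = d - 1.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    GeneInterval,
    GenotypeMatrix,
    PhenotypeTable,
    QTLRegion,
)
from .calling import classify_evidence, regions_to_frame
from .compare import CommonRegion, common_regions_to_frame
from .synth import SimulationTruth


# --- genotypes -----------------------------------------------------------

def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    """Dosage matrix TSV: header marker ids, first column animal_id, 0/1/2/NA."""
    dosage = G.genotypes + 1.0
    df = pd.DataFrame(
        dosage, columns=G.marker_map["marker_id"].to_numpy()
    )
    df.insert(0, "animal_id", G.animal_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_genotypes_tsv(genotype_path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(genotype_path, sep="\t", na_values=["NA"])
    marker_map = read_map(map_path)
    animal_ids = df["animal_id"].to_numpy()
    markers = marker_map["marker_id"].to_numpy()
    Z = df[markers].to_numpy(dtype=np.float64) - 1.0
    return GenotypeMatrix(genotypes=Z, animal_ids=animal_ids, marker_map=marker_map)


def write_map(G_or_map, path) -> None:
    """PLINK .map-style 4-column TSV: chrom, marker_id, cM placeholder 0, bp."""
    mm = G_or_map.marker_map if isinstance(G_or_map, GenotypeMatrix) else G_or_map
    out = pd.DataFrame(
        {
            "chrom": mm["chrom"],
            "marker_id": mm["marker_id"],
            "cm": 0,
            "pos_bp": mm["pos_bp"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_map(path) -> pd.DataFrame:
    mm = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "marker_id", "cm", "pos_bp"],
        dtype={"chrom": str},
    )
    return mm[["marker_id", "chrom", "pos_bp"]]


def write_plink_raw(G: GenotypeMatrix, path) -> None:
    """PLINK --recode A compatible dosage export (space-separated)."""
    dosage = G.genotypes + 1.0
    cols = [f"{mid}_1" for mid in G.marker_map["marker_id"]]
    df = pd.DataFrame(dosage, columns=cols)
    for name, value in (
        ("PHENOTYPE", -9), ("SEX", 0), ("MAT", 0), ("PAT", 0),
    ):
        df.insert(0, name, value)
    df.insert(0, "IID", G.animal_ids)
    df.insert(0, "FID", G.animal_ids)
    df.to_csv(path, sep=" ", index=False, na_rep="NA", float_format="%.6g")


# --- phenotypes and truth ------------------------------------------------

def write_phenotypes(phen: PhenotypeTable, path) -> None:
    phen.to_frame().to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    return PhenotypeTable(
        animal_id=df["animal_id"].to_numpy(),
        value=df["value"].to_numpy(),
        weight=df["weight"].to_numpy(),
    )


def write_truth(truth: SimulationTruth, animal_ids, prefix) -> None:
    """Two TSVs: <prefix>.qtl.tsv (planted QTL) and <prefix>.tbv.tsv (breeding values)."""
    qtl = truth.to_frame()
    qtl["sigma2_u_true"] = truth.sigma2_u_true
    qtl["sigma2_e_true"] = truth.sigma2_e_true
    qtl.to_csv(f"{prefix}.qtl.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"animal_id": animal_ids, "tbv": truth.true_breeding_values}
    ).to_csv(f"{prefix}.tbv.tsv", sep="\t", index=False)


# --- posterior and regions ----------------------------------------------

def write_posterior(posterior, path) -> None:
    posterior.to_frame().to_csv(path, sep="\t", index=False)


def read_posterior_track(path) -> pd.DataFrame:
    """Per-marker track (marker_id, chrom, pos_bp, P, logbf ...) for region calling."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_regions_tsv(regions: list[QTLRegion], path, trait: str = "") -> None:
    regions_to_frame(regions, trait=trait).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path) -> list[QTLRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            QTLRegion(
                chromosome=str(row.chrom),
                start_bp=int(round(row.start_mb * 1e6)),
                end_bp=int(round(row.end_mb * 1e6)),
                peak_bp=int(round(row.peak_mb * 1e6)),
                peak_logbf=float(row.peak_logbf),
                evidence_class=str(row.evidence_class),
            )
        )
    return out


def write_regions_bed(regions: list[QTLRegion], path, trait: str = "") -> None:
    """BED export: 0-based half-open, so start_bp-1 / end_bp at the boundary."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"{trait or 'qtl'}_{r.chromosome}_{r.peak_bp}"
            fh.write(
                f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\t"
                f"{r.peak_logbf:.3f}\t.\n"
            )


def write_common_regions(commons: list[CommonRegion], path) -> None:
    common_regions_to_frame(commons).to_csv(path, sep="\t", index=False)


def write_common_regions_bed(commons: list[CommonRegion], path) -> None:
    with open(path, "w") as fh:
        for c in commons:
            name = "-".join(c.traits)
            fh.write(f"{c.chromosome}\t{c.start_bp - 1}\t{c.end_bp}\t{name}\n")


def write_venn(counts: dict, path) -> None:
    pd.DataFrame([counts]).to_csv(path, sep="\t", index=False)


# --- gene intervals ------------------------------------------------------

def read_genes_bed(path) -> list[GeneInterval]:
    """Gene intervals from BED (0-based half-open converted to 1-based closed)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6), dtype={"chrom": str},
    )
    genes = []
    for row in df.itertuples(index=False):
        strand = row.strand if row.strand in ("+", "-") else "."
        genes.append(
            GeneInterval(
                gene_symbol=str(row.name),
                chromosome=str(row.chrom),
                start_bp=int(row.start) + 1,
                end_bp=int(row.end),
                strand=strand,
            )
        )
    return _sorted_genes(genes)


def read_genes_gff3(path) -> list[GeneInterval]:
    """Gene features from a GFF3 file (``gene`` records only)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        symbol = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        genes.append(
            GeneInterval(
                gene_symbol=symbol,
                chromosome=str(feat.seqid),
                start_bp=int(feat.start),
                end_bp=int(feat.end),
                strand=feat.strand if feat.strand in ("+", "-") else ".",
            )
        )
    return _sorted_genes(genes)


def _sorted_genes(genes: list[GeneInterval]) -> list[GeneInterval]:
    from .containers import chrom_sort_key

    return sorted(genes, key=lambda g: (chrom_sort_key(g.chromosome), g.start_bp))
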