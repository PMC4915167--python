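"""Core data containers shared across the pipeline.

Genotypes use the association-model coding: z = +1 for the homozygote of
allele 1, 0 for the heterozygote, -1 for the other homozygote.  Missing calls
are stored as NaN in a float matrix so that downstream stages must impute
explicitly before model fitting.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

VALID_CODES = (-1.0, 0.0, 1.0)


def chrom_sort_key(chrom) -> tuple:
    """Order chromosome labels numerically when possible ('2' before '10')."""
    s = str(chrom)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


@dataclass
class GenotypeMatrix:
    """Animals x markers genotype matrix with a physical marker map.

    Parameters
    ----------
    genotypes
        Float array of shape (n_animals, n_markers) with entries in
        {-1, 0, +1} or NaN for missing calls (continuous dosages appear only
        after mean imputation).
    animal_ids
        One identifier per row.
    marker_map
        DataFrame with columns ``marker_id``, ``chrom``, ``pos_bp`` sorted by
        (chromosome, position), one row per genotype column.
    """

    genotypes: np.ndarray
    animal_ids: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.float64)
        self.animal_ids = np.asarray(self.animal_ids)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D animals x markers array")
        n, m = self.genotypes.shape
        if len(self.animal_ids) != n:
            raise ValueError(f"{len(self.animal_ids)} animal ids for {n} rows")
        required = {"marker_id", "chrom", "pos_bp"}
        if not required.issubset(self.marker_map.columns):
            raise ValueError(f"marker_map must have columns {sorted(required)}")
        if len(self.marker_map) != m:
            raise ValueError(f"{len(self.marker_map)} map rows for {m} markers")
        self.marker_map = self.marker_map.reset_index(drop=True)
        keys = [
            (chrom_sort_key(c), p)
            for c, p in zip(self.marker_map["chrom"], self.marker_map["pos_bp"])
        ]
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError(
                "marker_map must be strictly sorted by (chrom, pos_bp)"
            )

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.genotypes)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the marker columns in ``keep`` (bool or index)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, keep].copy(),
            animal_ids=self.animal_ids.copy(),
            marker_map=self.marker_map.iloc[keep].reset_index(drop=True),
        )


@dataclass
class PhenotypeTable:
    """Per-animal trait records with residual weights.

    ``weight`` is 1 for station traits; for deregressed-EBV pseudo-phenotypes
    it is derived from the record reliability and enters the sampler through
    Var(e_i) = sigma2_e / w_i.
    """

    animal_id: np.ndarray
    value: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.animal_id = np.asarray(self.animal_id)
        self.value = np.asarray(self.value, dtype=np.float64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if not (len(self.animal_id) == len(self.value) == len(self.weight)):
            raise ValueError("animal_id, value, weight must be equal length")
        if len(np.unique(self.animal_id)) != len(self.animal_id):
            raise ValueError("one record per animal required")
        if not np.all(self.weight > 0):
            raise ValueError("weights must be strictly positive")

    def __len__(self) -> int:
        return len(self.value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal_id": self.animal_id, "value": self.value, "weight": self.weight}
        )


@dataclass
class AlleleFrequencies:
    """Per-marker allele-1 frequency computed on non-missing calls only."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class MarkerPosterior:
    """Per-marker posterior summaries from the variable-selection sampler."""

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    P: np.ndarray            # posterior inclusion probability
    mean_effect: np.ndarray  # posterior mean of a_j * delta_j
    bf: np.ndarray
    logbf: np.ndarray
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "P": self.P,
                "mean_effect": self.mean_effect,
                "bf": self.bf,
                "logbf": self.logbf,
            }
        )


@dataclass
class VarianceSummary:
    """Marker-captured genetic variance against the prior (preliminary) estimate."""

    sigma2_u_hat: float
    sigma2_u_prior: float
    fraction_captured: float


@dataclass
class QTLRegion:
    """A called QTL interval around a peak marker.

    Bounds are inclusive SNP positions in bp; ``member_markers`` are the ids
    of markers with logBF above the extension threshold that were absorbed
    into the region (the peak included).
    """

    chromosome: str
    start_bp: int
    end_bp: int
    peak_bp: int
    peak_logbf: float
    evidence_class: str
    member_markers: list = field(default_factory=list)
    max_P: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.start_bp <= self.peak_bp <= self.end_bp):
            raise ValueError("region must contain its peak")

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class CommonRegion:
    """Interval intersection of overlapping QTL regions from two traits."""

    traits: tuple
    chromosome: str
    start_bp: int
    end_bp: int
    peak_bp_by_trait: dict

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("empty intersection")


@dataclass
class GeneInterval:
    """A gene's genomic footprint used for region annotation."""

    gene_symbol: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("gene interval start must not exceed end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError("strand must be '+', '-' or '.'")
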