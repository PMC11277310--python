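"""Core containers shared across the pipeline.

Genotypes are held as a samples x variants matrix of small integers with the
standard additive coding: 0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate, -1 = missing. All genomic coordinates at module
boundaries are 1-based inclusive (VCF/GFF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass(frozen=True)
class VariantInfo:
    """A single biallelic variant."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")


@dataclass
class GenotypeMatrix:
    """Samples x variants genotype calls with variant metadata.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers.
    variants : pandas.DataFrame
        One row per variant with columns chrom, pos, id, ref, alt.
    calls : ndarray of int8, shape (n_samples, n_variants)
        Additive genotype codes; ``MISSING`` (-1) marks no-calls.
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            calls=self.calls[idx, :].copy(),
        )

    def take_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx].copy(),
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        unknown = [s for s in names if s not in lookup]
        if unknown:
            raise KeyError(f"unknown samples: {unknown}")
        return self.take_samples([lookup[s] for s in names])

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per variant from observed calls only."""
        obs = self.calls != MISSING
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, alt / denom, np.nan)

    def missing_rate_per_sample(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    def missing_rate_per_variant(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_variants)
        return (self.calls == MISSING).mean(axis=0)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its merged CDS intervals (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str
    gene_span: tuple[int, int]
    cds_intervals: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lo, hi = self.gene_span
        if hi < lo:
            raise ValueError(f"gene span reversed for {self.gene_id}")
        for a, b in self.cds_intervals:
            if not (lo <= a <= b <= hi):
                raise ValueError(
                    f"CDS interval ({a},{b}) outside gene span of {self.gene_id}"
                )


@dataclass(frozen=True)
class PetalMeasure:
    """Seven shape descriptors of one petal, in centimetre units.

    ``ratio`` is minor/major (<= 1); ``circularity`` is 4*pi*area/perimeter^2,
    1 for a perfect circle; ``eccentricity`` comes from the ellipse-equivalent
    second central moments of the region.
    """

    major_length_cm: float
    minor_length_cm: float
    area_cm2: float
    perimeter_cm: float
    eccentricity: float
    ratio: float
    circularity: float

    DESCRIPTORS = (
        "major_length_cm",
        "minor_length_cm",
        "area_cm2",
        "perimeter_cm",
        "eccentricity",
        "ratio",
        "circularity",
    )

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.DESCRIPTORS}


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge overlapping or touching 1-based inclusive intervals."""
    if not intervals:
        return ()
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for lo, hi in ordered[1:]:
        if lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return tuple((a, b) for a, b in merged)
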