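"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGE_EARLY = "early"
STAGE_ADULT = "adult"

#: allele pairs that cannot be resolved without strand information
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: ordered single-base allele pairs excluding the strand-ambiguous ones
UNAMBIGUOUS_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and (a, b) not in AMBIGUOUS_PAIRS
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with per-sample region and stage labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.  Units are
        arbitrary linear-scale expression (must be the same scale for the
        early and adult samples, since the developmental filter takes a
        ratio of means).
    samples
        DataFrame indexed by sample id with columns ``region`` (e.g. PFC,
        NAcc) and ``stage`` (``early`` = 0-18 months postnatal, ``adult`` =
        20-40 years).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"region", "stage"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")
        if not self.values.columns.equals(self.samples.index):
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("expression columns and sample metadata ids differ")
            self.samples = self.samples.loc[self.values.columns]
        bad = set(self.samples["stage"]) - {STAGE_EARLY, STAGE_ADULT}
        if bad:
            raise ValueError(f"unknown developmental stages: {sorted(bad)}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def region_samples(self, region: str, stage: str | None = None) -> pd.Index:
        """Sample ids belonging to *region*, optionally restricted to a stage."""
        mask = self.samples["region"] == region
        if stage is not None:
            mask &= self.samples["stage"] == stage
        ids = self.samples.index[mask]
        if len(ids) == 0:
            raise ValueError(f"no samples for region={region!r} stage={stage!r}")
        return ids

    def subset(self, region: str, stage: str | None = None) -> pd.DataFrame:
        """Expression values restricted to one region (and optionally stage)."""
        return self.values[self.region_samples(region, stage)]


#: columns every variant table must carry
VARIANT_COLUMNS = ("chrom", "pos", "effect_allele", "other_allele")


@dataclass
class GenotypeDosageMatrix:
    """Individuals-by-SNP effect-allele dosages in [0, 2], NaN = missing.

    ``dosages`` is indexed by individual id with one column per variant id;
    entries count copies of each variant's ``effect_allele`` as recorded in
    ``variants`` (indexed by variant id, columns chrom / pos /
    effect_allele / other_allele; positions are 1-based GRCh37-style).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table lacks columns: {sorted(missing)}")
        if not self.dosages.columns.equals(self.variants.index):
            if set(self.dosages.columns) != set(self.variants.index):
                raise ValueError("dosage columns and variant table ids differ")
            self.variants = self.variants.loc[self.dosages.columns]
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0) < 0 or np.nanmax(vals, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    def allele_frequency(self) -> pd.Series:
        """Per-variant effect-allele frequency from non-missing dosages."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0
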