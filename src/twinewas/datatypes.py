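"""Core in-memory containers for the twin-cohort methylation pipeline.

All matrices are pandas DataFrames with samples as *columns*; alignment
between tables is always by sample identifier, never by positional order.
Genomic positions are 1-based point coordinates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "TwinCohort",
    "GenotypeMatrix",
    "PhenotypeTable",
]

#: columns the probe annotation table must carry
ANNOTATION_COLUMNS = ("chrom", "pos", "nearest_gene", "tss_distance", "cpg_island", "unique")


def _autosomal(chrom: pd.Series) -> pd.Series:
    c = chrom.astype(str).str.removeprefix("chr")
    return ~c.isin(["X", "Y", "MT", "M"])


@dataclass
class MethylationMatrix:
    """Methylation beta values (probes x individuals) plus probe annotation.

    Betas are methylation fractions in [0, 1]; missing values are NaN.
    ``annotation`` is indexed by probe id with columns chrom, pos (1-based
    CpG coordinate), nearest_gene, tss_distance (bp), cpg_island (bool),
    unique (bool). An ``autosomal`` column is derived from chrom.
    """

    betas: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.betas.index.is_unique:
            dupes = self.betas.index[self.betas.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dupes[:5]}")
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in self.annotation.columns]
        if missing_cols:
            raise ValueError(f"annotation missing columns: {missing_cols}")
        if not self.betas.index.equals(self.annotation.index):
            if len(self.betas) != len(self.annotation) or not set(self.betas.index) == set(
                self.annotation.index
            ):
                raise ValueError("annotation rows do not match beta matrix probes")
            self.annotation = self.annotation.loc[self.betas.index]
        vals = self.betas.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value {vals[i, j]:g} out of [0,1] at probe "
                f"{self.betas.index[i]!r}, sample {self.betas.columns[j]!r}"
            )
        if "autosomal" not in self.annotation.columns:
            self.annotation = self.annotation.assign(autosomal=_autosomal(self.annotation["chrom"]))

    @property
    def probe_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.betas.columns

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.betas.loc[:, list(sample_ids)], self.annotation)

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        ids = list(probe_ids)
        return MethylationMatrix(self.betas.loc[ids], self.annotation.loc[ids])


@dataclass
class TwinCohort:
    """Per-individual sample sheet for a twin cohort.

    ``samples`` is indexed by individual id with columns family_id,
    zygosity (MZ/DZ/singleton), age (years), sex, chip_id, chip_position
    (ordinal within chip) and batch_id.
    """

    samples: pd.DataFrame

    REQUIRED = ("family_id", "zygosity", "age", "sex", "chip_id", "chip_position", "batch_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if not self.samples.index.is_unique:
            raise ValueError("duplicate individual ids in sample sheet")
        if (self.samples["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad = ~self.samples["zygosity"].isin(["MZ", "DZ", "singleton"])
        if bad.any():
            raise ValueError(f"unknown zygosity values: {self.samples.loc[bad, 'zygosity'].unique()}")
        for fam, grp in self.samples.groupby("family_id"):
            zyg = set(grp["zygosity"])
            if len(grp) == 2 and zyg == {"singleton"}:
                raise ValueError(f"family {fam} has 2 members marked singleton")
            if len(grp) == 2 and len(zyg) != 1:
                raise ValueError(f"family {fam} mixes zygosities {zyg}")
            if len(grp) > 2:
                raise ValueError(f"family {fam} has {len(grp)} members (max 2)")

    @property
    def individual_ids(self) -> pd.Index:
        return self.samples.index

    def twin_pairs(self, zygosity: str | None = None) -> list[tuple[str, str]]:
        """Co-twin id pairs, ordered (lower id, higher id) within pair."""
        pairs = []
        for _, grp in self.samples.groupby("family_id", sort=True):
            if len(grp) == 2 and grp["zygosity"].iloc[0] != "singleton":
                if zygosity is None or grp["zygosity"].iloc[0] == zygosity:
                    a, b = sorted(grp.index)
                    pairs.append((a, b))
        return pairs

    def subset(self, individual_ids) -> "TwinCohort":
        sub = self.samples.loc[list(individual_ids)].copy()
        # broken pairs become singletons for modelling purposes
        sizes = sub.groupby("family_id")["family_id"].transform("size")
        sub.loc[sizes == 1, "zygosity"] = "singleton"
        return TwinCohort(sub)


@dataclass
class GenotypeMatrix:
    """SNP dosages (SNPs x individuals) with a SNP map (chrom, pos, maf)."""

    dosages: pd.DataFrame
    snp_map: pd.DataFrame  # index snp_id; columns chrom, pos, maf

    def __post_init__(self) -> None:
        for col in ("chrom", "pos"):
            if col not in self.snp_map.columns:
                raise ValueError(f"snp map missing column {col!r}")
        if not self.dosages.index.equals(self.snp_map.index):
            if set(self.dosages.index) != set(self.snp_map.index):
                raise ValueError("snp map does not match dosage matrix")
            self.snp_map = self.snp_map.loc[self.dosages.index]
        vals = self.dosages.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if "maf" not in self.snp_map.columns:
            freq = np.nanmean(vals, axis=1) / 2.0
            self.snp_map = self.snp_map.assign(maf=np.minimum(freq, 1 - freq))

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns

    def filter_maf(self, min_maf: float = 0.05) -> "GenotypeMatrix":
        keep = self.snp_map["maf"] >= min_maf
        return GenotypeMatrix(self.dosages.loc[keep], self.snp_map.loc[keep])

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[:, list(sample_ids)], self.snp_map)


@dataclass
class PhenotypeTable:
    """Trait values (individuals x traits); missing values are NaN."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate individual ids in phenotype table")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missingness(self) -> pd.Series:
        """Fraction of individuals with observed data per trait (Table-1 'Data %' sense)."""
        return self.values.notna().mean(axis=0)

    def subset(self, individual_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.values.loc[list(individual_ids)])


@dataclass
class DatasetBundle:
    """Aligned bundle of all tables for one cohort."""

    methylation: MethylationMatrix
    cohort: TwinCohort
    genotypes: GenotypeMatrix | None = None
    phenotypes: PhenotypeTable | None = None
    expression: pd.DataFrame | None = None  # genes x individuals
    truth: pd.DataFrame | None = None  # simulation ground-truth sidecar
    wbc: pd.DataFrame | None = None  # individuals x cell-type counts
    log: dict = field(default_factory=dict)
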