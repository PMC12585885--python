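"""Core in-memory containers: genotype matrix, site table, sample sheet.

The genotype matrix is the substrate of every downstream stage: an
``n_samples x n_sites`` dosage array counting alternate-allele copies
(0, 1, 2) with ``-1`` marking missing calls, plus a site table and an
ordered sample list. Sites are biallelic SNPs with 1-based VCF
coordinates; all window arithmetic downstream is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


def make_site_table(chrom, pos, ref, alt) -> pd.DataFrame:
    """Assemble and validate a site table.

    Positions must be strictly increasing within each chromosome and all
    alleles single-character (biallelic SNPs only).
    """
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object),
            "alt": np.asarray(alt, dtype=object),
        }
    )
    df.index = pd.RangeIndex(len(df), name="site_id")
    for c, sub in df.groupby("chrom", sort=False):
        d = np.diff(sub["pos"].to_numpy())
        if len(d) and (d <= 0).any():
            raise ValueError(f"positions not strictly increasing on {c}")
    return df


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix over biallelic SNPs.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers.
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, ref, alt``.
    dosage : ndarray of int8, shape (n_samples, n_sites)
        Alternate-allele copy counts in {0, 1, 2}; ``-1`` is missing.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D")
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        bad = (self.dosage > 2) | (self.dosage < MISSING)
        if bad.any():
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        return list(pd.unique(self.sites["chrom"]))

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    # -- subsetting -----------------------------------------------------
    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sites = self.sites.iloc[idx].reset_index(drop=True)
        sites.index.name = "site_id"
        return GenotypeMatrix(list(self.samples), sites, self.dosage[:, idx])

    def take_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix([self.samples[i] for i in idx], self.sites.copy(), self.dosage[idx])

    def site_mask(self, chrom: str, start: int | None = None, end: int | None = None) -> np.ndarray:
        """Boolean mask of sites on ``chrom`` with 0-based half-open [start, end)."""
        m = (self.sites["chrom"] == chrom).to_numpy()
        pos0 = self.sites["pos"].to_numpy() - 1  # 0-based
        if start is not None:
            m &= pos0 >= start
        if end is not None:
            m &= pos0 < end
        return m

    def region(self, chrom: str, start: int | None = None, end: int | None = None) -> "GenotypeMatrix":
        return self.take_sites(self.site_mask(chrom, start, end))

    # -- allele frequencies --------------------------------------------
    def allele_counts(self, sample_idx=None):
        """(alt-allele count, called-allele count) per site over non-missing calls."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        called = d >= 0
        ac = np.where(called, d, 0).sum(axis=0).astype(np.int64)
        an = 2 * called.sum(axis=0).astype(np.int64)
        return ac, an

    def alt_freq(self, sample_idx=None) -> np.ndarray:
        ac, an = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)

    def minor_allele_freq(self, sample_idx=None) -> np.ndarray:
        p = self.alt_freq(sample_idx)
        return np.minimum(p, 1.0 - p)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.sites.copy(), self.dosage.copy())


HABITATS = {"coastal", "marine", "unknown"}
DATASETS = {"WGS", "RAD", "both"}


@dataclass
class SampleSheet:
    """Per-sample metadata: habitat label, location code, source dataset."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ["sample_id", "habitat", "location", "dataset"]

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id in sheet: {dup}")
        bad = set(self.table["habitat"]) - HABITATS
        if bad:
            raise ValueError(f"unknown habitat labels: {sorted(bad)}")
        bad = set(self.table["dataset"]) - DATASETS
        if bad:
            raise ValueError(f"unknown dataset labels: {sorted(bad)}")

    @classmethod
    def read_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    def validate_against(self, gm: GenotypeMatrix):
        """Every genotype-matrix sample must appear in the sheet."""
        known = set(self.table["sample_id"])
        absent = [s for s in gm.samples if s not in known]
        if absent:
            raise ValueError(f"samples missing from sheet: {absent[:5]}")

    def habitat_of(self) -> dict:
        return dict(zip(self.table["sample_id"], self.table["habitat"]))

    def location_of(self) -> dict:
        return dict(zip(self.table["sample_id"], self.table["location"]))
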