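"""In-memory model for a multi-breed SNP-array panel.

Three linked containers mirror how array genotypes are handled in practice:
a marker map (the positional backbone), a sample table carrying breed labels,
and a samples x SNPs allele-B dosage matrix with an explicit missing code.
Positions are 1-based base pairs throughout; markers are kept sorted by
(chromosome, position) with numeric chromosome labels ordering before
alphabetic ones (so autosomes come first, then X/Y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype in the dosage matrix.
MISSING: int = -1

VALID_ALLELES = frozenset("ACGT0")


def chrom_sort_key(label: str) -> tuple[int, int | str]:
    """Sort key placing numeric chromosome labels (as integers) before
    alphabetic ones (X, Y, MT ...)."""
    s = str(label)
    if s.isdigit():
        return (0, int(s))
    return (1, s)


class ModelError(ValueError):
    """Raised when a container violates its invariants."""


@dataclass
class MarkerMap:
    """Ordered marker map: one row per SNP.

    ``df`` columns: snp_id, chrom, pos_bp, allele_a, allele_b. Rows are
    sorted by (chrom, pos_bp); snp_ids are unique; positions are >= 1.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"]
        missing_cols = [c for c in required if c not in self.df.columns]
        if missing_cols:
            raise ModelError(f"marker map missing columns {missing_cols}")
        df = self.df.copy()
        df["snp_id"] = df["snp_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ModelError(f"duplicate snp_id {dup!r}")
        if (df["pos_bp"] < 1).any():
            raise ModelError("pos_bp must be >= 1")
        for col in ("allele_a", "allele_b"):
            bad = ~df[col].astype(str).isin(VALID_ALLELES)
            if bad.any():
                raise ModelError(
                    f"invalid {col} {df.loc[bad, col].iloc[0]!r} "
                    f"(alleles must be A/C/G/T or '0')"
                )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_id(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    def is_sorted(self) -> bool:
        keys = [chrom_sort_key(c) + (p,) for c, p in
                zip(self.df["chrom"], self.df["pos_bp"])]
        return all(keys[k] <= keys[k + 1] for k in range(len(keys) - 1))

    def sort_order(self) -> np.ndarray:
        """Indices that sort markers by (chrom, pos_bp), stable."""
        keys = [chrom_sort_key(c) + (p, k) for k, (c, p) in
                enumerate(zip(self.df["chrom"], self.df["pos_bp"]))]
        return np.array([k for *_, k in sorted(keys)], dtype=np.int64)


@dataclass
class SampleTable:
    """Sample register: unique sample_ids with a non-empty breed label each."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "breed"]
        missing_cols = [c for c in required if c not in self.df.columns]
        if missing_cols:
            raise ModelError(f"sample table missing columns {missing_cols}")
        df = self.df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["breed"] = df["breed"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ModelError(f"duplicate sample_id {dup!r}")
        if (df["breed"].str.len() == 0).any():
            raise ModelError("empty breed label")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_id(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy()

    @property
    def breed(self) -> np.ndarray:
        return self.df["breed"].to_numpy()

    @property
    def breeds(self) -> list[str]:
        """Distinct breed labels in first-appearance order."""
        return list(dict.fromkeys(self.df["breed"]))

    def indices_of(self, breed: str) -> np.ndarray:
        idx = np.flatnonzero(self.breed == breed)
        if idx.size == 0:
            raise ModelError(f"no samples for breed {breed!r}")
        return idx


@dataclass
class GenotypeMatrix:
    """samples x SNPs allele-B dosage matrix in {0, 1, 2, MISSING}.

    Rows follow ``samples``; columns follow ``markers`` (already sorted by
    genome position). The dosage counts copies of allele_b of the linked
    marker map row.
    """

    values: np.ndarray
    markers: MarkerMap
    samples: SampleTable
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ModelError("genotype values must be 2-D (samples x SNPs)")
        if v.shape != (len(self.samples), len(self.markers)):
            raise ModelError(
                f"genotype shape {v.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} SNPs"
            )
        v = v.astype(np.int8, copy=False)
        ok = np.isin(v, (0, 1, 2, MISSING))
        if not ok.all():
            bad = v[~ok].flat[0]
            raise ModelError(f"invalid dosage value {bad}")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.values != MISSING

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """New matrix restricted to the given row/column indices (order kept)."""
        v = self.values
        samples, markers = self.samples, self.markers
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            v = v[sample_idx, :]
            samples = SampleTable(samples.df.iloc[sample_idx])
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            v = v[:, snp_idx]
            markers = MarkerMap(markers.df.iloc[snp_idx])
        return GenotypeMatrix(v.copy(), markers, samples, dict(self.meta))


def sort_model(markers: MarkerMap, g: np.ndarray) -> tuple[MarkerMap, np.ndarray]:
    """Sort markers by (chrom, pos) and reorder genotype columns to match."""
    order = markers.sort_order()
    return MarkerMap(markers.df.iloc[order]), np.asarray(g)[:, order]
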