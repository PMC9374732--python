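"""Core in-memory containers shared across the pipeline.

The two central objects are :class:`GenotypeMatrix` (samples x variants
dosage matrix with variant metadata, VCF-backed) and :class:`ChromCounts`
(per-chromosome mapped-read counts for one sample, idxstats-backed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: dosage value marking a missing genotype call
MISSING = -1

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")

_SEX_CHROMS = {"X", "Y"}
_MITO = {"MT", "M"}


def normalize_chrom(name: str) -> str:
    """Strip a ``chr`` prefix and upper-case sex/mito chromosome names."""
    s = str(name)
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.upper() in _SEX_CHROMS | _MITO else s


def is_autosome(name: str) -> bool:
    return normalize_chrom(name) not in _SEX_CHROMS | _MITO


@dataclass
class GenotypeMatrix:
    """Dosage matrix (rows = samples, columns = variants).

    Dosages count alternate alleles per diploid genotype: 0, 1, 2, or
    :data:`MISSING` (-1). ``variants`` holds one row per column with at
    least the columns ``chrom, pos, ref, alt`` (``alt`` is a comma-joined
    string for multi-allelic records).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table lacks columns: {sorted(missing_cols)}")
        if self.dosages.size and self.dosages.max() > 2:
            raise ValueError("dosages must be <= 2")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    # -- subsetting ------------------------------------------------------
    def take_variants(self, index) -> "GenotypeMatrix":
        """Subset columns by positional index (order preserved as given)."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def take_samples(self, samples: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :],
        )

    def row(self, sample: str) -> np.ndarray:
        return self.dosages[self.sample_index(sample)]

    # -- per-variant summaries -------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant, ignoring missing calls."""
        d = self.dosages
        obs = d != MISSING
        alt = np.where(obs, d, 0).sum(axis=0)
        n_alleles = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1 - p)

    def is_biallelic(self) -> np.ndarray:
        alts = self.variants["alt"].astype(str)
        return (~alts.str.contains(",") & (alts != ".") & (alts != "")).to_numpy()

    def has_missing(self) -> np.ndarray:
        return (self.dosages == MISSING).any(axis=0)

    def concat_samples(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack sample rows of two matrices defined on identical variants."""
        if len(self.variants) != len(other.variants) or not (
            self.variants[list(VARIANT_COLUMNS)]
            .reset_index(drop=True)
            .equals(other.variants[list(VARIANT_COLUMNS)].reset_index(drop=True))
        ):
            raise ValueError("variant tables differ; cannot concatenate samples")
        dup = set(self.samples) & set(other.samples)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        return GenotypeMatrix(
            samples=self.samples + other.samples,
            variants=self.variants.copy(),
            dosages=np.vstack([self.dosages, other.dosages]),
        )


@dataclass
class ChromCounts:
    """idxstats-style per-chromosome mapped-read counts for one sample.

    ``table`` has columns ``chrom, length, mapped, unmapped``; chromosome
    names are stored as given and matched through :func:`normalize_chrom`.
    """

    sample: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        req = {"chrom", "length", "mapped", "unmapped"}
        if not req <= set(self.table.columns):
            raise ValueError(f"count table needs columns {sorted(req)}")
        if (self.table["length"] <= 0).any():
            raise ValueError("chromosome lengths must be positive")
        if (self.table[["mapped", "unmapped"]] < 0).to_numpy().any():
            raise ValueError("read counts must be non-negative")

    def get(self, chrom: str) -> pd.Series:
        """Return the row for ``chrom``, resolving name aliases."""
        want = normalize_chrom(chrom)
        hits = self.table[self.table["chrom"].map(normalize_chrom) == want]
        if hits.empty:
            raise KeyError(f"chromosome {chrom!r} absent for sample {self.sample}")
        return hits.iloc[0]

    def has(self, chrom: str) -> bool:
        want = normalize_chrom(chrom)
        return bool((self.table["chrom"].map(normalize_chrom) == want).any())
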