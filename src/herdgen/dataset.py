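"""In-memory representation of a diploid SNP genotype panel.

The central container is :class:`GenotypeDataset`: an ``n`` samples ×
``N`` loci matrix of allele-B dosages (0, 1, 2, or missing) together
with a locus map and sample metadata.  Every analysis stage in this
package consumes and returns this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

_VALID_DOSAGES = frozenset({-1, 0, 1, 2})

LOCUS_COLUMNS = ["locus_id", "chromosome", "position_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "sex"]

VALID_SEXES = ("male", "female", "unknown")


@dataclass(frozen=True)
class LocusInfo:
    """One biallelic marker: identifier, autosome label, 1-based bp position, alleles."""

    locus_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class SampleInfo:
    """One genotyped individual."""

    sample_id: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")


class GenotypeDataset:
    """Diploid genotypes for ``n`` samples at ``N`` biallelic loci.

    Parameters
    ----------
    dosages
        ``(n, N)`` integer matrix counting copies of ``allele_b`` per
        sample per locus; entries in ``{0, 1, 2}`` or :data:`MISSING`.
    loci
        DataFrame with columns ``locus_id, chromosome, position_bp,
        allele_a, allele_b`` (one row per matrix column).
    samples
        DataFrame with columns ``sample_id, sex`` (one row per matrix row).
    """

    def __init__(self, dosages: np.ndarray, loci: pd.DataFrame, samples: pd.DataFrame):
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        loci = loci.reset_index(drop=True)
        samples = samples.reset_index(drop=True)
        if list(loci.columns) != LOCUS_COLUMNS:
            missing = set(LOCUS_COLUMNS) - set(loci.columns)
            if missing:
                raise ValueError(f"loci table missing columns {sorted(missing)}")
            loci = loci[LOCUS_COLUMNS]
        if list(samples.columns) != SAMPLE_COLUMNS:
            missing = set(SAMPLE_COLUMNS) - set(samples.columns)
            if missing:
                raise ValueError(f"samples table missing columns {sorted(missing)}")
            samples = samples[SAMPLE_COLUMNS]
        if dosages.shape != (len(samples), len(loci)):
            raise ValueError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{len(samples)} samples × {len(loci)} loci"
            )
        bad = ~np.isin(dosages, (-1, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {dosages[i, j]} at sample {i}, locus {j}; "
                "entries must be 0, 1, 2 or missing (-1)"
            )
        if samples["sample_id"].duplicated().any():
            dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        self.dosages = dosages
        self.loci = loci
        self.samples = samples

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def locus_ids(self) -> list[str]:
        return self.loci["locus_id"].tolist()

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, N)`` mask, True where the call is missing."""
        return self.dosages == MISSING

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeDataset(n_samples={self.n_samples}, n_loci={self.n_loci})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.loci.equals(other.loci)
            and self.samples.equals(other.samples)
        )

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_records(
        cls,
        dosages: np.ndarray,
        loci: Iterable[LocusInfo],
        samples: Iterable[SampleInfo],
    ) -> "GenotypeDataset":
        loci_df = pd.DataFrame(
            [(l.locus_id, l.chromosome, int(l.position_bp), l.allele_a, l.allele_b) for l in loci],
            columns=LOCUS_COLUMNS,
        )
        samples_df = pd.DataFrame(
            [(s.sample_id, s.sex) for s in samples], columns=SAMPLE_COLUMNS
        )
        return cls(np.asarray(dosages), loci_df, samples_df)

    # -- subsetting / ordering -----------------------------------------------

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeDataset":
        """Positional subset of samples and/or loci, order-preserving."""
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        l = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        if s.dtype == bool:
            s = np.flatnonzero(s)
        if l.dtype == bool:
            l = np.flatnonzero(l)
        return GenotypeDataset(
            self.dosages[np.ix_(s, l)],
            self.loci.iloc[l],
            self.samples.iloc[s],
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "GenotypeDataset":
        order = {sid: i for i, sid in enumerate(self.sample_ids)}
        try:
            idx = [order[sid] for sid in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample id {exc.args[0]!r} not in dataset") from None
        return self.subset(sample_idx=np.asarray(idx))

    def sorted_loci(self) -> "GenotypeDataset":
        """Return a copy with loci sorted by (chromosome, position_bp).

        Chromosome labels that parse as integers sort numerically,
        others lexicographically after them.
        """
        chrom = self.loci["chromosome"].astype(str)

        def key(c: str) -> tuple:
            try:
                return (0, int(c), "")
            except ValueError:
                return (1, 0, c)

        order = sorted(
            range(self.n_loci),
            key=lambda j: (key(chrom.iloc[j]), int(self.loci["position_bp"].iloc[j])),
        )
        return self.subset(locus_idx=np.asarray(order))

    def is_sorted(self) -> bool:
        srt = self.sorted_loci()
        return self.loci["locus_id"].tolist() == srt.loci["locus_id"].tolist()
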