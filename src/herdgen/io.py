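"""Reading and writing SNP genotype panels (PLINK text and VCF).

Conventions
-----------
* ``allele_b`` is the **minor** allele computed from the data at load
  time (PLINK's A1-minor convention), so dosage = minor-allele count.
  A frequency tie (MAF exactly 0.5) is broken by taking the
  lexicographically later symbol as ``allele_b``.
* Coordinates are 1-based inclusive bp, as in ``.map`` and VCF.
* Monomorphic loci are retained; their ``allele_b`` is a placeholder
  (the next base in A→C→G→T→A order) so the pair stays distinct.
* Missing calls are ``0 0`` in ``.ped`` and ``./.`` in VCF.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset, LOCUS_COLUMNS, MISSING, SAMPLE_COLUMNS

logger = logging.getLogger(__name__)

_BASE_SUCCESSOR = {"A": "C", "C": "G", "G": "T", "T": "A"}

_PED_SEX = {"1": "male", "2": "female"}
_SEX_PED = {"male": "1", "female": "2", "unknown": "0"}


class PlinkParseError(ValueError):
    """Malformed PLINK text input."""


class VcfFormatError(ValueError):
    """VCF lacking required fields."""


def _placeholder_allele(observed: str) -> str:
    return _BASE_SUCCESSOR.get(observed, "N" if observed != "N" else "A")


def _orient_alleles(counts: dict[str, int]) -> tuple[str, str]:
    """Pick (allele_a, allele_b) with allele_b the minor allele.

    ``counts`` maps observed allele symbol -> allele count.
    """
    observed = [a for a, c in counts.items() if c > 0]
    if len(observed) == 0:
        return "A", "C"  # fully missing locus: arbitrary placeholder pair
    if len(observed) == 1:
        a = observed[0]
        return a, _placeholder_allele(a)
    if len(observed) > 2:
        raise PlinkParseError(f"more than two alleles observed: {sorted(observed)}")
    x, y = sorted(observed)  # lexicographic; tie-break makes allele_b the later symbol
    if counts[x] < counts[y]:
        return y, x
    return x, y


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    autosomes: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Read a whitespace-delimited PLINK ``.ped``/``.map`` pair.

    Parameters
    ----------
    ped_path, map_path
        PLINK text files; ``.map`` has 4 columns (chromosome, locus id,
        cM, bp), ``.ped`` has 6 metadata columns then two allele columns
        per locus with ``0`` denoting a missing allele.
    autosomes
        Optional chromosome whitelist; loci on other chromosomes are
        dropped at load (sex chromosomes are never analysed here).
    """
    map_df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "locus_id", "cm", "position_bp"],
        dtype={"chromosome": str, "locus_id": str},
    )
    n_loci = len(map_df)

    sample_rows: list[tuple[str, str]] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_loci:
                raise PlinkParseError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * n_loci} for {n_loci} mapped loci"
                )
            sample_rows.append((fields[1], _PED_SEX.get(fields[4], "unknown")))
            allele_rows.append(fields[6:])

    n = len(sample_rows)
    alleles = np.array(allele_rows, dtype=object).reshape(n, n_loci, 2) if n else np.empty(
        (0, n_loci, 2), dtype=object
    )

    dosages = np.full((n, n_loci), MISSING, dtype=np.int8)
    allele_a_col: list[str] = []
    allele_b_col: list[str] = []
    for j in range(n_loci):
        a1 = alleles[:, j, 0]
        a2 = alleles[:, j, 1]
        half_missing = (a1 == "0") != (a2 == "0")
        if half_missing.any():
            i = int(np.flatnonzero(half_missing)[0])
            raise PlinkParseError(
                f"{ped_path}: sample row {i + 1}, locus {j + 1}: "
                "half-missing genotype (one allele '0')"
            )
        counts: dict[str, int] = {}
        for arr in (a1, a2):
            vals, cnts = np.unique(arr[arr != "0"], return_counts=True)
            for v, c in zip(vals, cnts):
                counts[v] = counts.get(v, 0) + int(c)
        aa, ab = _orient_alleles(counts)
        allele_a_col.append(aa)
        allele_b_col.append(ab)
        called = a1 != "0"
        dosages[called, j] = (a1[called] == ab).astype(np.int8) + (
            a2[called] == ab
        ).astype(np.int8)

    loci = pd.DataFrame(
        {
            "locus_id": map_df["locus_id"],
            "chromosome": map_df["chromosome"],
            "position_bp": map_df["position_bp"].astype(np.int64),
            "allele_a": allele_a_col,
            "allele_b": allele_b_col,
        },
        columns=LOCUS_COLUMNS,
    )
    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    ds = GenotypeDataset(dosages, loci, samples)
    if autosomes is not None:
        keep = loci["chromosome"].isin([str(c) for c in autosomes]).to_numpy()
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d loci outside the autosome whitelist", dropped)
        ds = ds.subset(locus_idx=keep)
    return ds


def write_plink_text(dataset: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; re-readable by
    :func:`read_plink_text`. Missing dosages become ``0 0``."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    with open(map_path, "w") as fh:
        for row in dataset.loci.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.locus_id}\t0\t{row.position_bp}\n")

    aa = dataset.loci["allele_a"].to_numpy(dtype=object)
    ab = dataset.loci["allele_b"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(dataset.samples.itertuples(index=False)):
            d = dataset.dosages[i]
            first = np.where(d >= 1, ab, aa)
            second = np.where(d == 2, ab, aa)
            first = np.where(d == MISSING, "0", first)
            second = np.where(d == MISSING, "0", second)
            geno = " ".join(f"{x} {y}" for x, y in zip(first, second))
            sex = _SEX_PED.get(srow.sex, "0")
            fh.write(f"{srow.sample_id} {srow.sample_id} 0 0 {sex} -9 {geno}\n")
    return ped_path, map_path


def read_vcf(path: str | Path, autosomes: Sequence[str] | None = None) -> GenotypeDataset:
    """Read a VCF (plain or gzipped) of biallelic SNPs into a dataset.

    REF maps to ``allele_a`` and ALT to ``allele_b`` (no minor-allele
    re-orientation: the VCF fixes the allele roles). ``./.`` becomes
    missing. Records with more than one ALT allele are skipped and
    counted in the log.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VcfFormatError(f"{path}: no GT FORMAT field in header")
    sample_ids = list(vcf.samples)

    rows = []
    dosage_rows = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        dosage_rows.append(gt)
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF records", n_skipped)

    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    samples = pd.DataFrame({"sample_id": sample_ids, "sex": "unknown"}, columns=SAMPLE_COLUMNS)
    dosages = (
        np.stack(dosage_rows, axis=1)
        if dosage_rows
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    ds = GenotypeDataset(dosages, loci, samples)
    if autosomes is not None:
        keep = loci["chromosome"].isin([str(c) for c in autosomes]).to_numpy()
        ds = ds.subset(locus_idx=keep)
    return ds
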