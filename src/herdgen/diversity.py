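"""Genetic-diversity statistics: MAF, P_N, H_o, H_e, pairwise r², and
LD-based effective population size.

The effective population size follows Sved's relation between expected
LD and distance, E[r²] = 1/(1 + 4·Ne·c), inverted per distance bin:

    Ne = (1 / (4c)) · (1 / r²_adj − 1)

with c the bin-midpoint distance in Morgans and r²_adj the bin's mean
r², optionally corrected for the finite sample size. A bin at distance
c reflects the population roughly t = 1/(2c) generations ago.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset, MISSING

logger = logging.getLogger(__name__)

LD_COLUMNS = ["locus_i", "locus_j", "chromosome", "dist_bp", "dist_morgans", "r_squared"]


@dataclass
class DiversitySummary:
    """Cohort-level diversity parameters."""

    p_n: float
    h_o: float
    h_e: float
    m_polymorphic: int
    n_total_loci: int

    def to_dict(self) -> dict:
        return {
            "p_n": self.p_n,
            "h_o": self.h_o,
            "h_e": self.h_e,
            "m_polymorphic": self.m_polymorphic,
            "n_total_loci": self.n_total_loci,
        }


def _freq_counts(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """(allele-b count, called-sample count) per locus."""
    d = dataset.dosages
    called = d != MISSING
    b_count = np.where(called, d, 0).sum(axis=0)
    return b_count.astype(float), called.sum(axis=0).astype(float)


def alt_allele_frequencies(dataset: GenotypeDataset) -> np.ndarray:
    """Frequency of ``allele_b`` per locus; NaN where no calls."""
    b, n_called = _freq_counts(dataset)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, b / (2.0 * n_called), np.nan)
    return p


def allele_frequencies(dataset: GenotypeDataset) -> np.ndarray:
    """Minor allele frequency per locus; NaN for fully missing loci."""
    p = alt_allele_frequencies(dataset)
    n_undef = int(np.isnan(p).sum())
    if n_undef:
        logger.warning("%d loci entirely missing; MAF undefined", n_undef)
    return np.minimum(p, 1.0 - p)


def proportion_polymorphic(maf: np.ndarray, min_maf: float | None = None) -> float:
    """P_N: fraction of loci that are polymorphic.

    A locus counts as polymorphic when MAF > 0, or MAF >= ``min_maf``
    when a threshold is given. Undefined (NaN) MAFs count as
    non-polymorphic.
    """
    maf = np.asarray(maf, dtype=float)
    if maf.size == 0:
        raise ValueError("empty MAF vector")
    filled = np.nan_to_num(maf, nan=0.0)
    poly = filled > 0 if min_maf is None else filled >= min_maf
    return float(poly.sum() / maf.size)


def observed_heterozygosity(dataset: GenotypeDataset) -> float:
    """H_o: mean over loci of the heterozygote fraction among called samples."""
    if dataset.n_loci == 0 or dataset.n_samples == 0:
        raise ValueError("need at least one sample and one locus")
    d = dataset.dosages
    called = (d != MISSING).sum(axis=0).astype(float)
    het = (d == 1).sum(axis=0).astype(float)
    ok = called > 0
    if not ok.all():
        logger.warning("%d loci entirely missing; excluded from H_o", int((~ok).sum()))
    return float((het[ok] / called[ok]).mean())


def expected_heterozygosity(dataset: GenotypeDataset) -> float:
    """H_e: Nei's unbiased expected heterozygosity, averaged over loci.

    Per locus, (2n/(2n−1)) · (1 − p² − q²) with n the number of called
    samples at that locus.
    """
    if dataset.n_loci == 0 or dataset.n_samples == 0:
        raise ValueError("need at least one sample and one locus")
    b, n_called = _freq_counts(dataset)
    ok = n_called > 0
    if not ok.all():
        logger.warning("%d loci entirely missing; excluded from H_e", int((~ok).sum()))
    n = n_called[ok]
    p = b[ok] / (2.0 * n)
    gene_div = 1.0 - p**2 - (1.0 - p) ** 2
    corr = (2.0 * n) / (2.0 * n - 1.0)
    return float((corr * gene_div).mean())


def diversity_summary(dataset: GenotypeDataset, pn_maf_threshold: float | None = None) -> DiversitySummary:
    maf = allele_frequencies(dataset)
    filled = np.nan_to_num(maf, nan=0.0)
    poly = filled > 0 if pn_maf_threshold is None else filled >= pn_maf_threshold
    return DiversitySummary(
        p_n=proportion_polymorphic(maf, pn_maf_threshold),
        h_o=observed_heterozygosity(dataset),
        h_e=expected_heterozygosity(dataset),
        m_polymorphic=int(poly.sum()),
        n_total_loci=dataset.n_loci,
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium and Ne
# ---------------------------------------------------------------------------


def pairwise_r2(
    dataset: GenotypeDataset,
    max_distance_bp: int,
    cm_per_mb: float = 1.0,
) -> pd.DataFrame:
    """r² between all same-chromosome locus pairs within ``max_distance_bp``.

    r² is the squared Pearson correlation of unphased dosages over the
    samples called at both loci (composite LD, as PLINK ``--r2``).
    Distance in Morgans uses a uniform genetic map of ``cm_per_mb``
    cM/Mb. Pairs where either locus has zero dosage variance among the
    jointly called samples are skipped (and counted in the log).
    """
    if not dataset.is_sorted():
        raise ValueError("loci must be sorted by chromosome and position")
    d = dataset.dosages.astype(float)
    miss = dataset.dosages == MISSING
    d[miss] = np.nan
    chroms = dataset.loci["chromosome"].to_numpy()
    pos = dataset.loci["position_bp"].to_numpy(dtype=np.int64)
    ids = np.asarray(dataset.locus_ids, dtype=object)

    out_i, out_j, out_chrom, out_bp, out_r2 = [], [], [], [], []
    n_skipped = 0

    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        m = sel.size
        if m < 2:
            continue
        X = d[:, sel]
        valid = ~np.isnan(X)
        p = pos[sel]
        for k in range(1, m):
            gaps = p[k:] - p[:-k]
            within = gaps <= max_distance_bp
            if not within.any():
                if gaps.min() > max_distance_bp:
                    break
                continue
            A = X[:, :-k][:, within]
            B = X[:, k:][:, within]
            both = valid[:, :-k][:, within] & valid[:, k:][:, within]
            n_pair = both.sum(axis=0).astype(float)
            Az = np.where(both, A, 0.0)
            Bz = np.where(both, B, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ma = Az.sum(axis=0) / n_pair
                mb = Bz.sum(axis=0) / n_pair
                cov = (Az * Bz).sum(axis=0) / n_pair - ma * mb
                va = (Az**2).sum(axis=0) / n_pair - ma**2
                vb = (Bz**2).sum(axis=0) / n_pair - mb**2
                r2 = np.where((va > 0) & (vb > 0) & (n_pair > 1), cov**2 / (va * vb), np.nan)
            good = ~np.isnan(r2)
            n_skipped += int((~good).sum())
            left = sel[:-k][within][good]
            right = sel[k:][within][good]
            out_i.append(ids[left])
            out_j.append(ids[right])
            out_chrom.append(np.full(left.size, chrom, dtype=object))
            out_bp.append(pos[right] - pos[left])
            out_r2.append(np.clip(r2[good], 0.0, 1.0))

    if n_skipped:
        logger.info("skipped %d zero-variance or undersized locus pairs", n_skipped)
    if not out_i:
        return pd.DataFrame(columns=LD_COLUMNS)
    dist_bp = np.concatenate(out_bp)
    df = pd.DataFrame(
        {
            "locus_i": np.concatenate(out_i),
            "locus_j": np.concatenate(out_j),
            "chromosome": np.concatenate(out_chrom),
            "dist_bp": dist_bp,
            "dist_morgans": dist_bp / 1e6 * cm_per_mb / 100.0,
            "r_squared": np.concatenate(out_r2),
        },
        columns=LD_COLUMNS,
    )
    return df.reset_index(drop=True)


def estimate_ne(
    records: pd.DataFrame,
    bins: list[tuple[float, float]],
    n_samples: int | None = None,
    correction: str = "none",
    unit: str = "morgan",
    summary: str = "harmonic_mean",
) -> tuple[pd.DataFrame, float]:
    """Sved-formula Ne per distance bin plus a single summary value.

    Parameters
    ----------
    records
        Output of :func:`pairwise_r2`.
    bins
        Distance intervals ``(lo, hi]`` in Morgans.
    n_samples
        Cohort size; required when ``correction != "none"``.
    correction
        ``"none"``, ``"1/n"`` or ``"1/2n"``: amount subtracted from the
        bin mean r² to remove finite-sample inflation.
    unit
        ``"morgan"`` (Sved's derivation) or ``"centimorgan"`` for c.
    summary
        ``"harmonic_mean"`` over defined bins (default) or
        ``"largest_c"`` (the most recent generations).

    Returns
    -------
    (table, summary_ne) where the table has one row per bin with columns
    ``bin_lo, bin_hi, c, n_pairs, mean_r2, r2_adj, ne, generations_ago``.
    """
    if correction not in ("none", "1/n", "1/2n"):
        raise ValueError(f"unknown correction {correction!r}")
    if unit not in ("morgan", "centimorgan"):
        raise ValueError(f"unknown unit {unit!r}")
    if correction != "none" and not n_samples:
        raise ValueError("n_samples required for sample-size correction")

    adj = 0.0
    if correction == "1/n":
        adj = 1.0 / n_samples
    elif correction == "1/2n":
        adj = 1.0 / (2 * n_samples)

    dist = records["dist_morgans"].to_numpy() if len(records) else np.empty(0)
    r2 = records["r_squared"].to_numpy() if len(records) else np.empty(0)

    rows = []
    for lo, hi in bins:
        mask = (dist > lo) & (dist <= hi)
        n_pairs = int(mask.sum())
        if n_pairs == 0:
            raise ValueError(f"distance bin ({lo}, {hi}] Morgans contains no locus pairs")
        mean_r2 = float(r2[mask].mean())
        r2_adj = mean_r2 - adj
        c = (lo + hi) / 2.0
        c_units = c * 100.0 if unit == "centimorgan" else c
        if r2_adj <= 0:
            logger.warning("bin (%g, %g]: corrected r² ≤ 0; Ne undefined", lo, hi)
            ne = np.nan
        elif r2_adj >= 1.0:
            ne = 0.0
        else:
            ne = max((1.0 / (4.0 * c_units)) * (1.0 / r2_adj - 1.0), 0.0)
        rows.append((lo, hi, c, n_pairs, mean_r2, r2_adj, ne, 1.0 / (2.0 * c)))

    table = pd.DataFrame(
        rows,
        columns=["bin_lo", "bin_hi", "c", "n_pairs", "mean_r2", "r2_adj", "ne", "generations_ago"],
    )
    ne_vals = table["ne"].to_numpy()
    defined = ne_vals[~np.isnan(ne_vals)]
    if defined.size == 0 or (defined <= 0).all():
        summary_ne = float("nan")
    elif summary == "harmonic_mean":
        pos = defined[defined > 0]
        summary_ne = float(pos.size / (1.0 / pos).sum())
    elif summary == "largest_c":
        idx = table["c"].idxmax()
        summary_ne = float(table.loc[idx, "ne"])
    else:
        raise ValueError(f"unknown summary {summary!r}")
    return table, summary_ne
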