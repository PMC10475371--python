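"""Genomic relatedness: VanRaden G matrix, KS kinship, IBS distance.

G (VanRaden method 1) is ZZ′ / (2 Σ pᵢ(1−pᵢ)) where Z holds dosages
column-centered by twice the allele frequency; missing dosages are
mean-imputed (centered value 0). The kinship normalization
KS_jk = G_jk / √(G_jj·G_kk) puts exactly 1 on the diagonal, so 0.25 and
0.5 are the expected values for non-inbred half-sib and full-sib pairs.
IBS distance is 1 minus the allele-sharing proportion (PLINK
``--distance 1-ibs`` semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset, MISSING
from .diversity import alt_allele_frequencies


@dataclass
class GMatrix:
    """VanRaden genomic relationship matrix with its ingredients."""

    values: np.ndarray
    labels: list[str]
    allele_freqs_used: np.ndarray
    n_loci_used: int


@dataclass
class KinshipMatrix:
    """KS normalization of G; NaN marks pairs where G_jj·G_kk ≤ 0."""

    values: np.ndarray
    labels: list[str]
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle (j<k) kinship values as a flat vector."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance in [0,1], zero diagonal."""

    values: np.ndarray
    labels: list[str]


def vanraden_g(
    dataset: GenotypeDataset,
    freqs: np.ndarray | None = None,
) -> GMatrix:
    """Compute the VanRaden G matrix.

    Parameters
    ----------
    dataset
        Genotypes; missing calls are imputed to twice the allele
        frequency (i.e. to the centered value 0).
    freqs
        Optional externally supplied ``allele_b`` frequencies (one per
        locus); by default frequencies observed in this cohort are used.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least two samples")
    p = alt_allele_frequencies(dataset) if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (dataset.n_loci,):
        raise ValueError("frequency vector length must equal locus count")

    usable = ~np.isnan(p)
    p_used = p[usable]
    d = dataset.dosages[:, usable].astype(float)
    d[dataset.missing_mask()[:, usable]] = np.nan

    Z = d - 2.0 * p_used
    Z = np.nan_to_num(Z, nan=0.0)  # mean imputation after centering
    denom = 2.0 * float((p_used * (1.0 - p_used)).sum())
    if denom <= 0:
        raise ValueError("all usable loci are monomorphic; G undefined")
    G = (Z @ Z.T) / denom
    return GMatrix(
        values=G,
        labels=dataset.sample_ids,
        allele_freqs_used=p_used,
        n_loci_used=int(usable.sum()),
    )


def kinship_from_g(g: GMatrix) -> KinshipMatrix:
    """KS_jk = G_jk / √(G_jj·G_kk), with degenerate pairs flagged."""
    G = g.values
    diag = np.diag(G)
    prod = np.outer(diag, diag)
    with np.errstate(invalid="ignore", divide="ignore"):
        ks = np.where(prod > 0, G / np.sqrt(prod), np.nan)
    np.fill_diagonal(ks, np.where(diag > 0, 1.0, np.nan))
    undefined = []
    n = len(g.labels)
    for j in range(n):
        for k in range(j, n):
            if prod[j, k] <= 0:
                undefined.append((g.labels[j], g.labels[k]))
    return KinshipMatrix(values=ks, labels=list(g.labels), undefined_pairs=undefined)


def ibs_distance(dataset: GenotypeDataset) -> DistanceMatrix:
    """1 − allele-sharing proportion for every sample pair.

    Sharing at a locus is (2 − |dosage_i − dosage_j|)/2 over loci called
    in both samples. A pair with no jointly called locus is an error.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least two samples")
    d = dataset.dosages.astype(np.float64)
    valid = dataset.dosages != MISSING
    n = dataset.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        n_both = both.sum(axis=1).astype(float)
        if (n_both == 0).any():
            j = i + 1 + int(np.flatnonzero(n_both == 0)[0])
            raise ValueError(
                f"samples {dataset.sample_ids[i]!r} and {dataset.sample_ids[j]!r} "
                "share no jointly genotyped locus"
            )
        diff = np.where(both, np.abs(d[i] - d[i + 1 :]), 0.0).sum(axis=1)
        sim = (2.0 * n_both - diff) / (2.0 * n_both)
        dist[i, i + 1 :] = 1.0 - sim
        dist[i + 1 :, i] = dist[i, i + 1 :]
    return DistanceMatrix(values=dist, labels=dataset.sample_ids)


DEFAULT_KS_BREAKS = (0.125, 0.25, 0.5)


def relationship_distribution(
    ks: KinshipMatrix, breaks: tuple[float, ...] = DEFAULT_KS_BREAKS
) -> tuple[pd.DataFrame, float]:
    """Distribution of off-diagonal kinship values over intervals.

    Intervals are right-closed: (−∞, b₁], (b₁, b₂], …, (b_last, ∞).
    Returns (table of fractions, mean kinship); NaN (undefined) pairs
    are excluded.
    """
    if len(ks.labels) < 2:
        raise ValueError("need at least two samples")
    vals = ks.off_diagonal()
    vals = vals[~np.isnan(vals)]
    edges = (-np.inf, *breaks, np.inf)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        frac = float(((vals > lo) & (vals <= hi)).mean()) if vals.size else np.nan
        label = f"({lo:g}, {hi:g}]" if np.isfinite(hi) else f"({lo:g}, inf)"
        rows.append((lo, hi, label, frac))
    table = pd.DataFrame(rows, columns=["lo", "hi", "interval", "fraction"])
    mean_ks = float(vals.mean()) if vals.size else float("nan")
    return table, mean_ks


def matrix_to_tsv(values: np.ndarray, labels: list[str], path, float_fmt: str = "%.6g") -> None:
    """Write a square labelled matrix as TSV (header row and column)."""
    df = pd.DataFrame(values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=float_fmt, index_label="sample_id")


def distance_to_phylip(dist: DistanceMatrix, path) -> None:
    """Write a distance matrix in relaxed PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dist.labels)}\n")
        for lab, row in zip(dist.labels, dist.values):
            fh.write(lab + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
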