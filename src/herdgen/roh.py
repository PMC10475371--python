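"""Runs of homozygosity (ROH) and the genomic inbreeding coefficient F_ROH.

Detection follows the PLINK ``--homozyg`` sliding-window scheme:

1. a window of ``window_snps`` consecutive SNPs slides along each
   chromosome; a window is *homozygous* if it contains at most
   ``window_max_het`` heterozygous and ``window_max_missing`` missing
   calls (truncated windows at chromosome ends are not evaluated);
2. each SNP's hit proportion is the fraction of evaluated windows
   covering it that are homozygous; SNPs at or above
   ``min_hit_proportion`` are eligible;
3. maximal runs of eligible SNPs become candidate segments, split
   wherever two consecutive SNPs are more than ``max_gap_kb`` apart;
4. a segment is emitted when it has **more than** ``min_snps_per_segment``
   SNPs, is **longer than** ``min_length_kb``, and averages at least one
   SNP per ``min_density_kb_per_snp``.

F_ROH for an individual is the summed ROH length divided by the
autosomal genome length L covered by the chip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset, MISSING

#: Autosomal genome length (kb) covered by a ~57k porcine breeding chip;
#: override with the true (or simulated) genome length of your panel.
DEFAULT_AUTOSOME_LENGTH_KB: float = 2_450_462.292

SEGMENT_COLUMNS = ["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_kb"]


@dataclass
class ROHParams:
    """Sliding-window ROH detection parameters (PLINK-style)."""

    min_snps_per_segment: int = 30
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 1000.0
    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 1
    min_hit_proportion: float = 0.05

    def validate(self) -> None:
        if min(
            self.min_snps_per_segment,
            self.min_length_kb,
            self.max_gap_kb,
            self.min_density_kb_per_snp,
            self.window_snps,
        ) <= 0:
            raise ValueError("size/length parameters must be positive")
        if self.window_max_het < 0 or self.window_max_missing < 0:
            raise ValueError("window allowances must be non-negative")
        if not (0.0 < self.min_hit_proportion <= 1.0):
            raise ValueError("min_hit_proportion must lie in (0, 1]")


@dataclass
class ROHSegment:
    """One autozygous run in one individual."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


@dataclass
class FrohResult:
    """Per-individual inbreeding coefficient from ROH coverage."""

    sample_id: str
    total_roh_kb: float
    f_roh: float
    autosome_length_kb: float


def _eligible_snps(geno: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean eligibility per SNP for one sample on one chromosome."""
    m = geno.size
    W = params.window_snps
    eligible = np.zeros(m, dtype=bool)
    if m < W:
        return eligible  # no full window fits: nothing is evaluated
    het = (geno == 1).astype(np.int32)
    mis = (geno == MISSING).astype(np.int32)
    het_c = np.concatenate(([0], np.cumsum(het)))
    mis_c = np.concatenate(([0], np.cumsum(mis)))
    w_het = het_c[W:] - het_c[:-W]
    w_mis = mis_c[W:] - mis_c[:-W]
    hom_win = ((w_het <= params.window_max_het) & (w_mis <= params.window_max_missing)).astype(
        np.int32
    )
    # windows covering SNP i start in [max(0, i-W+1), min(i, m-W)]
    hom_c = np.concatenate(([0], np.cumsum(hom_win)))
    i = np.arange(m)
    lo = np.maximum(0, i - W + 1)
    hi = np.minimum(i, m - W)
    n_cover = (hi - lo + 1).astype(float)
    n_hom = hom_c[hi + 1] - hom_c[lo]
    eligible = (n_hom / n_cover) >= params.min_hit_proportion
    return eligible


def detect_roh(dataset: GenotypeDataset, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect ROH segments for every sample; returns a segment table.

    Columns: ``sample_id, chromosome, start_bp, end_bp, n_snps,
    length_kb``. Loci must be sorted by chromosome and position.
    """
    params = params or ROHParams()
    params.validate()
    if not dataset.is_sorted():
        raise ValueError("loci must be sorted by chromosome and position")

    chroms = dataset.loci["chromosome"].to_numpy()
    pos = dataset.loci["position_bp"].to_numpy(dtype=np.int64)
    rows: list[tuple] = []

    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        p = pos[sel]
        gap_break = np.diff(p) > params.max_gap_kb * 1000.0
        for i, sid in enumerate(dataset.sample_ids):
            geno = dataset.dosages[i, sel]
            eligible = _eligible_snps(geno, params)
            if not eligible.any():
                continue
            # run boundaries: eligibility changes or oversized gap
            start = None
            for k in range(eligible.size):
                if eligible[k] and start is None:
                    start = k
                split = (not eligible[k]) or (
                    k + 1 < eligible.size and gap_break[k]
                ) or k == eligible.size - 1
                if start is not None and split:
                    end = k if eligible[k] else k - 1
                    n_snps = end - start + 1
                    length_kb = (p[end] - p[start] + 1) / 1000.0
                    if (
                        n_snps > params.min_snps_per_segment
                        and length_kb > params.min_length_kb
                        and length_kb / n_snps <= params.min_density_kb_per_snp
                    ):
                        rows.append((sid, chrom, int(p[start]), int(p[end]), n_snps, length_kb))
                    start = None
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return df.sort_values(["sample_id", "chromosome", "start_bp"], kind="stable").reset_index(
        drop=True
    )


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [spans[0]]
    for s, e in spans[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def froh(
    segments: pd.DataFrame,
    autosome_length_kb: float = DEFAULT_AUTOSOME_LENGTH_KB,
) -> FrohResult:
    """F_ROH for the single individual whose segments are given.

    Overlapping or adjacent segments are merged per chromosome before
    summing, so coverage is never double-counted.
    """
    if autosome_length_kb <= 0:
        raise ValueError("autosome_length_kb must be positive")
    sids = segments["sample_id"].unique() if len(segments) else np.array([])
    if len(sids) > 1:
        raise ValueError("froh expects segments of exactly one individual")
    sid = str(sids[0]) if len(sids) else ""
    total_kb = 0.0
    for _, chrom_df in segments.groupby("chromosome"):
        spans = list(zip(chrom_df["start_bp"].astype(int), chrom_df["end_bp"].astype(int)))
        for s, e in _merge_spans(spans):
            total_kb += (e - s + 1) / 1000.0
    return FrohResult(
        sample_id=sid,
        total_roh_kb=total_kb,
        f_roh=total_kb / autosome_length_kb,
        autosome_length_kb=autosome_length_kb,
    )


def froh_table(
    segments: pd.DataFrame,
    sample_ids: list[str],
    autosome_length_kb: float = DEFAULT_AUTOSOME_LENGTH_KB,
) -> pd.DataFrame:
    """Per-individual F_ROH table covering every listed sample (zero if
    no segments were detected for it)."""
    rows = []
    for sid in sample_ids:
        sub = segments[segments["sample_id"] == sid] if len(segments) else segments
        res = froh(sub, autosome_length_kb) if len(sub) else FrohResult(
            sid, 0.0, 0.0, autosome_length_kb
        )
        rows.append((sid, res.total_roh_kb, res.f_roh))
    return pd.DataFrame(rows, columns=["sample_id", "total_roh_kb", "f_roh"])


def population_mean_froh(results: pd.DataFrame | list[FrohResult]) -> float:
    """Arithmetic mean F_ROH over individuals."""
    if isinstance(results, pd.DataFrame):
        vals = results["f_roh"].to_numpy(dtype=float)
    else:
        vals = np.array([r.f_roh for r in results], dtype=float)
    if vals.size == 0:
        raise ValueError("no individuals")
    return float(vals.mean())


def roh_summary(
    segments: pd.DataFrame, length_class_mb: float = 6.0
) -> pd.DataFrame:
    """Per-individual ROH count and length summary.

    Columns: segment count, min/median/max length (Mb), and counts in
    the two length classes below/at-or-above ``length_class_mb``.
    """
    if len(segments) == 0:
        return pd.DataFrame(
            columns=[
                "sample_id",
                "n_segments",
                "min_length_mb",
                "median_length_mb",
                "max_length_mb",
                "n_short",
                "n_long",
            ]
        )
    rows = []
    for sid, sub in segments.groupby("sample_id"):
        mb = sub["length_kb"].to_numpy() / 1000.0
        rows.append(
            (
                sid,
                len(mb),
                float(mb.min()),
                float(np.median(mb)),
                float(mb.max()),
                int((mb < length_class_mb).sum()),
                int((mb >= length_class_mb).sum()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "n_segments",
            "min_length_mb",
            "median_length_mb",
            "max_length_mb",
            "n_short",
            "n_long",
        ],
    )
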