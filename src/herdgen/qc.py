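"""Quality control: call rates, Hardy–Weinberg exact test, MAF filtering.

Three named presets mirror the three analysis tracks used when
characterizing a chip-genotyped herd:

* ``pn_track``   — call rates + HWE (for the proportion of polymorphic loci)
* ``core_track`` — call rates + HWE + MAF (for Ne, He, Ho, G, IBS, clustering)
* ``roh_track``  — call rates only (for ROH / F_ROH)

Filter order is fixed and PLINK-conventional: samples below the sample
call-rate threshold are dropped first, then loci by call rate, then HWE,
then MAF; the report attributes each removed locus to the first filter
it fails.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import GenotypeDataset, MISSING


@dataclass
class QCConfig:
    """Thresholds for the locus/sample filters.

    All rates and probabilities must lie in [0, 1].
    """

    min_locus_call_rate: float = 0.90
    min_sample_call_rate: float = 0.90
    hwe_p_threshold: float = 1e-6
    min_maf: float = 0.01
    enable_hwe: bool = True
    enable_maf: bool = True

    def validate(self) -> None:
        for name in ("min_locus_call_rate", "min_sample_call_rate", "hwe_p_threshold", "min_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


#: The three analysis-track presets (see module docstring).
PRESETS: dict[str, QCConfig] = {
    "pn_track": QCConfig(enable_hwe=True, enable_maf=False),
    "core_track": QCConfig(enable_hwe=True, enable_maf=True),
    "roh_track": QCConfig(enable_hwe=False, enable_maf=False),
}


def preset(name: str) -> QCConfig:
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown QC preset {name!r}; choose from {sorted(PRESETS)}") from None
    return QCConfig(**asdict(cfg))


@dataclass
class QCReport:
    """What survived and why the rest was removed.

    Locus removals use first-failure attribution, so
    ``n_loci_pass + sum(per-filter removals) == n_loci_input``.
    """

    n_loci_input: int = 0
    n_loci_pass: int = 0
    n_samples_input: int = 0
    n_samples_removed: int = 0
    n_loci_removed_call_rate: int = 0
    n_loci_removed_hwe: int = 0
    n_loci_removed_maf: int = 0
    removed_sample_ids: list[str] = field(default_factory=list)
    removed_locus_ids: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def locus_call_rate(dataset: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing calls per locus (length-N vector)."""
    if dataset.n_samples < 1:
        raise ValueError("need at least one sample")
    return 1.0 - (dataset.dosages == MISSING).mean(axis=0)


def sample_call_rate(dataset: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing calls per sample (length-n vector)."""
    if dataset.n_loci < 1:
        raise ValueError("need at least one locus")
    return 1.0 - (dataset.dosages == MISSING).mean(axis=1)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy–Weinberg test p-value for one locus.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose probability does not exceed that of
    the observed count (no mid-p adjustment) — the classic exact test as
    used by PLINK's ``--hwe``.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("at least one genotyped individual required")

    n_b = 2 * n_bb + n_ab
    n_rare = min(n_b, 2 * n - n_b)
    if n_rare == 0:
        return 1.0  # monomorphic: single attainable configuration

    # Heterozygote counts share the parity of the rare-allele count.
    het_values = list(range(n_rare % 2, n_rare + 1, 2))

    # Unnormalized probabilities via the standard recurrence
    #   P(h+2)/P(h) = [ (rare-h)(common-h) ] / [ (h+2)(h+1)/4 ]
    # where rare + common = 2n.
    common = 2 * n - n_rare
    probs = {}
    h = het_values[0]
    probs[h] = 1.0
    while h + 2 <= n_rare:
        probs[h + 2] = probs[h] * 4.0 * ((n_rare - h) / 2.0) * ((common - h) / 2.0) / (
            (h + 2.0) * (h + 1.0)
        )
        h += 2
    total = sum(probs.values())
    for k in probs:
        probs[k] /= total

    obs_het = n_ab
    if obs_het not in probs:
        raise ValueError(
            f"heterozygote count {obs_het} inconsistent with allele counts "
            f"(parity of rare-allele count {n_rare})"
        )
    p_obs = probs[obs_het]
    p = sum(v for v in probs.values() if v <= p_obs * (1.0 + 1e-12))
    return min(p, 1.0)


def _genotype_counts(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = dataset.dosages
    return (d == 0).sum(axis=0), (d == 1).sum(axis=0), (d == 2).sum(axis=0)


def hwe_pvalues(dataset: GenotypeDataset) -> np.ndarray:
    """HWE exact-test p-value per locus (NaN for fully missing loci)."""
    n0, n1, n2 = _genotype_counts(dataset)
    out = np.full(dataset.n_loci, np.nan)
    cache: dict[tuple[int, int, int], float] = {}
    for j in range(dataset.n_loci):
        key = (int(n0[j]), int(n1[j]), int(n2[j]))
        if sum(key) == 0:
            continue
        if key not in cache:
            cache[key] = hwe_exact_test(*key)
        out[j] = cache[key]
    return out


def apply_qc(dataset: GenotypeDataset, config: QCConfig) -> tuple[GenotypeDataset, QCReport]:
    """Filter a dataset per ``config`` and report what was removed.

    Stage order: (1) samples by call rate, (2) loci by call rate
    (recomputed on the surviving samples), (3) loci by HWE if enabled,
    (4) loci by MAF if enabled.
    """
    from .diversity import allele_frequencies

    config.validate()
    report = QCReport(
        n_loci_input=dataset.n_loci,
        n_samples_input=dataset.n_samples,
    )

    scr = sample_call_rate(dataset) if dataset.n_loci else np.ones(dataset.n_samples)
    keep_samples = scr >= config.min_sample_call_rate
    report.n_samples_removed = int((~keep_samples).sum())
    report.removed_sample_ids = [
        sid for sid, k in zip(dataset.sample_ids, keep_samples) if not k
    ]
    ds = dataset.subset(sample_idx=keep_samples)

    locus_ids = np.asarray(ds.locus_ids, dtype=object)
    if ds.n_samples == 0:
        # nobody left to genotype the loci: attribute them all to call rate
        report.n_loci_removed_call_rate = ds.n_loci
        report.removed_locus_ids = {"call_rate": locus_ids.tolist(), "hwe": [], "maf": []}
        return ds.subset(locus_idx=np.zeros(ds.n_loci, dtype=bool)), report
    lcr = locus_call_rate(ds)
    fail_cr = lcr < config.min_locus_call_rate

    fail_hwe = np.zeros(ds.n_loci, dtype=bool)
    if config.enable_hwe:
        with np.errstate(invalid="ignore"):
            pvals = hwe_pvalues(ds)
        fail_hwe = np.nan_to_num(pvals, nan=1.0) < config.hwe_p_threshold

    fail_maf = np.zeros(ds.n_loci, dtype=bool)
    if config.enable_maf:
        maf = allele_frequencies(ds)
        fail_maf = np.nan_to_num(maf, nan=0.0) < config.min_maf

    # first-failure attribution
    rm_cr = fail_cr
    rm_hwe = fail_hwe & ~rm_cr
    rm_maf = fail_maf & ~rm_cr & ~rm_hwe
    keep = ~(rm_cr | rm_hwe | rm_maf)

    report.n_loci_removed_call_rate = int(rm_cr.sum())
    report.n_loci_removed_hwe = int(rm_hwe.sum())
    report.n_loci_removed_maf = int(rm_maf.sum())
    report.n_loci_pass = int(keep.sum())
    report.removed_locus_ids = {
        "call_rate": locus_ids[rm_cr].tolist(),
        "hwe": locus_ids[rm_hwe].tolist(),
        "maf": locus_ids[rm_maf].tolist(),
    }
    return ds.subset(locus_idx=keep), report
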