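"""Synthetic genotype panels with known truth.

Because chip genotypes of real conservation herds are rarely public,
every pipeline stage here is validated against data generated with
known ground truth:

* :func:`simulate_founders` — unrelated founders in linkage
  equilibrium (clean relatedness truth);
* :func:`gene_drop` — transmission of founder haplotypes down an
  explicit pedigree, with Poisson crossovers (or fully unlinked loci),
  so pedigree relationships are exactly known;
* :func:`simulate_ld_panel` — locus *pairs* with a prescribed
  E[r²] = 1/(1 + 4·Ne·c), the Sved relation, for Ne recovery tests;
* :func:`implant_roh` — autozygous tracts written into a
  heterozygosity-rich background, for ROH recovery tests;
* :func:`simulate_papershape` — a herd-shaped preset (54 animals:
  6 boars in 4 sire lines + 48 sows, ~50k SNPs on 18 autosomes,
  implanted ROH) exercising the whole pipeline end to end.

All generators are deterministic given their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset, LOCUS_COLUMNS, MISSING, SAMPLE_COLUMNS


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    sire: str | None
    dam: str | None
    sex: str = "unknown"


@dataclass
class Pedigree:
    """Ordered pedigree; founders (no parents) must precede offspring."""

    individuals: list[PedigreeMember]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.individuals:
            if m.id in seen:
                raise ValueError(f"duplicate pedigree id {m.id!r}")
            if (m.sire is None) != (m.dam is None):
                raise ValueError(f"{m.id!r}: both parents or neither must be given")
            for parent in (m.sire, m.dam):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"{m.id!r}: parent {parent!r} not defined earlier in pedigree"
                    )
            seen.add(m.id)

    @property
    def founder_ids(self) -> list[str]:
        return [m.id for m in self.individuals if m.sire is None]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.individuals]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tsire\tdam\tsex\n")
            for m in self.individuals:
                fh.write(f"{m.id}\t{m.sire or '0'}\t{m.dam or '0'}\t{m.sex}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
        members = [
            PedigreeMember(
                r.id,
                None if r.sire == "0" else r.sire,
                None if r.dam == "0" else r.dam,
                r.sex,
            )
            for r in df.itertuples(index=False)
        ]
        return cls(members)


@dataclass
class SimConfig:
    """Knobs of the synthetic chip panel.

    Defaults emulate a ~50k-SNP porcine breeding array laid out on 18
    equally long autosomes (total ≈ 2.45 Gb) with founder minor-allele
    frequencies drawn uniformly and a uniform 1 cM/Mb genetic map.
    """

    n_loci: int = 50_000
    n_chromosomes: int = 18
    chrom_length_bp: int = 136_137_000
    n_founders: int = 54
    founder_maf_range: tuple[float, float] = (0.05, 0.95)
    monomorphic_fraction: float = 0.0
    missing_rate: float = 0.0
    recombination_rate_cm_per_mb: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_loci, self.n_chromosomes, self.chrom_length_bp, self.n_founders) <= 0:
            raise ValueError("counts and lengths must be positive")
        lo, hi = self.founder_maf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("founder_maf_range must be an interval within [0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if not (0.0 <= self.monomorphic_fraction <= 1.0):
            raise ValueError("monomorphic_fraction must lie in [0, 1]")

    @property
    def genome_length_kb(self) -> float:
        return self.n_chromosomes * self.chrom_length_bp / 1000.0


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    # Distinct, reproducible stream per stochastic operation.
    return np.random.default_rng([int(config_seed), int(stream)])


def _locus_table(config: SimConfig) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    per_chrom[: config.n_loci % config.n_chromosomes] += 1
    rows = []
    for c in range(config.n_chromosomes):
        m = int(per_chrom[c])
        if m == 0:
            continue
        spacing = config.chrom_length_bp // (m + 1)
        if spacing < 1:
            raise ValueError("more loci than base pairs on a chromosome")
        chrom = str(c + 1)
        for k in range(m):
            pos = spacing * (k + 1)
            rows.append((f"snp_{chrom}_{k + 1}", chrom, pos, "A", "C"))
    return pd.DataFrame(rows, columns=LOCUS_COLUMNS)


def apply_missingness(
    dataset: GenotypeDataset, rate: float, rng: np.random.Generator
) -> GenotypeDataset:
    """Return a copy with calls independently masked at ``rate``."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    d = dataset.dosages.copy()
    if rate > 0:
        mask = rng.random(d.shape) < rate
        d[mask] = MISSING
    return GenotypeDataset(d, dataset.loci, dataset.samples)


def simulate_founders(
    config: SimConfig,
    sample_ids: list[str] | None = None,
    sexes: list[str] | None = None,
) -> GenotypeDataset:
    """Unrelated founders in linkage equilibrium, Binomial(2, p) per locus."""
    config.validate()
    rng = _rng(config.seed, 1)
    loci = _locus_table(config)
    n = config.n_founders if sample_ids is None else len(sample_ids)
    lo, hi = config.founder_maf_range
    p = rng.uniform(lo, hi, size=len(loci))
    if config.monomorphic_fraction > 0:
        # chip loci fixed in this population (allele B absent)
        p[rng.random(len(loci)) < config.monomorphic_fraction] = 0.0
    dosages = rng.binomial(2, p, size=(n, len(loci))).astype(np.int8)
    if sample_ids is None:
        sample_ids = [f"F{i + 1:03d}" for i in range(n)]
    if sexes is None:
        sexes = ["unknown"] * n
    samples = pd.DataFrame({"sample_id": sample_ids, "sex": sexes}, columns=SAMPLE_COLUMNS)
    ds = GenotypeDataset(dosages, loci, samples)
    if config.missing_rate > 0:
        ds = apply_missingness(ds, config.missing_rate, _rng(config.seed, 2))
    return ds


def _chromosome_blocks(loci: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    blocks = []
    for chrom in pd.unique(loci["chromosome"]):
        sel = np.flatnonzero((loci["chromosome"] == chrom).to_numpy())
        blocks.append((sel, loci["position_bp"].to_numpy()[sel]))
    return blocks


def _gamete(
    haps: np.ndarray,
    blocks: list[tuple[np.ndarray, np.ndarray]],
    chrom_len_bp: float,
    morgans_per_bp: float,
    rng: np.random.Generator,
    independent_loci: bool,
) -> np.ndarray:
    """One recombinant haplotype from a (2, m) parental pair."""
    m = haps.shape[1]
    if independent_loci:
        src = rng.integers(0, 2, size=m)
        return haps[src, np.arange(m)]
    out = np.empty(m, dtype=haps.dtype)
    for sel, pos in blocks:
        length_m = chrom_len_bp * morgans_per_bp
        n_x = rng.poisson(length_m)
        start = rng.integers(0, 2)
        if n_x == 0:
            src = np.full(sel.size, start)
        else:
            xpos = np.sort(rng.uniform(0, chrom_len_bp, size=n_x))
            src = (start + np.searchsorted(xpos, pos)) % 2
        out[sel] = haps[src, sel]
    return out


def gene_drop(
    pedigree: Pedigree,
    founders: GenotypeDataset,
    config: SimConfig,
    independent_loci: bool = False,
) -> GenotypeDataset:
    """Drop founder genotypes down the pedigree.

    Founder genotypes are randomly phased into two haplotypes; each
    non-founder inherits one recombinant haplotype per parent, with
    crossovers a Poisson process at ``recombination_rate_cm_per_mb``
    (no interference). With ``independent_loci=True`` every locus
    segregates independently (fully unlinked markers).

    Returns genotypes for *all* pedigree members, in pedigree order.
    """
    config.validate()
    rng = _rng(config.seed, 3)
    founder_pos = {sid: i for i, sid in enumerate(founders.sample_ids)}
    for fid in pedigree.founder_ids:
        if fid not in founder_pos:
            raise ValueError(f"pedigree founder {fid!r} absent from founder genotypes")
    if (founders.dosages[[founder_pos[f] for f in pedigree.founder_ids]] == MISSING).any():
        raise ValueError("founder genotypes must be complete (no missing calls) to phase")

    m = founders.n_loci
    blocks = _chromosome_blocks(founders.loci)
    morgans_per_bp = config.recombination_rate_cm_per_mb / 1e6 / 100.0
    chrom_len = float(config.chrom_length_bp)

    haplotypes: dict[str, np.ndarray] = {}
    for member in pedigree.individuals:
        if member.sire is None:
            g = founders.dosages[founder_pos[member.id]]
            h1 = (g == 2).astype(np.int8)
            h2 = h1.copy()
            het = g == 1
            which = rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
            h1[het] = which
            h2[het] = 1 - which
            haplotypes[member.id] = np.stack([h1, h2])
        else:
            pat = _gamete(
                haplotypes[member.sire], blocks, chrom_len, morgans_per_bp, rng, independent_loci
            )
            mat = _gamete(
                haplotypes[member.dam], blocks, chrom_len, morgans_per_bp, rng, independent_loci
            )
            haplotypes[member.id] = np.stack([pat, mat])

    dosages = np.stack([haplotypes[i].sum(axis=0) for i in pedigree.ids]).astype(np.int8)
    samples = pd.DataFrame(
        {"sample_id": pedigree.ids, "sex": [mm.sex for mm in pedigree.individuals]},
        columns=SAMPLE_COLUMNS,
    )
    return GenotypeDataset(dosages, founders.loci, samples)


def simulate_ld_panel(
    ne_true: float,
    config: SimConfig,
    pair_distance_bp: tuple[int, int] = (100_000, 5_000_000),
) -> GenotypeDataset:
    """Locus pairs whose expected r² follows Sved's relation at ``ne_true``.

    ``config.n_loci // 2`` pairs are generated, each on its own
    chromosome so only within-pair LD exists. The two loci of a pair
    share an allele frequency p (drawn from ``founder_maf_range``) and
    their haplotypes are correlated Bernoulli draws with haplotype
    correlation ρ = √(1/(1 + 4·Ne·c)); summing two independent
    haplotypes per individual then gives genotype dosages whose
    expected squared correlation is the Sved value at map distance c.
    """
    if ne_true <= 0:
        raise ValueError("ne_true must be positive")
    config.validate()
    rng = _rng(config.seed, 4)
    n = config.n_founders
    n_pairs = config.n_loci // 2
    lo_d, hi_d = pair_distance_bp

    loci_rows = []
    dosage_cols = np.empty((n, 2 * n_pairs), dtype=np.int8)
    lo, hi = config.founder_maf_range
    for k in range(n_pairs):
        d_bp = int(rng.integers(lo_d, hi_d + 1))
        c = d_bp / 1e6 * config.recombination_rate_cm_per_mb / 100.0
        rho = np.sqrt(1.0 / (1.0 + 4.0 * ne_true * c))
        p = rng.uniform(lo, hi)
        q = 1.0 - p
        p11 = p * p + rho * p * q
        p10 = p * q * (1.0 - rho)
        p00 = q * q + rho * p * q
        cum = np.cumsum([p00, p10, p10, p11])
        cats = np.searchsorted(cum, rng.random((n, 2)), side="right")
        x = (cats >= 2).sum(axis=1)  # first locus allele count
        y = ((cats == 1) | (cats == 3)).sum(axis=1)  # second locus
        dosage_cols[:, 2 * k] = x
        dosage_cols[:, 2 * k + 1] = y
        chrom = f"p{k + 1}"
        loci_rows.append((f"ld_{k + 1}_a", chrom, 1, "A", "C"))
        loci_rows.append((f"ld_{k + 1}_b", chrom, 1 + d_bp, "A", "C"))

    loci = pd.DataFrame(loci_rows, columns=LOCUS_COLUMNS)
    samples = pd.DataFrame(
        {"sample_id": [f"S{i + 1:03d}" for i in range(n)], "sex": "unknown"},
        columns=SAMPLE_COLUMNS,
    )
    ds = GenotypeDataset(dosage_cols, loci, samples)
    if config.missing_rate > 0:
        ds = apply_missingness(ds, config.missing_rate, _rng(config.seed, 5))
    return ds


def implant_roh(
    dataset: GenotypeDataset,
    plan: list[tuple[str, str, int, int]],
    seed: int = 0,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Make planned spans autozygous (homozygous runs).

    ``plan`` rows are (sample_id, chromosome, start_bp, end_bp),
    1-based inclusive. Within each span heterozygous calls of that
    sample are resolved to a homozygote by a fair per-locus coin flip —
    exactly the marginal effect of autozygosity, since an autozygous
    individual carries two copies of one of its two alleles with equal
    probability; homozygous and missing calls are left unchanged.
    Overlapping spans for one sample are rejected. Returns the modified
    dataset plus a truth table (with per-span SNP counts).
    """
    rng = np.random.default_rng([int(seed), 6])
    by_sample: dict[str, list[tuple[str, int, int]]] = {}
    for sid, chrom, s, e in plan:
        if e < s:
            raise ValueError(f"span end {e} before start {s} for {sid!r}")
        for oc, os_, oe in by_sample.get(sid, []):
            if oc == str(chrom) and not (e < os_ or s > oe):
                raise ValueError(f"overlapping spans for sample {sid!r} on chromosome {chrom}")
        by_sample.setdefault(sid, []).append((str(chrom), int(s), int(e)))

    d = dataset.dosages.copy()
    pos = dataset.loci["position_bp"].to_numpy(dtype=np.int64)
    chroms = dataset.loci["chromosome"].astype(str).to_numpy()
    sample_pos = {sid: i for i, sid in enumerate(dataset.sample_ids)}
    truth_rows = []
    for sid, chrom, s, e in plan:
        if sid not in sample_pos:
            raise KeyError(f"unknown sample {sid!r} in implant plan")
        sel = np.flatnonzero((chroms == str(chrom)) & (pos >= s) & (pos <= e))
        row = d[sample_pos[sid], sel]
        het = row == 1
        row[het] = rng.integers(0, 2, size=int(het.sum())).astype(np.int8) * 2
        d[sample_pos[sid], sel] = row
        truth_rows.append((sid, str(chrom), int(s), int(e), int(sel.size), (e - s + 1) / 1000.0))
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_kb"],
    )
    return GenotypeDataset(d, dataset.loci, dataset.samples), truth


# ---------------------------------------------------------------------------
# herd-shaped preset
# ---------------------------------------------------------------------------


def papershape_pedigree() -> tuple[Pedigree, dict]:
    """Pedigree of a 54-animal herd: 6 boars in 4 sire lines, 48 sows.

    Family A holds three paternal half-sib boars (shared sire GS1);
    families B, C, D one boar each (sires GS2–GS4). 23 sows are
    paternal half-sibs of the boars (8 via GS1, 5 each via GS2–GS4) and
    so belong to a boar family; the remaining 25 sows are unrelated
    founders, the separate 'distant' family. The truth mapping is
    returned alongside.
    """
    members: list[PedigreeMember] = []
    for i in range(1, 5):
        members.append(PedigreeMember(f"GS{i}", None, None, "male"))
    dam_counter = 0

    def new_dam() -> str:
        nonlocal dam_counter
        dam_counter += 1
        did = f"DAM{dam_counter:02d}"
        members.append(PedigreeMember(did, None, None, "female"))
        return did

    boar_truth: dict[str, str] = {}
    boars = []
    for k in range(3):
        bid = f"BOAR_A{k + 1}"
        members.append(PedigreeMember(bid, "GS1", new_dam(), "male"))
        boars.append(bid)
        boar_truth[bid] = "A"
    for fam, sire in zip("BCD", ("GS2", "GS3", "GS4")):
        bid = f"BOAR_{fam}1"
        members.append(PedigreeMember(bid, sire, new_dam(), "male"))
        boars.append(bid)
        boar_truth[bid] = fam

    sow_truth: dict[str, str] = {}
    sows = []
    per_sire = {"GS1": 8, "GS2": 5, "GS3": 5, "GS4": 5}
    fam_of_sire = {"GS1": "A", "GS2": "B", "GS3": "C", "GS4": "D"}
    idx = 0
    for sire, count in per_sire.items():
        for _ in range(count):
            idx += 1
            sid = f"SOW{idx:02d}"
            members.append(PedigreeMember(sid, sire, new_dam(), "female"))
            sows.append(sid)
            sow_truth[sid] = fam_of_sire[sire]
    for _ in range(25):
        idx += 1
        sid = f"SOW{idx:02d}"
        members.append(PedigreeMember(sid, None, None, "female"))
        sows.append(sid)
        sow_truth[sid] = "unassigned"

    ped = Pedigree(members)
    truth = {"boar_families": boar_truth, "sow_families": sow_truth}
    return ped, truth


def _roh_plan(
    cohort_ids: list[str],
    config: SimConfig,
    rng: np.random.Generator,
    n_tracts_range: tuple[int, int] = (35, 60),
    length_range_mb: tuple[float, float] = (3.0, 8.0),
    length_beta: tuple[float, float] = (1.0, 1.8),
) -> list[tuple[str, str, int, int]]:
    """Random non-overlapping autozygous tracts per individual.

    Tract counts are uniform on ``n_tracts_range`` and lengths
    ``lo + (hi−lo)·Beta(a, b)`` Mb — right-skewed so most tracts fall
    under 6 Mb; together these give a population mean F_ROH ≈ 0.09 on
    the default genome.
    """
    lo_mb, hi_mb = length_range_mb
    a, b = length_beta
    plan: list[tuple[str, str, int, int]] = []
    for sid in cohort_ids:
        n_tracts = int(rng.integers(n_tracts_range[0], n_tracts_range[1] + 1))
        placed: dict[str, list[tuple[int, int]]] = {}
        tries = 0
        while sum(len(v) for v in placed.values()) < n_tracts and tries < 50 * n_tracts:
            tries += 1
            length = int((lo_mb + (hi_mb - lo_mb) * rng.beta(a, b)) * 1e6)
            chrom = str(int(rng.integers(1, config.n_chromosomes + 1)))
            start = int(rng.integers(1, config.chrom_length_bp - length))
            end = start + length - 1
            if any(not (end < s or start > e) for s, e in placed.get(chrom, [])):
                continue
            placed.setdefault(chrom, []).append((start, end))
            plan.append((sid, chrom, start, end))
    return plan


def simulate_papershape(
    seed: int,
    n_loci: int = 50_000,
    missing_rate: float = 0.02,
    with_roh: bool = True,
) -> dict:
    """Generate the full herd-shaped cohort with all truth tables.

    Returns a dict with keys ``dataset`` (the 54-animal cohort),
    ``pedigree``, ``config``, ``boar_ids``, ``sow_ids``, ``truth``
    (family truth), and ``roh_truth`` (implanted tract table).
    """
    ped, truth = papershape_pedigree()
    # ~48.5% of chip loci are fixed in a single closed herd, so roughly
    # half the panel is monomorphic, as breeding arrays behave off-breed.
    config = SimConfig(n_loci=n_loci, monomorphic_fraction=0.485, missing_rate=0.0, seed=seed)
    founders = simulate_founders(config, sample_ids=ped.founder_ids)
    full = gene_drop(ped, founders, config)

    boar_ids = [m.id for m in ped.individuals if m.id.startswith("BOAR")]
    sow_ids = [m.id for m in ped.individuals if m.id.startswith("SOW")]
    cohort = full.select_samples(boar_ids + sow_ids)

    roh_truth = pd.DataFrame(
        columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_kb"]
    )
    if with_roh:
        plan = _roh_plan(cohort.sample_ids, config, _rng(seed, 7))
        cohort, roh_truth = implant_roh(cohort, plan, seed=seed)
    if missing_rate > 0:
        cohort = apply_missingness(cohort, missing_rate, _rng(seed, 8))
    cohort = cohort.sorted_loci()
    return {
        "dataset": cohort,
        "pedigree": ped,
        "config": config,
        "boar_ids": boar_ids,
        "sow_ids": sow_ids,
        "truth": truth,
        "roh_truth": roh_truth,
    }
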