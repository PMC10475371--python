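"""End-to-end herd characterization: QC → diversity → relatedness →
tree/families → ROH, with flat TSV/JSON outputs.

The single entry point :func:`run_characterize` mirrors how a
conservation-herd report is assembled: the panel is filtered three
ways (the polymorphism track keeps HWE-passing loci, the core track
additionally applies the MAF filter, the ROH track only call rates),
each statistic is computed on its track, and one ``summary.json``
collects the headline parameters (Ne, P_N, H_o, H_e, mean kinship,
mean F_ROH, family count).

All outputs are deterministic given the inputs; TSVs carry a
provenance comment line (tool version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import GenotypeDataset
from .diversity import (
    allele_frequencies,
    diversity_summary,
    estimate_ne,
    pairwise_r2,
)
from .clustering import (
    assign_sows,
    build_boar_families,
    family_table,
    neighbor_joining,
    write_newick,
)
from .qc import QCConfig, apply_qc, preset
from .relatedness import (
    ibs_distance,
    kinship_from_g,
    matrix_to_tsv,
    relationship_distribution,
    vanraden_g,
)
from .roh import (
    DEFAULT_AUTOSOME_LENGTH_KB,
    ROHParams,
    detect_roh,
    froh_table,
    population_mean_froh,
    roh_summary,
)

logger = logging.getLogger(__name__)

#: Distance bins (Morgans) for the Sved Ne profile: 0.5–5 Mb on a 1 cM/Mb map.
DEFAULT_NE_BINS: list[tuple[float, float]] = [
    (0.005, 0.01),
    (0.01, 0.02),
    (0.02, 0.03),
    (0.03, 0.04),
    (0.04, 0.05),
]


@dataclass
class RunConfig:
    """Everything one characterization run needs."""

    out_dir: str = "herdgen_out"
    qc: QCConfig = field(default_factory=QCConfig)
    roh_params: ROHParams = field(default_factory=ROHParams)
    ne_bins: list[tuple[float, float]] = field(default_factory=lambda: list(DEFAULT_NE_BINS))
    ne_max_distance_bp: int = 5_000_000
    ne_correction: str = "none"
    ne_summary: str = "harmonic_mean"
    cm_per_mb: float = 1.0
    family_threshold: float = 0.1
    ks_breaks: tuple[float, ...] = (0.125, 0.25, 0.5)
    pn_maf_threshold: float | None = None
    autosome_length_kb: float = DEFAULT_AUTOSOME_LENGTH_KB
    seed: int = 0

    def config_hash(self) -> str:
        params = asdict(self)
        params.pop("out_dir", None)  # scientific parameters only
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> dict:
    return {
        "tool": "herdgen",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def _prov_line(config: RunConfig) -> str:
    p = _provenance(config)
    return f"# herdgen {p['version']} config={p['config_hash']} seed={p['seed']}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_prov_line(config))
        df.to_csv(fh, sep="\t", index=False)


def _write_json(obj: dict, path: Path, config: RunConfig) -> None:
    obj = dict(obj)
    obj["provenance"] = _provenance(config)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_characterize(
    dataset: GenotypeDataset,
    config: RunConfig,
    boar_ids: list[str] | None = None,
) -> dict:
    """Run the full characterization and write the report bundle.

    Parameters
    ----------
    dataset
        The genotyped cohort (loci need not be pre-sorted).
    config
        Thresholds, ROH parameters, Ne bins, output directory.
    boar_ids
        Sires used for family construction; defaults to all samples
        recorded as male.

    Returns the ``summary.json`` content as a dict.
    """
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = dataset.sorted_loci()
    if boar_ids is None:
        boar_ids = dataset.samples.loc[dataset.samples["sex"] == "male", "sample_id"].tolist()

    def stage(name):
        logger.info("stage %-12s %6.1f s elapsed", name, time.monotonic() - t0)

    # --- three QC tracks ---------------------------------------------------
    tracks = {}
    qc_reports = {}
    for track in ("pn_track", "core_track", "roh_track"):
        cfg = preset(track)
        cfg.min_locus_call_rate = config.qc.min_locus_call_rate
        cfg.min_sample_call_rate = config.qc.min_sample_call_rate
        cfg.hwe_p_threshold = config.qc.hwe_p_threshold
        cfg.min_maf = config.qc.min_maf
        tracks[track], qc_reports[track] = apply_qc(dataset, cfg)
        stage(f"qc:{track}")
    _write_json(
        {t: r.to_dict() for t, r in qc_reports.items()}, out / "qc_report.json", config
    )

    core = tracks["core_track"]
    pn_ds = tracks["pn_track"]
    roh_ds = tracks["roh_track"]

    # --- diversity ---------------------------------------------------------
    div = diversity_summary(pn_ds, config.pn_maf_threshold)
    core_div = diversity_summary(core)
    ld = pairwise_r2(core, config.ne_max_distance_bp, config.cm_per_mb)
    dist = ld["dist_morgans"].to_numpy() if len(ld) else np.empty(0)
    bins = [(lo, hi) for lo, hi in config.ne_bins if ((dist > lo) & (dist <= hi)).any()]
    if len(bins) < len(config.ne_bins):
        logger.warning(
            "%d of %d Ne distance bins hold no locus pairs on this panel; skipped",
            len(config.ne_bins) - len(bins), len(config.ne_bins),
        )
    if bins:
        ne_table, summary_ne = estimate_ne(
            ld,
            bins,
            n_samples=core.n_samples,
            correction=config.ne_correction,
            summary=config.ne_summary,
        )
    else:
        ne_table = pd.DataFrame(
            columns=["bin_lo", "bin_hi", "c", "n_pairs", "mean_r2", "r2_adj", "ne", "generations_ago"]
        )
        summary_ne = float("nan")
    _write_tsv(ne_table, out / "ne_bins.tsv", config)
    _write_json(
        {
            "p_n": div.p_n,
            "m_polymorphic": div.m_polymorphic,
            "n_total_loci_pn_track": div.n_total_loci,
            "h_o": core_div.h_o,
            "h_e": core_div.h_e,
            "ne_summary": summary_ne,
            "ne_bins": ne_table.to_dict(orient="records"),
        },
        out / "diversity.json",
        config,
    )
    stage("diversity")

    # --- relatedness -------------------------------------------------------
    g = vanraden_g(core)
    ks = kinship_from_g(g)
    dist = ibs_distance(core)
    with open(out / "g_matrix.tsv", "w") as fh:
        fh.write(_prov_line(config))
        matrix_to_tsv(g.values, g.labels, fh)
    with open(out / "kinship.tsv", "w") as fh:
        fh.write(_prov_line(config))
        matrix_to_tsv(ks.values, ks.labels, fh)
    with open(out / "ibs_distance.tsv", "w") as fh:
        fh.write(_prov_line(config))
        matrix_to_tsv(dist.values, dist.labels, fh)
    ks_table, mean_ks = relationship_distribution(ks, config.ks_breaks)
    _write_tsv(ks_table, out / "ks_distribution.tsv", config)
    stage("relatedness")

    # --- tree + families ---------------------------------------------------
    tree = neighbor_joining(dist)
    write_newick(tree, out / "tree.nwk")
    families = build_boar_families(ks, boar_ids, config.family_threshold)
    sow_ids = [s for s in core.sample_ids if s not in set(boar_ids)]
    families = assign_sows(ks, families, sow_ids, config.family_threshold)
    _write_tsv(family_table(ks, families), out / "families.tsv", config)
    stage("families")

    # --- ROH ---------------------------------------------------------------
    segments = detect_roh(roh_ds, config.roh_params)
    _write_tsv(segments, out / "roh.tsv", config)
    froh_df = froh_table(segments, roh_ds.sample_ids, config.autosome_length_kb)
    _write_tsv(froh_df, out / "froh.tsv", config)
    _write_tsv(roh_summary(segments), out / "roh_summary.tsv", config)
    mean_froh = population_mean_froh(froh_df)
    stage("roh")

    summary = {
        "n_samples": int(core.n_samples),
        "n_loci_input": int(dataset.n_loci),
        "n_loci_pn_track": int(pn_ds.n_loci),
        "n_loci_core_track": int(core.n_loci),
        "n_loci_roh_track": int(roh_ds.n_loci),
        "ne": summary_ne,
        "pn": div.p_n,
        "ho": core_div.h_o,
        "he": core_div.h_e,
        "mean_ks": mean_ks,
        "mean_froh": mean_froh,
        "n_families": families.n_families,
        "n_sows_assigned": sum(1 for v in families.sow_assignments.values() if v != "unassigned"),
        "n_sows_unassigned": sum(
            1 for v in families.sow_assignments.values() if v == "unassigned"
        ),
    }
    _write_json(summary, out / "summary.json", config)
    stage("done")
    return summary


def run_simulate(seed: int, out_dir: str | Path, n_loci: int = 50_000) -> dict:
    """Generate the herd-shaped synthetic cohort and write it to disk.

    Writes PLINK text files, the pedigree, and the truth tables
    (family membership, implanted ROH tracts); returns the file map.
    """
    from .io import write_plink_text
    from .simulate import simulate_papershape

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_papershape(seed=seed, n_loci=n_loci)
    ped_path, map_path = write_plink_text(sim["dataset"], out / "cohort")
    sim["pedigree"].to_tsv(out / "pedigree.tsv")
    fam_truth = pd.DataFrame(
        [
            *[(b, "boar", f) for b, f in sim["truth"]["boar_families"].items()],
            *[(s, "sow", f) for s, f in sim["truth"]["sow_families"].items()],
        ],
        columns=["sample_id", "role", "family"],
    )
    fam_truth.to_csv(out / "family_truth.tsv", sep="\t", index=False)
    sim["roh_truth"].to_csv(out / "roh_truth.tsv", sep="\t", index=False)
    return {
        "ped": str(ped_path),
        "map": str(map_path),
        "pedigree": str(out / "pedigree.tsv"),
        "family_truth": str(out / "family_truth.tsv"),
        "roh_truth": str(out / "roh_truth.tsv"),
        "genome_length_kb": sim["config"].genome_length_kb,
    }
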