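"""Synthetic-data generators: determinism and statistical truth."""

import numpy as np
import pytest

from herdgen import (
    MISSING,
    Pedigree,
    PedigreeMember,
    SimConfig,
    apply_missingness,
    gene_drop,
    implant_roh,
    simulate_founders,
    simulate_ld_panel,
    simulate_papershape,
)
from herdgen.dataset import GenotypeDataset
from herdgen.diversity import alt_allele_frequencies, observed_heterozygosity, pairwise_r2
from herdgen.roh import ROHParams, detect_roh, froh_table, population_mean_froh

from conftest import make_dataset


class TestPedigree:
    def test_parent_must_precede_offspring(self):
        with pytest.raises(ValueError, match="not defined earlier"):
            Pedigree([PedigreeMember("kid", "dad", "mom", "female")])

    def test_tsv_round_trip(self, tmp_path):
        ped = Pedigree(
            [
                PedigreeMember("a", None, None, "male"),
                PedigreeMember("b", None, None, "female"),
                PedigreeMember("c", "a", "b", "female"),
            ]
        )
        ped.to_tsv(tmp_path / "ped.tsv")
        back = Pedigree.from_tsv(tmp_path / "ped.tsv")
        assert back.individuals == ped.individuals


class TestFounders:
    def test_bit_reproducible_given_seed(self):
        cfg = SimConfig(n_loci=500, n_founders=10, missing_rate=0.1, seed=42)
        assert simulate_founders(cfg) == simulate_founders(cfg)

    def test_different_seed_differs(self):
        a = simulate_founders(SimConfig(n_loci=500, n_founders=10, seed=1))
        b = simulate_founders(SimConfig(n_loci=500, n_founders=10, seed=2))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_degenerate_frequency_interval(self):
        cfg = SimConfig(n_loci=3000, n_founders=100, founder_maf_range=(0.5, 0.5), seed=3)
        p = alt_allele_frequencies(simulate_founders(cfg))
        assert p.mean() == pytest.approx(0.5, abs=0.01)

    def test_missing_rate_realized(self):
        cfg = SimConfig(n_loci=2000, n_founders=20, missing_rate=0.1, seed=4)
        ds = simulate_founders(cfg)
        assert (ds.dosages == MISSING).mean() == pytest.approx(0.1, abs=0.01)

    def test_monomorphic_fraction(self):
        cfg = SimConfig(n_loci=4000, n_founders=30, monomorphic_fraction=0.5, seed=5)
        ds = simulate_founders(cfg)
        mono = (ds.dosages == 0).all(axis=0).mean()
        assert mono == pytest.approx(0.5, abs=0.03)

    def test_loci_evenly_placed_and_sorted(self):
        cfg = SimConfig(n_loci=100, n_chromosomes=4, chrom_length_bp=10_000_000, n_founders=2)
        ds = simulate_founders(cfg)
        assert ds.is_sorted()
        assert ds.loci["chromosome"].nunique() == 4


def _trio_pedigree():
    return Pedigree(
        [
            PedigreeMember("sire", None, None, "male"),
            PedigreeMember("dam", None, None, "female"),
            PedigreeMember("kid1", "sire", "dam", "female"),
            PedigreeMember("kid2", "sire", "dam", "male"),
        ]
    )


class TestGeneDrop:
    def test_zero_recombination_transmits_intact_haplotypes(self):
        # sire heterozygous everywhere, dam carries no B alleles: the
        # child dosage *is* the paternal gamete, and without crossovers
        # two gametes from one parent are identical or complementary.
        m = 400
        d = np.vstack([np.ones(m), np.zeros(m)]).astype(np.int8)
        founders = make_dataset(d)
        founders.samples.loc[:, "sample_id"] = ["sire", "dam"]
        cfg = SimConfig(
            n_loci=m, n_chromosomes=1, recombination_rate_cm_per_mb=0.0, seed=9
        )
        out = gene_drop(_trio_pedigree(), founders, cfg)
        k1 = out.dosages[2]
        k2 = out.dosages[3]
        assert set(np.unique(k1)) <= {0, 1}
        assert np.array_equal(k1, k2) or np.array_equal(k1, 1 - k2)

    def test_allele_frequency_conserved_in_expectation(self):
        members = [
            PedigreeMember(f"P{i}", None, None, "male" if i % 2 == 0 else "female")
            for i in range(40)
        ]
        members += [
            PedigreeMember(f"C{i}", f"P{2 * (i % 20)}", f"P{2 * (i % 20) + 1}", "unknown")
            for i in range(40)
        ]
        ped = Pedigree(members)
        cfg = SimConfig(n_loci=3000, n_founders=40, seed=10)
        founders = simulate_founders(cfg, sample_ids=ped.founder_ids)
        out = gene_drop(ped, founders, cfg)
        kids = out.select_samples([f"C{i}" for i in range(40)])
        pf = alt_allele_frequencies(founders)
        pk = alt_allele_frequencies(kids)
        assert np.mean(np.abs(pf - pk)) < 0.08
        assert np.mean(pf - pk) == pytest.approx(0.0, abs=0.01)

    def test_selfing_accumulates_autozygosity(self):
        """Mean F_ROH rises with generations of selfing."""
        n_lines = 8

        def mean_froh(gens, seed):
            members = [PedigreeMember(f"L{l}_g0", None, None, "unknown") for l in range(n_lines)]
            for g in range(1, gens + 1):
                members += [
                    PedigreeMember(f"L{l}_g{g}", f"L{l}_g{g-1}", f"L{l}_g{g-1}", "unknown")
                    for l in range(n_lines)
                ]
            ped = Pedigree(members)
            cfg = SimConfig(
                n_loci=3000, n_chromosomes=2, chrom_length_bp=100_000_000,
                n_founders=n_lines, seed=seed,
            )
            founders = simulate_founders(cfg, sample_ids=ped.founder_ids)
            out = gene_drop(ped, founders, cfg)
            last = out.select_samples([f"L{l}_g{gens}" for l in range(n_lines)])
            segs = detect_roh(last, ROHParams())
            table = froh_table(segs, last.sample_ids, cfg.genome_length_kb)
            return population_mean_froh(table)

        assert mean_froh(4, seed=21) > mean_froh(1, seed=21) + 0.1

    def test_missing_founder_rejected(self):
        founders = make_dataset(np.zeros((1, 10), dtype=np.int8))
        founders.samples.loc[:, "sample_id"] = ["sire"]
        with pytest.raises(ValueError, match="absent"):
            gene_drop(_trio_pedigree(), founders, SimConfig(n_loci=10, n_founders=1))


class TestLdPanel:
    def test_reproducible(self):
        cfg = SimConfig(n_loci=400, n_founders=50, seed=6)
        assert simulate_ld_panel(50, cfg) == simulate_ld_panel(50, cfg)

    def test_target_r2_at_short_distance(self):
        cfg = SimConfig(n_loci=1600, n_founders=300, seed=7)
        # all pairs at c = 0.005 M: target r2 = 1/(1 + 4*50*0.005) = 0.5
        ds = simulate_ld_panel(50, cfg, pair_distance_bp=(500_000, 500_000))
        ld = pairwise_r2(ds.sorted_loci(), max_distance_bp=600_000)
        assert ld["r_squared"].mean() == pytest.approx(0.5, abs=0.04)

    def test_independence_limit_hits_noise_floor(self):
        n = 400
        cfg = SimConfig(n_loci=1600, n_founders=n, seed=8)
        ds = simulate_ld_panel(50_000, cfg, pair_distance_bp=(4_000_000, 5_000_000))
        ld = pairwise_r2(ds.sorted_loci(), max_distance_bp=5_000_000)
        assert ld["r_squared"].mean() == pytest.approx(1 / n, abs=1.5 / n)


class TestImplantRoh:
    def test_empty_plan_leaves_dataset_unchanged(self, rng):
        from conftest import random_dataset

        ds = random_dataset(rng, n=4, m=10)
        out, truth = implant_roh(ds, [])
        assert out == ds and len(truth) == 0

    def test_spans_become_homozygous_elsewhere_untouched(self, rng):
        cfg = SimConfig(n_loci=500, n_chromosomes=1, chrom_length_bp=10_000_000,
                        n_founders=3, seed=12)
        ds = simulate_founders(cfg)
        out, truth = implant_roh(ds, [("F001", "1", 2_000_000, 6_000_000)], seed=12)
        pos = ds.loci["position_bp"].to_numpy()
        inside = (pos >= 2_000_000) & (pos <= 6_000_000)
        assert not (out.dosages[0, inside] == 1).any()
        np.testing.assert_array_equal(out.dosages[0, ~inside], ds.dosages[0, ~inside])
        np.testing.assert_array_equal(out.dosages[1:], ds.dosages[1:])
        assert truth.loc[0, "n_snps"] == int(inside.sum())

    def test_overlapping_spans_rejected(self, rng):
        from conftest import random_dataset

        ds = random_dataset(rng, n=2, m=10)
        plan = [("s0", "1", 100, 5000), ("s0", "1", 4000, 9000)]
        with pytest.raises(ValueError, match="overlapping"):
            implant_roh(ds, plan)


class TestPapershapePreset:
    def test_cohort_structure_and_truth_tables(self):
        sim = simulate_papershape(seed=2, n_loci=4000)
        ds = sim["dataset"]
        assert ds.n_samples == 54
        assert len(sim["boar_ids"]) == 6 and len(sim["sow_ids"]) == 48
        truth = sim["truth"]
        assert sorted(set(truth["boar_families"].values())) == ["A", "B", "C", "D"]
        assert sum(1 for v in truth["sow_families"].values() if v == "unassigned") == 25
        assert ds.loci["chromosome"].nunique() == 18
        assert isinstance(ds, GenotypeDataset)

    def test_reproducible(self):
        a = simulate_papershape(seed=3, n_loci=2000)
        b = simulate_papershape(seed=3, n_loci=2000)
        assert a["dataset"] == b["dataset"]
        assert a["roh_truth"].equals(b["roh_truth"])
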