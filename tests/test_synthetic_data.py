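"""Generator behaviour: divergence model, pedigree, meiosis, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ailfm.io_formats import PedigreeTable
from ailfm.synthetic_data import (
    RegionSpec,
    SimulationConfig,
    build_marker_map,
    recombination_fractions,
    simulate_ail,
    simulate_founder_lines,
    simulate_pedigree,
    _meiose,
)
from tests.conftest import small_config


class TestDivergenceModel:
    def test_fixation_limit(self):
        cfg = small_config(f_fixed=1.0)
        _, _, _, freqs = simulate_founder_lines(cfg)
        delta = (freqs["p_hws"] - freqs["p_lws"]).abs()
        assert (delta == 1.0).all()

    def test_null_limit_no_divergence(self):
        # concentrated Beta puts both lines at ~0.5: only sampling noise
        cfg = small_config(f_fixed=0.0, beta_shape=(5e5, 5e5))
        _, _, _, freqs = simulate_founder_lines(cfg)
        delta = (freqs["p_hws"] - freqs["p_lws"]).abs()
        assert delta.mean() < 0.01

    def test_delta_af_distribution_matches_mixture(self):
        # distributional oracle: an independent sample from the configured
        # Beta-mixture, compared by two-sample KS at large n
        cfg = small_config(
            regions=(RegionSpec("R", "GGA1", 1, 200_000_000, 2000, 0),)
        )
        _, _, _, freqs = simulate_founder_lines(cfg)
        delta = (freqs["p_hws"] - freqs["p_lws"]).abs().to_numpy()
        rng = np.random.default_rng(12345)
        n = 20_000
        fixed = rng.random(n) < cfg.f_fixed
        a, b = cfg.beta_shape
        oracle = np.abs(rng.beta(a, b, n) - rng.beta(a, b, n))
        oracle[fixed] = 1.0
        ks = stats.ks_2samp(delta, oracle)
        assert ks.pvalue > 0.01

    def test_both_regimes_present_at_defaults(self):
        cfg = small_config()
        _, _, _, freqs = simulate_founder_lines(cfg)
        delta = (freqs["p_hws"] - freqs["p_lws"]).abs()
        assert (delta == 1.0).any()  # alternative fixation
        assert (delta < 0.5).any()   # still segregating


class TestPedigree:
    def test_structure_and_size_at_defaults(self, sim):
        ped = sim.pedigree
        gens = ped.table["generation"].unique().tolist()
        assert gens == [f"F{i}" for i in range(9)]
        assert abs(len(ped) - 1536) / 1536 < 0.10
        gen_of = dict(zip(ped.table["id"], ped.table["generation"]))
        for row in ped.table.itertuples():
            if row.generation != "F0":
                expected = f"F{int(row.generation[1:]) - 1}"
                assert gen_of[row.sire] == expected
                assert gen_of[row.dam] == expected

    def test_f1_is_reciprocal_line_cross(self, sim):
        lines = sim.pedigree.line_of()
        f1 = sim.pedigree.table[sim.pedigree.table["generation"] == "F1"]
        for row in f1.itertuples():
            assert {lines[row.sire], lines[row.dam]} == {"HWS", "LWS"}

    def test_minimal_chain_pedigree(self):
        cfg = small_config(
            n_hws=2, n_lws=2, n_per_generation=2, n_breeding_pairs=None
        )
        _, _, f0, _ = simulate_founder_lines(cfg)
        ped = simulate_pedigree(cfg, f0)
        sizes = ped.table.groupby("generation").size()
        assert (sizes.drop("F0") == 2).all()

    def test_single_sex_founders_error(self):
        cfg = small_config()
        f0 = PedigreeTable(
            pd.DataFrame(
                {
                    "id": ["H1", "L1"],
                    "sire": [None, None],
                    "dam": [None, None],
                    "sex": ["M", "M"],
                    "generation": ["F0", "F0"],
                    "line": ["HWS", "LWS"],
                }
            )
        )
        with pytest.raises(ValueError, match="too few"):
            simulate_pedigree(cfg, f0)

    def test_no_full_sib_matings(self, sim):
        parents = sim.pedigree.parents_of()
        for row in sim.pedigree.table.itertuples():
            if row.generation in ("F0", "F1"):
                continue
            assert parents[row.sire] != parents[row.dam]


class TestGeneDrop:
    def test_no_recombination_transmits_intact_haplotypes(self):
        cfg = small_config(cm_per_mb=0.0)
        sim = simulate_ail(cfg)
        idx = {i: k for k, i in enumerate(sim.haplotypes.ids)}
        chrom = sim.marker_map.table["chrom"].to_numpy()
        for row in sim.pedigree.table.itertuples():
            if row.generation == "F0":
                continue
            i = idx[row.id]
            for h, par in enumerate((row.sire, row.dam)):
                j = idx[str(par)]
                for c in np.unique(chrom):
                    sel = chrom == c
                    child = sim.haplotypes.alleles[i, h, sel]
                    match = any(
                        (child == sim.haplotypes.alleles[j, hp, sel]).all()
                        for hp in (0, 1)
                    )
                    assert match

    def test_single_marker_fair_coin(self):
        # 10,000 gametes from one heterozygous-haplotype parent
        rng = np.random.default_rng(5)
        alleles = np.array([[0], [1]], dtype=np.int8)
        origin = np.array([[0], [1]], dtype=np.int32)
        rec = np.array([0.5])
        picks = [
            _meiose(alleles, origin, rec, rng)[0][0] for _ in range(10_000)
        ]
        share = np.mean(picks)
        assert abs(share - 0.5) < 0.015

    def test_haldane_closed_form_recombinant_fraction(self):
        # adjacent markers 1 Mb apart at 3 cM/Mb: r = (1-exp(-0.06))/2
        rng = np.random.default_rng(17)
        alleles = np.array([[0, 0], [1, 1]], dtype=np.int8)
        origin = np.array([[0, 0], [1, 1]], dtype=np.int32)
        mmap = build_marker_map(
            small_config(regions=(RegionSpec("R", "GGA1", 1, 1_000_001, 2, 0),))
        )
        rec = recombination_fractions(mmap, cm_per_mb=3.0)
        assert rec[0] == 0.5
        expected = 0.5 * (1 - np.exp(-0.06))
        recomb = 0
        n = 50_000
        for _ in range(n):
            g, _ = _meiose(alleles, origin, rec, rng)
            recomb += int(g[0] != g[1])
        assert abs(recomb / n - expected) < 0.003

    def test_mendelian_consistency_exhaustive(self, sim):
        haps, ped = sim.haplotypes, sim.pedigree
        idx = {i: k for k, i in enumerate(haps.ids)}
        for row in ped.table.itertuples():
            if row.generation == "F0":
                continue
            i = idx[row.id]
            for h, par in enumerate((row.sire, row.dam)):
                j = idx[str(par)]
                ok = (haps.alleles[i, h] == haps.alleles[j, 0]) | (
                    haps.alleles[i, h] == haps.alleles[j, 1]
                )
                assert ok.all()

    def test_origin_points_to_correct_line_founders(self, sim):
        lines = sim.pedigree.line_of()
        founder_line = np.array(
            [lines[f] for f in sim.haplotypes.founder_ids]
        )
        f1_rows = [
            k
            for k, iid in enumerate(sim.haplotypes.ids)
            if iid.startswith("F1_")
        ]
        # F1 paternal/maternal gametes come from single founders of the
        # sire's and dam's lines respectively
        ped = sim.pedigree.table.set_index("id")
        for k in f1_rows[:20]:
            iid = sim.haplotypes.ids[k]
            for h, parent_col in ((0, "sire"), (1, "dam")):
                parent = ped.at[iid, parent_col]
                orig = sim.haplotypes.origin[k, h] // 2
                assert len(np.unique(founder_line[orig])) == 1
                assert founder_line[orig][0] == lines[parent]

    def test_allele_frequency_drift_is_unbiased(self):
        # neutral marker: F8 frequency equals the F0 AIL frequency in
        # expectation; z-test over replicate simulations at alpha=0.01
        diffs, vars_ = [], []
        for seed in range(25):
            cfg = small_config(
                seed=1000 + seed,
                regions=(RegionSpec("R", "GGA1", 1, 2_000_000, 6, 0),),
            )
            s = simulate_ail(cfg)
            gen = s.pedigree.table.set_index("id")["generation"]
            dose = s.haplotypes.dosages()
            f0 = dose.loc[gen[gen == "F0"].index].mean() / 2.0
            f8 = dose.loc[gen[gen == "F8"].index].mean() / 2.0
            diffs.append((f8 - f0).mean())
        z = np.mean(diffs) / (np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
        assert abs(z) < stats.norm.ppf(1 - 0.01 / 2)


class TestPhenotypes:
    def test_noise_free_limit_recovers_mu(self):
        cfg = small_config(
            sigma_e=1e-9, sex_effect=0.0,
            generation_effects=(0,) * 7, qtl_spec=(),
        )
        s = simulate_ail(cfg)
        ph = s.phenotypes.phenotyped()
        assert np.allclose(ph["bw56"], cfg.mu)

    def test_additive_effect_analytic_expectation(self):
        cfg = small_config(seed=3)
        mm = build_marker_map(cfg)
        # pick a backbone marker segregating near 0.5 so both homozygote
        # classes are populated
        _, _, _, freqs = simulate_founder_lines(cfg)
        freqs = freqs.set_index("marker")
        backbone = mm.table[mm.table.source == "backbone"]["marker"]
        mean_f = ((freqs["p_hws"] + freqs["p_lws"]) / 2).loc[backbone]
        qtl = (mean_f - 0.5).abs().idxmin()
        cfg.qtl_spec = ((qtl, 20.0),)
        cfg.sigma_e = 1.0
        s = simulate_ail(cfg)
        ph = s.phenotypes.phenotyped().set_index("id")
        dose = s.haplotypes.dosages()[qtl].reindex(ph.index)
        females_f2_f7 = ph[(ph.sex == "F") & (ph.generation != "F8")]
        d = dose.reindex(females_f2_f7.index)
        m2 = females_f2_f7.loc[d == 2, "bw56"].mean()
        m0 = females_f2_f7.loc[d == 0, "bw56"].mean()
        assert abs((m2 - m0) - 40.0) < 1.0

    def test_f8_mean_below_earlier_generations(self, sim):
        ph = sim.phenotypes.phenotyped()
        means = ph.groupby("generation")["bw56"].mean()
        assert (means["F8"] < means.drop("F8")).all()

    def test_only_f2_to_f8_phenotyped(self, sim):
        tab = sim.phenotypes.table
        assert tab.loc[
            tab["generation"].isin(["F0", "F1"]), "bw56"
        ].isna().all()


class TestMasking:
    def test_full_dense_founder_fraction_no_founder_missingness(self):
        cfg = small_config(dense_founder_fraction=1.0)
        s = simulate_ail(cfg)
        founders = s.pedigree.founder_ids
        assert s.observed.dosages.loc[founders].notna().all().all()

    def test_dense_markers_fully_missing_outside_founders(self, sim):
        dense = sim.marker_map.table.loc[
            sim.marker_map.table.source == "dense", "marker"
        ]
        non_founders = [
            i for i in sim.observed.individual_ids
            if i not in set(sim.pedigree.founder_ids)
        ]
        assert sim.observed.dosages.loc[non_founders, dense].isna().all().all()

    def test_observed_never_disagrees_with_truth(self, sim):
        truth = sim.haplotypes.dosages().astype(float)
        obs = sim.observed.dosages
        mask = obs.notna().to_numpy()
        assert (obs.to_numpy()[mask] == truth.to_numpy()[mask]).all()


def test_reproducibility_bitwise():
    a = simulate_ail(small_config(seed=42))
    b = simulate_ail(small_config(seed=42))
    assert np.array_equal(a.haplotypes.alleles, b.haplotypes.alleles)
    assert np.array_equal(a.haplotypes.origin, b.haplotypes.origin)
    pd.testing.assert_frame_equal(a.pedigree.table, b.pedigree.table)
    pd.testing.assert_frame_equal(a.phenotypes.table, b.phenotypes.table)
    pd.testing.assert_frame_equal(a.observed.dosages, b.observed.dosages)
    assert a.dense_founder_ids == b.dense_founder_ids


def test_zero_marker_region_rejected():
    with pytest.raises(ValueError, match="zero markers"):
        SimulationConfig(
            regions=(RegionSpec("R", "GGA1", 1, 100, 0, 0),)
        )
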