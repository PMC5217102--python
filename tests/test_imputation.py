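"""Phasing, segment painting and dense imputation against simulator truth."""

import numpy as np
import pandas as pd
import pytest

from ailfm.evaluate import (
    backbone_phase_accuracy,
    imputation_metrics,
    painting_accuracy,
)
from ailfm.imputation import (
    FounderDenseHaplotypes,
    ImputedGenotypes,
    MendelianError,
    impute_dense,
    impute_pipeline,
    paint_founder_segments,
    phase_backbone,
    phase_founder_dense,
)
from ailfm.io_formats import GenotypeMatrix, MarkerMap, PedigreeTable
from ailfm.synthetic_data import simulate_ail
from tests.conftest import small_config


def _trio(sire_d, dam_d, child_d, n_markers=1):
    ped = PedigreeTable(
        pd.DataFrame(
            {
                "id": ["S", "D", "C"],
                "sire": [None, None, "S"],
                "dam": [None, None, "D"],
                "sex": ["M", "F", "F"],
                "generation": ["F0", "F0", "F1"],
                "line": ["HWS", "LWS", None],
            }
        )
    )
    markers = [f"m{j}" for j in range(n_markers)]
    mmap = MarkerMap(
        pd.DataFrame(
            {
                "marker": markers,
                "chrom": ["1"] * n_markers,
                "pos_bp": [100 * (j + 1) for j in range(n_markers)],
                "region": [None] * n_markers,
                "source": ["backbone"] * n_markers,
            }
        )
    )
    geno = GenotypeMatrix(
        pd.DataFrame(
            [sire_d, dam_d, child_d],
            index=["S", "D", "C"],
            columns=markers,
            dtype=float,
        )
    )
    return geno, ped, mmap


class TestPhaseBackbone:
    def test_het_child_forced_by_homozygous_parents(self):
        geno, ped, mmap = _trio([0], [2], [1])
        phased = phase_backbone(geno, ped, mmap)
        c = phased.index_of("C")
        # paternal haplotype carries the sire's (dosage-0) allele
        assert phased.alleles[c, 0, 0] == 0.0
        assert phased.alleles[c, 1, 0] == 1.0

    def test_all_homozygous_fully_phased(self):
        geno, ped, mmap = _trio([2, 0], [2, 0], [2, 0], n_markers=2)
        phased = phase_backbone(geno, ped, mmap)
        assert not np.isnan(phased.alleles).any()

    def test_mendelian_violation_names_trio_and_marker(self):
        geno, ped, mmap = _trio([0], [0], [2])
        with pytest.raises(MendelianError) as err:
            phase_backbone(geno, ped, mmap)
        msg = str(err.value)
        assert "C" in msg and "S" in msg and "m0" in msg

    def test_mask_mode_blanks_violating_call(self):
        geno, ped, mmap = _trio([0], [0], [2])
        phased = phase_backbone(geno, ped, mmap, mode="mask")
        c = phased.index_of("C")
        assert np.isnan(phased.alleles[c, :, 0]).all()

    def test_phase_accuracy_against_truth(self, sim, imputed_bundle):
        _, phased, _ = imputed_bundle
        acc = backbone_phase_accuracy(phased, sim.haplotypes, sim.pedigree)
        assert acc["accuracy_overall"] >= 0.95

    def test_phasing_consistent_with_observed_dosages(self, sim, imputed_bundle):
        _, phased, _ = imputed_bundle
        dos = sim.observed.dosages[phased.marker_ids].to_numpy(dtype=float)
        summed = phased.alleles.sum(axis=1)
        resolved = ~np.isnan(summed)
        assert np.array_equal(summed[resolved], dos[resolved])


class TestPainting:
    def test_zero_recombination_single_segment(self):
        """Without recombination every gamete is an intact founder
        haplotype, so each haplotype-chromosome should carry one founder
        label.  Rule-based phasing admits rare block ambiguities (runs of
        jointly unconstrained heterozygotes), so the property is asserted
        at the population level with a tight bound."""
        cfg = small_config(seed=21, cm_per_mb=0.0)
        s = simulate_ail(cfg)
        phased = phase_backbone(s.observed, s.pedigree, s.marker_map)
        painting = paint_founder_segments(phased, s.pedigree, s.marker_map)
        chroms = painting.chroms
        n_units = n_single = n_pos = n_gap = 0
        for i in range(len(painting.ids)):
            for h in (0, 1):
                for c in np.unique(chroms):
                    seg = painting.origin[i, h, chroms == c]
                    labels = np.unique(seg[seg >= 0])
                    n_units += 1
                    n_single += int(len(labels) <= 1)
                    n_pos += len(seg)
                    n_gap += int((seg < 0).sum())
        assert n_single / n_units >= 0.995
        assert n_gap / n_pos <= 0.02

    def test_f1_has_one_founder_label_per_line_per_homolog(self, sim, imputed_bundle):
        _, _, painting = imputed_bundle
        lines = sim.pedigree.line_of()
        founder_line = np.array(
            [lines[f] for f in painting.founder_ids]
        )
        ped = sim.pedigree.table.set_index("id")
        f1_ids = [i for i in painting.ids if i.startswith("F1_")][:20]
        for iid in f1_ids:
            k = painting.ids.index(iid)
            for h, col in ((0, "sire"), (1, "dam")):
                seg = painting.origin[k, h]
                labelled = seg[seg >= 0]
                assert len(labelled)
                assert (founder_line[labelled // 2] == lines[ped.at[iid, col]]).all()

    def test_painting_agreement_with_truth(self, sim, imputed_bundle):
        _, _, painting = imputed_bundle
        acc = painting_accuracy(painting, sim.haplotypes, sim.pedigree)
        assert acc["agreement_outside_gaps"] >= 0.90


class TestImputeDense:
    def test_error_rate_and_preservation(self, sim, imputed_bundle):
        imputed, _, _ = imputed_bundle
        m = imputation_metrics(imputed, sim.haplotypes, sim.observed)
        assert m["observed_preserved"]
        assert m["imputed_error_rate"] <= 0.02
        # two-tier design cap: both homologs must trace to one of the 40/59
        # dense-genotyped founders through confidently phased sites
        assert m["call_rate_missing"] >= 0.10

    def test_no_dense_founders_degrades_to_missing(self):
        cfg = small_config(seed=23, dense_founder_fraction=0.0)
        s = simulate_ail(cfg)
        imputed, _, _ = impute_pipeline(
            s.observed, s.pedigree, s.marker_map, [], seed=1
        )
        dense = s.marker_map.table.loc[
            s.marker_map.table.source == "dense", "marker"
        ]
        assert imputed.genotypes.dosages[dense].isna().all().all()
        assert (imputed.provenance[dense] != ImputedGenotypes.IMPUTED).all().all()

    def test_unknown_founder_reference_rejected(self, sim, imputed_bundle):
        _, _, painting = imputed_bundle
        fd = FounderDenseHaplotypes(
            ["GHOST"],
            sim.marker_map.table.loc[
                sim.marker_map.table.source == "dense", "marker"
            ].tolist(),
            np.zeros((1, 2, 270)),
            np.zeros((1, 270), dtype=bool),
        )
        with pytest.raises(ValueError, match="GHOST"):
            impute_dense(painting, fd, sim.marker_map, sim.observed)

    def test_determinism_given_seed(self, sim):
        runs = [
            impute_pipeline(
                sim.observed,
                sim.pedigree,
                sim.marker_map,
                sim.dense_founder_ids,
                seed=5,
            )[0]
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(
            runs[0].genotypes.dosages, runs[1].genotypes.dosages
        )
        pd.testing.assert_frame_equal(runs[0].provenance, runs[1].provenance)

    def test_denser_backbone_does_not_hurt_accuracy(self, sim):
        """Monotone information: demoting half the backbone markers to
        dense status (same meioses, fewer informative sites) must not
        DECREASE the imputation error on the shared dense markers."""
        mm = sim.marker_map.table.copy()
        backbone_idx = mm.index[mm.source == "backbone"]
        demoted = mm.copy()
        demoted.loc[backbone_idx[::2], "source"] = "dense"
        sparse_map = type(sim.marker_map)(demoted, sim.marker_map.region_bounds)
        # observation under the sparser design, from the same haplotypes
        dense_cols = demoted.loc[demoted.source == "dense", "marker"]
        dos = sim.haplotypes.dosages().astype(float)
        hidden = [
            i for i in dos.index if i not in set(sim.dense_founder_ids)
        ]
        dos.loc[hidden, dense_cols] = np.nan
        sparse_obs = GenotypeMatrix(dos)

        common_dense = sim.marker_map.table.loc[
            sim.marker_map.table.source == "dense", "marker"
        ].tolist()
        truth = sim.haplotypes.dosages()

        def error_rate(imp):
            mask = (
                imp.provenance[common_dense] == ImputedGenotypes.IMPUTED
            ).to_numpy()
            out = imp.genotypes.dosages[common_dense].to_numpy()
            tru = truth[common_dense].to_numpy()
            return (out[mask] != tru[mask]).mean()

        imp_dense, _, _ = impute_pipeline(
            sim.observed, sim.pedigree, sim.marker_map,
            sim.dense_founder_ids, seed=5,
        )
        imp_sparse, _, _ = impute_pipeline(
            sparse_obs, sim.pedigree, sparse_map,
            sim.dense_founder_ids, seed=5,
        )
        assert error_rate(imp_dense) <= error_rate(imp_sparse) + 1e-12


class TestPhaseFounderDense:
    def test_all_homozygous_founder_trivially_phased(self, sim, imputed_bundle):
        _, _, painting = imputed_bundle
        founder_geno = sim.observed.subset(individuals=sim.dense_founder_ids)
        fd = phase_founder_dense(
            founder_geno, sim.pedigree, sim.marker_map, painting, seed=3
        )
        dos = founder_geno.dosages[fd.marker_ids].to_numpy(dtype=float)
        hom = np.isin(dos, (0.0, 2.0))
        assert not fd.uncertain[hom].any()
        assert np.array_equal(fd.alleles.sum(axis=1)[hom], dos[hom])

    def test_het_resolved_by_dense_genotyped_offspring(self, sim, imputed_bundle):
        """Operational check: handing the phaser the F1 offspring's true
        dense genotypes resolves founder heterozygote phase relative to
        the backbone, which must RAISE the imputation call rate while
        keeping the error within the conservative bound."""
        imputed_base, _, painting = imputed_bundle
        founder_geno = sim.observed.subset(individuals=sim.dense_founder_ids)
        offspring = [i for i in sim.pedigree.ids if i.startswith("F1_")]
        off_truth = GenotypeMatrix(
            sim.haplotypes.dosages().loc[offspring].astype(float)
        )
        fd = phase_founder_dense(
            founder_geno, sim.pedigree, sim.marker_map, painting,
            offspring_geno=off_truth, seed=3,
        )
        het = founder_geno.dosages[fd.marker_ids].to_numpy(dtype=float) == 1.0
        resolved_het = het & ~fd.uncertain & ~np.isnan(fd.alleles[:, 0, :])
        assert resolved_het.sum() > 100
        imputed = impute_dense(painting, fd, sim.marker_map, sim.observed)
        m = imputation_metrics(imputed, sim.haplotypes, sim.observed)
        base = imputation_metrics(imputed_base, sim.haplotypes, sim.observed)
        assert m["n_imputed"] > base["n_imputed"]
        assert m["imputed_error_rate"] <= 0.02

    def test_confidently_phased_sites_match_truth(self, sim, imputed_bundle):
        # without offspring dense data only homozygotes are confident;
        # they must match truth exactly
        _, _, painting = imputed_bundle
        founder_geno = sim.observed.subset(individuals=sim.dense_founder_ids)
        fd = phase_founder_dense(
            founder_geno, sim.pedigree, sim.marker_map, painting, seed=3
        )
        truth = sim.haplotypes
        cols = [truth.marker_ids.index(m) for m in fd.marker_ids]
        n_ok = n_tot = 0
        for fi, fid in enumerate(fd.founder_ids):
            ti = truth.index_of(fid)
            confident = ~fd.uncertain[fi] & ~np.isnan(fd.alleles[fi, 0])
            t = truth.alleles[ti][:, cols]
            same = (
                fd.alleles[fi].sum(axis=0) == t.sum(axis=0)
            )[confident]
            n_ok += int(same.sum())
            n_tot += int(confident.sum())
        assert n_tot and n_ok / n_tot >= 0.9
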