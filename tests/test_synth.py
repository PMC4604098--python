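"""Generators: planted truths are faithful, outputs deterministic and valid."""

import io

import numpy as np
import pandas as pd
import pytest

from fepi.foldchange import compute_fold_change, fold_change_table
from fepi.motif import P1BS, scan_promoter_set
from fepi.ontology import parse_obo, propagate_annotations
from fepi.synth import (
    expected_module_r,
    gen_compendium,
    gen_contrast_experiment,
    gen_go_universe,
    gen_promoters,
    read_abundance_tsv,
    write_abundance_tsv,
)


class TestContrast:
    def test_noiseless_fold_recovery_exact(self):
        trt, ctrl, truth = gen_contrast_experiment(
            20, 5, n_reps=3, noise_cv=0.0, seed=1)
        records = fold_change_table(trt, ctrl)
        degs = truth.deg_genes_per_contrast["contrast"]
        for g, r in records.items():
            assert r.mean_fold == pytest.approx(degs.get(g, 1.0), rel=1e-12)
            assert r.sd_fold == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_single_gene_ratio(self):
        trt, ctrl, truth = gen_contrast_experiment(
            1, 1, fold_sampler=lambda rng, k: np.full(k, 4.0),
            n_reps=3, noise_cv=0.0, seed=0)
        assert np.allclose(trt.to_numpy(), 4.0 * ctrl.to_numpy())
        assert (trt.to_numpy() == trt.to_numpy()[0, 0]).all()

    def test_zero_control_fraction_one(self):
        trt, ctrl, truth = gen_contrast_experiment(
            10, 3, noise_cv=0.1, zero_control_fraction=1.0, seed=2)
        degs = truth.deg_genes_per_contrast["contrast"]
        assert len(degs) == 3
        for g in degs:
            assert (ctrl.loc[g] == 0).all()
            assert (trt.loc[g] > 0).all()
        records = fold_change_table(trt, ctrl)
        assert all(records[g].undetermined for g in degs)

    def test_determinism(self):
        a = gen_contrast_experiment(100, 10, noise_cv=0.1, seed=42)
        b = gen_contrast_experiment(100, 10, noise_cv=0.1, seed=42)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        c = gen_contrast_experiment(100, 10, noise_cv=0.1, seed=43)
        assert not a[0].equals(c[0])

    def test_non_negative_and_validated(self):
        trt, ctrl, _ = gen_contrast_experiment(50, 10, noise_cv=0.5, seed=3)
        assert (trt.to_numpy() >= 0).all() and (ctrl.to_numpy() >= 0).all()
        with pytest.raises(ValueError):
            gen_contrast_experiment(0, 0)
        with pytest.raises(ValueError):
            gen_contrast_experiment(10, 2, n_reps=0)
        with pytest.raises(ValueError):
            gen_contrast_experiment(10, 20)

    def test_tsv_roundtrip(self, tmp_path):
        trt, ctrl, _ = gen_contrast_experiment(10, 2, seed=4)
        path = tmp_path / "ab.tsv"
        write_abundance_tsv(trt, ctrl, path)
        trt2, ctrl2 = read_abundance_tsv(path)
        assert np.allclose(trt.to_numpy(), trt2.to_numpy())
        assert list(trt2.columns) == ["trt_1", "trt_2", "trt_3"]


class TestCompendium:
    def test_noiseless_module_perfectly_correlated(self):
        comp, truth = gen_compendium(5, 10, [(3, 1.0)], noise_sd=0.0, seed=0)
        mod = [g for g, m in truth.module_membership.items() if m == 0]
        sub = comp.loc[mod].to_numpy()
        r = np.corrcoef(sub)
        assert np.allclose(r, 1.0)

    def test_closed_form_expected_correlation(self):
        # within-module r = w^2 / (w^2 + sd^2) = 0.9 for w=3, sd=1,
        # checked by Monte Carlo over 200 arrays
        assert expected_module_r(3.0, 1.0) == pytest.approx(0.9)
        comp, truth = gen_compendium(10, 200, [(6, 3.0)], noise_sd=1.0, seed=7)
        mod = [g for g, m in truth.module_membership.items() if m == 0]
        r = np.corrcoef(comp.loc[mod].to_numpy())
        off = r[np.triu_indices_from(r, k=1)]
        assert abs(off.mean() - 0.9) < 0.05

    def test_zero_weight_uncorrelated(self):
        comp, truth = gen_compendium(10, 500, [(5, 0.0)], noise_sd=1.0, seed=8)
        mod = [g for g, m in truth.module_membership.items() if m == 0]
        r = np.corrcoef(comp.loc[mod].to_numpy())
        off = r[np.triu_indices_from(r, k=1)]
        assert abs(off.mean()) < 0.05

    def test_validation(self):
        with pytest.raises(ValueError):
            gen_compendium(10, 2, [])
        with pytest.raises(ValueError):
            gen_compendium(10, 5, [(1, 1.0)])
        with pytest.raises(ValueError):
            gen_compendium(4, 5, [(3, 1.0), (3, 1.0)])

    def test_module_sets_disjoint(self):
        comp, truth = gen_compendium(20, 5, [(4, 1.0), (5, 1.0)], seed=9)
        by_mod = {}
        for g, m in truth.module_membership.items():
            by_mod.setdefault(m, set()).add(g)
        assert len(by_mod[0] & by_mod[1]) == 0
        assert len(by_mod[0]) == 4 and len(by_mod[1]) == 5


class TestGoUniverse:
    def test_obo_parses_and_is_single_rooted(self):
        obo_text, direct, study, truth = gen_go_universe(
            30, max_depth=4, universe_size=100, study_size=20,
            enrichment_odds=5.0, seed=1)
        dag = parse_obo(io.StringIO(obo_text))
        assert len(dag.terms) == 30
        assert len(dag.roots()) == 1
        assert truth.enriched_term in dag.terms
        assert set(study) <= set(direct)
        # annotations are emitted unpropagated: propagation must grow them
        prop = propagate_annotations(dag, direct)
        assert any(len(prop[g]) > len(direct[g]) for g in direct)

    def test_single_term_ontology_maps_to_root(self):
        obo_text, direct, study, truth = gen_go_universe(
            1, max_depth=1, universe_size=10, study_size=2,
            enrichment_odds=1.0, seed=2)
        dag = parse_obo(io.StringIO(obo_text))
        assert dag.terms == {"GO:0000001"}
        assert all(t == "GO:0000001" for ts in direct.values() for t in ts)

    def test_null_odds_matches_hypergeometric_mean(self):
        # with odds 1 the study overlap is a plain hypergeometric draw
        overlaps, expected = [], []
        for seed in range(60):
            _, direct, study, truth = gen_go_universe(
                10, max_depth=3, universe_size=100, study_size=20,
                enrichment_odds=1.0, seed=seed)
            carriers = {g for g, ts in direct.items() if truth.enriched_term in ts}
            overlaps.append(len(carriers & set(study)))
            expected.append(20 * len(carriers) / 100)
        assert abs(np.mean(overlaps) - np.mean(expected)) < 0.5

    def test_invalid_odds(self):
        with pytest.raises(ValueError):
            gen_go_universe(5, 2, 10, 2, enrichment_odds=0.0)


class TestPromoters:
    def test_planted_hit_recovered_exactly(self):
        recs, truth = gen_promoters(
            1, plant_spec={"AT3G56980": [(153, "GTATATGC")]},
            forbid_background_hits=True, seed=0)
        hits = scan_promoter_set(recs, P1BS)
        assert [(h.gene, h.d_near, h.d_far) for h in hits] == \
            [("AT3G56980", 153, 160)]

    def test_forbid_background_no_spurious_hits(self):
        recs, _ = gen_promoters(20, plant_spec={},
                                forbid_background_hits=True, seed=1)
        assert scan_promoter_set(recs, P1BS) == []

    def test_nonconforming_plant_rejected(self):
        with pytest.raises(ValueError, match="conform"):
            gen_promoters(1, plant_spec={"g": [(100, "AAAAAAAA")]}, seed=0)

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gen_promoters(1, plant_spec={"g": [(100, "GTATATGC"),
                                               (103, "GTATATGC")]}, seed=0)

    def test_out_of_range_distance_rejected(self):
        with pytest.raises(ValueError):
            gen_promoters(1, length=100, plant_spec={"g": [(99, "GTATATGC")]},
                          seed=0)

    def test_sequences_acgt_and_deterministic(self):
        a, _ = gen_promoters(5, length=500, seed=6)
        b, _ = gen_promoters(5, length=500, seed=6)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert all(set(r.sequence) <= set("ACGT") for r in a)
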