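import numpy as np
import pandas as pd
import pytest

from cloneflow.io_formats import count_matrices
from cloneflow.single_cell import MISSING, MUTANT, CellGenotypeMatrix
from cloneflow.synthetic import (
    GroundTruth,
    SimulationConfig,
    expected_vaf,
    simulate_bulk_counts,
    simulate_cnv,
    simulate_single_cells,
    simulate_tree_and_prevalences,
)


def _random_config(seed, **kw):
    return SimulationConfig(seed=seed, parents=None, prevalence=None, **kw)


class TestTreeAndPrevalences:
    def test_random_draws_always_satisfy_sum_rule(self):
        """1,000 random K=5 truths: clade prevalences never violate the sum rule."""
        for seed in range(1000):
            t = simulate_tree_and_prevalences(_random_config(seed, n_mutations_per_clone=1))
            prev = t.prevalence.to_numpy()
            excl = t.clone_fractions.to_numpy()
            assert (excl >= -1e-9).all()  # parent >= sum of children
            assert (prev <= 1 + 1e-9).all() and (prev >= -1e-9).all()
            for s in range(prev.shape[1]):
                assert prev[t.parents == -1, s].sum() <= 1 + 1e-9

    def test_single_clone(self):
        t = simulate_tree_and_prevalences(_random_config(3, n_clones=1, n_mutations_per_clone=4))
        assert list(t.parents) == [-1]
        assert ((t.prevalence.to_numpy() >= 0) & (t.prevalence.to_numpy() <= 1)).all()

    def test_infeasible_script_names_stage(self):
        cfg = SimulationConfig(
            n_clones=2,
            parents=(-1, 0),
            prevalence=((0.8, 0.8, 0.8), (0.0, 0.5, 0.9)),
        )
        with pytest.raises(ValueError, match="AML"):
            simulate_tree_and_prevalences(cfg)

    def test_scripted_default_matches_config(self):
        cfg = SimulationConfig(seed=5, n_mutations_per_clone=2)
        t = simulate_tree_and_prevalences(cfg)
        assert tuple(t.parents) == cfg.parents
        np.testing.assert_allclose(t.prevalence.to_numpy(), np.asarray(cfg.prevalence))

    def test_clade_and_genotype_consistency(self):
        t = simulate_tree_and_prevalences(SimulationConfig(seed=5, n_mutations_per_clone=2))
        # clade prevalence equals sum of exclusive fractions over the clade
        for c in range(5):
            clade = t.clade(c)
            np.testing.assert_allclose(
                t.prevalence.iloc[c], t.clone_fractions.iloc[clade].sum(axis=0)
            )
        # descendants carry ancestors' mutations
        assert t.genotype(3)[t.clone_of_mutation == 0].all()
        assert not t.genotype(0)[t.clone_of_mutation == 3].any()


class TestBulkCounts:
    def test_same_seed_is_reproducible(self):
        cfg = SimulationConfig(seed=9, n_mutations_per_clone=5)
        a = simulate_bulk_counts(simulate_tree_and_prevalences(cfg), cfg)
        b = simulate_bulk_counts(simulate_tree_and_prevalences(cfg), cfg)
        assert [(r.variant_id, sorted(r.observations.items())) for r in a] == [
            (r.variant_id, sorted(r.observations.items())) for r in b
        ]

    def test_expected_vaf_formula(self):
        assert expected_vaf(1.0, 1.0, 2, 1) == 0.5  # clonal het, pure diploid
        assert expected_vaf(0.7, 0.8, 3, 1) == pytest.approx(0.7 * 0.8 / (0.8 * 3 + 0.4))

    def test_high_depth_vaf_converges_to_expectation(self):
        """At depth 10,000 the empirical VAF sits within 3 s.e. of the model VAF."""
        cfg = SimulationConfig(seed=2, n_mutations_per_clone=30, depth_mean=10_000,
                               pb_bm_noise=0.0)
        truth = simulate_tree_and_prevalences(cfg)
        records = simulate_bulk_counts(truth, cfg)
        exp = {
            vid: expected_vaf(truth.prevalence.iloc[truth.clone_of_mutation[i], 1], cfg.purity)
            for i, vid in enumerate(truth.mutation_ids)
        }
        sid = cfg.sample_id("MDS", "BM")
        bad = 0
        for rec in records:
            a, d = rec.observations[sid]
            e = exp[rec.variant_id]
            se = np.sqrt(max(e * (1 - e), 1e-12) / d)
            if abs(a / d - e) > 3 * max(se, 1e-9):
                bad += 1
        assert bad <= np.ceil(0.01 * len(records))  # 3 s.e. ~ 99.7% coverage

    def test_zero_pb_noise_gives_high_concordance(self):
        from cloneflow.profiles import vaf_concordance

        cfg = _random_config(4, n_clones=5, n_mutations_per_clone=20, depth_mean=500,
                             pb_bm_noise=0.0)
        truth = simulate_tree_and_prevalences(cfg)
        records = simulate_bulk_counts(truth, cfg)
        r, _, n = vaf_concordance(records, "MDS_PB", "MDS_BM")
        assert n == 100 and r > 0.95

    def test_vaf_never_exceeds_purity_bound(self):
        cfg = SimulationConfig(seed=6, n_mutations_per_clone=10, purity=0.7, pb_bm_noise=0.0)
        truth = simulate_tree_and_prevalences(cfg)
        records = simulate_bulk_counts(truth, cfg)
        bound = cfg.purity * 2 / (cfg.purity * 2 + (1 - cfg.purity) * 2)
        mut_ccf = truth.prevalence.to_numpy()[truth.clone_of_mutation]
        assert (expected_vaf(mut_ccf, cfg.purity) <= bound + 1e-12).all()


class TestSingleCells:
    def test_total_dropout_means_no_mutant_calls(self):
        cfg = SimulationConfig(seed=7, n_mutations_per_clone=3, ado_rate=1.0, fp_rate=0.0,
                               n_cells=40, cell_depth_mean=80)
        truth = simulate_tree_and_prevalences(cfg)
        alt, tot, labels = simulate_single_cells(truth, cfg, "AML")
        m = CellGenotypeMatrix.from_counts(alt, tot)
        assert not (m.calls.to_numpy() == MUTANT).any()

    def test_no_artifacts_calls_match_truth(self):
        """With ado=fp=0 and deep coverage, every callable entry equals the clade genotype."""
        cfg = SimulationConfig(seed=8, n_mutations_per_clone=3, ado_rate=0.0, fp_rate=0.0,
                               n_cells=50, cell_depth_mean=100)
        truth = simulate_tree_and_prevalences(cfg)
        alt, tot, labels = simulate_single_cells(truth, cfg, "MDS")
        m = CellGenotypeMatrix.from_counts(alt, tot, depth_min=5)
        geno = {c: truth.genotype(c) for c in range(cfg.n_clones)}
        zero = np.zeros(len(truth.mutation_ids), dtype=bool)
        for j, cell in enumerate(m.calls.index):
            g = geno.get(int(labels[j]), zero)
            for k, vid in enumerate(m.calls.columns):
                call = m.calls.iloc[j, k]
                if call == MISSING:
                    continue
                assert bool(call == MUTANT) == bool(g[k])

    def test_zero_cells_gives_empty_table(self):
        cfg = SimulationConfig(seed=1, n_mutations_per_clone=2, n_cells=0)
        truth = simulate_tree_and_prevalences(cfg)
        alt, tot, labels = simulate_single_cells(truth, cfg, "FA")
        assert alt.shape[0] == 0 and labels.size == 0

    def test_unknown_stage_rejected(self):
        cfg = SimulationConfig(seed=1, n_mutations_per_clone=2)
        truth = simulate_tree_and_prevalences(cfg)
        with pytest.raises(ValueError):
            simulate_single_cells(truth, cfg, "CR")


class TestCnv:
    def test_ratio_formula(self):
        cfg = SimulationConfig(
            seed=3, n_mutations_per_clone=2, cnv_ratio_sd=0.0,
            cnv_specs=(("chr1", 0, 10, 3, (1.0, 0.5, 0.0)), ("chr17", 0, 10, 1, (0.5, 0.0, 1.0))),
        )
        truth = simulate_tree_and_prevalences(cfg)
        segs = simulate_cnv(truth, cfg)
        ratios = {(s.chrom, s.stage): s.depth_ratio for s in segs}
        assert ratios[("chr1", "FA")] == pytest.approx(1.5)  # CN=3 fully clonal
        assert ratios[("chr1", "MDS")] == pytest.approx(1.25)
        assert ratios[("chr1", "AML")] == pytest.approx(1.0)  # f=0
        assert ratios[("chr17", "FA")] == pytest.approx(0.75)  # CN=1 at f=0.5

    def test_neutral_copy_number_rejected(self):
        cfg = SimulationConfig(seed=3, n_mutations_per_clone=2,
                               cnv_specs=(("chr1", 0, 10, 2, (0.1, 0.1, 0.1)),))
        truth = simulate_tree_and_prevalences(cfg)
        with pytest.raises(ValueError):
            simulate_cnv(truth, cfg)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [{"ado_rate": 1.5}, {"fp_rate": -0.1}, {"purity": 0.0}, {"depth_mean": 0},
         {"n_clones": 0}, {"n_cells": -1}],
    )
    def test_bad_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)
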