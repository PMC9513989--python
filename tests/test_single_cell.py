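import numpy as np
import pandas as pd
import pytest

from cloneflow.single_cell import (
    MISSING,
    MUTANT,
    WILDTYPE,
    CellGenotypeMatrix,
    CloneAssigner,
    call_genotype,
    compartment_comparison,
    mutated_cell_fraction,
)
from cloneflow.synthetic import SimulationConfig, simulate_single_cells, simulate_tree_and_prevalences


class TestCallGenotype:
    def test_threshold_examples(self):
        assert call_genotype(2, 4) == MISSING       # depth < 5
        assert call_genotype(2, 20) == MUTANT       # VAF 0.10 > 0.05
        assert call_genotype(1, 20) == WILDTYPE     # VAF exactly 0.05 is not mutant
        assert call_genotype(0, 5) == WILDTYPE      # depth exactly 5 is callable

    def test_invalid_depths(self):
        with pytest.raises(ValueError):
            call_genotype(6, 5)
        with pytest.raises(ValueError):
            call_genotype(-1, 5)

    def test_exhaustive_oracle_all_depths_to_30(self):
        """Agreement with a direct enumeration of the calling rule for total <= 30."""
        for total in range(0, 31):
            for alt in range(0, total + 1):
                if total < 5:
                    expected = MISSING
                elif alt / total > 0.05:
                    expected = MUTANT
                else:
                    expected = WILDTYPE
                assert call_genotype(alt, total) == expected

    def test_matrix_matches_scalar_rule(self, rng):
        tot = pd.DataFrame(rng.integers(0, 30, (20, 6)))
        alt = pd.DataFrame(rng.binomial(tot.to_numpy(), 0.2))
        m = CellGenotypeMatrix.from_counts(alt, tot)
        for i in range(20):
            for j in range(6):
                assert m.calls.iloc[i, j] == call_genotype(int(alt.iloc[i, j]), int(tot.iloc[i, j]))


class TestMutatedCellFraction:
    def _matrix(self, calls):
        calls = pd.DataFrame({"locus": calls})
        shape = calls.shape
        return CellGenotypeMatrix(
            calls=calls,
            alt=pd.DataFrame(np.zeros(shape, dtype=int), columns=["locus"]),
            total=pd.DataFrame(np.zeros(shape, dtype=int), columns=["locus"]),
        )

    def test_missing_excluded(self):
        frac, n_mut, n_called = mutated_cell_fraction(
            self._matrix([MUTANT, WILDTYPE, MISSING]), "locus"
        )
        assert (frac, n_mut, n_called) == (0.5, 1, 2)

    def test_all_mutant_and_all_missing(self):
        assert mutated_cell_fraction(self._matrix([MUTANT] * 4), "locus")[0] == 1.0
        frac, _, n = mutated_cell_fraction(self._matrix([MISSING] * 3), "locus")
        assert np.isnan(frac) and n == 0

    def test_permutation_invariance(self, rng):
        calls = rng.choice([MUTANT, WILDTYPE, MISSING], size=30)
        a = mutated_cell_fraction(self._matrix(list(calls)), "locus")
        b = mutated_cell_fraction(self._matrix(list(rng.permutation(calls))), "locus")
        assert a == b

    def test_fraction_tracks_simulated_clone_fractions(self):
        """Artifact-free simulation: per-locus mutated fraction is within the binomial CI."""
        cfg = SimulationConfig(seed=13, n_mutations_per_clone=2, ado_rate=0.0, fp_rate=0.0,
                               n_cells=300, cell_depth_mean=100)
        truth = simulate_tree_and_prevalences(cfg)
        alt, tot, labels = simulate_single_cells(truth, cfg, "MDS")
        m = CellGenotypeMatrix.from_counts(alt, tot)
        s = list(cfg.stages).index("MDS")
        for k, vid in enumerate(m.calls.columns):
            clone = truth.clone_of_mutation[k]
            carriers = [c for c in range(cfg.n_clones) if truth.genotype(c)[k]]
            true_frac = truth.clone_fractions.iloc[carriers, s].sum()
            frac, n_mut, n_called = mutated_cell_fraction(m, vid)
            se = np.sqrt(true_frac * (1 - true_frac) / n_called)
            assert abs(frac - true_frac) <= 3.5 * max(se, 1e-3)


def _profiles():
    # nested profiles over 8 loci: A founder, B adds 3, C adds 2 more
    return pd.DataFrame(
        {
            "A": [1, 1, 1, 0, 0, 0, 0, 0],
            "B": [1, 1, 1, 1, 1, 1, 0, 0],
            "C": [1, 1, 1, 1, 1, 1, 1, 1],
        },
        index=[f"L{i}" for i in range(8)],
    ).T


class TestCloneAssigner:
    def _matrix_from_calls(self, rows):
        calls = pd.DataFrame(rows, columns=[f"L{i}" for i in range(8)])
        z = pd.DataFrame(np.zeros(calls.shape, dtype=int), columns=calls.columns)
        return CellGenotypeMatrix(calls=calls, alt=z, total=z)

    def test_exact_profile_match_assigned(self):
        asn = CloneAssigner(ado_rate=0.01, fp_rate=0.01).fit(_profiles())
        m = self._matrix_from_calls([[1, 1, 1, 0, 0, 0, 0, 0]])
        assert asn.predict(m).iloc[0] == "A"
        post = asn.predict_proba(m)
        assert post.sum(axis=1).iloc[0] == pytest.approx(1.0)
        assert post.idxmax(axis=1).iloc[0] == "A"

    def test_all_missing_is_unassigned(self):
        asn = CloneAssigner().fit(_profiles())
        m = self._matrix_from_calls([[MISSING] * 8])
        assert asn.predict(m).iloc[0] is None

    def test_ambiguous_cell_unassigned_by_gap(self):
        # one informative wildtype locus cannot separate A from normal by 2 nats
        asn = CloneAssigner(ado_rate=0.2, fp_rate=0.005, gap_min=2.0).fit(_profiles())
        row = [MISSING] * 8
        row[7] = WILDTYPE
        assert asn.predict(self._matrix_from_calls([row])).iloc[0] is None

    def test_no_profiles_rejected(self):
        with pytest.raises(ValueError):
            CloneAssigner().fit(pd.DataFrame())

    def test_noise_free_assignment_is_exact(self):
        """ado=fp=0 with complete data: every simulated cell maps to its true clone."""
        cfg = SimulationConfig(seed=17, n_clones=3, n_mutations_per_clone=3,
                               parents=(-1, 0, 1),
                               prevalence=((0.9, 0.9, 0.9), (0.6, 0.6, 0.6), (0.3, 0.3, 0.3)),
                               ado_rate=0.0, fp_rate=0.0, n_cells=100, cell_depth_mean=60)
        truth = simulate_tree_and_prevalences(cfg)
        alt, tot, labels = simulate_single_cells(truth, cfg, "MDS")
        m = CellGenotypeMatrix.from_counts(alt, tot)
        profiles = pd.DataFrame(
            {c: truth.genotype(c) for c in range(3)}, index=truth.mutation_ids
        ).T
        # small dummy error rates keep likelihoods finite; gap off to assign all
        asn = CloneAssigner(ado_rate=1e-6, fp_rate=1e-6, gap_min=0.0).fit(profiles)
        pred = asn.predict(m)
        expected = ["normal" if l == -1 else l for l in labels]
        assert list(pred) == expected

    def test_accuracy_monotone_in_dropout(self):
        """>= 90% of assigned cells correct at ado 0.2; accuracy non-increasing in ado."""
        accs = []
        for ado in (0.0, 0.1, 0.2, 0.3):
            correct = assigned = 0
            for seed in range(5):
                cfg = SimulationConfig(
                    seed=100 + seed, n_clones=3, n_mutations_per_clone=3,
                    parents=(-1, 0, 1),
                    prevalence=((0.9, 0.9, 0.9), (0.6, 0.6, 0.6), (0.3, 0.3, 0.3)),
                    ado_rate=ado, fp_rate=0.005, n_cells=40, cell_depth_mean=50,
                )
                truth = simulate_tree_and_prevalences(cfg)
                # 8-locus targeted panel: first 2-3 mutations of each clone
                loci = [truth.mutation_ids[i] for i in (0, 1, 2, 3, 4, 5, 6, 7)]
                alt, tot, labels = simulate_single_cells(truth, cfg, "MDS", loci=loci)
                m = CellGenotypeMatrix.from_counts(alt, tot)
                profiles = pd.DataFrame(
                    {c: truth.genotype(c)[:8] for c in range(3)}, index=loci
                ).T
                asn = CloneAssigner(ado_rate=max(ado, 0.01), fp_rate=0.005, gap_min=2.0).fit(profiles)
                pred = asn.predict(m)
                for cell_i, clone in enumerate(pred):
                    if clone is None:
                        continue
                    assigned += 1
                    want = "normal" if labels[cell_i] == -1 else labels[cell_i]
                    correct += clone == want
            accs.append(correct / assigned)
        assert accs[2] >= 0.9
        assert all(accs[i] >= accs[i + 1] - 0.03 for i in range(3))  # monotone within noise


class TestCompartmentComparison:
    def test_stem_only_flag(self):
        df = pd.DataFrame(
            {"stem": [0.6, 0.3], "BM": [0.0, 0.3], "PB": [0.01, 0.3]},
            index=["ASXL1-like", "concordant"],
        )
        out = compartment_comparison(df, present_thresh=0.10, absent_thresh=0.02)
        assert out.at["ASXL1-like", "stem_only_vs_BM"]
        assert out.at["ASXL1-like", "stem_only_vs_PB"]
        assert out.at["ASXL1-like", "discordant"]
        assert not out.loc["concordant"].filter(like="_only_vs_").any()

    def test_identical_values_no_flags(self):
        df = pd.DataFrame({"stem": [0.4], "BM": [0.4]}, index=["x"])
        out = compartment_comparison(df)
        assert not out["discordant"].any()

    def test_flags_track_simulated_compartment_shift(self):
        rng = np.random.default_rng(0)
        truth_a = rng.uniform(0.2, 0.8, 10)
        truth_b = truth_a.copy()
        shifted = rng.choice(10, 3, replace=False)
        truth_b[shifted] = 0.0
        df = pd.DataFrame({"A": truth_a, "B": truth_b})
        out = compartment_comparison(df, 0.10, 0.02)
        assert set(np.flatnonzero(out["A_only_vs_B"])) == set(shifted)

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            compartment_comparison(pd.DataFrame({"a": [0.1], "b": [0.1]}), 0.02, 0.10)
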