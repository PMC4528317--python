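"""Split construction, GEBV prediction rules, accuracy bookkeeping."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import poolwgr as pw
from poolwgr.evaluation import APPROACHES, ExperimentConfig
from poolwgr.wgr import ChainSettings


def labels_for(sizes: dict[int, int]) -> np.ndarray:
    return np.concatenate([np.full(n, p) for p, n in sizes.items()])


class TestMakeSplit:
    def test_fractional_np_printed_construction(self):
        # P=20, Np=12.5 on 25 populations: 19 training sets of 12 and one of
        # 22, N = 250
        labels = labels_for({p: 188 for p in range(1, 26)})
        split = pw.make_split(labels, 20, 12.5, seed=4)
        sizes = sorted(len(split.training_indices[int(p)]) for p in split.pi_populations)
        assert sizes == [12] * 19 + [22]
        assert split.N == 250
        assert split.pi_bar_populations.size == 5

    def test_integer_np(self):
        labels = labels_for({p: 188 for p in range(1, 26)})
        split = pw.make_split(labels, 5, 50, seed=1)
        assert split.N == 250
        assert split.pi_bar_populations.size == 20
        for p in split.pi_populations:
            assert len(split.training_indices[int(p)]) == 50

    def test_training_exhausting_population_rejected(self):
        labels = labels_for({1: 30, 2: 30})
        with pytest.raises(ValueError, match="test set"):
            pw.make_split(labels, 2, 30, seed=0)

    def test_oversized_draw_rejected(self):
        labels = labels_for({1: 10, 2: 10})
        with pytest.raises(ValueError):
            pw.make_split(labels, 2, 40, seed=0)
        with pytest.raises(ValueError):
            pw.make_split(labels, 3, 5, seed=0)

    def test_deterministic(self):
        labels = labels_for({p: 50 for p in range(1, 11)})
        a = pw.make_split(labels, 4, 10, seed=9)
        b = pw.make_split(labels, 4, 10, seed=9)
        assert np.array_equal(a.pi_populations, b.pi_populations)
        for p in a.pi_populations:
            assert np.array_equal(a.training_indices[int(p)], b.training_indices[int(p)])

    @given(st.integers(0, 10_000))
    def test_split_conservation(self, seed):
        sizes = {1: 17, 2: 23, 3: 31, 4: 12, 5: 40}
        labels = labels_for(sizes)
        split = pw.make_split(labels, 3, 7, seed=seed)
        seen = np.zeros(labels.size, dtype=int)
        for p in split.pi_populations:
            seen[split.training_indices[int(p)]] += 1
            seen[split.testing_indices[int(p)]] += 1
        for p in split.pi_bar_populations:
            seen[np.flatnonzero(labels == p)] += 1
        assert np.all(seen == 1)


class TestMakeSplitByFraction:
    def test_average_training_size_matches_design(self):
        # five populations averaging 127 lines at 25% training
        labels = labels_for({1: 43, 2: 101, 3: 127, 4: 160, 5: 204})
        split = pw.make_split_by_fraction(labels, 0.25, seed=2)
        sizes = [len(split.training_indices[p]) for p in (1, 2, 3, 4, 5)]
        assert sizes == [round(0.25 * s) for s in (43, 101, 127, 160, 204)]
        assert np.mean(sizes) == pytest.approx(31, abs=1.0)
        assert split.pi_bar_populations.size == 0

    def test_even_halves(self):
        labels = labels_for({1: 40, 2: 60})
        split = pw.make_split_by_fraction(labels, 0.5, seed=3)
        assert len(split.training_indices[1]) == 20
        assert len(split.training_indices[2]) == 30

    def test_degenerate_fraction_rejected(self):
        labels = labels_for({1: 43})
        with pytest.raises(ValueError):
            pw.make_split_by_fraction(labels, 0.999, seed=0)
        with pytest.raises(ValueError):
            pw.make_split_by_fraction(labels, 1.5, seed=0)


class TestPredictGebv:
    def test_zero_effects(self):
        assert np.array_equal(pw.predict_gebv(np.ones((4, 3)), np.zeros(3)), np.zeros(4))

    def test_single_marker_identity(self):
        Z = np.array([[1.0], [-0.5], [0.0]])
        assert np.array_equal(pw.predict_gebv(Z, [1.0]), Z[:, 0])

    def test_linearity(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(6, 4))
        e1, e2 = rng.normal(size=4), rng.normal(size=4)
        assert np.allclose(
            pw.predict_gebv(Z, e1 + e2), pw.predict_gebv(Z, e1) + pw.predict_gebv(Z, e2)
        )

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pw.predict_gebv(np.ones((2, 3)), np.ones(4))

    def test_truth_injection_gives_perfect_accuracy(self, small_nam):
        # scoring GEBVs built from the true architecture against true genetic
        # values gives within-population correlation 1 (centering only shifts)
        arch = pw.sample_effects(
            small_nam.n_markers, small_nam.populations.size, 1.0, seed=3
        )
        g = pw.genetic_values(small_nam.genotypes, arch, small_nam.population_labels)
        Z = pw.center_genotypes(small_nam)
        for j, p in enumerate(small_nam.populations):
            rows = small_nam.lines_of(int(p))
            gebv = pw.predict_gebv(Z.values[rows], arch.specific_effects[j])
            assert np.corrcoef(gebv, g[rows])[0, 1] == pytest.approx(1.0, abs=1e-10)


@pytest.fixture(scope="module")
def split_setup(small_nam, small_trait):
    reduced, trait, _ = small_trait
    split = pw.make_split(reduced.population_labels, 3, 10, seed=5)
    st_ = ChainSettings(60, 200, 2, seed=1)
    return reduced, trait, split, st_


@pytest.fixture(scope="module")
def tiny_result(small_nam):
    cfg = ExperimentConfig(
        P=3,
        Np=10,
        n_replicates=2,
        approaches=("no_pooling", "complete_pooling"),
        settings=ChainSettings(50, 100, 1),
        accuracy_target="true_genetic_value",
        seed=21,
        rsd=1.0,
        n_qtl=8,
    )
    return cfg, pw.run_experiment(cfg, small_nam)


class TestEvaluateSplit:
    def test_no_pooling_has_no_new_population_accuracy(self, split_setup):
        reduced, trait, split, st_ = split_setup
        res = pw.evaluate_split(reduced, trait.phenotypes, split, "no_pooling", st_)
        assert res.r_pi_bar is None
        assert set(res.per_population_r) == {int(p) for p in split.pi_populations}

    def test_pooling_scores_new_populations(self, split_setup):
        reduced, trait, split, st_ = split_setup
        res = pw.evaluate_split(
            reduced, trait.phenotypes, split, "partial_pooling", st_, target=trait.genetic_values
        )
        assert res.r_pi_bar is not None
        assert res.divergence is not None
        assert set(res.per_population_r) == set(reduced.populations.tolist())
        assert all(-1 <= r <= 1 for r in res.per_population_r.values() if np.isfinite(r))

    def test_unknown_approach_rejected(self, split_setup):
        reduced, trait, split, st_ = split_setup
        with pytest.raises(ValueError):
            pw.evaluate_split(reduced, trait.phenotypes, split, "mega_pooling", st_)


class TestRunExperiment:
    def test_row_bookkeeping(self, tiny_result):
        cfg, res = tiny_result
        assert len(res.summary) == cfg.n_replicates * len(cfg.approaches)
        assert set(res.summary["approach"]) == set(cfg.approaches)
        assert set(res.per_population.columns) == {"replicate", "approach", "population", "set", "r"}

    def test_same_master_seed_reproduces_tables(self, tiny_result, small_nam):
        cfg, res = tiny_result
        again = pw.run_experiment(cfg, small_nam)
        pd.testing.assert_frame_equal(res.summary, again.summary)
        pd.testing.assert_frame_equal(res.per_population, again.per_population)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExperimentConfig(P=3, Np=10, training_fraction=0.5)
        with pytest.raises(ValueError):
            ExperimentConfig(Np=10)  # P missing
        with pytest.raises(ValueError):
            ExperimentConfig(P=3, Np=10, approaches=("bogus",))


class TestPairedComparison:
    def test_identical_inputs(self):
        a = np.array([0.4, 0.5, 0.6, 0.55])
        mean, t, p = pw.paired_comparison(a, a.copy())
        assert (mean, t, p) == (0.0, 0.0, 1.0)

    def test_constant_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.5, 0.01, 20)
        mean, t, p = pw.paired_comparison(a + 0.1, a)
        assert mean == pytest.approx(0.1)
        assert p < 0.001

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(size=10)
        m1, t1, _ = pw.paired_comparison(a, b)
        m2, t2, _ = pw.paired_comparison(b, a)
        assert m1 == pytest.approx(-m2)
        assert t1 == pytest.approx(-t2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pw.paired_comparison([0.1, 0.2], [0.2, 0.1])

    def test_frame_input_aligned_by_replicate(self):
        a = pd.DataFrame({"replicate": [2, 0, 1], "r_pi": [0.3, 0.1, 0.2]})
        b = pd.DataFrame({"replicate": [0, 1, 2], "r_pi": [0.1, 0.2, 0.3]})
        mean, t, p = pw.paired_comparison(a, b)
        assert (mean, t, p) == (0.0, 0.0, 1.0)


class TestSummarize:
    def test_hand_checked_mean_and_se(self):
        df = pd.DataFrame(
            {
                "approach": ["complete_pooling"] * 3,
                "r_pi": [0.4, 0.5, 0.6],
                "r_pi_bar": [np.nan] * 3,
            }
        )
        out = pw.summarize(df)
        row = out[(out.approach == "complete_pooling") & (out.metric == "r_pi")].iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["se"] == pytest.approx(0.1 / np.sqrt(3))

    def test_constant_column_and_single_replicate(self):
        df = pd.DataFrame(
            {
                "approach": ["a", "a", "b"],
                "r_pi": [0.4, 0.4, 0.7],
                "r_pi_bar": [np.nan, np.nan, 0.2],
            }
        )
        out = pw.summarize(df)
        assert out[(out.approach == "a") & (out.metric == "r_pi")].iloc[0]["se"] == 0.0
        assert out[(out.approach == "b") & (out.metric == "r_pi")].iloc[0]["se"] == 0.0

    def test_all_approaches_known(self):
        assert APPROACHES == ("no_pooling", "partial_pooling", "complete_pooling")
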