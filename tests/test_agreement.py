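import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score, cohen_kappa_score

from periwound.agreement import (
    adjusted_rand,
    align_labels,
    cohen_kappa,
    pairwise_kappa,
    two_sample_t,
)
from periwound.io_config import AnnotationTable
from periwound.synthetic import (
    KappaUndefinedError,
    expected_kappa,
    identity_annotator,
    simulate_annotations,
    uniform_error_annotator,
)


class TestCohenKappa:
    def test_identical_vectors(self):
        v = ["a", "b", "a", "c", "b"]
        assert cohen_kappa(v, v) == 1.0

    def test_hand_computed_2x2_table(self):
        # contingency [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert cohen_kappa(a, b) == pytest.approx(0.4)

    def test_cyclic_shift_of_balanced_five_classes(self):
        # zero observed agreement with uniform marginals: kappa = -p_e/(1-p_e)
        a = np.repeat(np.arange(5), 20)
        b = (a + 1) % 5
        assert cohen_kappa(a, b) == pytest.approx(-0.25)

    def test_matches_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.choice(list("abcd"), 200)
            b = rng.choice(list("abcd"), 200)
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_undefined_when_both_constant_equal(self):
        with pytest.raises(KappaUndefinedError):
            cohen_kappa(["a"] * 5, ["a"] * 5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa(["a", "b"], ["a", "b", "c"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        labels=st.lists(st.integers(0, 3), min_size=10, max_size=60),
        perm=st.permutations(range(4)),
    )
    def test_invariant_to_bijective_relabeling(self, labels, perm):
        rng = np.random.default_rng(1)
        a = np.array(labels)
        b = rng.permutation(a)
        if len(np.unique(a)) < 2:
            return
        mapped = np.array(perm)
        assert cohen_kappa(mapped[a], mapped[b]) == pytest.approx(
            cohen_kappa(a, b), abs=1e-12
        )


class TestPairwiseKappa:
    def _table(self, cols):
        n = len(next(iter(cols.values())))
        return AnnotationTable(
            pd.DataFrame(cols, index=pd.Index([f"i{k}" for k in range(n)], name="image_id")),
            merged=True,
        )

    def test_four_identical_raters(self):
        col = ["attached", "indistinct"] * 10
        rep = pairwise_kappa(self._table({f"e{i}": col for i in range(1, 5)}))
        np.testing.assert_allclose(rep.kappa_matrix, 1.0)
        assert rep.mean == 1.0 and rep.sd == 0.0

    def test_two_raters_sd_zero_by_convention(self):
        rep = pairwise_kappa(
            self._table(
                {
                    "a": ["attached", "indistinct", "attached", "indistinct"],
                    "b": ["attached", "attached", "attached", "indistinct"],
                }
            )
        )
        assert rep.sd == 0.0

    def test_simulated_raters_match_closed_form(self):
        models = [uniform_error_annotator(f"e{i}", 0.2 + 0.1 * i) for i in range(3)]
        truths = [
            ["indistinct", "attached", "not_attached", "rolled_fibrotic", "hyperkeratotic"][
                i % 5
            ]
            for i in range(10_000)
        ]
        table = simulate_annotations(truths, models, seed=9)
        rep = pairwise_kappa(table)
        prior = np.full(5, 0.2)
        for i in range(3):
            for j in range(i + 1, 3):
                exp = expected_kappa(models[i], models[j], prior)
                assert rep.pair(f"e{i}", f"e{j}") == pytest.approx(exp, abs=0.03)


class TestAdjustedRand:
    def test_identical_partitions(self):
        assert adjusted_rand([1, 2, 2, 3], [5, 6, 6, 7]) == 1.0

    def test_one_cluster_versus_split(self):
        assert adjusted_rand([1, 1, 1, 1], [1, 1, 2, 2]) == pytest.approx(0.0)

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 5, 10_000)
        b = rng.integers(0, 5, 10_000)
        assert abs(adjusted_rand(a, b)) < 0.01

    def test_matches_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 4, 300)
            b = rng.integers(0, 6, 300)
            assert adjusted_rand(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )


class TestAlignLabels:
    def test_recovers_name_permutation(self):
        rng = np.random.default_rng(4)
        ref = rng.choice(["a", "b", "c"], 100)
        name_map = {"a": "z", "b": "x", "c": "y"}
        pred = np.array([name_map[v] for v in ref])
        mapping, relabeled = align_labels(pred, ref)
        assert (relabeled == ref).all()
        assert mapping == {"z": "a", "x": "b", "y": "c"}

    def test_random_predictions_stay_at_chance(self):
        rng = np.random.default_rng(5)
        ref = rng.choice(list("abcde"), 10_000)
        pred = rng.integers(0, 5, 10_000)
        _, relabeled = align_labels(pred, ref)
        assert abs(cohen_kappa(relabeled, ref)) < 0.03

    def test_fewer_groups_than_categories_is_injective(self):
        rng = np.random.default_rng(6)
        ref = rng.choice(list("abcde"), 500)
        pred = rng.integers(0, 3, 500)
        mapping, relabeled = align_labels(pred, ref)
        assert len(set(mapping.values())) == 3  # injective
        assert set(np.unique(relabeled)) <= set("abcde")

    def test_never_worse_than_identity_mapping(self):
        rng = np.random.default_rng(7)
        ref = rng.integers(0, 4, 300)
        pred = rng.integers(0, 4, 300)
        _, relabeled = align_labels(pred, ref)
        assert (relabeled == ref).mean() >= (pred == ref).mean()


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_value(self):
        t, p = two_sample_t([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
        assert t == pytest.approx(-2.0)
        # pooled variance 2.5, df = 8
        from scipy.stats import t as t_dist

        assert p == pytest.approx(2 * t_dist.sf(2.0, 8))

    def test_separated_gaussians_significant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 30)
        y = rng.normal(3, 1, 30)
        _, p = two_sample_t(x, y)
        assert p < 0.001

    def test_degenerate_unequal_constants_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])
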