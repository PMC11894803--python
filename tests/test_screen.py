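"""Gene-subset partitioning, silhouette scoring and extreme selection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import silhouette_score as sklearn_silhouette

from gembridge.io import GEM
from gembridge.preprocess import apply_scaler, fit_scaler, log2p1
from gembridge.screen import (
    embed_2d,
    partition_gene_set,
    random_background,
    screen_subsets,
    select_extremes,
    silhouette,
)
from gembridge.synthetic import SyntheticSpec, generate_two_state_gem


class TestPartition:
    def test_exact_division(self):
        genes = [f"g{i}" for i in range(32)]
        subs = partition_gene_set(genes, 16, seed=0)
        assert len(subs) == 2
        union = set(subs[0].gene_ids) | set(subs[1].gene_ids)
        assert union == set(genes)

    def test_remainder_dropped(self):
        subs = partition_gene_set([f"g{i}" for i in range(30)], 16, seed=1)
        assert len(subs) == 1 and len(subs[0].gene_ids) == 16

    def test_too_few_genes_yields_empty(self):
        assert partition_gene_set([f"g{i}" for i in range(15)], 16, seed=0) == []
        assert partition_gene_set([], 16, seed=0) == []

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=200),
        st.integers(min_value=1, max_value=40),
        st.integers(min_value=0, max_value=100),
    )
    def test_sizes_and_disjointness_exact_for_any_length(self, n_genes, size, seed):
        genes = [f"g{i}" for i in range(n_genes)]
        subs = partition_gene_set(genes, size, seed=seed)
        assert len(subs) == n_genes // size
        seen: set[str] = set()
        for s in subs:
            assert len(s.gene_ids) == size
            assert not seen & set(s.gene_ids)
            seen |= set(s.gene_ids)

    def test_seeded_shuffle_deterministic(self):
        genes = [f"g{i}" for i in range(40)]
        assert partition_gene_set(genes, 10, seed=3) == partition_gene_set(genes, 10, seed=3)


class TestSilhouette:
    def test_hand_evaluated_two_cluster_example(self):
        coords = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = ["a", "a", "b", "b"]
        # per point: a=1, b=(10+sqrt(101))/2; s=(b-a)/b
        b = (10.0 + np.sqrt(101.0)) / 2.0
        expected = (b - 1.0) / b
        assert silhouette(coords, labels) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.900, abs=5e-4)

    def test_identical_clouds_score_nonpositive(self):
        rng = np.random.default_rng(0)
        cloud = rng.normal(size=(20, 2))
        coords = np.vstack([cloud, cloud])
        labels = ["a"] * 20 + ["b"] * 20
        assert silhouette(coords, labels) <= 0.0

    def test_matches_sklearn_oracle_to_1e12(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            coords = rng.normal(size=(40, 2))
            labels = rng.integers(0, 3, size=40)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette(coords, labels) == pytest.approx(
                float(sklearn_silhouette(coords, labels)), abs=1e-12
            )

    def test_result_bounded(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(30, 2))
        labels = rng.integers(0, 2, size=30)
        assert -1.0 <= silhouette(coords, labels) <= 1.0

    def test_singleton_cluster_contributes_zero(self):
        coords = np.array([[0.0, 0.0], [5.0, 5.0], [5.0, 6.0]])
        val = silhouette(coords, ["solo", "b", "b"])
        # solo point contributes 0; b points are far from the singleton
        assert 0.0 < val < 1.0

    def test_single_cluster_error(self):
        with pytest.raises(ValueError, match="two clusters"):
            silhouette(np.zeros((3, 2)), ["a", "a", "a"])


class TestEmbed:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        a = embed_2d(X, n_neighbors=10, min_dist=0.3, seed=4)
        b = embed_2d(X, n_neighbors=10, min_dist=0.3, seed=4)
        assert a.shape == (60, 2)
        np.testing.assert_array_equal(a, b)

    def test_neighbors_shrunk_when_samples_scarce(self, caplog):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        out = embed_2d(X, n_neighbors=90, seed=0)
        assert out.shape == (12, 2)

    def test_separated_blobs_embed_separably(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=(40, 6))
        b = rng.normal(10, 1, size=(40, 6))
        coords = embed_2d(np.vstack([a, b]), n_neighbors=15, seed=1)
        labels = ["a"] * 40 + ["b"] * 40
        assert silhouette(coords, labels) > 0.8


class TestSelectExtremes:
    def make(self, scores):
        from gembridge.screen import GeneSubset, ScreenResult

        return [
            ScreenResult(GeneSubset("p", i, ("g",)), s) for i, s in enumerate(scores)
        ]

    def test_documented_arithmetic(self):
        out = select_extremes(self.make([0.0, 0.0, 0.0, 1.0]), k_sd=1.0)
        # mean 0.25, population sd 0.433; only 1.0 > 0.683
        assert [r.selected for r in out] == ["neither", "neither", "neither", "high"]

    def test_all_equal_selects_none(self):
        out = select_extremes(self.make([0.4, 0.4, 0.4]), k_sd=1.0)
        assert all(r.selected == "neither" for r in out)

    def test_k_zero_flags_everything_off_mean(self):
        out = select_extremes(self.make([0.1, 0.5, 0.9]), k_sd=0.0)
        assert [r.selected for r in out] == ["low", "neither", "high"]

    def test_needs_two_results(self):
        with pytest.raises(ValueError):
            select_extremes(self.make([0.5]), k_sd=1.0)


@pytest.fixture(scope="module")
def screen_study():
    gem, signal = generate_two_state_gem(
        SyntheticSpec(n_per_class=100, n_genes=32, n_signal=8, effect_size=3.0, seed=11)
    )
    norm = apply_scaler(log2p1(gem), fit_scaler(log2p1(gem)))
    return norm, signal


class TestScreenSubsets:
    def test_signal_subset_outscores_null_subset(self, screen_study):
        norm, signal = screen_study
        from gembridge.screen import GeneSubset

        null_genes = [g for g in norm.gene_ids if g not in signal][:8]
        subs = [
            GeneSubset("signal", 0, tuple(signal)),
            GeneSubset("null", 0, tuple(null_genes)),
        ]
        res = screen_subsets(norm, subs, n_neighbors=30, seed=2)
        scores = {r.subset.parent_set_name: r.silhouette for r in res}
        assert scores["signal"] > scores["null"]

    def test_label_permutation_destroys_separation(self, screen_study):
        norm, signal = screen_study
        from dataclasses import replace

        from gembridge.screen import GeneSubset

        rng = np.random.default_rng(3)
        shuffled = replace(norm, labels=rng.permutation(np.asarray(norm.labels)))
        sub = [GeneSubset("signal", 0, tuple(signal))]
        true_res = screen_subsets(norm, sub, n_neighbors=30, seed=2)
        perm_res = screen_subsets(shuffled, sub, n_neighbors=30, seed=2)
        assert perm_res[0].silhouette < true_res[0].silhouette
        assert perm_res[0].silhouette < 0.1

    def test_missing_gene_error_names_subset(self, screen_study):
        norm, _ = screen_study
        from gembridge.screen import GeneSubset

        with pytest.raises(ValueError, match="ghost"):
            screen_subsets(norm, [GeneSubset("p", 0, ("ghost",))], seed=0)


def test_planted_subset_silhouette_increases_with_effect_size():
    """Mean screen silhouette of the planted subset is monotone in effect size."""
    from gembridge.screen import GeneSubset

    means = []
    for effect in (0.0, 1.0, 3.0):
        vals = []
        for seed in range(3):
            gem, signal = generate_two_state_gem(
                SyntheticSpec(n_per_class=80, n_genes=24, n_signal=6,
                              effect_size=effect, seed=50 + seed)
            )
            norm = apply_scaler(log2p1(gem), fit_scaler(log2p1(gem)))
            res = screen_subsets(
                norm, [GeneSubset("planted", 0, tuple(signal))],
                n_neighbors=25, seed=seed,
            )
            vals.append(res[0].silhouette)
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_random_background_below_planted_signal(screen_study):
    norm, signal = screen_study
    from gembridge.screen import GeneSubset

    mean_bg, sd_bg = random_background(
        norm, subset_size=8, n_reps=5, seed=6, n_neighbors=30, exclude_genes=signal
    )
    res = screen_subsets(norm, [GeneSubset("signal", 0, tuple(signal))],
                         n_neighbors=30, seed=6)
    assert sd_bg >= 0
    assert mean_bg < res[0].silhouette
    again = random_background(
        norm, subset_size=8, n_reps=5, seed=6, n_neighbors=30, exclude_genes=signal
    )
    assert again == (mean_bg, sd_bg)
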