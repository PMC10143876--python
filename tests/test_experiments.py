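"""Experiment-harness contracts: splits, sweeps, semiquant pools, PCA."""

from __future__ import annotations

import numpy as np
import pytest

from enose_transfer import (
    CLASS_NONE,
    PESTICIDES,
    DatasetDesign,
    DomainShiftParams,
    feature_table,
    generate_domain_dataset,
    pca_diagnostic,
    run_semiquant,
    screen_features,
    split_target,
    stratified_source_order,
    sweep_parameters,
)
from enose_transfer.experiments import ExperimentDesign, compare_methods, task_labels


def design_labels(design: DatasetDesign) -> np.ndarray:
    """The pesticide label vector the generator realises, without generating."""
    labels = [CLASS_NONE] * design.n_unpolluted_per_domain
    for p in design.pesticide_classes:
        labels += [p] * design.n_per_class_per_domain
    return np.asarray(labels)


@pytest.fixture(scope="module")
def small_tables(small_acq, small_model, small_design):
    shift = DomainShiftParams.from_magnitude(1.0, small_acq.n_sensors)
    src = generate_domain_dataset(small_design, "source", small_model, shift, small_acq, 0)
    tgt = generate_domain_dataset(small_design, "target", small_model, shift, small_acq, 1)
    return (
        feature_table(src, "Mean"),
        feature_table(tgt, "Mean"),
        src,
        tgt,
    )


class TestSplits:
    def test_qualitative_default_split_sizes(self):
        """Full design: 30 target-train rows leave 490 for testing."""
        labels = design_labels(DatasetDesign())
        train, test = split_target(labels, 30, np.random.default_rng(0))
        assert len(train) == 30 and len(test) == 490
        assert np.intersect1d(train, test).size == 0

    def test_semiquant_default_split_sizes(self):
        """One pesticide's 120 samples: 30 train, 90 test."""
        labels = np.repeat([100, 500, 1000], 40)
        train, test = split_target(labels, 30, np.random.default_rng(0))
        assert len(train) == 30 and len(test) == 90
        # stratification: 10 per concentration in the training half
        assert all((labels[train] == c).sum() == 10 for c in (100, 500, 1000))

    def test_degenerate_splits_rejected(self):
        labels = np.repeat(["a", "b"], 10)
        with pytest.raises(ValueError):
            split_target(labels, 20, np.random.default_rng(0))
        with pytest.raises(ValueError, match="cannot stratify"):
            split_target(np.array(["a"] * 10 + ["b"]), 5, np.random.default_rng(0))

    def test_source_order_prefixes_are_stratified_and_nested(self):
        labels = design_labels(DatasetDesign.reduced())
        order = stratified_source_order(labels, np.random.default_rng(3))
        assert sorted(order) == list(range(len(labels)))
        big, small = set(order[:100]), set(order[:50])
        assert small < big  # prefixes nest by construction
        prefix = labels[order[:52]]
        for p in PESTICIDES:  # 30/130 of each pesticide -> 12 of 52
            assert abs((prefix == p).sum() - 12) <= 1


class TestSweepAndCompare:
    def test_sweep_grid_cardinality(self, small_tables):
        src, tgt, _, _ = small_tables
        df = sweep_parameters(
            src, tgt, task="qualitative", N_grid=(0, 2, 4), Ts_grid=(10, 20),
            Tt=15, C=0.5, rng=np.random.default_rng(0),
        )
        assert len(df) == 6
        assert df.accuracy.between(0, 1).all()

    def test_invalid_grid_points_warn_and_skip(self, small_tables):
        src, tgt, _, _ = small_tables
        with pytest.warns(UserWarning, match="invalid grid point"):
            df = sweep_parameters(
                src, tgt, task="qualitative", N_grid=(1,), Ts_grid=(10, 10_000),
                Tt=15, C=0.5, rng=np.random.default_rng(0),
            )
        assert set(df.Ts) == {10}

    def test_compare_returns_all_four_methods(self, small_tables):
        src, tgt, _, _ = small_tables
        accs = compare_methods(
            src, tgt, task="qualitative", N=3, Tt=15, C=0.5,
            rng=np.random.default_rng(1),
        )
        assert set(accs) == {"Ts-SVM", "Tt-SVM", "Tc-SVM", "TL"}
        assert all(0 <= a <= 1 for a in accs.values())

    def test_results_are_reproducible_for_fixed_rng(self, small_tables):
        src, tgt, _, _ = small_tables
        kwargs = dict(task="qualitative", N_grid=(2,), Ts_grid=(20,), Tt=15, C=0.5)
        a = sweep_parameters(src, tgt, rng=np.random.default_rng(5), **kwargs)
        b = sweep_parameters(src, tgt, rng=np.random.default_rng(5), **kwargs)
        assert a.equals(b)


class TestScreening:
    def test_screen_reports_both_accuracies_per_method(self, small_tables):
        _, _, src_samples, tgt_samples = small_tables
        df = screen_features(src_samples, tgt_samples, methods=("Mean", "MAX"))
        assert list(df.method) == ["Mean", "MAX"]
        assert df.train_accuracy_resubstitution.between(0, 1).all()
        assert df.target_accuracy.between(0, 1).all()


class TestSemiquant:
    def test_pools_restrict_to_one_pesticide(self, small_tables):
        src, tgt, _, _ = small_tables
        design = ExperimentDesign.semiquant_default(
            Ts_grid=(6, 12), N_grid=(0, 2), Tt=6, seeds=(0,)
        )
        out = run_semiquant("lindane", src, tgt, design, np.random.default_rng(0))
        assert set(out) == {"sweep", "compare"}
        assert (out["compare"].pesticide == "lindane").all()
        sub = src.subset(src.pesticide == "lindane")
        assert len(sub) == 12  # 3 concentrations x 4
        assert set(task_labels(sub, "semiquant")) == {100, 500, 1000}

    def test_unpolluted_samples_never_enter_semiquant_pools(self, small_tables):
        src, _, _, _ = small_tables
        sub = src.subset(src.pesticide == "malathion")
        assert CLASS_NONE not in set(sub.pesticide)
        assert 0 not in set(sub.concentration)

    def test_unknown_pesticide_rejected(self, small_tables):
        src, tgt, _, _ = small_tables
        design = ExperimentDesign.semiquant_default(Ts_grid=(6,), N_grid=(2,), Tt=6)
        with pytest.raises(ValueError, match="unknown pesticide"):
            run_semiquant("atrazine", src, tgt, design, np.random.default_rng(0))


class TestPCA:
    def test_separated_domains_have_separated_scores(
        self, bench_acq, bench_model, bench_design, bench_shift
    ):
        """At the calibrated shift the two domains form distinct clusters in
        the top-2 principal components of Mean features."""
        from sklearn.metrics import silhouette_score

        src = feature_table(generate_domain_dataset(
            bench_design, "source", bench_model, bench_shift, bench_acq, 0), "Mean")
        tgt = feature_table(generate_domain_dataset(
            bench_design, "target", bench_model, bench_shift, bench_acq, 1), "Mean")
        X = np.vstack([src.X, tgt.X])
        domains = np.concatenate([src.domain, tgt.domain])
        scores, evr = pca_diagnostic(X)
        assert evr[0] >= evr[1] >= 0
        assert evr.sum() <= 1 + 1e-9
        assert silhouette_score(scores, domains) > 0.5

    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        scores, _ = pca_diagnostic(np.vstack([X, X]))
        np.testing.assert_allclose(scores[:10], scores[10:], atol=1e-9)

    def test_constant_matrix_is_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            pca_diagnostic(np.ones((5, 3)))
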