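"""Generator contracts: kinetics closed forms, design counts, determinism."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enose_transfer import (
    CLASS_NONE,
    PESTICIDES,
    AcquisitionConfig,
    DatasetDesign,
    DomainShiftParams,
    SensorResponseModel,
    generate_domain_dataset,
    iter_domain_samples,
    simulate_sample,
)

from .conftest import deterministic_model


class TestSimulateSample:
    def test_plateau_reaches_baseline_plus_amplitude(self):
        """With no noise/shift, the late-time trace sits at baseline + amplitude."""
        acq = AcquisitionConfig(duration_s=30.0, rate_hz=10.0, n_sensors=3,
                                baseline_v=np.full(3, 1.0))
        model = deterministic_model(3, amplitude=2.0, tau=0.5)
        shift = DomainShiftParams.identity(3)
        sample = simulate_sample(model, shift, acq, "malathion", 1000, rng=0)
        assert sample.matrix[-1] == pytest.approx(np.full(3, 3.0), abs=1e-9)
        # trace starts at the baseline (rise term vanishes at t = 0)
        assert sample.matrix[0] == pytest.approx(np.full(3, 1.0), abs=1e-9)

    def test_unpolluted_sample_is_flat_at_baseline(self):
        acq = AcquisitionConfig(duration_s=2.0, rate_hz=10.0, n_sensors=4,
                                baseline_v=np.full(4, 0.8))
        model = deterministic_model(4, background=0.0)
        sample = simulate_sample(model, DomainShiftParams.identity(4), acq,
                                 CLASS_NONE, 0, rng=0)
        assert np.allclose(sample.matrix, 0.8)

    def test_default_config_matrix_shape(self):
        """A default acquisition yields the 6000 x 26 record."""
        acq = AcquisitionConfig()
        model = SensorResponseModel.default(acq)
        sample = simulate_sample(model, DomainShiftParams.identity(26), acq,
                                 "lindane", 500, rng=1)
        assert sample.matrix.shape == (6000, 26)
        assert np.all(np.isfinite(sample.matrix))
        assert sample.matrix.min() >= 0 and sample.matrix.max() <= acq.v_max

    def test_rejects_bad_labels_and_configs(self):
        acq = AcquisitionConfig(duration_s=1, rate_hz=10, n_sensors=2)
        model = deterministic_model(2)
        shift = DomainShiftParams.identity(2)
        with pytest.raises(ValueError, match="unknown pesticide"):
            simulate_sample(model, shift, acq, "ddt", 100, rng=0)
        with pytest.raises(ValueError, match="concentration 0"):
            simulate_sample(model, shift, acq, CLASS_NONE, 100, rng=0)
        with pytest.raises(ValueError, match="positive concentration"):
            simulate_sample(model, shift, acq, "malathion", 0, rng=0)
        with pytest.raises(ValueError, match="positive"):
            AcquisitionConfig(duration_s=0)
        with pytest.raises(ValueError, match="positive"):
            AcquisitionConfig(rate_hz=-5)

    def test_concentration_monotonicity_of_plateau(self):
        """Noise off: the plateau rises strictly with concentration."""
        acq = AcquisitionConfig(duration_s=20.0, rate_hz=10.0, n_sensors=3)
        model = deterministic_model(3, amplitude=1.5, tau=0.5)
        shift = DomainShiftParams.identity(3)
        plateaus = [
            simulate_sample(model, shift, acq, "chlorpyrifos", c, rng=0).matrix[-1]
            for c in (100, 500, 1000)
        ]
        assert np.all(plateaus[0] < plateaus[1])
        assert np.all(plateaus[1] < plateaus[2])


class TestDatasetDesign:
    def test_default_design_realises_the_benchmark_counts(self):
        design = DatasetDesign()
        assert design.n_per_class_per_domain == 120
        assert design.total_per_domain == 520

    def test_generated_counts_match_design(self, small_acq, small_model, small_design):
        samples = generate_domain_dataset(
            small_design, "source", small_model,
            DomainShiftParams.identity(small_acq.n_sensors), small_acq, rng=3,
        )
        assert len(samples) == small_design.total_per_domain
        pests = np.array([s.pesticide for s in samples])
        concs = np.array([s.concentration_ug_L for s in samples])
        assert (pests == CLASS_NONE).sum() == small_design.n_unpolluted_per_domain
        for p in PESTICIDES:
            assert (pests == p).sum() == small_design.n_per_class_per_domain
            for c in small_design.concentrations_ug_L:
                assert ((pests == p) & (concs == c)).sum() == small_design.n_per_concentration
        assert len({s.sample_id for s in samples}) == len(samples)

    @given(n_unpolluted=st.integers(0, 4), n_per_conc=st.integers(0, 3))
    @settings(max_examples=10, deadline=None)
    def test_count_conservation_for_any_design(self, n_unpolluted, n_per_conc):
        acq = AcquisitionConfig(duration_s=1.0, rate_hz=5.0, n_sensors=2)
        model = deterministic_model(2)
        design = DatasetDesign(
            n_unpolluted_per_domain=n_unpolluted, n_per_concentration=n_per_conc
        )
        samples = generate_domain_dataset(
            design, "target", model, DomainShiftParams.identity(2), acq, rng=0
        )
        assert len(samples) == n_unpolluted + 4 * 3 * n_per_conc

    def test_empty_design_yields_empty_collection(self):
        acq = AcquisitionConfig(duration_s=1.0, rate_hz=5.0, n_sensors=2)
        design = DatasetDesign(n_unpolluted_per_domain=0, n_per_concentration=0)
        assert generate_domain_dataset(
            design, "source", deterministic_model(2),
            DomainShiftParams.identity(2), acq, rng=0,
        ) == []


class TestDeterminismAndShift:
    def test_same_seed_gives_bit_identical_datasets(self, small_acq, small_model, small_design):
        shift = DomainShiftParams.from_magnitude(1.0, small_acq.n_sensors)
        a = generate_domain_dataset(small_design, "target", small_model, shift, small_acq, rng=7)
        b = generate_domain_dataset(small_design, "target", small_model, shift, small_acq, rng=7)
        for sa, sb in zip(a, b):
            assert sa.sample_id == sb.sample_id
            np.testing.assert_array_equal(sa.matrix, sb.matrix)

    def test_magnitude_zero_is_exact_identity(self):
        shift = DomainShiftParams.from_magnitude(0.0, 5)
        assert np.all(shift.gain == 1.0)
        assert np.all(shift.offset_v == 0.0)
        assert np.all(shift.interference_v == 0.0)
        assert np.all(shift.selectivity_warp == 1.0)

    def test_zero_shift_makes_domains_exchangeable(self, small_acq, small_model, small_design):
        """No shift: cross-domain accuracy tracks within-domain accuracy."""
        from sklearn.model_selection import cross_val_score
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        from enose_transfer import feature_table

        shift = DomainShiftParams.from_magnitude(0.0, small_acq.n_sensors)
        within, cross = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            s1, s2 = (int(s) for s in rng.integers(2**31, size=2))
            src = feature_table(generate_domain_dataset(
                small_design, "source", small_model, shift, small_acq, s1), "Mean")
            tgt = feature_table(generate_domain_dataset(
                small_design, "target", small_model, shift, small_acq, s2), "Mean")
            pipe = make_pipeline(StandardScaler(), SVC(kernel="linear"))
            within.append(np.mean(cross_val_score(pipe, src.X, src.pesticide, cv=5)))
            pipe.fit(src.X, src.pesticide)
            cross.append(np.mean(pipe.predict(tgt.X) == tgt.pesticide))
        assert abs(np.mean(within) - np.mean(cross)) < 0.03


class TestShiftParams:
    def test_magnitude_scales_distortion_away_from_identity(self):
        weak = DomainShiftParams.from_magnitude(0.5, 6)
        strong = DomainShiftParams.from_magnitude(2.0, 6)
        assert np.linalg.norm(np.log(strong.gain)) > np.linalg.norm(np.log(weak.gain))
        assert np.all(strong.interference_v >= weak.interference_v)

    def test_rejects_negative_interference(self):
        with pytest.raises(ValueError):
            DomainShiftParams(gain=np.ones(2), offset_v=np.zeros(2),
                              interference_v=np.array([-0.1, 0.0]))
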