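"""Shared fixtures.

Most tests run on a miniature acquisition protocol (a few seconds at low
rate over a handful of sensors) — the physics and the algorithms do not care
about the record length, and small records keep the suite fast.  The
full-size protocol is exercised where the contract is about its exact shape.

Session-scoped fixtures hold the calibrated benchmark shared by the
acceptance tests: one frozen instrument, one calibrated shift magnitude, and
per-seed feature tables reused across criteria.
"""

from __future__ import annotations

import numpy as np
import pytest

from enose_transfer import (
    AcquisitionConfig,
    DatasetDesign,
    DomainShiftParams,
    SensorResponseModel,
    calibrate_shift,
    feature_table,
    generate_domain_dataset,
)


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionConfig:
    return AcquisitionConfig(duration_s=4.0, rate_hz=25.0, n_sensors=8)


@pytest.fixture(scope="session")
def small_model(small_acq) -> SensorResponseModel:
    return SensorResponseModel.default(small_acq)


@pytest.fixture(scope="session")
def small_design() -> DatasetDesign:
    return DatasetDesign(n_unpolluted_per_domain=6, n_per_concentration=4)


def deterministic_model(
    n_sensors: int,
    baseline: float = 1.0,
    amplitude: float = 2.0,
    background: float = 0.0,
    tau: float = 1.0,
) -> SensorResponseModel:
    """A jitter- and noise-free instrument whose traces have closed forms."""
    return SensorResponseModel(
        sensitivity=np.full((n_sensors, 4), amplitude),
        background_v=np.full(n_sensors, background),
        tau_s=np.full(n_sensors, tau),
        noise_sd=0.0,
        gain_jitter=0.0,
        headspace_jitter=0.0,
        background_jitter=0.0,
        baseline_jitter_v=0.0,
    )


# -- calibrated benchmark (shared by the acceptance tests) -------------------


@pytest.fixture(scope="session")
def bench_acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def bench_model(bench_acq) -> SensorResponseModel:
    return SensorResponseModel.default(bench_acq)


@pytest.fixture(scope="session")
def bench_design() -> DatasetDesign:
    # Reduced plan: 130 samples per domain, same class/concentration layout.
    return DatasetDesign.reduced()


@pytest.fixture(scope="session")
def bench_shift(bench_model, bench_acq, bench_design) -> DomainShiftParams:
    return calibrate_shift(
        bench_model, bench_acq, 0.90, 0.70, np.random.default_rng(0), design=bench_design
    )


@pytest.fixture(scope="session")
def bench_tables(bench_model, bench_shift, bench_acq, bench_design):
    """Per-seed (source, target) FT feature tables on the calibrated benchmark."""

    def build(seed: int):
        rng = np.random.default_rng(seed)
        s_seed, t_seed = (int(s) for s in rng.integers(2**31, size=2))
        src = generate_domain_dataset(
            bench_design, "source", bench_model, bench_shift, bench_acq, s_seed
        )
        tgt = generate_domain_dataset(
            bench_design, "target", bench_model, bench_shift, bench_acq, t_seed
        )
        return feature_table(src, "FT"), feature_table(tgt, "FT")

    cache: dict[int, tuple] = {}

    def get(seed: int):
        if seed not in cache:
            cache[seed] = build(seed)
        return cache[seed]

    return get
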