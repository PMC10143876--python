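"""Synthetic two-domain electronic-nose data generator.

Emulates a 26-channel MOS (metal-oxide-semiconductor) gas-sensor array
sampling the headspace of groundwater samples spiked with one of four
pesticides (or left unpolluted) at three concentrations.  Two "regions"
are modelled as a source and a target domain whose response distributions
differ through a per-sensor gain / offset / interference shift; the shift
magnitude can be calibrated so that a classifier trained within one domain
transfers poorly to the other while remaining accurate at home, which is
the regime the transfer-learning machinery in :mod:`enose_transfer.transfer`
is designed for.

All randomness flows through :class:`numpy.random.Generator` objects passed
by the caller; the module never touches global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PESTICIDES",
    "CLASS_NONE",
    "CLASSES",
    "CONCENTRATIONS",
    "AcquisitionConfig",
    "DatasetDesign",
    "SensorResponseModel",
    "DomainShiftParams",
    "ENoseSample",
    "CalibrationError",
    "simulate_sample",
    "iter_domain_samples",
    "generate_domain_dataset",
    "calibrate_shift",
]

#: Pesticide classes measured in the benchmark (groundwater-quality indicators).
PESTICIDES: tuple[str, ...] = ("chlorpyrifos", "malathion", "chlorothalonil", "lindane")

#: Label for unpolluted groundwater samples.
CLASS_NONE = "none"

#: Full qualitative label set (5 classes).
CLASSES: tuple[str, ...] = (CLASS_NONE,) + PESTICIDES

#: Spiking concentrations in micrograms per litre.
CONCENTRATIONS: tuple[int, ...] = (100, 500, 1000)

DOMAINS: tuple[str, str] = ("source", "target")

# Frozen seeds for the shared "instrument" fixture and the shift direction,
# so every user of the defaults simulates the same virtual sensor array.
_INSTRUMENT_SEED = 20230410
_SHIFT_SEED = 20230411


class CalibrationError(RuntimeError):
    """Raised when the domain-shift calibration cannot satisfy its constraints."""


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True, eq=False)
class AcquisitionConfig:
    """Acquisition protocol of the virtual e-nose.

    Defaults follow a 60 s record at 100 Hz over 26 sensors, read out as
    conditioning-circuit voltages bounded by a 5 V supply.
    """

    duration_s: float = 60.0
    rate_hz: float = 100.0
    n_sensors: int = 26
    baseline_v: np.ndarray | None = None
    v_max: float = 5.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration_s and rate_hz must be positive")
        if self.n_sensors < 1:
            raise ValueError("n_sensors must be >= 1")
        if self.baseline_v is None:
            rng = np.random.default_rng(_INSTRUMENT_SEED)
            baseline = rng.uniform(0.5, 1.5, self.n_sensors)
        else:
            baseline = np.asarray(self.baseline_v, dtype=float)
            if baseline.shape != (self.n_sensors,):
                raise ValueError("baseline_v must have one entry per sensor")
        if np.any(baseline < 0) or np.any(baseline >= self.v_max):
            raise ValueError("baseline voltages must lie in [0, v_max)")
        object.__setattr__(self, "baseline_v", baseline)

    @property
    def n_rows(self) -> int:
        """Number of time points per sample matrix (duration x rate)."""
        n = self.duration_s * self.rate_hz
        n_int = int(round(n))
        if n_int <= 0 or abs(n - n_int) > 1e-9:
            raise ValueError("duration_s * rate_hz must be a positive integer")
        return n_int

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_rows) / self.rate_hz


@dataclass(frozen=True)
class DatasetDesign:
    """Sampling plan realised per domain.

    The default mirrors the benchmark layout: 40 unpolluted samples plus
    4 pesticides x 3 concentrations x 40 samples = 520 per domain.
    """

    pesticide_classes: tuple[str, ...] = PESTICIDES
    concentrations_ug_L: tuple[int, ...] = CONCENTRATIONS
    n_unpolluted_per_domain: int = 40
    n_per_concentration: int = 40

    def __post_init__(self) -> None:
        if self.n_unpolluted_per_domain < 0 or self.n_per_concentration < 0:
            raise ValueError("sample counts must be non-negative")
        if len(set(self.pesticide_classes)) != len(self.pesticide_classes):
            raise ValueError("duplicate pesticide class labels")
        if CLASS_NONE in self.pesticide_classes:
            raise ValueError("pesticide_classes lists polluted classes only")
        if any(c <= 0 for c in self.concentrations_ug_L):
            raise ValueError("concentrations must be positive")

    @property
    def n_per_class_per_domain(self) -> int:
        return len(self.concentrations_ug_L) * self.n_per_concentration

    @property
    def total_per_domain(self) -> int:
        return (
            self.n_unpolluted_per_domain
            + len(self.pesticide_classes) * self.n_per_class_per_domain
        )

    @classmethod
    def reduced(cls, factor: int = 4) -> "DatasetDesign":
        """Down-scaled plan (same structure, 1/factor of the samples)."""
        return cls(
            n_unpolluted_per_domain=max(2, 40 // factor),
            n_per_concentration=max(2, 40 // factor),
        )


@dataclass(frozen=True, eq=False)
class SensorResponseModel:
    """Stochastic response model of one sensor array ("instrument").

    Each sensor's trace rises from its baseline toward a plateau with
    first-order kinetics ``1 - exp(-t/tau)``.  The plateau amplitude is a
    class-independent background (volatiles of the leachate itself) plus a
    pesticide term ``sensitivity[s, class] * conc_response(c)``.  Sample-to-
    sample variability enters through lognormal jitters: a global headspace
    delivery factor on the pesticide term, a global factor on the background,
    and a per-sensor drift factor on the total amplitude — the dominant noise
    sources of repeated MOS measurements.

    sensitivity columns follow the order of :data:`PESTICIDES`.
    """

    sensitivity: np.ndarray  # (n_sensors, n_classes) volts at reference conc
    background_v: np.ndarray  # (n_sensors,) volts
    tau_s: np.ndarray  # (n_sensors,) seconds
    noise_sd: float = 0.01  # volts, white readout noise per time point
    gain_jitter: float = 0.12  # lognormal sd, per-sample per-sensor drift
    headspace_jitter: float = 0.15  # lognormal sd, per-sample pesticide delivery
    background_jitter: float = 0.10  # lognormal sd, per-sample background level
    baseline_jitter_v: float = 0.02  # volts, per-sample baseline wander
    conc_ref_ug_L: float = 1000.0
    conc_scale_ug_L: float = 100.0
    class_order: tuple[str, ...] = PESTICIDES

    def __post_init__(self) -> None:
        for name in ("sensitivity", "background_v", "tau_s"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.sensitivity.ndim != 2 or self.sensitivity.shape[1] != len(self.class_order):
            raise ValueError("sensitivity must be (n_sensors, n_classes)")
        if np.any(self.sensitivity < 0) or np.any(self.background_v < 0):
            raise ValueError("amplitudes must be non-negative")
        if np.any(self.tau_s <= 0):
            raise ValueError("tau_s must be positive")

    @property
    def n_sensors(self) -> int:
        return self.sensitivity.shape[0]

    def conc_response(self, concentration_ug_L: float) -> float:
        """Saturating (logarithmic) amplitude multiplier, 1 at the reference.

        Strictly increasing in concentration; 0 at concentration 0.
        """
        if concentration_ug_L < 0:
            raise ValueError("concentration must be non-negative")
        if concentration_ug_L == 0:
            return 0.0
        num = np.log1p(concentration_ug_L / self.conc_scale_ug_L)
        den = np.log1p(self.conc_ref_ug_L / self.conc_scale_ug_L)
        return float(num / den)

    @classmethod
    def default(
        cls,
        acq: AcquisitionConfig | None = None,
        seed: int = _INSTRUMENT_SEED,
        **overrides,
    ) -> "SensorResponseModel":
        """The frozen default instrument, drawn once from a fixed seed.

        Class selectivity is modelled as a moderate lognormal modulation of a
        shared cross-sensitive profile: MOS sensors respond broadly to all
        volatiles, and class identity lives in relative pattern differences
        across the array, not in class-exclusive channels.
        """
        acq = acq or AcquisitionConfig()
        rng = np.random.default_rng(seed)
        n = acq.n_sensors
        base_profile = rng.uniform(0.4, 1.2, n)
        selectivity = np.exp(0.3 * rng.standard_normal((n, len(PESTICIDES))))
        params = dict(
            sensitivity=base_profile[:, None] * selectivity,
            background_v=rng.uniform(0.2, 0.6, n),
            tau_s=rng.uniform(3.0, 10.0, n),
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True, eq=False)
class DomainShiftParams:
    """Per-sensor distortion separating the two domains.

    ``gain`` rescales the responsive part of each trace, ``offset_v`` shifts
    the whole trace, and ``interference_v`` adds a class-independent plateau
    amplitude from region-specific background volatiles.  ``selectivity_warp``
    multiplies each (sensor, pesticide) sensitivity: background compounds
    co-adsorbing on a MOS surface modify its response to each analyte by a
    compound-specific factor, so the relative class patterns — not just the
    per-sensor scale — differ between regions.  ``magnitude`` is the scalar
    knob that scales the fixed distortion direction away from identity;
    magnitude 0 is exactly the identity.
    """

    gain: np.ndarray
    offset_v: np.ndarray
    interference_v: np.ndarray
    selectivity_warp: np.ndarray | None = None  # (n_sensors, n_classes), 1 = none
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gain", "offset_v", "interference_v"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.gain.shape == self.offset_v.shape == self.interference_v.shape):
            raise ValueError("shift fields must share one shape")
        if np.any(self.interference_v < 0):
            raise ValueError("interference amplitudes must be non-negative")
        if self.selectivity_warp is not None:
            warp = np.asarray(self.selectivity_warp, dtype=float)
            if warp.ndim != 2 or warp.shape[0] != self.gain.shape[0]:
                raise ValueError("selectivity_warp must be (n_sensors, n_classes)")
            if np.any(warp < 0):
                raise ValueError("selectivity factors must be non-negative")
            object.__setattr__(self, "selectivity_warp", warp)

    @classmethod
    def identity(cls, n_sensors: int) -> "DomainShiftParams":
        return cls(
            gain=np.ones(n_sensors),
            offset_v=np.zeros(n_sensors),
            interference_v=np.zeros(n_sensors),
            selectivity_warp=None,
            magnitude=0.0,
        )

    @classmethod
    def from_magnitude(
        cls,
        magnitude: float,
        n_sensors: int,
        seed: int = _SHIFT_SEED,
        n_classes: int = len(PESTICIDES),
    ) -> "DomainShiftParams":
        """Scale the frozen per-sensor distortion direction by ``magnitude``."""
        if magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        rng = np.random.default_rng(seed)
        u_gain = rng.normal(0.0, 0.25, n_sensors)
        u_off = rng.normal(0.0, 0.08, n_sensors)
        u_intf = np.abs(rng.normal(0.0, 0.15, n_sensors))
        u_warp = rng.normal(0.0, 0.30, (n_sensors, n_classes))
        return cls(
            gain=np.exp(magnitude * u_gain),
            offset_v=magnitude * u_off,
            interference_v=magnitude * u_intf,
            selectivity_warp=np.exp(magnitude * u_warp),
            magnitude=float(magnitude),
        )


@dataclass(frozen=True, eq=False)
class ENoseSample:
    """One measurement: a time x sensor voltage matrix plus its labels."""

    matrix: np.ndarray
    domain: str
    pesticide: str
    concentration_ug_L: int
    sample_id: str


def simulate_sample(
    model: SensorResponseModel,
    shift: DomainShiftParams,
    acq: AcquisitionConfig,
    pesticide: str,
    concentration_ug_L: float,
    rng: np.random.Generator | int | None,
    *,
    domain: str = "source",
    sample_id: str = "",
) -> ENoseSample:
    """Simulate one acquisition.

    Per sensor ``s`` the trace is::

        v(t) = baseline[s] + offset[s]
               + gain[s] * (amplitude[s] + interference[s]) * (1 - exp(-t/tau[s]))
               + readout noise,

    clipped to ``[0, v_max]``, where ``amplitude`` combines the jittered
    background and pesticide terms described on :class:`SensorResponseModel`.
    """
    rng = _as_rng(rng)
    if pesticide not in CLASSES and pesticide not in model.class_order:
        raise ValueError(f"unknown pesticide class {pesticide!r}")
    if pesticide == CLASS_NONE:
        if concentration_ug_L != 0:
            raise ValueError("unpolluted samples must have concentration 0")
        pest_amp = np.zeros(model.n_sensors)
    else:
        if concentration_ug_L <= 0:
            raise ValueError("polluted samples need a positive concentration")
        col = model.class_order.index(pesticide)
        pest_amp = model.sensitivity[:, col] * model.conc_response(concentration_ug_L)
        if shift.selectivity_warp is not None:
            pest_amp = pest_amp * shift.selectivity_warp[:, col]
    if model.n_sensors != acq.n_sensors:
        raise ValueError("model and acquisition config disagree on n_sensors")

    # Fixed draw order keeps a given seed bit-reproducible.
    g_head = np.exp(model.headspace_jitter * rng.standard_normal())
    g_bg = np.exp(model.background_jitter * rng.standard_normal())
    g_sensor = np.exp(model.gain_jitter * rng.standard_normal(model.n_sensors))
    base_jit = model.baseline_jitter_v * rng.standard_normal(model.n_sensors)

    amplitude = (model.background_v * g_bg + pest_amp * g_head) * g_sensor
    rise = 1.0 - np.exp(-acq.time_s[:, None] / model.tau_s[None, :])
    base = acq.baseline_v + base_jit + shift.offset_v
    trace = base[None, :] + (shift.gain * (amplitude + shift.interference_v))[None, :] * rise
    if model.noise_sd > 0:
        trace = trace + model.noise_sd * rng.standard_normal(trace.shape)
    np.clip(trace, 0.0, acq.v_max, out=trace)
    return ENoseSample(
        matrix=trace,
        domain=domain,
        pesticide=pesticide,
        concentration_ug_L=int(concentration_ug_L),
        sample_id=sample_id or f"{domain}-{pesticide}-{int(concentration_ug_L)}",
    )


def iter_domain_samples(
    design: DatasetDesign,
    domain: str,
    model: SensorResponseModel,
    shift: DomainShiftParams,
    acq: AcquisitionConfig,
    rng: np.random.Generator | int | None,
) -> Iterator[ENoseSample]:
    """Yield one domain's samples in the canonical design order.

    By convention the source domain is acquired at identity shift and the
    target domain through the supplied :class:`DomainShiftParams`.
    """
    if domain not in DOMAINS:
        raise ValueError(f"domain must be one of {DOMAINS}")
    rng = _as_rng(rng)
    eff_shift = shift if domain == "target" else DomainShiftParams.identity(acq.n_sensors)

    def make(pesticide: str, conc: int, idx: int) -> ENoseSample:
        sid = f"{domain}-{pesticide}-{conc:04d}-{idx:03d}"
        return simulate_sample(
            model, eff_shift, acq, pesticide, conc, rng, domain=domain, sample_id=sid
        )

    for i in range(design.n_unpolluted_per_domain):
        yield make(CLASS_NONE, 0, i)
    for pesticide in design.pesticide_classes:
        for conc in design.concentrations_ug_L:
            for i in range(design.n_per_concentration):
                yield make(pesticide, conc, i)


def generate_domain_dataset(
    design: DatasetDesign,
    domain: str,
    model: SensorResponseModel,
    shift: DomainShiftParams,
    acq: AcquisitionConfig,
    rng: np.random.Generator | int | None,
) -> list[ENoseSample]:
    """Materialise one domain's full sample collection as a list."""
    return list(iter_domain_samples(design, domain, model, shift, acq, rng))


def calibrate_shift(
    base_model: SensorResponseModel,
    acq: AcquisitionConfig,
    within_floor: float,
    cross_ceiling: float,
    rng: np.random.Generator | int | None,
    *,
    design: DatasetDesign | None = None,
    max_magnitude: float = 16.0,
    n_bisect: int = 6,
    C: float = 1.0,
) -> DomainShiftParams:
    """Find the smallest shift magnitude producing the cross-domain gap.

    Criterion: with Mean features and a linear SVM, 5-fold within-domain
    accuracy must stay >= ``within_floor`` while a model trained on the full
    (unshifted) source domain scores <= ``cross_ceiling`` on the shifted
    target domain.  The bisection does not stop at the first magnitude
    slipping under the ceiling — a shift calibrated onto the boundary holds
    only marginally on fresh data — but aims a quarter of the way up from
    chance (majority-class share) toward the ceiling, i.e. deep inside the
    admissible region.  Target datasets at every candidate magnitude reuse
    one random stream (common random numbers), so the accuracy-vs-magnitude
    profile is effectively monotone.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    from .features import feature_table

    if not (0.0 < cross_ceiling < within_floor <= 1.0):
        raise ValueError("need 0 < cross_ceiling < within_floor <= 1")
    rng = _as_rng(rng)
    design = design or DatasetDesign.reduced()
    source_seed, target_seed, cv_seed = (int(s) for s in rng.integers(2**31, size=3))

    identity = DomainShiftParams.identity(acq.n_sensors)
    source = generate_domain_dataset(design, "source", base_model, identity, acq, source_seed)
    src = feature_table(source, "Mean", rate_hz=acq.rate_hz)

    pipe = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
    cv = StratifiedKFold(5, shuffle=True, random_state=cv_seed % 2**31)
    within = float(np.mean(cross_val_score(pipe, src.X, src.pesticide, cv=cv)))
    if within < within_floor:
        raise CalibrationError(
            f"within-domain accuracy {within:.3f} below floor {within_floor:.3f}; "
            "the instrument itself does not support the requested gap"
        )

    clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
    clf.fit(src.X, src.pesticide)

    def cross_accuracy(magnitude: float) -> float:
        shift = DomainShiftParams.from_magnitude(magnitude, acq.n_sensors)
        target = generate_domain_dataset(design, "target", base_model, shift, acq, target_seed)
        tgt = feature_table(target, "Mean", rate_hz=acq.rate_hz)
        return float(np.mean(clf.predict(tgt.X) == tgt.pesticide))

    # Aim point: well below the ceiling, a quarter of the way up from chance.
    classes, counts = np.unique(src.pesticide, return_counts=True)
    chance = counts.max() / counts.sum()
    aim = chance + 0.25 * (cross_ceiling - chance)

    # Bracket: magnitude 0 reproduces the within-domain accuracy, so it is
    # rejected whenever cross_ceiling < within_floor; double until under aim.
    hi = 1.0
    while cross_accuracy(hi) > aim:
        hi *= 2.0
        if hi > max_magnitude:
            raise CalibrationError(
                f"cross-domain accuracy still {cross_accuracy(max_magnitude):.3f} > "
                f"aim {aim:.3f} at magnitude {max_magnitude}"
            )
    lo = 0.0
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if cross_accuracy(mid) <= aim:
            hi = mid
        else:
            lo = mid

    cross = cross_accuracy(hi)
    if cross > cross_ceiling:
        raise CalibrationError(
            f"calibration failed: within {within:.3f}, cross {cross:.3f} "
            f"(floor {within_floor:.3f}, ceiling {cross_ceiling:.3f})"
        )
    return DomainShiftParams.from_magnitude(hi, acq.n_sensors)
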