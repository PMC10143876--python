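"""Feature extraction for e-nose response matrices.

Five methods, two families:

* steady-state — one scalar per sensor: integral under the response curve
  (``IV``, volt-seconds on the true time grid), maximum voltage (``MAX``),
  or mean voltage (``Mean``);
* transient-state — transform-domain coefficients of the full trace:
  magnitudes of the leading discrete-Fourier coefficients (``FT``) or leading
  approximation coefficients of a discrete wavelet decomposition (``WT``),
  concatenated across sensors.

Functions accept a raw ``(time, sensor)`` matrix or any object with a
``matrix`` attribute (e.g. :class:`~enose_transfer.simulate.ENoseSample`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pywt

__all__ = [
    "METHODS",
    "STEADY_STATE_METHODS",
    "TRANSFORM_METHODS",
    "FeatureVector",
    "FeatureTable",
    "extract_steady_state",
    "extract_transform",
    "extract_features",
    "feature_table",
]

STEADY_STATE_METHODS = ("IV", "MAX", "Mean")
TRANSFORM_METHODS = ("FT", "WT")
METHODS = TRANSFORM_METHODS + STEADY_STATE_METHODS


@dataclass(frozen=True, eq=False)
class FeatureVector:
    """Fixed-length descriptor of one sample under one extraction method."""

    values: np.ndarray
    method: str
    per_sensor_dim: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(eq=False)
class FeatureTable:
    """Feature matrix for a sample collection, with per-row labels."""

    X: np.ndarray
    pesticide: np.ndarray
    concentration: np.ndarray
    domain: np.ndarray
    sample_id: np.ndarray
    method: str

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            X=self.X[mask],
            pesticide=self.pesticide[mask],
            concentration=self.concentration[mask],
            domain=self.domain[mask],
            sample_id=self.sample_id[mask],
            method=self.method,
        )


def _as_matrix(sample) -> np.ndarray:
    matrix = getattr(sample, "matrix", sample)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError("sample matrix must be a non-empty 2-D array")
    return matrix


def extract_steady_state(sample, kind: str, *, rate_hz: float = 100.0) -> FeatureVector:
    """One steady-state value per sensor.

    ``IV`` integrates each trace by the trapezoid rule on the real time grid
    (dt = 1/rate_hz), giving volt-seconds; ``MAX`` and ``Mean`` are the
    per-column maximum and arithmetic mean.
    """
    matrix = _as_matrix(sample)
    if kind == "IV":
        values = np.trapezoid(matrix, dx=1.0 / rate_hz, axis=0)
    elif kind == "MAX":
        values = matrix.max(axis=0)
    elif kind == "Mean":
        values = matrix.mean(axis=0)
    else:
        raise ValueError(f"unknown steady-state method {kind!r}")
    return FeatureVector(values=values, method=kind, per_sensor_dim=1)


def extract_transform(
    sample,
    kind: str,
    *,
    n_coeffs: int = 8,
    wt_basis: str = "db4",
    wt_level: int = 3,
) -> FeatureVector:
    """Leading transform coefficients per sensor, concatenated sensor-major.

    ``FT`` keeps the magnitudes of the first ``n_coeffs`` one-sided DFT
    coefficients (DC included); phase is discarded so the features are
    insensitive to small acquisition-start offsets.  ``WT`` keeps the first
    ``n_coeffs`` approximation coefficients of a level-``wt_level`` discrete
    wavelet decomposition.
    """
    matrix = _as_matrix(sample)
    if n_coeffs < 1:
        raise ValueError("n_coeffs must be >= 1")
    if kind == "FT":
        spectrum = np.abs(np.fft.rfft(matrix, axis=0))
        if n_coeffs > spectrum.shape[0]:
            raise ValueError(
                f"n_coeffs={n_coeffs} exceeds the {spectrum.shape[0]} available "
                "one-sided Fourier coefficients"
            )
        block = spectrum[:n_coeffs]
    elif kind == "WT":
        if wt_basis not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown discrete wavelet {wt_basis!r}")
        approx = pywt.wavedec(matrix, wt_basis, level=wt_level, axis=0)[0]
        if n_coeffs > approx.shape[0]:
            raise ValueError(
                f"n_coeffs={n_coeffs} exceeds the {approx.shape[0]} available "
                f"level-{wt_level} approximation coefficients"
            )
        block = approx[:n_coeffs]
    else:
        raise ValueError(f"unknown transform method {kind!r}")
    # Sensor-major layout: all coefficients of sensor 0, then sensor 1, ...
    return FeatureVector(values=block.T.ravel(), method=kind, per_sensor_dim=n_coeffs)


def extract_features(
    sample,
    method: str,
    *,
    rate_hz: float = 100.0,
    n_coeffs: int = 8,
    wt_basis: str = "db4",
    wt_level: int = 3,
) -> FeatureVector:
    """Dispatch to the steady-state or transform extractor by method name."""
    if method in STEADY_STATE_METHODS:
        return extract_steady_state(sample, method, rate_hz=rate_hz)
    if method in TRANSFORM_METHODS:
        return extract_transform(
            sample, method, n_coeffs=n_coeffs, wt_basis=wt_basis, wt_level=wt_level
        )
    raise ValueError(f"unknown feature method {method!r}; expected one of {METHODS}")


def feature_table(samples: Iterable, method: str, **kwargs) -> FeatureTable:
    """Extract one method's features for a whole sample collection."""
    rows, pest, conc, dom, ids = [], [], [], [], []
    for sample in samples:
        rows.append(extract_features(sample, method, **kwargs).values)
        pest.append(getattr(sample, "pesticide", ""))
        conc.append(getattr(sample, "concentration_ug_L", 0))
        dom.append(getattr(sample, "domain", ""))
        ids.append(getattr(sample, "sample_id", ""))
    if not rows:
        raise ValueError("empty sample collection")
    return FeatureTable(
        X=np.vstack(rows),
        pesticide=np.asarray(pest),
        concentration=np.asarray(conc, dtype=int),
        domain=np.asarray(dom),
        sample_id=np.asarray(ids),
        method=method,
    )
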