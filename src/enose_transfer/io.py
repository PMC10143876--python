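"""File formats and run configuration.

On disk a dataset is a directory of per-sample CSV matrices (time x sensor,
no header) plus a ``manifest.csv`` with columns ``sample_id, domain,
pesticide, concentration_ug_L, path``.  Run configuration lives in YAML and
round-trips losslessly through :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .features import METHODS
from .simulate import AcquisitionConfig, DatasetDesign, ENoseSample

__all__ = [
    "ManifestError",
    "MANIFEST_COLUMNS",
    "write_sample_csv",
    "read_sample_csv",
    "write_manifest",
    "read_manifest",
    "RunConfig",
]

MANIFEST_COLUMNS = ("sample_id", "domain", "pesticide", "concentration_ug_L", "path")


class ManifestError(ValueError):
    """A manifest or one of its referenced sample files is invalid."""


def write_sample_csv(sample: ENoseSample, path: Path) -> Path:
    path = Path(path)
    np.savetxt(path, sample.matrix, delimiter=",", fmt="%.5f")
    return path


def read_sample_csv(path: Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_manifest(samples: Sequence[ENoseSample], out_dir: Path) -> Path:
    """Write one CSV per sample plus the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "samples").mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in samples:
        rel = Path("samples") / f"{sample.sample_id}.csv"
        write_sample_csv(sample, out_dir / rel)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "domain": sample.domain,
                "pesticide": sample.pesticide,
                "concentration_ug_L": sample.concentration_ug_L,
                "path": str(rel),
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest_path, index=False)
    return manifest_path


def read_manifest(
    manifest_path: Path, acq: AcquisitionConfig | None = None
) -> list[ENoseSample]:
    """Load a manifest and every referenced sample matrix, validating shapes.

    Errors name the offending sample_id.  An empty manifest yields an empty
    list without error.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest is missing columns: {sorted(missing)}")
    base = manifest_path.parent
    samples = []
    for row in df.itertuples(index=False):
        path = base / row.path
        if not path.exists():
            raise ManifestError(f"sample {row.sample_id!r}: file not found: {path}")
        matrix = read_sample_csv(path)
        if acq is not None and matrix.shape != (acq.n_rows, acq.n_sensors):
            raise ManifestError(
                f"sample {row.sample_id!r}: shape {matrix.shape} does not match "
                f"the configured ({acq.n_rows}, {acq.n_sensors})"
            )
        samples.append(
            ENoseSample(
                matrix=matrix,
                domain=str(row.domain),
                pesticide=str(row.pesticide),
                concentration_ug_L=int(row.concentration_ug_L),
                sample_id=str(row.sample_id),
            )
        )
    return samples


@dataclass
class RunConfig:
    """Everything one end-to-end pipeline run needs; YAML round-trippable.

    All randomness flows from ``seed`` through named child streams, so a
    rerun with an identical config reproduces identical result tables.
    """

    out_dir: str = "runs/demo"
    seed: int = 0
    # acquisition
    duration_s: float = 60.0
    rate_hz: float = 100.0
    n_sensors: int = 26
    # dataset design
    n_unpolluted_per_domain: int = 40
    n_per_concentration: int = 40
    # domain shift: "calibrate" searches the magnitude, "fixed" uses shift_magnitude
    shift_mode: str = "calibrate"
    shift_magnitude: float = 2.0
    within_floor: float = 0.90
    cross_ceiling: float = 0.70
    # features
    qualitative_method: str = "FT"
    semiquant_method: str = "Mean"
    n_coeffs: int = 8
    wt_basis: str = "db4"
    wt_level: int = 3
    # transfer / experiments
    N: int = 50
    C: float = 0.0015  # qualitative task (FT features)
    C_semiquant: float = 0.05  # concentration task (Mean features, lower dim)
    Tt: int = 30
    N_grid: tuple[int, ...] = (0, 10, 20, 30, 40, 50)
    n_seeds: int = 20
    write_data: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.qualitative_method not in METHODS:
            raise ValueError(f"unknown feature method {self.qualitative_method!r}")
        if self.semiquant_method not in METHODS:
            raise ValueError(f"unknown feature method {self.semiquant_method!r}")
        if self.shift_mode not in ("calibrate", "fixed"):
            raise ValueError("shift_mode must be 'calibrate' or 'fixed'")
        if self.n_seeds < 1 or self.N < 1 or self.Tt < 1:
            raise ValueError("n_seeds, N and Tt must be >= 1")

    # -- structural views -------------------------------------------------
    def acquisition(self) -> AcquisitionConfig:
        return AcquisitionConfig(
            duration_s=self.duration_s, rate_hz=self.rate_hz, n_sensors=self.n_sensors
        )

    def dataset_design(self) -> DatasetDesign:
        return DatasetDesign(
            n_unpolluted_per_domain=self.n_unpolluted_per_domain,
            n_per_concentration=self.n_per_concentration,
        )

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["N_grid"] = list(self.N_grid)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "N_grid" in data:
            data["N_grid"] = tuple(int(n) for n in data["N_grid"])
        return cls(**data)

    def to_yaml(self, path: Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
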