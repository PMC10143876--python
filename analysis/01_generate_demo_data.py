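"""Generate a miniature two-domain dataset and write it in the on-disk format.

Demonstrates the data layout (per-sample CSV matrices plus a manifest) on a
short, low-rate acquisition so the artifacts stay small.  The full-size
benchmark (520 samples/domain, 6000 x 26 matrices) is generated in memory by
the later scripts instead of being stored.
"""

from pathlib import Path

import numpy as np

from enose_transfer import (
    AcquisitionConfig,
    DatasetDesign,
    DomainShiftParams,
    SensorResponseModel,
    generate_domain_dataset,
    read_manifest,
    write_manifest,
)

OUT = Path("data/demo")
SEED = 0

acq = AcquisitionConfig(duration_s=4.0, rate_hz=25.0, n_sensors=8)
model = SensorResponseModel.default(acq)
design = DatasetDesign(n_unpolluted_per_domain=4, n_per_concentration=4)
shift = DomainShiftParams.from_magnitude(2.0, acq.n_sensors)

rng = np.random.default_rng(SEED)
s_seed, t_seed = (int(s) for s in rng.integers(2**31, size=2))
samples = generate_domain_dataset(design, "source", model, shift, acq, s_seed)
samples += generate_domain_dataset(design, "target", model, shift, acq, t_seed)
manifest = write_manifest(samples, OUT)

reloaded = read_manifest(manifest, acq=acq)
assert len(reloaded) == 2 * design.total_per_domain

print(f"wrote {len(samples)} samples ({design.total_per_domain} per domain) to {OUT}")
print(f"each matrix: {acq.n_rows} time points x {acq.n_sensors} sensors")
print(f"manifest: {manifest} — round-trip load OK")
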