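#!/usr/bin/env python
"""Simulate the characterization plate.

Generates the standard 96-well layout — five malonyl-CoA producing
constructs x six IPTG doses x three replicates plus empty-vector controls —
with readings every 12 min for 48 h and 2% multiplicative measurement
noise, and writes the plate plus its full parameter sidecar.
"""

from pathlib import Path

from fapsense import default_design, generate_plate, write_plate_csv
from fapsense.config import RunConfig, save_config

OUT = Path("results")
SEED = 20240917


def main() -> None:
    design = default_design()
    plate = generate_plate(design, seed=SEED)
    path = write_plate_csv(plate, OUT / "plate.csv")
    save_config(RunConfig(seed=SEED), OUT / "plate.toml")
    n_grow = sum(w.od.max() >= 0.6 for w in plate.wells)
    print(f"wrote {len(plate.wells)} wells x {plate.time_min.size} readings to {path}")
    print(f"sampling period {plate.ts:.0f} min; {n_grow} wells reach OD 0.6")


if __name__ == "__main__":
    main()
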