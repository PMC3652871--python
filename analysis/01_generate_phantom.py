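"""Generate the phantom subject: ellipsoidal FA volume + modular tractogram.

The phantom emulates the inputs the network-construction pipeline expects
from a real scan: a brain-sized FA map whose non-zero support is the brain
mask, and a whole-brain streamline set whose endpoints cluster into five
spatially contiguous planted modules, with 10% short noise streamlines
below the 5 mm length threshold.
"""

import argparse
import json

import numpy as np

import tractnet as tn
from common import FA_PATH, PLANTED_PATH, RESULTS, TRK_PATH, ensure_phantom


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    spec, fa, tract, planted = ensure_phantom(args.seed)
    lengths = tract.lengths()
    n_noise = int((lengths < spec.length_threshold_mm).sum())
    summary = {
        "seed": args.seed,
        "radii_mm": list(spec.radii_mm),
        "voxel_mm": spec.voxel_mm,
        "grid_shape": list(fa.data.shape),
        "n_brain_voxels": int((fa.data > 0).sum()),
        "n_streamlines": len(tract),
        "n_noise_streamlines": n_noise,
        "planted_modules": int(planted.max()),
        "nodes_per_module": {
            str(m): int((planted == m).sum()) for m in np.unique(planted) if m > 0
        },
        "length_mm": {
            "min": float(lengths.min()),
            "median": float(np.median(lengths)),
            "max": float(lengths.max()),
        },
    }
    out = RESULTS / "phantom_summary.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")

    print(f"phantom FA volume  : {FA_PATH}  shape={fa.data.shape}")
    print(f"phantom tractogram : {TRK_PATH}  {len(tract)} streamlines "
          f"({n_noise} below the {spec.length_threshold_mm} mm threshold)")
    print(f"planted modules    : {PLANTED_PATH}  "
          f"{summary['planted_modules']} sectors, node counts "
          f"{list(summary['nodes_per_module'].values())}")
    print(f"summary            : {out}")


if __name__ == "__main__":
    main()
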