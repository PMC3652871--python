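"""Shared plumbing for the numbered analysis scripts.

The phantom subject (FA volume + tractogram + planted module labels) is
generated once into scratch/phantom/ and reused by the later stages; text
tables land in results/.  Every script regenerates missing inputs, so each
one can be run on its own.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import tractnet as tn
from tractnet import io

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "phantom"
RESULTS = ROOT / "results"

FA_PATH = SCRATCH / "fa.nii.gz"
TRK_PATH = SCRATCH / "tracks.trk"
PLANTED_PATH = SCRATCH / "planted_modules.csv"


def ensure_phantom(seed: int = 0):
    """Generate (or reload) the study phantom; returns (spec, fa, tract, planted)."""
    spec = tn.PhantomSpec(seed=seed)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    if FA_PATH.exists() and TRK_PATH.exists() and PLANTED_PATH.exists():
        fa = io.read_fa_volume(FA_PATH)
        tract = io.read_tractogram(TRK_PATH)
        planted = pd.read_csv(PLANTED_PATH)["module"].to_numpy()
        return spec, fa, tract, planted
    fa = tn.make_phantom_fa(spec)
    surface = tn.extract_subcortical_surface(fa, depth_mm=5.0)
    parc = tn.label_surface(surface, tn.eq_partition(100))
    tract, planted = tn.make_phantom_tractogram(fa, parc, spec)
    io.write_fa_volume(fa, FA_PATH)
    io.write_tractogram(tract, TRK_PATH, fa=fa)
    pd.DataFrame(
        {"node_id": np.arange(1, len(planted) + 1), "module": planted}
    ).to_csv(PLANTED_PATH, index=False)
    return spec, fa, tract, planted


def build_parcellation(fa: tn.FAVolume, n_nodes: int = 100) -> tn.Parcellation:
    surface = tn.extract_subcortical_surface(fa, depth_mm=5.0)
    return tn.label_surface(surface, tn.eq_partition(n_nodes))
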