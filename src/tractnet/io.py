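"""File I/O for the formats the pipeline touches.

NIfTI volumes go through nibabel; streamline sets go through
nibabel.streamlines (TrackVis .trk and MRtrix .tck), always converted to
world (RAS mm) coordinates on read.  Connectivity matrices, centroids,
partitions and reports are written as plain CSV/JSON with 1-based node
ids in every user-facing file.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .network import ConnectivityMatrix, Tractogram
from .parcellation import FAVolume, Parcellation

__all__ = [
    "read_fa_volume",
    "write_fa_volume",
    "read_tractogram",
    "write_tractogram",
    "write_connectivity",
    "read_connectivity",
    "write_parcellation",
    "write_partition_csv",
    "write_json",
]


def read_fa_volume(path) -> FAVolume:
    """Load a 3-D scalar NIfTI volume, preserving grid, spacing and affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3-D scalar image, got shape {data.shape} from {path}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite voxels")
    return FAVolume(data=np.asarray(data, dtype=float), affine=img.affine)


def write_fa_volume(fa: FAVolume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(fa.data.astype(np.float32), fa.affine), path)
    return path


def read_tractogram(path) -> Tractogram:
    """Load a .trk/.tck streamline file; points come back in world mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tf = nib.streamlines.load(str(path))  # applies affine_to_rasmm
    except Exception as exc:  # malformed header / truncated body
        raise ValueError(f"cannot read streamline file {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    if not streamlines:
        import logging

        logging.getLogger(__name__).warning("%s holds zero streamlines", path)
        return Tractogram([])
    return Tractogram(streamlines)


def write_tractogram(tractogram: Tractogram, path, fa: FAVolume | None = None) -> Path:
    """Write .trk or .tck (by extension), points already in world mm.

    For .trk the header's voxel size/dimension/affine fields are populated
    from ``fa`` when given, so downstream TrackVis-convention readers can
    convert correctly.
    """
    path = Path(path)
    sl = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix == ".trk":
        header = {}
        if fa is not None:
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = tuple(
                np.asarray(fa.voxel_mm, dtype=np.float32)
            )
            header[nib.streamlines.trk.Field.DIMENSIONS] = tuple(fa.data.shape)
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = fa.affine.astype(
                np.float32
            )
        nib.streamlines.save(sl, str(path), header=header)
    elif path.suffix == ".tck":
        nib.streamlines.save(sl, str(path))
    else:
        raise ValueError(f"unsupported tractogram extension: {path.suffix}")
    return path


def write_connectivity(conn: ConnectivityMatrix, csv_path, edges_path=None) -> Path:
    """Dense N x N weight CSV (1-based node headers) + optional edge list."""
    csv_path = Path(csv_path)
    ids = np.arange(1, conn.n_nodes + 1)
    pd.DataFrame(conn.weights, index=ids, columns=ids).to_csv(
        csv_path, index_label="node"
    )
    if edges_path is not None:
        iu, ju = np.nonzero(np.triu(conn.weights, 1))
        pd.DataFrame(
            {"i": iu + 1, "j": ju + 1, "weight": conn.weights[iu, ju]}
        ).to_csv(edges_path, index=False)
    return csv_path


def read_connectivity(csv_path, binarize_threshold: int = 1) -> ConnectivityMatrix:
    df = pd.read_csv(csv_path, index_col=0)
    weights = df.to_numpy(dtype=np.int64)
    return ConnectivityMatrix(
        weights=weights,
        adjacency=(weights >= binarize_threshold).astype(np.uint8),
        n_nodes=weights.shape[0],
    )


def write_parcellation(parc: Parcellation, nifti_path, centroid_csv_path) -> None:
    """Label volume on the input grid + node centroid table."""
    vol = parc.label_volume()
    nib.save(nib.Nifti1Image(vol.astype(np.int16), parc.surface.affine), nifti_path)
    ids = np.arange(1, parc.n_nodes + 1)
    pd.DataFrame(
        {
            "node_id": ids,
            "x_mm": parc.node_centroids_mm[:, 0],
            "y_mm": parc.node_centroids_mm[:, 1],
            "z_mm": parc.node_centroids_mm[:, 2],
            "n_voxels": parc.voxel_counts(),
        }
    ).to_csv(centroid_csv_path, index=False)


def write_partition_csv(labels: np.ndarray, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"node_id": np.arange(1, len(labels) + 1), "module_id": labels}
    ).to_csv(path, index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
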