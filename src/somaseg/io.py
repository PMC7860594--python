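"""File formats: multi-page TIFF volumes, centers CSV, stats and checkpoints.

Volumes are stored one z-slice per TIFF page, matching how microscopy stacks
ship.  Normalization statistics live in a small YAML file next to the model
checkpoint so prediction always reuses the training-set statistics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from somaseg.nn.model import MultiTaskUNet3D, NetworkConfig
from somaseg.postprocess import SegmentationResult
from somaseg.preprocess import NormalizationStats

CHECKPOINT_VERSION = 1


def read_volume(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a (z, y, x) array.

    Raises a named error on unreadable files or inconsistent page shapes.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read TIFF volume {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise IOError(
            f"{path}: expected a 3D stack (one z-slice per page), got shape "
            f"{data.shape}"
        )
    return data


def write_volume(path: str | Path, volume: np.ndarray,
                 as_labels: bool = False) -> None:
    """Write a (z, y, x) array as multi-page TIFF.

    Labels are stored as uint16, promoted to uint32 when values overflow;
    intensities as float32 (or uint8 if already that dtype).
    """
    volume = np.asarray(volume)
    if as_labels:
        if volume.min() < 0:
            raise ValueError("label volumes must be non-negative")
        dtype = np.uint16 if volume.max() < 2**16 else np.uint32
        volume = volume.astype(dtype)
    elif volume.dtype != np.uint8:
        volume = volume.astype(np.float32)
    tifffile.imwrite(Path(path), volume, photometric="minisblack")


def write_centers(path: str | Path, result: SegmentationResult) -> None:
    """Centers CSV: header ``instance_id,z,y,x``, floats at 3 decimals."""
    rows = [
        {"instance_id": i + 1, "z": round(z, 3), "y": round(y, 3), "x": round(x, 3)}
        for i, (z, y, x) in enumerate(result.centers)
    ]
    pd.DataFrame(rows, columns=["instance_id", "z", "y", "x"]).to_csv(
        Path(path), index=False, float_format="%.3f"
    )


def read_centers(path: str | Path) -> np.ndarray:
    """Read a centers CSV back as an (n, 3) array of (z, y, x)."""
    try:
        df = pd.read_csv(Path(path))
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read centers CSV {path}: {exc}") from exc
    for col in ("instance_id", "z", "y", "x"):
        if col not in df.columns:
            raise IOError(f"{path}: malformed centers CSV, missing column {col!r}")
    return df[["z", "y", "x"]].to_numpy(dtype=np.float64)


def write_stats(path: str | Path, stats: NormalizationStats) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"mean": stats.mean, "std": stats.std, "n_voxels": stats.n_voxels}, fh
        )


def read_stats(path: str | Path) -> NormalizationStats:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return NormalizationStats(
        mean=float(d["mean"]), std=float(d["std"]), n_voxels=int(d["n_voxels"])
    )


def save_checkpoint(
    path: str | Path,
    network: MultiTaskUNet3D,
    stats: NormalizationStats | None = None,
) -> None:
    """Versioned checkpoint: weights + NetworkConfig + NormalizationStats."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "network": network.config.to_dict(),
        "stats": None
        if stats is None
        else {"mean": stats.mean, "std": stats.std, "n_voxels": stats.n_voxels},
    }
    arrays = {f"param/{k}": v for k, v in network.state_dict().items()}
    with open(Path(path), "wb") as fh:  # keep the exact filename, any suffix
        np.savez_compressed(fh, meta=json.dumps(meta), **arrays)


def load_checkpoint(
    path: str | Path,
) -> tuple[MultiTaskUNet3D, NormalizationStats | None]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise IOError(
                f"{path}: unsupported checkpoint version {meta.get('version')}"
            )
        state = {
            k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")
        }
    network = MultiTaskUNet3D(NetworkConfig.from_dict(meta["network"]))
    network.load_state_dict(state)
    stats = None
    if meta["stats"] is not None:
        s = meta["stats"]
        stats = NormalizationStats(
            mean=s["mean"], std=s["std"], n_voxels=s["n_voxels"]
        )
    return network, stats
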