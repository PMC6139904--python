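"""Containers and NIfTI-1 I/O for weighted-volume stacks and T1 maps.

Volumes travel as NIfTI-1 files; the per-volume preparation delays live in a
JSON sidecar mapping volume id to its saturation delay in ms, with the
equilibrium volume encoded as the string ``"inf"``::

    {"IMG1": 400.0, "IMG2": 800.0, "IMG3": "inf"}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import nibabel as nib
import numpy as np

from .fitting import T1Map

__all__ = [
    "WeightedVolumeSet",
    "save_weighted_volumes",
    "load_weighted_volumes",
    "write_delay_sidecar",
    "read_delay_sidecar",
    "save_t1_map",
    "load_t1_map",
]

VOLUME_IDS = ("IMG1", "IMG2", "IMG3")


@dataclass
class WeightedVolumeSet:
    """Co-registered T1-weighted volumes with their preparation delays.

    ``data`` is shaped ``(nx, ny, nz, n_volumes)``; ``delays_ms`` holds one
    delay per volume with ``numpy.inf`` marking the equilibrium volume.
    """

    data: np.ndarray
    delays_ms: Tuple[float, ...]
    volume_ids: Tuple[str, ...] = VOLUME_IDS
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, volume), got {self.data.ndim}D")
        if len(self.delays_ms) != self.data.shape[-1]:
            raise ValueError("one delay per volume required")
        if len(self.volume_ids) != self.data.shape[-1]:
            raise ValueError("one volume id per volume required")

    def volume(self, volume_id: str) -> np.ndarray:
        return self.data[..., self.volume_ids.index(volume_id)]


def _delay_to_json(d: float) -> Union[float, str]:
    return "inf" if np.isinf(d) else float(d)


def _delay_from_json(d: Union[float, str]) -> float:
    if isinstance(d, str):
        if d.lower() in ("inf", "infinity"):
            return np.inf
        return float(d)
    return float(d)


def write_delay_sidecar(path: Union[str, Path], wvs: WeightedVolumeSet) -> None:
    payload: Dict[str, object] = {
        vid: _delay_to_json(d) for vid, d in zip(wvs.volume_ids, wvs.delays_ms)
    }
    if wvs.meta:
        payload["_meta"] = wvs.meta
    Path(path).write_text(json.dumps(payload, indent=2))


def read_delay_sidecar(path: Union[str, Path]) -> Tuple[Dict[str, float], dict]:
    raw = json.loads(Path(path).read_text())
    meta = raw.pop("_meta", {})
    return {k: _delay_from_json(v) for k, v in raw.items()}, meta


def save_weighted_volumes(wvs: WeightedVolumeSet, outdir: Union[str, Path]) -> List[Path]:
    """Write one NIfTI per volume plus ``delays.json``; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, vid in enumerate(wvs.volume_ids):
        p = outdir / f"{vid.lower()}.nii.gz"
        nib.save(nib.Nifti1Image(wvs.data[..., i], wvs.affine), p)
        paths.append(p)
    write_delay_sidecar(outdir / "delays.json", wvs)
    paths.append(outdir / "delays.json")
    return paths


def load_weighted_volumes(
    volume_paths: Sequence[Union[str, Path]],
    sidecar_path: Union[str, Path],
    volume_ids: Sequence[str] = VOLUME_IDS,
) -> WeightedVolumeSet:
    delays, meta = read_delay_sidecar(sidecar_path)
    missing = [vid for vid in volume_ids if vid not in delays]
    if missing:
        raise ValueError(f"delay sidecar is missing volume ids: {missing}")
    imgs = [nib.load(str(p)) for p in volume_paths]
    data = np.stack([np.asarray(img.dataobj, dtype=float) for img in imgs], axis=-1)
    zooms = imgs[0].header.get_zooms()[:3]
    return WeightedVolumeSet(
        data=data,
        delays_ms=tuple(delays[vid] for vid in volume_ids),
        volume_ids=tuple(volume_ids),
        spacing_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(imgs[0].affine),
        meta=meta,
    )


def save_t1_map(t1map: T1Map, path: Union[str, Path], affine=None) -> Path:
    """Write the T1 channel as NIfTI (QC channels as extra files alongside)."""
    path = Path(path)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.nan_to_num(t1map.t1, nan=0.0), affine), path)
    stem = path.name.split(".")[0]
    for channel, arr in (("rss", t1map.rss), ("converged", t1map.converged.astype(np.uint8))):
        nib.save(
            nib.Nifti1Image(np.nan_to_num(np.asarray(arr, dtype=float), nan=0.0), affine),
            path.parent / f"{stem}_{channel}.nii.gz",
        )
    return path


def load_t1_map(path: Union[str, Path]) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)
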