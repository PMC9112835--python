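"""Readers/writers for pipeline artifacts.

Image stacks and maps are NIfTI-1 (third dimension = offset index for
stacks) with JSON sidecars carrying the ppm axis, S0 convention, seed
and config hash.  Tables are RFC 4180 CSV with '.' decimals; spectra
round-trip through CSV losslessly to 1e-12.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from glucest.zspec import FrequencyAxis, ZSpectrum, ZStack

_VOXEL_MM = 0.16  # 16 mm FOV / 100 px


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _affine() -> np.ndarray:
    return np.diag([_VOXEL_MM, _VOXEL_MM, 1.0, 1.0])


def write_nifti_stack(path: str | Path, stack: ZStack,
                      meta: dict | None = None) -> Path:
    """Write a Z-stack as NIfTI plus a JSON sidecar next to it."""
    path = Path(path)
    nib.save(nib.Nifti1Image(stack.data.astype(np.float64), _affine()), path)
    sidecar = {
        "offsets_ppm": stack.axis.offsets.tolist(),
        "field_mhz": stack.axis.field_mhz,
        "s0_convention": "per-pixel s0 array; normalized signal = data / s0",
        "s0": stack.s0.tolist(),
        "mask": stack.mask.astype(int).tolist(),
    }
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def read_nifti_stack(path: str | Path) -> tuple[ZStack, dict]:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    offsets = np.asarray(sidecar["offsets_ppm"], dtype=float)
    if data.ndim != 3 or data.shape[2] != offsets.size:
        raise ValueError(
            f"sidecar lists {offsets.size} offsets but stack has "
            f"{data.shape[2] if data.ndim == 3 else 'non-3D'} volumes")
    axis = FrequencyAxis(offsets, float(sidecar["field_mhz"]))
    stack = ZStack(axis, data, np.asarray(sidecar["mask"], dtype=bool),
                   np.asarray(sidecar["s0"], dtype=float))
    return stack, sidecar


def write_nifti_map(path: str | Path, values: np.ndarray,
                    meta: dict | None = None) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine()),
             path)
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, default=str))
    return path


def read_nifti_map(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    values = np.asarray(nib.load(path).dataobj, dtype=float)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return values, meta


def spectrum_to_csv(spec: ZSpectrum, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "offset_ppm": spec.axis.offsets,
        "signal": spec.signal,
        "s0": np.full(len(spec.axis), spec.s0),
    })
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def spectrum_from_csv(path: str | Path,
                      field_mhz: float | None = None) -> ZSpectrum:
    df = pd.read_csv(path)
    axis = FrequencyAxis(df["offset_ppm"].to_numpy(),
                         field_mhz if field_mhz is not None else 400.0)
    return ZSpectrum(axis, df["signal"].to_numpy(), float(df["s0"].iloc[0]))


def write_table_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, float_format="%.17g")
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
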