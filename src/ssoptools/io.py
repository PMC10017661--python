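"""File plumbing: TIFF frames with JSON sidecars, maps, manifests.

Conventions: raw frames are 16-bit little-endian TIFF plus a JSON
sidecar carrying wavelength, pattern frequency/phase, pixel pitch and
seed; float maps (optical properties, StO2) are 32-bit float TIFF; masks
are 8-bit TIFF; tables are CSV.  Every output directory gets a manifest
with SHA-256 checksums so runs can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .scene import PatternSpec, RawFrame

__all__ = [
    "write_frame", "read_frame", "write_float_map", "read_float_map",
    "write_mask", "write_sto2_png", "write_manifest", "sha256_file",
]


class DataError(ValueError):
    """Inconsistent or unreadable data inputs (exit code 3 at the CLI)."""


def write_frame(frame: RawFrame, path: str | Path) -> Path:
    """Write a frame as 16-bit TIFF + JSON sidecar; returns the path."""
    path = Path(path)
    img = np.clip(np.round(frame.image), 0, 2**16 - 1).astype("<u2")
    tifffile.imwrite(path, img)
    sidecar = {
        "wavelength_nm": frame.wavelength,
        "fx_per_mm": frame.pattern.fx,
        "phase_rad": frame.pattern.phase,
        "pixel_pitch_mm": frame.pattern.pixel_pitch,
        "dc_level": frame.pattern.dc_level,
        "modulation_depth": frame.pattern.modulation_depth,
        "seed": frame.noise_meta.get("seed"),
        "read_sd": frame.noise_meta.get("read_sd"),
        "shot": frame.noise_meta.get("shot"),
        "n_saturated": frame.noise_meta.get("n_saturated", 0),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_frame(path: str | Path) -> RawFrame:
    """Read a frame written by :func:`write_frame`."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise DataError(f"missing sidecar for {path}")
    meta = json.loads(sidecar_path.read_text())
    image = tifffile.imread(path).astype(float)
    pattern = PatternSpec(
        fx=meta["fx_per_mm"], phase=meta["phase_rad"],
        dc_level=meta["dc_level"],
        modulation_depth=meta["modulation_depth"],
        pixel_pitch=meta["pixel_pitch_mm"])
    return RawFrame(image=image, wavelength=meta["wavelength_nm"],
                    pattern=pattern,
                    noise_meta={"seed": meta.get("seed"),
                                "read_sd": meta.get("read_sd"),
                                "shot": meta.get("shot")})


def write_float_map(arr: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(arr, dtype="<f4"))
    return path


def read_float_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))
    return path


def write_sto2_png(sto2: np.ndarray, quality_mask: np.ndarray,
                   path: str | Path, cmap: str = "magma") -> Path:
    """8-bit colour-mapped PNG of an StO2 map for visual inspection.

    Display copy only: values are clamped to [0, 1] and masked pixels
    are blacked out; the quantitative map stays in the float TIFF.
    """
    import matplotlib

    path = Path(path)
    disp = np.clip(np.nan_to_num(sto2, nan=0.0), 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](disp)
    rgba[~np.asarray(quality_mask, dtype=bool)] = 0.0
    rgb8 = (rgba[..., :3] * 255).astype(np.uint8)
    # PIL ships with matplotlib's stack; use it for PNG encoding
    from PIL import Image

    Image.fromarray(rgb8).save(path)
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, extra: dict | None = None) -> Path:
    """Checksum every file in ``out_dir`` into manifest.json."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "files": {str(p.relative_to(out_dir)): sha256_file(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
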