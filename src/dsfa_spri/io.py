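"""File formats: spectrum CSV, frame-stack TIFF + JSON sidecar, manifests.

Spectra travel as two-column CSV (``wavelength_nm, value``, header required).
Frame stacks are multi-page 16-bit grayscale TIFF with a JSON sidecar holding
the mosaic geometry, timestamps, bit depth, and seed; gamma maps are 32-bit
float TIFF.  Run manifests record SHA-256 hashes of every product for
reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import FrameStack, MosaicGeometry
from .spectral import Spectrum, WavelengthGrid
from .tmm import SIO2_INDEX, TA2O5_INDEX, Layer, Stack

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_frame_stack",
    "read_frame_stack",
    "write_gamma_tiff",
    "read_stack_yaml",
    "write_manifest",
]

MATERIAL_INDICES = {"SiO2": SIO2_INDEX, "Ta2O5": TA2O5_INDEX}


def write_spectrum_csv(path, spectrum: Spectrum, value_name: str = "value") -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                  value_name: spectrum.samples}).to_csv(path, index=False)


def read_spectrum_csv(path) -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV onto a uniform grid."""
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
    lam = table.iloc[:, 0].to_numpy(dtype=float)
    vals = table.iloc[:, 1].to_numpy(dtype=float)
    steps = np.diff(lam)
    if len(lam) < 2 or np.any(steps <= 0):
        raise ValueError(f"{path}: wavelengths must be strictly increasing")
    step = float(steps.mean())
    if np.max(np.abs(steps - step)) > 1e-6 * step:
        raise ValueError(f"{path}: wavelength grid is not uniform")
    grid = WavelengthGrid(float(lam[0]), float(lam[-1]), step)
    return Spectrum(grid, vals)


def write_frame_stack(path, stack: FrameStack) -> Path:
    """Write a stack as multi-page uint16 TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.round(stack.data).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "geometry": {
            "n_tiles_x": stack.geometry.n_tiles_x,
            "n_tiles_y": stack.geometry.n_tiles_y,
            "tile_px": stack.geometry.tile_px,
            "parity": stack.geometry.parity,
        },
        "times_s": [float(t) for t in stack.times],
        "bit_depth": stack.bit_depth,
        "seed": stack.seed,
    }
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return sidecar_path


def read_frame_stack(path) -> FrameStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    geometry = MosaicGeometry(**meta["geometry"])
    return FrameStack(data, np.asarray(meta["times_s"], dtype=float), geometry,
                      bit_depth=meta.get("bit_depth", 12), seed=meta.get("seed"))


def write_gamma_tiff(path, values: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32),
                     photometric="minisblack")


def read_stack_yaml(path) -> Stack:
    """Read a thin-film stack definition from YAML.

    Layout::

        n_incident: 1.0
        n_substrate: 1.5
        layers:
          - {material: SiO2, thickness_nm: 101.0}
          - {index: 2.10, thickness_nm: 70.2}
    """
    spec = yaml.safe_load(Path(path).read_text())
    layers = []
    for entry in spec.get("layers", []):
        if "index" in entry:
            index = complex(entry["index"])
        elif "material" in entry:
            try:
                index = MATERIAL_INDICES[entry["material"]]
            except KeyError as exc:
                raise ValueError(f"unknown material {entry['material']!r}; "
                                 f"known: {sorted(MATERIAL_INDICES)}") from exc
        else:
            raise ValueError(f"layer entry needs 'index' or 'material': {entry}")
        layers.append(Layer(index, float(entry["thickness_nm"])))
    return Stack(tuple(layers),
                 n_incident=float(spec.get("n_incident", 1.0)),
                 n_substrate=float(spec.get("n_substrate", 1.5)))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(path, products, *, seed=None, config_hash=None) -> dict:
    """Write a JSON manifest listing products with their SHA-256 hashes."""
    from . import __version__

    path = Path(path)
    entries = {}
    for product in products:
        product = Path(product)
        entries[product.name] = _sha256(product)
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": config_hash,
        "products": entries,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
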