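"""Image and metadata I/O.

Images travel as 32-bit float TIFFs.  Physical metadata (nm per pixel,
filament endpoints, category, seeds) lives in a JSON sidecar next to each
image rather than in TIFF tags, whose dialects vary across writers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .grid import ImageGrid
from .simulate import ExamplePairImage, FilamentSpec

__all__ = ["read_image", "write_image", "write_example_set", "read_example_set"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_image(path, pixel_size_nm: float | None = None) -> ImageGrid:
    """Read a grayscale TIFF; pixel size from the sidecar or the argument.

    An explicit ``pixel_size_nm`` overrides the sidecar.  Multi-channel
    (RGB) images are rejected: select a channel upstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    data = tifffile.imread(path)
    data = np.squeeze(np.asarray(data))
    if data.ndim != 2:
        raise ValueError(
            f"{path} has shape {data.shape}; expected a single-channel 2-D "
            "image -- select one channel/page before loading"
        )
    if pixel_size_nm is None:
        sc = _sidecar(path)
        if sc.exists():
            meta = json.loads(sc.read_text())
            pixel_size_nm = meta.get("pixel_size_nm")
        if pixel_size_nm is None:
            raise ValueError(
                f"pixel size for {path} unknown: provide pixel_size_nm or a "
                f"sidecar file {sc.name}"
            )
    return ImageGrid(data.astype(np.float64), float(pixel_size_nm))


def write_image(path, img: ImageGrid, extra_meta: dict | None = None) -> None:
    """Write a 32-bit float TIFF plus its JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, img.data.astype(np.float32))
    meta = {"pixel_size_nm": img.pixel_size_nm}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def _spec_to_json(spec: FilamentSpec) -> dict:
    return {
        "endpoint_a_nm": list(spec.endpoint_a),
        "endpoint_b_nm": list(spec.endpoint_b),
        "intensity": spec.intensity,
    }


def write_example_set(directory, pairs: list[ExamplePairImage]) -> None:
    """Write LR/SR TIFF pairs plus one metadata JSON for the whole set."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, ex in enumerate(pairs):
        lr_name, sr_name = f"example_{i:05d}_lr.tif", f"example_{i:05d}_sr.tif"
        tifffile.imwrite(directory / lr_name, ex.lr.data.astype(np.float32))
        tifffile.imwrite(directory / sr_name, ex.sr.data.astype(np.float32))
        records.append(
            {
                "lr": lr_name,
                "sr": sr_name,
                "lr_pixel_size_nm": ex.lr.pixel_size_nm,
                "sr_pixel_size_nm": ex.sr.pixel_size_nm,
                "category": ex.category,
                "angles_deg": ex.angles_deg,
                "seed": ex.seed,
                "filaments": [_spec_to_json(s) for s in ex.specs],
            }
        )
    (directory / "examples.json").write_text(json.dumps(records, indent=1))


def read_example_set(directory) -> list[ExamplePairImage]:
    """Load a set written by :func:`write_example_set`."""
    directory = Path(directory)
    meta_path = directory / "examples.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no examples.json in {directory}")
    records = json.loads(meta_path.read_text())
    pairs = []
    for rec in records:
        lr = ImageGrid(
            tifffile.imread(directory / rec["lr"]).astype(np.float64),
            rec["lr_pixel_size_nm"],
        )
        sr = ImageGrid(
            tifffile.imread(directory / rec["sr"]).astype(np.float64),
            rec["sr_pixel_size_nm"],
        )
        specs = [
            FilamentSpec(
                tuple(s["endpoint_a_nm"]), tuple(s["endpoint_b_nm"]), s["intensity"]
            )
            for s in rec["filaments"]
        ]
        pairs.append(
            ExamplePairImage(
                lr=lr,
                sr=sr,
                category=rec["category"],
                specs=specs,
                angles_deg=rec.get("angles_deg", []),
                seed=rec.get("seed"),
            )
        )
    return pairs
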