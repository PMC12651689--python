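"""Dataset and run-artifact I/O.

Dataset layout on disk::

    <root>/
      manifest.csv            sample id, classes, target, prompt
      images/<id>.png         8-bit grayscale (quantized view)
      masks/<class>/<id>.png  0/255 binary masks
      arrays.npz              full-precision images + masks (what tests use)

PNG export quantizes intensities to 8 bits; the array archive preserves
full precision and is the round-trip source of truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import ImageSample, dataset_hash


def write_mask_png(path, mask: np.ndarray):
    """Binary mask -> 0/255 8-bit PNG."""
    arr = (np.asarray(getattr(mask, "values", mask)) > 0).astype(np.uint8) * 255
    iio.imwrite(Path(path), arr)


def read_mask_png(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    return (arr > 127).astype(np.uint8)


def write_dataset(samples: list[ImageSample], root) -> str:
    """Write PNGs + manifest + array archive; returns the dataset hash."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    arrays: dict[str, np.ndarray] = {}
    for i, s in enumerate(samples):
        sid = f"{i:05d}"
        iio.imwrite(root / "images" / f"{sid}.png",
                    np.clip(s.image * 255, 0, 255).astype(np.uint8))
        arrays[f"image_{sid}"] = s.image
        for cls, m in s.masks.items():
            d = root / "masks" / cls
            d.mkdir(parents=True, exist_ok=True)
            write_mask_png(d / f"{sid}.png", m)
            arrays[f"mask_{cls}_{sid}"] = m.astype(np.uint8)
        rows.append({"id": sid, "classes": "|".join(s.labels),
                     "target": s.target_class or "", "prompt": s.prompt or ""})
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    np.savez_compressed(root / "arrays.npz", **arrays)
    return dataset_hash(samples)


def read_dataset(root) -> list[ImageSample]:
    """Inverse of write_dataset, reading from the full-precision archive."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv", dtype=str,
                           keep_default_na=False)
    with np.load(root / "arrays.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    samples = []
    for _, row in manifest.iterrows():
        sid = row["id"]
        labels = [c for c in row["classes"].split("|") if c]
        masks = {c: arrays[f"mask_{c}_{sid}"] for c in labels}
        samples.append(ImageSample(
            image=arrays[f"image_{sid}"], masks=masks, labels=labels,
            prompt=row["prompt"] or None, target_class=row["target"] or None))
    return samples


@dataclass
class RunManifest:
    """Self-describing record written alongside every run directory."""

    command: str
    config: dict
    seed: int
    package_version: str
    dataset_hash: str
    outputs: list[str]

    def write(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def save_model(model, path):
    """Checkpoint: flat list of parameter/buffer arrays."""
    arrays = model.state_arrays()
    np.savez_compressed(Path(path),
                        **{f"arr_{i:04d}": a for i, a in enumerate(arrays)})


def load_model(model, path):
    with np.load(Path(path)) as npz:
        arrays = [npz[k] for k in sorted(npz.files)]
    model.load_state_arrays(arrays)
    return model
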