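"""On-disk formats: PNG images/masks, JSON box records, CSV manifests, and
single-file model checkpoints with a JSON manifest.

Images are stored as 16-bit grayscale PNG (the float images live in [0, 1];
16 bits keeps the round-trip loss below 1/65535).  Masks are 8-bit 0/255
PNG, one file per instance.  Everything round-trips byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import Box
from .nn import Module
from .synthetic import SegSample

__all__ = [
    "save_dataset", "load_dataset", "save_checkpoint", "load_checkpoint",
    "write_mask_png", "read_mask_png",
]

_IMG_SCALE = 65535.0


def write_image_png(path: Path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    Image.fromarray((arr * _IMG_SCALE).round().astype(np.uint16)).save(path)


def read_image_png(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.float64) / _IMG_SCALE


def write_mask_png(path: Path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0)
                    .astype(np.uint8)).save(path)


def read_mask_png(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValueError(f"{path} is not a 0/255 mask (values {vals[:10]})")
    return arr == 255


def save_dataset(samples: list[SegSample], out_dir: str | Path,
                 splits: dict[str, str] | None = None,
                 budget_flags: dict[str, dict[str, bool]] | None = None) -> None:
    """Write images, per-instance masks, a boxes JSON, and a manifest CSV.

    `splits` maps sample id -> split name; `budget_flags` maps sample id to
    {column: bool} budget-membership columns.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    box_records = []
    manifest_rows = []
    for s in sorted(samples, key=lambda x: x.sample_id):
        write_image_png(out / "images" / f"{s.sample_id}.png", s.image)
        for j, m in enumerate(s.instance_masks):
            write_mask_png(out / "masks" / f"{s.sample_id}_inst{j}.png", m)
        for j, b in enumerate(s.boxes):
            box_records.append(b.to_record(s.sample_id, j))
        row = {"sample_id": s.sample_id, "n_instances": len(s.instance_masks)}
        if splits is not None:
            row["split"] = splits.get(s.sample_id, "")
        if budget_flags is not None:
            row.update(budget_flags.get(s.sample_id, {}))
        manifest_rows.append(row)
    (out / "boxes.json").write_text(
        json.dumps(box_records, indent=2, sort_keys=True) + "\n")
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)


def load_dataset(in_dir: str | Path) -> list[SegSample]:
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    boxes_by_image: dict[str, list] = {}
    for rec in json.loads((src / "boxes.json").read_text()):
        boxes_by_image.setdefault(rec["image_id"], []).append(rec)
    samples = []
    for _, row in manifest.iterrows():
        sid = row["sample_id"]
        image = read_image_png(src / "images" / f"{sid}.png")
        masks = [read_mask_png(src / "masks" / f"{sid}_inst{j}.png")
                 for j in range(int(row["n_instances"]))]
        recs = sorted(boxes_by_image.get(sid, []), key=lambda r: r["instance_id"])
        boxes = [Box.from_record(r) for r in recs]
        samples.append(SegSample(sample_id=sid, image=image,
                                 instance_masks=masks, boxes=boxes))
    return samples


def save_checkpoint(path: str | Path, module: Module, manifest: dict) -> None:
    """Single-file .npz archive: parameter arrays plus a JSON manifest."""
    state = module.state_dict()
    meta = json.dumps(manifest, sort_keys=True)
    np.savez(path, __manifest__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{f"param/{k}": v for k, v in state.items()})


def load_checkpoint(path: str | Path, module: Module) -> dict:
    """Load parameters into `module`; returns the manifest dict."""
    with np.load(path) as archive:
        manifest = json.loads(bytes(archive["__manifest__"]).decode())
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    module.load_state_dict(state)
    return manifest
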