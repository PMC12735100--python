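"""Reading class-per-folder image datasets.

Folders named ``<class_id>_<species>`` (the generator's layout) keep the
reference class numbering; any other folder naming is accepted and ordered
lexicographically. Listing is deterministic, and the resulting class-index
assignment can be frozen to a labels JSON next to the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .training import ArrayDataset

__all__ = ["DatasetRecord", "load_image_folder", "load_arrays"]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class DatasetRecord:
    path: Path
    class_index: int
    class_name: str


def load_image_folder(
    root: str | Path,
    strict: bool = True,
    labels_json: str | Path | None = None,
) -> tuple[list[DatasetRecord], list[str]]:
    """Deterministically list a class-per-folder dataset.

    Returns (records, class_names) with class indices assigned by sorted
    folder name. Unreadable images raise in strict mode and are skipped
    (with a warning on stderr) otherwise. When ``labels_json`` is given the
    class-index mapping is written there.
    """
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subfolders found under {root}")
    class_names = [p.name for p in class_dirs]
    records: list[DatasetRecord] = []
    for ci, cdir in enumerate(class_dirs):
        files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        for f in files:
            try:
                with Image.open(f) as im:
                    im.verify()
            except Exception as exc:
                if strict:
                    raise ValueError(f"unreadable image {f}: {exc}") from exc
                import sys

                print(f"warning: skipping unreadable image {f}: {exc}", file=sys.stderr)
                continue
            records.append(DatasetRecord(f, ci, class_names[ci]))
    if not records:
        raise ValueError(f"no readable images found under {root}")
    if labels_json is not None:
        Path(labels_json).write_text(
            json.dumps({name: i for i, name in enumerate(class_names)}, indent=2)
        )
    return records, class_names


def load_arrays(
    root: str | Path,
    image_size: int | None = None,
    strict: bool = True,
) -> ArrayDataset:
    """Load a folder dataset into memory as float32 NCHW in [0, 1]."""
    records, class_names = load_image_folder(root, strict=strict)
    images, labels = [], []
    for rec in records:
        with Image.open(rec.path) as im:
            im = im.convert("RGB")
            if image_size is not None and im.size != (image_size, image_size):
                im = im.resize((image_size, image_size), Image.BILINEAR)
            arr = np.asarray(im, np.float32) / 255.0
        images.append(arr.transpose(2, 0, 1))
        labels.append(rec.class_index)
    return ArrayDataset(np.stack(images), np.asarray(labels, np.int64), class_names)
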