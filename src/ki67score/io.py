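"""Image and table I/O.

Images are held internally as 8-bit RGB arrays (H, W, 3), channel order
RGB regardless of the container — the classifier is color-driven, so a
silent channel swap would be fatal. Seed tables are CSVs with columns
image_id, row, col, class[, area].
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .seeds import NUCLEUS_CLASSES, SeedPoint

log = logging.getLogger(__name__)

SEED_COLUMNS = ["image_id", "row", "col", "class", "area"]


def read_image(path) -> np.ndarray:
    """Read a PNG or TIFF as 8-bit RGB.

    Grayscale input is promoted by channel replication and an alpha
    channel is dropped, each with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable/corrupt
        raise OSError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 2:
        log.warning("%s: grayscale image promoted to RGB by replication", path)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        log.warning("%s: alpha channel dropped", path)
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise OSError(f"{path}: unsupported image shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(image: np.ndarray, path) -> None:
    """Write an 8-bit RGB array as PNG or TIFF (by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_seeds(seeds, path, image_id: str = "") -> None:
    """Write seed points to CSV. ``seeds`` is a list of SeedPoint or of
    (image_id, SeedPoint) pairs."""
    rows = []
    for item in seeds:
        iid, s = item if isinstance(item, tuple) else (image_id, item)
        rows.append({"image_id": iid, "row": s.row, "col": s.col,
                     "class": s.klass, "area": s.component_area})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=SEED_COLUMNS).to_csv(path, index=False)


def read_seeds(path) -> list[tuple[str, SeedPoint]]:
    """Read a seed CSV back to (image_id, SeedPoint) pairs, validating
    the class vocabulary."""
    df = pd.read_csv(path, dtype={"image_id": str})
    missing = {"image_id", "row", "col", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing seed columns {sorted(missing)}")
    has_area = "area" in df.columns
    out = []
    for i in range(len(df)):
        klass = df["class"].iloc[i]
        if klass not in NUCLEUS_CLASSES:
            raise ValueError(f"{path} line {i + 2}: unknown class {klass!r}")
        iid = df["image_id"].iloc[i]
        out.append(
            (
                iid if isinstance(iid, str) else "",
                SeedPoint(
                    row=int(df["row"].iloc[i]),
                    col=int(df["col"].iloc[i]),
                    klass=klass,
                    component_area=int(df["area"].iloc[i]) if has_area else 0,
                ),
            )
        )
    return out
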