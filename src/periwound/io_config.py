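"""Readers/writers, the annotation table, category vocabulary, and run configuration.

The clinical wound-edge vocabulary has six raw categories.  Following expert
consensus, ``rolled_under`` and ``fibrotic`` are merged into a single
``rolled_fibrotic`` category for analysis, because the two are hard to tell
apart on two-dimensional photographs.
"""

from __future__ import annotations

import dataclasses
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

logger = logging.getLogger("periwound")

RAW_CATEGORIES: tuple[str, ...] = (
    "indistinct",
    "attached",
    "not_attached",
    "rolled_under",
    "hyperkeratotic",
    "fibrotic",
)
MERGED_CATEGORIES: tuple[str, ...] = (
    "indistinct",
    "attached",
    "not_attached",
    "rolled_fibrotic",
    "hyperkeratotic",
)
#: raw -> merged label mapping
MERGE_MAP: dict[str, str] = {
    "rolled_under": "rolled_fibrotic",
    "fibrotic": "rolled_fibrotic",
}
#: machine name -> display name
DISPLAY_NAMES: dict[str, str] = {
    "indistinct": "Indistinct",
    "attached": "Attached",
    "not_attached": "Not attached",
    "rolled_under": "Rolled-under",
    "hyperkeratotic": "Hyperkeratotic",
    "fibrotic": "Fibrotic",
    "rolled_fibrotic": "Rolled/fibrotic",
}


class VocabularyError(ValueError):
    """A label outside the declared category vocabulary."""


class DuplicateImageError(ValueError):
    """The same image_id appears more than once."""


class MissingLabelError(ValueError):
    """An (image, rater) cell has no label."""


class TableStateError(ValueError):
    """Operation invalid for the table's raw/merged state."""


@dataclasses.dataclass(frozen=True)
class AnnotationTable:
    """Image x rater categorical labels.

    ``data`` is indexed by ``image_id`` with one column per rater; every cell
    holds a category string from the raw (6) or merged (5) vocabulary
    according to ``merged``.
    """

    data: pd.DataFrame
    merged: bool = False

    def __post_init__(self) -> None:
        vocab = set(MERGED_CATEGORIES if self.merged else RAW_CATEGORIES)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DuplicateImageError(f"duplicate image_id {dup!r}")
        for rater in self.data.columns:
            col = self.data[rater]
            if col.isna().any():
                row = col.index[col.isna()][0]
                raise MissingLabelError(
                    f"missing label for image {row!r}, rater {rater!r}"
                )
            bad = ~col.isin(vocab)
            if bad.any():
                row = col.index[bad][0]
                raise VocabularyError(
                    f"unknown category {col[row]!r} for image {row!r}, "
                    f"rater {rater!r} (expected one of {sorted(vocab)})"
                )

    @property
    def raters(self) -> list[str]:
        return list(self.data.columns)

    @property
    def image_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return MERGED_CATEGORIES if self.merged else RAW_CATEGORIES

    def labels(self, rater_id: str) -> np.ndarray:
        if rater_id not in self.data.columns:
            raise KeyError(f"unknown rater {rater_id!r}")
        return self.data[rater_id].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


def read_annotations(path: str | Path, merged: bool = False) -> AnnotationTable:
    """Read a ``image_id,<rater>,...`` CSV into a validated table."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if "image_id" not in df.columns:
        raise ValueError(f"{path}: first column must be named 'image_id'")
    df = df.set_index("image_id")
    return AnnotationTable(df, merged=merged)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="image_id")


def merge_categories(table: AnnotationTable) -> AnnotationTable:
    """Merge ``rolled_under`` and ``fibrotic`` into ``rolled_fibrotic``."""
    if table.merged:
        raise TableStateError("table is already in the merged 5-category state")
    data = table.data.replace(MERGE_MAP)
    return AnnotationTable(data, merged=True)


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def category_counts(
    table: AnnotationTable, rater_id: str
) -> dict[str, tuple[int, float]]:
    """Per-category ``(count, percentage of all rows)`` for one rater.

    Percentages are rounded half-away-from-zero to one decimal, matching the
    convention used for published annotation-distribution tables.
    """
    labels = table.labels(rater_id)
    total = len(labels)
    out: dict[str, tuple[int, float]] = {}
    for cat in table.vocabulary:
        n = int(np.sum(labels == cat))
        out[cat] = (n, _round_half_up(100.0 * n / total))
    return out


# ---------------------------------------------------------------------------
# Raster I/O


def read_image(path: str | Path) -> np.ndarray:
    """8-bit RGB image as a (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Binary mask: any nonzero pixel is foreground (wound)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)).save(
        path
    )


def read_depth(path: str | Path) -> np.ndarray:
    """Single-channel float32 depth raster from TIFF."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: depth raster must be single-channel 2-D")
    return np.asarray(arr, dtype=np.float32)


def write_depth(depth: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(depth, dtype=np.float32))


# ---------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Band half-widths are in pixels on either side of the wound contour:
    ``d_out`` outward into peri-wound skin, ``d_in`` inward into the bed.
    """

    d_in: int = 20
    d_out: int = 20
    contour_points: int = 360
    templates: tuple[str, ...] = ("flat", "linear", "abrupt", "smooth")
    w_abrupt: float = 3.0
    detrend_region: str = "band"  # "band" | "full"
    reduction: str = "pca"  # "pca" | "umap"
    reduction_dims: int = 2
    n_clusters: int = 5
    classifier: str = "hist_gradient_boosting"  # or "random_forest"
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_in < 1 or self.d_out < 1:
            raise ValueError("band half-widths d_in, d_out must be >= 1 px")
        if self.contour_points < 16:
            raise ValueError("contour sample count must be >= 16")
        if self.n_clusters < 2:
            raise ValueError("cluster count must be >= 2")
        if self.detrend_region not in ("band", "full"):
            raise ValueError("detrend_region must be 'band' or 'full'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "templates" in raw:
            raw["templates"] = tuple(raw["templates"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["templates"] = list(d["templates"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
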