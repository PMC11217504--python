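"""Image + metadata dataset handling and preprocessing.

A dataset is a directory of RGB specimen photographs plus a metadata CSV with
one row per image (``image_id, species, sex, surface, path``).  Photographs
are assumed pre-cropped to the specimen plus a 1-pixel border; preprocessing
here is limited to fixed-aspect rescaling to a uniform height and horizontal
flipping (used to orient ventral views like dorsal ones).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, InvalidArgumentError, MissingFilesError

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
SURFACES = ("dorsal", "ventral")
METADATA_COLUMNS = ("image_id", "species", "sex", "surface", "path")


@dataclass(frozen=True)
class ImageRecord:
    """One specimen photograph with its biological labels.

    ``pixels`` is an H x W x 3 uint8 array, row-major with the origin at the
    top-left; "height" is the first axis.
    """

    image_id: str
    pixels: np.ndarray
    species: str
    sex: str
    surface: str

    def __post_init__(self):
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidArgumentError(
                f"{self.image_id}: pixels must be H x W x 3, got {px.shape}"
            )
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise InvalidArgumentError(
                f"{self.image_id}: image smaller than 3 px plus border"
            )
        if self.sex not in SEXES:
            raise FormatError(f"{self.image_id}: unknown sex {self.sex!r}")
        if self.surface not in SURFACES:
            raise FormatError(f"{self.image_id}: unknown surface {self.surface!r}")


@dataclass
class DatasetManifest:
    """All records of a dataset plus per-subset bookkeeping."""

    records: list[ImageRecord]
    species_list: list[str] = field(init=False)
    counts: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.species_list = sorted({r.species for r in self.records})
        rows = [(r.species, r.sex, r.surface) for r in self.records]
        if rows:
            df = pd.DataFrame(rows, columns=["species", "sex", "surface"])
            self.counts = (
                df.value_counts().rename("count").reset_index()
                .sort_values(["species", "sex", "surface"], ignore_index=True)
            )
        else:
            self.counts = pd.DataFrame(
                columns=["species", "sex", "surface", "count"]
            )

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, species=None, sex=None, surface=None) -> list[ImageRecord]:
        """Records matching every given label (None or 'both' = no filter)."""
        out = []
        for r in self.records:
            if species is not None and r.species != species:
                continue
            if sex not in (None, "both") and r.sex != sex:
                continue
            if surface not in (None, "both") and r.surface != surface:
                continue
            out.append(r)
        return out


def load_manifest(metadata_path, image_dir) -> DatasetManifest:
    """Load a dataset from its metadata CSV and image directory.

    Raises :class:`FormatError` on missing columns or unknown sex/surface
    values, and :class:`MissingFilesError` naming every image_id whose file
    is absent.
    """
    meta = pd.read_csv(metadata_path, dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata missing columns: {missing_cols}")

    missing_files = []
    paths = []
    for _, row in meta.iterrows():
        path = os.path.join(image_dir, row["path"])
        if not os.path.exists(path):
            missing_files.append(row["image_id"])
        paths.append(path)
    if missing_files:
        raise MissingFilesError(missing_files)

    records = []
    for (_, row), path in zip(meta.iterrows(), paths):
        with Image.open(path) as im:
            pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
        records.append(
            ImageRecord(
                image_id=row["image_id"],
                pixels=pixels,
                species=row["species"],
                sex=row["sex"],
                surface=row["surface"],
            )
        )
    return DatasetManifest(records)


def save_dataset(records, out_dir, metadata_name="metadata.csv") -> str:
    """Write records as PNGs plus a metadata CSV; returns the CSV path."""
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    rows = []
    for r in records:
        rel = os.path.join("images", f"{r.image_id}.png")
        Image.fromarray(r.pixels).save(os.path.join(out_dir, rel))
        rows.append((r.image_id, r.species, r.sex, r.surface, rel))
    meta_path = os.path.join(out_dir, metadata_name)
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(meta_path, index=False)
    return meta_path


def _round_half_even(x: float) -> int:
    # numpy rounds half to even, unlike builtin round on floats near .5
    return int(np.rint(x))


def rescale_image(rec: ImageRecord, target_height: int) -> ImageRecord:
    """Rescale to ``target_height`` preserving aspect ratio (bilinear).

    Width = round-half-to-even(W * target_height / H), minimum 1.
    """
    if target_height < 2:
        raise InvalidArgumentError("target_height must be >= 2")
    h, w = rec.pixels.shape[:2]
    if h == 0 or w == 0:
        raise InvalidArgumentError("degenerate image with zero extent")
    if h == target_height:
        return rec
    new_w = max(1, _round_half_even(w * target_height / h))
    im = Image.fromarray(rec.pixels).resize(
        (new_w, target_height), Image.Resampling.BILINEAR
    )
    return replace(rec, pixels=np.asarray(im, dtype=np.uint8))


def resize_to(rec: ImageRecord, height: int, width: int) -> ImageRecord:
    """Bilinear resize to exact dimensions (used by pairwise pixel comparison)."""
    if height < 1 or width < 1:
        raise InvalidArgumentError("target dimensions must be positive")
    if rec.pixels.shape[:2] == (height, width):
        return rec
    im = Image.fromarray(rec.pixels).resize(
        (width, height), Image.Resampling.BILINEAR
    )
    return replace(rec, pixels=np.asarray(im, dtype=np.uint8))


def flip_horizontal(rec: ImageRecord) -> ImageRecord:
    """Reverse column order per row and channel."""
    return replace(rec, pixels=np.ascontiguousarray(rec.pixels[:, ::-1, :]))
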