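"""Reading and writing per-cell images, dataset manifests and population files.

The on-disk layout mirrors what imaging flow cytometers export: one 16-bit
single-page grayscale TIF per cell and channel (brightfield + fluorescence),
with the object number encoded in the file name. Sorted cell subsets travel
back to the acquisition software as "population" files — here an open
plain-text dialect (`#population <name>` header, one object number per line)
rather than the vendor's binary format.

Coordinates are 0-based, row-major, origin top-left. Pixel values are stored
and compared as integers; nothing in this module rescales intensities.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

IMAGE_SIZE = 32
N_CHANNELS = 2
CHANNEL_ROLES = {0: "brightfield", 1: "fluorescence"}
LABELS = ("apoptotic", "ev", "unlabeled")

#: default IDEAS-style export naming: ``<object_id>_Ch<k>.ome.tif``
DEFAULT_NAME_PATTERN = r"(?P<object_id>\d+)_Ch(?P<channel>\d+)\.ome\.tif$"


class PopulationFormatError(ValueError):
    """Raised for malformed or invariant-violating population files."""


@dataclass
class CellImage:
    """One cell: a 2-channel, 32x32, 16-bit pixel raster.

    Channel 0 is brightfield, channel 1 fluorescence.
    """

    object_id: int
    pixels: np.ndarray  # (2, 32, 32) uint16
    channel_roles: Mapping[int, str] = field(
        default_factory=lambda: dict(CHANNEL_ROLES))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.object_id < 0:
            raise ValueError(f"object_id must be non-negative, got {self.object_id}")
        if self.pixels.shape != (N_CHANNELS, IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(
                f"expected pixels of shape (2, 32, 32), got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 65535:
            raise ValueError("pixel intensities must lie in the 16-bit range")
        if set(self.channel_roles) != {0, 1}:
            raise ValueError("channel_roles must map exactly channels 0 and 1")
        self.pixels = self.pixels.astype(np.uint16)

    @property
    def brightfield(self) -> np.ndarray:
        return self.pixels[0]

    @property
    def fluorescence(self) -> np.ndarray:
        return self.pixels[1]


@dataclass
class CellRecord:
    object_id: int
    channel_paths: tuple[str, str]  # (brightfield path, fluorescence path)
    label: str = "unlabeled"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class DatasetManifest:
    """Ordered collection of cell records; object ids are unique."""

    records: list[CellRecord]
    name: str = "dataset"
    channel_convention: str = DEFAULT_NAME_PATTERN

    def __post_init__(self) -> None:
        ids = [r.object_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate object_id in manifest")

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def object_ids(self) -> list[int]:
        return [r.object_id for r in self.records]

    def to_csv(self, path) -> Path:
        path = Path(path)
        df = pd.DataFrame(
            {
                "object_id": [r.object_id for r in self.records],
                "ch0_path": [r.channel_paths[0] for r in self.records],
                "ch1_path": [r.channel_paths[1] for r in self.records],
                "label": [r.label for r in self.records],
                "provenance": [r.provenance for r in self.records],
            }
        )
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "DatasetManifest":
        path = Path(path)
        df = pd.read_csv(path, dtype={"provenance": str}, keep_default_na=False)
        records = [
            CellRecord(int(row.object_id), (row.ch0_path, row.ch1_path),
                       row.label or "unlabeled", row.provenance)
            for row in df.itertuples()
        ]
        return cls(records, name=name or path.stem)

    def load_images(self) -> list[CellImage]:
        """Read every record's TIF pair into memory (strict 32x32)."""
        return [
            read_cell_image(r.channel_paths, object_id=r.object_id)
            for r in self.records
        ]

    def load_pixel_array(self) -> np.ndarray:
        """All images stacked as an (n, 2, 32, 32) uint16 array."""
        return np.stack([img.pixels for img in self.load_images()])


@dataclass
class PopulationFile:
    name: str
    object_ids: list[int]

    def __post_init__(self) -> None:
        if len(self.object_ids) != len(set(self.object_ids)):
            raise PopulationFormatError("duplicate object ids in population")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def _fit_to_frame(arr: np.ndarray, crop_policy: str) -> np.ndarray:
    h, w = arr.shape
    if (h, w) == (IMAGE_SIZE, IMAGE_SIZE):
        return arr
    if crop_policy == "strict":
        raise ValueError(
            f"strict crop policy: expected 32x32 image, got {h}x{w}")
    if crop_policy not in ("center_crop", "center_pad"):
        raise ValueError(f"unknown crop policy {crop_policy!r}")
    if crop_policy == "center_crop" and (h < IMAGE_SIZE or w < IMAGE_SIZE):
        raise ValueError(
            f"center_crop cannot enlarge a {h}x{w} image; use center_pad")
    # crop any oversized axis to 32 (symmetric, extra pixel trimmed at the end)
    if h > IMAGE_SIZE:
        top = (h - IMAGE_SIZE) // 2
        arr = arr[top:top + IMAGE_SIZE, :]
    if w > IMAGE_SIZE:
        left = (w - IMAGE_SIZE) // 2
        arr = arr[:, left:left + IMAGE_SIZE]
    # pad any undersized axis with zeros (center_pad only reaches here)
    h, w = arr.shape
    if h < IMAGE_SIZE or w < IMAGE_SIZE:
        pt = (IMAGE_SIZE - h) // 2
        pl = (IMAGE_SIZE - w) // 2
        arr = np.pad(arr, ((pt, IMAGE_SIZE - h - pt), (pl, IMAGE_SIZE - w - pl)))
    return arr


def read_cell_image(channel_paths: Sequence, crop_policy: str = "strict",
                    object_id: int | None = None) -> CellImage:
    """Read one cell from per-channel single-page 16-bit TIFs.

    ``crop_policy`` handles non-32x32 exports: ``strict`` rejects them,
    ``center_crop`` takes the central 32x32 window, ``center_pad``
    additionally zero-pads undersized axes. Pixel values are never rescaled.
    """
    if len(channel_paths) != N_CHANNELS:
        raise ValueError(
            f"expected exactly {N_CHANNELS} channel paths, got {len(channel_paths)}")
    planes = []
    for p in channel_paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(str(p))
        arr = tifffile.imread(p)
        if arr.ndim != 2:
            raise ValueError(f"{p}: expected a single-page grayscale TIF, "
                             f"got shape {arr.shape}")
        planes.append(_fit_to_frame(arr, crop_policy))
    if object_id is None:
        m = re.search(r"(\d+)", Path(channel_paths[0]).stem)
        object_id = int(m.group(1)) if m else 0
    return CellImage(object_id, np.stack(planes))


def write_cell_image(image: CellImage, directory,
                     name_format: str = "{object_id}_Ch{channel}.ome.tif",
                     ) -> tuple[Path, Path]:
    """Write one TIF per channel; returns the (brightfield, fluorescence) paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch in range(N_CHANNELS):
        path = directory / name_format.format(object_id=image.object_id, channel=ch)
        tifffile.imwrite(path, image.pixels[ch].astype(np.uint16))
        paths.append(path)
    return tuple(paths)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def assemble_dataset(root, name_pattern: str = DEFAULT_NAME_PATTERN,
                     label_table: Mapping[int, str] | None = None,
                     name: str = "dataset") -> DatasetManifest:
    """Scan a directory of per-cell per-channel TIFs into a manifest.

    ``name_pattern`` is a regex with named groups ``object_id`` and
    ``channel``; channel 0 is taken as brightfield, channel 1 as
    fluorescence. Cells missing either channel are logged and skipped.
    Records are sorted by object id, so assembly is deterministic.
    """
    root = Path(root)
    rx = re.compile(name_pattern)
    found: dict[int, dict[int, Path]] = {}
    for path in sorted(root.iterdir()):
        m = rx.search(path.name)
        if not m:
            continue
        oid, ch = int(m.group("object_id")), int(m.group("channel"))
        slot = found.setdefault(oid, {})
        if ch in slot and slot[ch] != path:
            raise ValueError(
                f"object {oid}: conflicting files for channel {ch}: "
                f"{slot[ch].name} vs {path.name}")
        slot[ch] = path
    if not found:
        raise ValueError(f"no cell images matching {name_pattern!r} under {root}")
    label_table = dict(label_table or {})
    records = []
    for oid in sorted(found):
        chans = found[oid]
        if 0 not in chans or 1 not in chans:
            missing = {0, 1} - set(chans)
            logger.warning("object %d skipped: missing channel(s) %s",
                           oid, sorted(missing))
            continue
        records.append(CellRecord(
            oid, (str(chans[0]), str(chans[1])),
            label=label_table.get(oid, "unlabeled")))
    return DatasetManifest(records, name=name, channel_convention=name_pattern)


# ---------------------------------------------------------------------------
# population files
# ---------------------------------------------------------------------------

def write_population(population: PopulationFile, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#population {population.name}\n")
        for oid in population.object_ids:
            fh.write(f"{oid}\n")
    return path


def read_population(path) -> PopulationFile:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#population "):
            raise PopulationFormatError(
                f"{path}: missing '#population <name>' header")
        name = header[len("#population "):]
        ids: list[int] = []
        seen: set[int] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                oid = int(line)
            except ValueError:
                raise PopulationFormatError(
                    f"{path}:{lineno}: not an object id: {line!r}") from None
            if oid in seen:
                raise PopulationFormatError(
                    f"{path}:{lineno}: duplicate object id {oid}")
            seen.add(oid)
            ids.append(oid)
    return PopulationFile(name, ids)


def ground_truth_to_provenance(info: Mapping) -> str:
    """Serialise generator ground truth into the manifest's provenance column."""
    return json.dumps(info, sort_keys=True)


def provenance_to_ground_truth(text: str) -> dict:
    return json.loads(text) if text else {}
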