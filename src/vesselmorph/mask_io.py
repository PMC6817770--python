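"""Calibrated 3-label vessel masks: in-memory model and file round-trip.

A segmented cross-section is a small integer raster over three labels
(0 = background, 1 = lumen, 2 = wall) plus a JSON sidecar carrying the
pixel calibration and per-vessel flags.  Rasters are stored losslessly
(PNG or TIFF, single channel); the sidecar's ``palette`` entry maps the
raw pixel values found in the file to the three semantic roles, so masks
exported from other tools with arbitrary two-colour schemes can be
ingested without rewriting the raster.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import MaskFormatError, MaskValidationError

BACKGROUND, LUMEN, WALL = 0, 1, 2

_DEFAULT_PALETTE = {"background": 0, "lumen": 1, "wall": 2}

# 4-connectivity for the lumen component check
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PixelCalibration:
    """Physical size of one pixel edge, in microns."""

    microns_per_pixel: float

    def __post_init__(self) -> None:
        m = self.microns_per_pixel
        if not (np.isfinite(m) and m > 0):
            raise MaskFormatError(
                f"microns_per_pixel must be finite and > 0, got {m!r}"
            )

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in square microns."""
        return self.microns_per_pixel ** 2


@dataclass
class SegmentedVessel:
    """One vessel cross-section as a calibrated 3-label raster.

    ``labels`` is a 2-D uint8 array over {0, 1, 2}.  ``transverse_plane``
    records whether the section was cut perpendicular to the vessel axis
    (obliquely cut vessels are excluded downstream, not corrected);
    ``pathology_flag`` marks vessels whose surroundings showed
    wall-altering pathology and must likewise be excluded.
    """

    vessel_id: str
    labels: np.ndarray
    calibration: PixelCalibration
    transverse_plane: bool = True
    pathology_flag: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise MaskFormatError(
                f"label grid must be 2-D, got shape {self.labels.shape}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentedVessel):
            return NotImplemented
        return (
            self.vessel_id == other.vessel_id
            and self.calibration == other.calibration
            and self.transverse_plane == other.transverse_plane
            and self.pathology_flag == other.pathology_flag
            and self.labels.shape == other.labels.shape
            and bool(np.array_equal(self.labels, other.labels))
        )

    def label_counts(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=3)
        return {BACKGROUND: int(counts[0]), LUMEN: int(counts[1]), WALL: int(counts[2])}


def validate_vessel(v: SegmentedVessel) -> None:
    """Check the semantic invariants of a vessel mask.

    Raises :class:`MaskValidationError` with an explicit reason if the
    mask has extra label values, no lumen or wall pixels, a fragmented
    (non-4-connected) lumen, or a lumen that touches the image border.
    """
    bad = np.setdiff1d(np.unique(v.labels), [BACKGROUND, LUMEN, WALL])
    if bad.size:
        raise MaskFormatError(
            f"vessel {v.vessel_id!r}: unknown label value(s) {bad.tolist()}"
        )
    counts = v.label_counts()
    if counts[LUMEN] == 0:
        raise MaskValidationError(f"vessel {v.vessel_id!r}: no lumen pixels")
    if counts[WALL] == 0:
        raise MaskValidationError(f"vessel {v.vessel_id!r}: no wall pixels")
    lumen = v.labels == LUMEN
    _, n_components = ndimage.label(lumen, structure=_STRUCT4)
    if n_components != 1:
        raise MaskValidationError(
            f"vessel {v.vessel_id!r}: lumen is fragmented into "
            f"{n_components} 4-connected components"
        )
    border = np.concatenate([lumen[0, :], lumen[-1, :], lumen[:, 0], lumen[:, -1]])
    if border.any():
        raise MaskValidationError(
            f"vessel {v.vessel_id!r}: lumen touches the image border "
            "(vessel not fully contained in the field of view)"
        )


def _load_raster(raster_path: str | os.PathLike) -> np.ndarray:
    path = str(raster_path)
    try:
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            arr = tifffile.imread(path)
        else:
            with Image.open(path) as img:
                arr = np.asarray(img)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt file, wrong codec...
        raise MaskFormatError(f"cannot decode raster {path!r}: {exc}") from exc
    if arr.ndim != 2:
        raise MaskFormatError(
            f"raster {path!r} must be single-channel 2-D, got shape {arr.shape}"
        )
    return arr


def read_mask(
    raster_path: str | os.PathLike,
    sidecar_path: str | os.PathLike,
    *,
    validate: bool = True,
) -> SegmentedVessel:
    """Read a raster + JSON sidecar pair into a :class:`SegmentedVessel`.

    The sidecar must provide ``microns_per_pixel``; ``palette`` maps raw
    pixel values to the roles background/lumen/wall (defaults to the
    canonical 0/1/2).  Any raster value outside the declared palette is
    a format error naming the offending value.
    """
    try:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise MaskFormatError(f"sidecar {sidecar_path!r} is not valid JSON: {exc}") from exc
    if "microns_per_pixel" not in meta:
        raise MaskFormatError(
            f"sidecar {sidecar_path!r} is missing the required "
            "'microns_per_pixel' calibration"
        )
    calibration = PixelCalibration(float(meta["microns_per_pixel"]))
    palette = meta.get("palette", _DEFAULT_PALETTE)
    for role in ("background", "lumen", "wall"):
        if role not in palette:
            raise MaskFormatError(
                f"sidecar {sidecar_path!r}: palette is missing the {role!r} entry"
            )

    raw = _load_raster(raster_path)
    declared = {int(palette["background"]): BACKGROUND,
                int(palette["lumen"]): LUMEN,
                int(palette["wall"]): WALL}
    present = np.unique(raw)
    unknown = [int(p) for p in present if int(p) not in declared]
    if unknown:
        raise MaskFormatError(
            f"raster {str(raster_path)!r} contains pixel value(s) {unknown} "
            f"outside the declared palette {sorted(declared)}"
        )
    labels = np.zeros(raw.shape, dtype=np.uint8)
    for raw_value, label in declared.items():
        labels[raw == raw_value] = label

    vessel = SegmentedVessel(
        vessel_id=str(meta.get("vessel_id", os.path.splitext(os.path.basename(str(raster_path)))[0])),
        labels=labels,
        calibration=calibration,
        transverse_plane=bool(meta.get("transverse_plane", True)),
        pathology_flag=bool(meta.get("pathology_flag", False)),
    )
    if validate:
        validate_vessel(vessel)
    return vessel


def write_mask(
    v: SegmentedVessel,
    raster_path: str | os.PathLike,
    sidecar_path: str | os.PathLike,
) -> None:
    """Write a vessel as a lossless raster plus JSON sidecar.

    The output format follows the raster extension: PNG (default) or
    TIFF.  Lossy formats are refused — label images do not survive
    JPEG quantisation.
    """
    path = str(raster_path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".jpg", ".jpeg"):
        raise MaskFormatError(
            f"refusing lossy format for {path!r}: JPEG corrupts label values"
        )
    arr = v.labels.astype(np.uint8)
    try:
        if ext in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, arr)
        else:
            Image.fromarray(arr, mode="L").save(path, format="PNG")
    except OSError as exc:
        raise MaskFormatError(f"cannot write raster {path!r}: {exc}") from exc

    meta = {
        "vessel_id": v.vessel_id,
        "microns_per_pixel": v.calibration.microns_per_pixel,
        "palette": dict(_DEFAULT_PALETTE),
        "transverse_plane": v.transverse_plane,
        "pathology_flag": v.pathology_flag,
    }
    try:
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise MaskFormatError(f"cannot write sidecar {str(sidecar_path)!r}: {exc}") from exc


def read_manifest(manifest_path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a batch manifest CSV with columns ``raster,sidecar``.

    Relative paths are resolved against the manifest's own directory.
    """
    import csv

    base = os.path.dirname(os.path.abspath(str(manifest_path)))
    pairs: list[tuple[str, str]] = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"raster", "sidecar"} <= set(reader.fieldnames):
            raise MaskFormatError(
                f"manifest {str(manifest_path)!r} must have 'raster' and 'sidecar' columns"
            )
        for row in reader:
            raster = row["raster"]
            sidecar = row["sidecar"]
            if not os.path.isabs(raster):
                raster = os.path.join(base, raster)
            if not os.path.isabs(sidecar):
                sidecar = os.path.join(base, sidecar)
            pairs.append((raster, sidecar))
    return pairs
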