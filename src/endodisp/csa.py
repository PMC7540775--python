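"""Anatomical cross-sectional area (ACSA) from segmented label volumes.

A labeled voxel volume (e.g. a DiceCT segmentation of the mandibular
adductor musculature) with anisotropic spacing yields per-slice areas by
voxel counting: area = labeled-pixel count x the two in-plane spacings.
The measurement protocol mirrors manual tracing practice — several
measurements cycled over a handful of consecutive slices, reporting their
mean and SD — but voxel counting is deterministic, so repeated
measurements of one slice are identical and the SD reflects
between-slice variation only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LabelVolume",
    "CsaMeasurement",
    "slice_area",
    "mean_csa",
    "write_label_stack",
    "read_label_stack",
]

_AXIS_TO_DIM = {"z": 0, "y": 1, "x": 2}


@dataclass
class LabelVolume:
    """3D integer label array with anisotropic voxel spacing.

    ``labels`` is indexed (z, y, x); ``spacing`` is (dx, dy, dz) in mm per
    voxel — dz commonly differs from dx = dy in downsampled CT stacks.
    Label 0 is background.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (z, y, x) array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_volume_mm3(self, label: int) -> float:
        """Voxel count x voxel volume for one label (mm^3)."""
        dx, dy, dz = self.spacing
        return float(np.count_nonzero(self.labels == label)) * dx * dy * dz


@dataclass
class CsaMeasurement:
    region_name: str
    slice_indices: list[int]
    per_slice_areas: list[float]
    mean_area: float
    sd_area: float
    n_measurements: int
    axis: str = "z"


def _in_plane_pixel_area(volume: LabelVolume, axis: str) -> float:
    dx, dy, dz = volume.spacing
    if axis == "z":
        return dx * dy
    if axis == "y":
        return dx * dz
    if axis == "x":
        return dy * dz
    raise ValueError(f"axis must be one of x, y, z; got {axis!r}")


def slice_area(volume: LabelVolume, label: int, axis: str, index: int) -> float:
    """Area (mm^2) of one label in one slice perpendicular to ``axis``.

    Counts voxels carrying the label in the slice and multiplies by the
    product of the two in-plane spacings for that axis.  An index outside
    the volume raises; a label absent from the whole volume yields 0 with
    a warning.
    """
    pixel_area = _in_plane_pixel_area(volume, axis)
    dim = _AXIS_TO_DIM[axis]
    n = volume.labels.shape[dim]
    if not 0 <= index < n:
        raise IndexError(f"slice index {index} out of bounds for axis {axis} (n={n})")
    sl = np.take(volume.labels, index, axis=dim)
    count = int(np.count_nonzero(sl == label))
    if count == 0 and not (volume.labels == label).any():
        import warnings

        warnings.warn(f"label {label} not present in volume", stacklevel=2)
    return count * pixel_area


def mean_csa(
    volume: LabelVolume,
    label: int,
    axis: str = "z",
    region: Sequence[int] = (),
    repeats: int = 10,
    region_name: str = "",
) -> CsaMeasurement:
    """Mean ACSA over a contiguous run of slices with repeated measurement.

    Measures slices cyclically from ``region`` until ``repeats``
    measurements accumulate (10 measurements over 5 slices = each slice
    twice), then reports the mean and sample SD over the measurement list.
    """
    region = list(region)
    if not region:
        raise ValueError("region must contain at least one slice index")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    per_slice = {i: slice_area(volume, label, axis, i) for i in region}
    picks = [region[i % len(region)] for i in range(repeats)]
    measurements = np.array([per_slice[i] for i in picks])
    sd = float(measurements.std(ddof=1)) if repeats > 1 else 0.0
    return CsaMeasurement(
        region_name=region_name,
        slice_indices=picks,
        per_slice_areas=measurements.tolist(),
        mean_area=float(measurements.mean()),
        sd_area=sd,
        n_measurements=repeats,
        axis=axis,
    )


def write_label_stack(volume: LabelVolume, directory) -> Path:
    """Write per-slice images (PNG) plus a JSON spacing sidecar.

    Slice ``k`` (z index) becomes ``slice_0000.png`` etc.; the sidecar
    ``spacing.json`` records spacing in mm and any label names.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if volume.labels.max(initial=0) > 65535 or volume.labels.min(initial=0) < 0:
        raise ValueError("labels must fit in uint16 for image export")
    for k in range(volume.labels.shape[0]):
        iio.imwrite(
            directory / f"slice_{k:04d}.png",
            volume.labels[k].astype(np.uint16),
        )
    sidecar = {
        "spacing_mm": list(volume.spacing),
        "label_names": {str(k): v for k, v in volume.label_names.items()},
        "n_slices": int(volume.labels.shape[0]),
    }
    (directory / "spacing.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_label_stack(path) -> LabelVolume:
    """Read a label volume from a slice-image directory or multi-page TIFF.

    A directory must contain ``slice_*.png``/``*.pgm`` images and a
    ``spacing.json`` sidecar; a ``.tif``/``.tiff`` file is read as a
    multi-page stack with spacing from a sibling ``<name>.spacing.json``
    if present (else 1 mm isotropic).
    """
    path = Path(path)
    if path.is_dir():
        sidecar = json.loads((path / "spacing.json").read_text())
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".pgm"}
        )
        if not files:
            raise FileNotFoundError(f"no slice images in {path}")
        import imageio.v3 as iio

        slices = [np.asarray(iio.imread(f)) for f in files]
        labels = np.stack(slices).astype(np.int64)
        names = {int(k): v for k, v in sidecar.get("label_names", {}).items()}
        return LabelVolume(labels, tuple(sidecar["spacing_mm"]), names)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        labels = np.asarray(tifffile.imread(path)).astype(np.int64)
        if labels.ndim == 2:
            labels = labels[None]
        sidecar_path = path.with_suffix(path.suffix + ".spacing.json")
        alt = path.parent / (path.stem + ".spacing.json")
        spacing = (1.0, 1.0, 1.0)
        names: dict[int, str] = {}
        for cand in (sidecar_path, alt):
            if cand.exists():
                sidecar = json.loads(cand.read_text())
                spacing = tuple(sidecar["spacing_mm"])
                names = {
                    int(k): v for k, v in sidecar.get("label_names", {}).items()
                }
                break
        return LabelVolume(labels, spacing, names)
    raise FileNotFoundError(f"not a label stack directory or TIFF: {path}")
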