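"""Calibrated image I/O, projections, ROI masks, and unit-annotated tables.

All physical quantities are carried in micrometres (µm) and square
micrometres (µm²). Pixel-domain values are converted at measurement time and
never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class StackReadError(Exception):
    """Base error for stack reading problems."""


class UnreadableTiffError(StackReadError):
    """The file exists but cannot be parsed as a TIFF stack."""


class MissingCalibrationError(StackReadError):
    """No pixel calibration in the file and no override supplied."""


EXPANSION_STATES = ("non-expanded", "expanded")


@dataclass
class CalibratedStack:
    """Multi-channel 3D intensity grid with physical pixel calibration.

    channels map marker name -> (z, y, x) array. All channels share one grid
    and one calibration. Intensities must be finite and non-negative.
    """

    channels: dict[str, np.ndarray]
    pixel_size_xy: float  # µm / px, lateral
    z_step: float         # µm between z sections
    expansion_state: str = "expanded"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have differing shapes: {shapes}")
        (shape,) = shapes
        if len(shape) != 3:
            raise ValueError(f"channels must be 3D (z, y, x), got {shape}")
        if not (self.pixel_size_xy > 0 and self.z_step > 0):
            raise ValueError("pixel_size_xy and z_step must be > 0")
        if self.expansion_state not in EXPANSION_STATES:
            raise ValueError(f"expansion_state must be one of {EXPANSION_STATES}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} has non-finite intensities")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class ProjectedImage:
    """2D multi-channel image with lateral calibration (a projected stack)."""

    channels: dict[str, np.ndarray]
    pixel_size_xy: float
    expansion_state: str = "expanded"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have differing shapes: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2D (y, x), got {shape}")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


ROI_PROVENANCES = (
    "contact-outline", "center", "periphery", "background", "punctum", "manual",
)


@dataclass
class RoiMask:
    """Binary 2D mask aligned to an image's (y, x) grid."""

    mask: np.ndarray
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if self.provenance not in ROI_PROVENANCES:
            raise ValueError(f"provenance must be one of {ROI_PROVENANCES}")

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> "RoiMask":
        if self.size == 0:
            raise ValueError(f"empty ROI (provenance={self.provenance!r})")
        return self


@dataclass
class ResultTable:
    """Named, typed columns with unit annotations; one row per object.

    ``units`` maps column name -> unit string ("" for unitless columns).
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in self.data.columns:
            self.units.setdefault(col, "")

    def __len__(self) -> int:
        return len(self.data)


def _header_name(col: str, unit: str) -> str:
    return f"{col} [{unit}]" if unit else col


def _parse_header(name: str) -> tuple[str, str]:
    if name.endswith("]") and " [" in name:
        col, unit = name.rsplit(" [", 1)
        return col, unit[:-1]
    return name, ""


def write_table(table: ResultTable, path: str | Path) -> None:
    """Write a ResultTable as CSV; unit annotations go in the header row."""
    df = table.data.rename(
        columns={c: _header_name(c, table.units.get(c, "")) for c in table.data.columns}
    )
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> ResultTable:
    df = pd.read_csv(path)
    cols, units = [], {}
    for name in df.columns:
        col, unit = _parse_header(name)
        cols.append(col)
        units[col] = unit
    df.columns = cols
    return ResultTable(df, units)


def write_stack(stack: CalibratedStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF (axes CZYX) with physical pixel sizes."""
    data = np.stack([stack.channels[n] for n in stack.channel_names])
    tifffile.imwrite(
        path,
        data,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": stack.channel_names},
        },
        ome=True,
    )


def _ome_calibration(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = root.tag.split("}")[0] + "}" if "}" in root.tag else ""
        pixels = root.find(f".//{ns}Pixels")
        if pixels is None:
            return None, None
        px = pixels.get("PhysicalSizeX")
        pz = pixels.get("PhysicalSizeZ")
        return (float(px) if px else None, float(pz) if pz else None)
    except Exception:
        return None, None


def _ome_channel_names(tif: tifffile.TiffFile) -> list[str] | None:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = root.tag.split("}")[0] + "}" if "}" in root.tag else ""
        names = [c.get("Name") for c in root.iter(f"{ns}Channel")]
        if names and all(n is not None for n in names):
            return list(names)
    except Exception:
        pass
    return None


def _resolution_tag_calibration(tif: tifffile.TiffFile) -> float | None:
    # TIFF XResolution is px per unit; invert to µm/px when unit is known.
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else None
    per_px = den / num
    if unit == 3:  # centimetre
        return per_px * 1e4
    if unit == 2:  # inch
        return per_px * 2.54e4
    return None


def read_stack(
    path: str | Path,
    calibration_override: tuple[float, float] | None = None,
    channel_names: list[str] | None = None,
    expansion_state: str = "expanded",
) -> CalibratedStack:
    """Read a multi-channel z-stack from a (OME-)TIFF file.

    Calibration source order: explicit ``calibration_override``
    (pixel_size_xy, z_step) > OME metadata > TIFF resolution tags > error.
    Channel names come from ``channel_names``, else OME metadata, else
    ``ch0, ch1, ...``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            ome_px = ome_z = None
            ome_names = None
            if tif.is_ome and tif.ome_metadata:
                ome_px, ome_z = _ome_calibration(tif)
                ome_names = _ome_channel_names(tif)
            tag_px = _resolution_tag_calibration(tif)
    except StackReadError:
        raise
    except Exception as exc:
        raise UnreadableTiffError(f"cannot parse TIFF {path}: {exc}") from exc

    # Normalise axes to (C, Z, Y, X)
    if axes in ("CZYX",):
        pass
    elif axes == "ZCYX":
        data = np.moveaxis(data, 1, 0)
    elif axes == "ZYX":
        data = data[None]
    elif axes == "QYX" or (data.ndim == 3 and len(axes) == 3):
        data = data[None]
    elif axes == "YX" or data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 4:
        pass  # assume (C, Z, Y, X)
    else:
        raise UnreadableTiffError(f"unsupported axis layout {axes!r} in {path}")
    if data.ndim == 3:
        data = data[None]

    if calibration_override is not None:
        pixel_size_xy, z_step = calibration_override
    elif ome_px is not None:
        pixel_size_xy = ome_px
        z_step = ome_z if ome_z is not None else ome_px
    elif tag_px is not None:
        pixel_size_xy = tag_px
        z_step = tag_px
    else:
        raise MissingCalibrationError(
            f"{path} carries no pixel calibration; pass calibration_override="
            "(pixel_size_xy, z_step) in µm"
        )

    n_ch = data.shape[0]
    if channel_names is not None:
        names = list(channel_names)
    elif ome_names is not None and len(ome_names) == n_ch:
        names = ome_names
    else:
        names = [f"ch{i}" for i in range(n_ch)]
    if len(names) != n_ch:
        raise ValueError(f"got {len(names)} channel names for {n_ch} channels")

    channels = {name: data[i].astype(np.float64) for i, name in enumerate(names)}
    return CalibratedStack(
        channels=channels,
        pixel_size_xy=float(pixel_size_xy),
        z_step=float(z_step),
        expansion_state=expansion_state,
        metadata={"source": str(path)},
    )


def max_project(
    stack: CalibratedStack | ProjectedImage,
    z_range: tuple[int, int] | None = None,
) -> ProjectedImage:
    """Maximum-intensity projection over an inclusive z-slice interval.

    Projecting an already-projected image returns it unchanged (idempotence).
    """
    if isinstance(stack, ProjectedImage):
        return stack
    nz = stack.shape[0]
    if z_range is None:
        z_range = (0, nz - 1)
    z0, z1 = z_range
    if not (0 <= z0 <= z1 < nz):
        raise ValueError(f"z_range {z_range} out of bounds for depth {nz}")
    channels = {
        name: arr[z0 : z1 + 1].max(axis=0) for name, arr in stack.channels.items()
    }
    return ProjectedImage(
        channels=channels,
        pixel_size_xy=stack.pixel_size_xy,
        expansion_state=stack.expansion_state,
        metadata=dict(stack.metadata, z_range=z_range),
    )


def sum_project(
    stack: CalibratedStack | ProjectedImage,
    z_range: tuple[int, int] | None = None,
) -> ProjectedImage:
    """Sum-intensity projection over an inclusive z-slice interval.

    Unlike the maximum projection, the summed column intensity of a blurred
    surface is independent of how the surface tilts through the z slices,
    which makes it the projection of choice for integrated-fluorescence
    measurements (occupancy, CTCF).
    """
    if isinstance(stack, ProjectedImage):
        return stack
    nz = stack.shape[0]
    if z_range is None:
        z_range = (0, nz - 1)
    z0, z1 = z_range
    if not (0 <= z0 <= z1 < nz):
        raise ValueError(f"z_range {z_range} out of bounds for depth {nz}")
    channels = {
        name: arr[z0 : z1 + 1].sum(axis=0) for name, arr in stack.channels.items()
    }
    return ProjectedImage(
        channels=channels,
        pixel_size_xy=stack.pixel_size_xy,
        expansion_state=stack.expansion_state,
        metadata=dict(stack.metadata, z_range=z_range, projection="sum"),
    )
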