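"""Calibrated image stacks, profile tables and run configuration.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``; ``spacing_um`` is ``(dz, dy, dx)``.
* Physical stack coordinates are ``index * spacing`` in micrometres, i.e. the
  centre of voxel ``(0, 0, 0)`` is the origin.
* The analysis position grid is the closed integer set −1000..2000 µm in 1 µm
  steps (3001 samples) with 0 at the lesion plane; proximal→distal is the
  direction of increasing position.
* File writes are byte-deterministic for fixed inputs: the OME-XML we embed
  carries no timestamps or UUIDs.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import CalibrationError, ConfigError, ParseError

#: Acquisition voxel sizes of the confocal setup this pipeline targets:
#: 1.24 µm lateral pixels, 2.45 µm z-step.
DEFAULT_SPACING_UM: tuple[float, float, float] = (2.45, 1.24, 1.24)

DEFAULT_WINDOW_UM: tuple[int, int] = (-1000, 2000)
DEFAULT_BASELINE_UM: tuple[int, int] = (-1000, -500)

DEFAULT_SEGMENTS_UM: dict[str, tuple[int, int]] = {
    "proximal": (-1000, 0),
    "distal": (0, 2000),
    "distal_1": (0, 1000),
    "distal_2": (1000, 2000),
}


@dataclass(frozen=True)
class CalibratedStack:
    """A 3D single-channel intensity grid plus physical voxel spacing.

    Attributes
    ----------
    intensities:
        ``(z, y, x)`` array, finite and non-negative.
    spacing_um:
        ``(dz, dy, dx)`` voxel sizes in micrometres, all > 0.
    """

    intensities: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise CalibrationError(f"stack must be 3D (z, y, x), got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise CalibrationError("stack intensities must be finite")
        if arr.size and float(arr.min()) < 0:
            raise CalibrationError("stack intensities must be non-negative")
        sp = tuple(float(s) for s in self.spacing_um)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise CalibrationError(f"spacing_um must be three positive values, got {self.spacing_um}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing_um", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size along (z, y, x), from first to last voxel centre."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing_um))


def _ome_xml(shape: tuple[int, int, int], spacing_um, dtype: str) -> str:
    nz, ny, nx = shape
    dz, dy, dx = spacing_um
    # Minimal OME-XML with physical pixel sizes only; deliberately no UUID or
    # timestamp so that identical inputs give identical bytes.
    return (
        '<?xml version="1.0" encoding="UTF-8"?>'
        '<OME xmlns="http://www.openmicroscopy.org/Schemas/OME/2016-06">'
        '<Image ID="Image:0" Name="axonquant">'
        f'<Pixels ID="Pixels:0" DimensionOrder="XYZCT" Type="{dtype}" '
        f'SizeX="{nx}" SizeY="{ny}" SizeZ="{nz}" SizeC="1" SizeT="1" '
        f'PhysicalSizeX="{dx!r}" PhysicalSizeXUnit="&#181;m" '
        f'PhysicalSizeY="{dy!r}" PhysicalSizeYUnit="&#181;m" '
        f'PhysicalSizeZ="{dz!r}" PhysicalSizeZUnit="&#181;m">'
        '<Channel ID="Channel:0:0" SamplesPerPixel="1"/><TiffData/>'
        "</Pixels></Image></OME>"
    )


_OME_TYPES = {"float32": "float", "float64": "double", "uint8": "uint8", "uint16": "uint16", "int16": "int16"}


def write_stack(stack: CalibratedStack, path: str | Path) -> Path:
    """Write ``stack`` as an OME-TIFF with physical pixel-size metadata."""
    path = Path(path)
    arr = stack.intensities
    dtype = _OME_TYPES.get(arr.dtype.name)
    if dtype is None:
        arr = arr.astype(np.float32)
        dtype = "float"
    tifffile.imwrite(
        path,
        arr,
        description=_ome_xml(arr.shape, stack.spacing_um, dtype),
        photometric="minisblack",
    )
    return path


def _spacing_from_ome(desc: str) -> tuple[float, float, float] | None:
    try:
        root = ET.fromstring(desc)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            try:
                return (
                    float(el.attrib["PhysicalSizeZ"]),
                    float(el.attrib["PhysicalSizeY"]),
                    float(el.attrib["PhysicalSizeX"]),
                )
            except KeyError:
                return None
    return None


def read_stack(path: str | Path, spacing_um=None) -> CalibratedStack:
    """Read a TIFF/OME-TIFF stack.

    Spacing is taken from OME metadata when present; otherwise ``spacing_um``
    must supply it (``(dz, dy, dx)`` in µm). A file with neither raises
    :class:`CalibrationError`.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description or ""
    except (FileNotFoundError, tifffile.TiffFileError) as exc:
        raise CalibrationError(f"cannot read stack {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    found = _spacing_from_ome(desc) if "OME" in desc else None
    if found is None:  # foreign OME writers keep the XML elsewhere
        found = tif_ome_spacing(path)
    spacing = found or spacing_um
    if spacing is None:
        raise CalibrationError(
            f"{path} carries no physical pixel size metadata and no spacing override was given"
        )
    return CalibratedStack(np.ascontiguousarray(arr), tuple(spacing))


def tif_ome_spacing(path: str | Path) -> tuple[float, float, float] | None:
    """Spacing from a foreign OME-TIFF's ome_metadata, if tifffile exposes it."""
    try:
        with tifffile.TiffFile(path) as tif:
            if tif.ome_metadata:
                return _spacing_from_ome(tif.ome_metadata)
    except Exception:
        return None
    return None


# ---------------------------------------------------------------------------
# profile tables


def write_profile_csv(
    positions_um: np.ndarray,
    values: np.ndarray,
    path: str | Path,
    value_column: str = "value",
) -> Path:
    """Write (position, value) pairs; integer positions, full-precision values.

    Missing values (NaN) are written as empty fields and round-trip as NaN.
    """
    positions_um = np.asarray(positions_um)
    values = np.asarray(values, dtype=float)
    if positions_um.shape != values.shape:
        raise ParseError("positions and values must have equal length")
    df = pd.DataFrame(
        {"position_um": positions_um.astype(np.int64), value_column: values}
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_profile_csv(path: str | Path, value_column: str | None = None):
    """Read a two-column profile CSV back as ``(positions, values, column_name)``.

    Malformed rows raise :class:`ParseError` with their 1-based file line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError as exc:
        raise ParseError(f"no such profile file: {path}") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"unparseable CSV {path}: {exc}") from exc
    if "position_um" not in df.columns:
        raise ParseError(f"{path}: missing required column 'position_um'")
    if value_column is None:
        others = [c for c in df.columns if c != "position_um"]
        if len(others) != 1:
            raise ParseError(f"{path}: expected exactly one value column, found {others}")
        value_column = others[0]
    elif value_column not in df.columns:
        raise ParseError(f"{path}: missing required column '{value_column}'")

    positions = np.empty(len(df), dtype=np.int64)
    values = np.empty(len(df), dtype=float)
    for i, (p, v) in enumerate(zip(df["position_um"], df[value_column])):
        line = i + 2  # header is line 1
        try:
            positions[i] = int(p)
        except ValueError:
            raise ParseError(f"{path}: bad position {p!r}", line=line) from None
        if v == "":
            values[i] = np.nan
        else:
            try:
                values[i] = float(v)
            except ValueError:
                raise ParseError(f"{path}: bad value {v!r}", line=line) from None
    return positions, values, value_column


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class DetectorParams:
    """Spot-detector settings (see :mod:`axonquant.detect`)."""

    sigma_um: float = 1.06          # LoG scale ≈ fiber radius / sqrt(2)
    rel_threshold: float = 5.0      # multiples of the plane's MAD noise scale
    min_sep_um: float = 3.0         # non-maximum suppression radius
    peak_floor_frac: float = 0.05   # response floor relative to the plane max
    plane_halfwidth_um: float = 50.0
    plane_step_um: float = 1.0


@dataclass(frozen=True)
class ClassifierParams:
    """Pixel-classifier settings (see :mod:`axonquant.masking`)."""

    scales_um: tuple[float, ...] = (2.0, 5.0)
    n_estimators: int = 50
    samples_per_class: int = 4000
    closing_radius_um: float = 2.0


@dataclass(frozen=True)
class RunConfig:
    """Everything the analysis half of the pipeline needs for one sample.

    ``axis_points_um`` are two (z, y, x) points in stack µm coordinates
    defining the nerve axis; ``lesion_position_um`` is measured along that
    axis from the first point.
    """

    axis_points_um: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    lesion_position_um: float = 0.0
    window_um: tuple[int, int] = DEFAULT_WINDOW_UM
    baseline_um: tuple[int, int] = DEFAULT_BASELINE_UM
    smooth_um: int = 50
    segments_um: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENTS_UM))
    detector: DetectorParams = field(default_factory=DetectorParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    spacing_override_um: tuple[float, float, float] | None = None
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigError` listing every violation at once."""
        problems = []
        a, b = self.window_um
        if not a < b:
            problems.append(f"window_um must be ordered (a < b), got {self.window_um}")
        lo, hi = self.baseline_um
        if not lo < hi:
            problems.append(f"baseline_um must be ordered, got {self.baseline_um}")
        if lo < a or hi > b:
            problems.append(f"baseline_um {self.baseline_um} outside window {self.window_um}")
        if hi > 0:
            problems.append(f"baseline_um must be proximal to the lesion (end ≤ 0), got {self.baseline_um}")
        if self.smooth_um < 1:
            problems.append(f"smooth_um must be ≥ 1, got {self.smooth_um}")
        for name, (sa, sb) in self.segments_um.items():
            if not sa < sb:
                problems.append(f"segment {name!r} must be ordered, got {(sa, sb)}")
            if sa < a or sb > b:
                problems.append(f"segment {name!r} {(sa, sb)} outside window {self.window_um}")
        if not 0 < self.alpha < 1:
            problems.append(f"alpha must be in (0, 1), got {self.alpha}")
        if self.detector.sigma_um <= 0:
            problems.append("detector.sigma_um must be > 0")
        if self.detector.min_sep_um < 0:
            problems.append("detector.min_sep_um must be ≥ 0")
        if len(self.classifier.scales_um) < 1:
            problems.append("classifier.scales_um needs at least one scale")
        if list(self.classifier.scales_um) != sorted(set(self.classifier.scales_um)):
            problems.append("classifier.scales_um must be strictly increasing")
        if problems:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "axis_points_um": [list(p) for p in self.axis_points_um] if self.axis_points_um else None,
            "lesion_position_um": self.lesion_position_um,
            "window_um": list(self.window_um),
            "baseline_um": list(self.baseline_um),
            "smooth_um": self.smooth_um,
            "segments_um": {k: list(v) for k, v in self.segments_um.items()},
            "detector": vars(self.detector).copy(),
            "classifier": dict(vars(self.classifier), scales_um=list(self.classifier.scales_um)),
            "spacing_override_um": list(self.spacing_override_um) if self.spacing_override_um else None,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        if d.get("axis_points_um"):
            kwargs["axis_points_um"] = tuple(tuple(float(x) for x in p) for p in d["axis_points_um"])
        for key in ("lesion_position_um", "alpha"):
            if key in d:
                kwargs[key] = float(d[key])
        for key in ("smooth_um", "seed"):
            if key in d:
                kwargs[key] = int(d[key])
        for key in ("window_um", "baseline_um"):
            if key in d:
                kwargs[key] = tuple(int(x) for x in d[key])
        if d.get("segments_um"):
            kwargs["segments_um"] = {k: tuple(int(x) for x in v) for k, v in d["segments_um"].items()}
        if d.get("detector"):
            kwargs["detector"] = DetectorParams(**d["detector"])
        if d.get("classifier"):
            c = dict(d["classifier"])
            if "scales_um" in c:
                c["scales_um"] = tuple(float(s) for s in c["scales_um"])
            kwargs["classifier"] = ClassifierParams(**c)
        if d.get("spacing_override_um"):
            kwargs["spacing_override_um"] = tuple(float(s) for s in d["spacing_override_um"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


def make_grid(window_um: tuple[int, int] = DEFAULT_WINDOW_UM) -> np.ndarray:
    """Closed integer position grid from window start to end inclusive."""
    a, b = int(window_um[0]), int(window_um[1])
    if not a < b:
        raise ConfigError(f"window must be ordered, got {window_um}")
    return np.arange(a, b + 1, dtype=np.int64)
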