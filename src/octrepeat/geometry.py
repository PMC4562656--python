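"""Scan-protocol geometry: coordinate grids, region masks and thickness maps.

A macular OCT volume scan is a stack of ``n_bscans`` cross-sectional B-scans,
each made of ``n_ascans_per_bscan`` axial depth profiles (A-scans).  Layer
segmentation assigns each boundary surface an axial pixel position per A-scan;
subtracting two bounding surfaces and scaling by the axial sampling gives a
layer thickness map on a fovea-centered grid of physical (mm) coordinates.

Conventions
-----------
* Axial positions are 0-based pixels from the image top; increasing pixel
  value means increasing depth, so an outer boundary has the larger value.
* All grids are stored as ``(n_bscans, n_ascans)`` arrays.  For a horizontal
  protocol each row is one B-scan running along x; for a vertical protocol
  each row is one B-scan running along y.
* The fovea is the coordinate origin.  Mask membership is evaluated at A-scan
  cell centers; outer boundaries are closed (``<=``), inner annulus
  boundaries open (``>``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "LAYERS",
    "ELEMENTARY_LAYERS",
    "BOUNDARIES",
    "LAYER_BOUNDARIES",
    "ScanProtocol",
    "SegmentedVolume",
    "ThicknessMap",
    "RegionMask",
    "SPECTRALIS_AXIAL_UM_PER_PX",
    "CIRRUS_AXIAL_UM_PER_PX",
    "default_protocols",
    "grid_coordinates",
    "thickness_from_surfaces",
    "circular_mask",
    "elliptical_annulus_mask",
    "full_area_mask",
    "point_set_mask",
    "extract_bscan",
    "nearest_bscan_index",
]

#: Layers with a thickness map, inner to outer.  GCIP is the composite of
#: GCL and IPL (the only macular layers Cirrus segments besides the RNFL).
LAYERS = ("RNFL", "GCL", "IPL", "GCIP", "INL", "OPL", "ONL")
ELEMENTARY_LAYERS = ("RNFL", "GCL", "IPL", "INL", "OPL", "ONL")

#: Segmentation boundary surfaces, inner (vitreous side) to outer.
BOUNDARIES = (
    "ILM",
    "RNFL/GCL",
    "GCL/IPL",
    "IPL/INL",
    "INL/OPL",
    "OPL/ONL",
    "ONL-outer",
)

#: layer -> (inner boundary, outer boundary)
LAYER_BOUNDARIES: Mapping[str, tuple[str, str]] = {
    "RNFL": ("ILM", "RNFL/GCL"),
    "GCL": ("RNFL/GCL", "GCL/IPL"),
    "IPL": ("GCL/IPL", "IPL/INL"),
    "GCIP": ("RNFL/GCL", "IPL/INL"),
    "INL": ("IPL/INL", "INL/OPL"),
    "OPL": ("INL/OPL", "OPL/ONL"),
    "ONL": ("OPL/ONL", "ONL-outer"),
}

SPECTRALIS_AXIAL_UM_PER_PX = 3.87
CIRRUS_AXIAL_UM_PER_PX = 1.96

_NAME_RE = re.compile(r"^(?P<dir>[HV])-(?P<nb>\d+)-(?P<na>\d+)$")


@dataclass(frozen=True)
class ScanProtocol:
    """One volume-scan setting, named ``direction-nBscans-nAscans``.

    The name follows the scan-protocol taxonomy used for macular repeat
    scans, e.g. ``"V-25-1024"`` = vertical B-scans, 25 of them, 1024 A-scans
    each.  ``art_frames`` is the Spectralis automatic-real-time averaging
    count (``None`` for devices without it).
    """

    name: str
    direction: str  # "horizontal" | "vertical"
    n_bscans: int
    n_ascans_per_bscan: int
    width_mm: float
    height_mm: float
    axial_scale_um_per_px: float
    device: str  # "spectralis" | "cirrus"
    art_frames: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("horizontal", "vertical"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.device not in ("spectralis", "cirrus"):
            raise ValueError(f"unknown device {self.device!r}")
        if self.n_bscans < 1:
            raise ValueError("n_bscans must be >= 1")
        if self.n_ascans_per_bscan < 2:
            raise ValueError("n_ascans_per_bscan must be >= 2")
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("scan extents must be positive")
        if self.axial_scale_um_per_px <= 0:
            raise ValueError("axial scale must be positive")
        expected = format_protocol_name(
            self.direction, self.n_bscans, self.n_ascans_per_bscan
        )
        if self.name != expected:
            raise ValueError(
                f"protocol name {self.name!r} does not match fields ({expected!r})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_bscans, self.n_ascans_per_bscan)

    @property
    def scan_center_mm(self) -> tuple[float, float]:
        return (self.width_mm / 2.0, self.height_mm / 2.0)


def format_protocol_name(direction: str, n_bscans: int, n_ascans: int) -> str:
    return f"{'H' if direction == 'horizontal' else 'V'}-{n_bscans}-{n_ascans}"


def parse_protocol_name(name: str) -> tuple[str, int, int]:
    """Parse ``direction-nB-nA`` into (direction, n_bscans, n_ascans)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"malformed protocol name {name!r}")
    direction = "horizontal" if m.group("dir") == "H" else "vertical"
    return direction, int(m.group("nb")), int(m.group("na"))


def _spectralis(name: str, w: float, h: float, art: int) -> ScanProtocol:
    d, nb, na = parse_protocol_name(name)
    return ScanProtocol(
        name=name, direction=d, n_bscans=nb, n_ascans_per_bscan=na,
        width_mm=w, height_mm=h,
        axial_scale_um_per_px=SPECTRALIS_AXIAL_UM_PER_PX,
        device="spectralis", art_frames=art,
    )


def _cirrus(name: str) -> ScanProtocol:
    d, nb, na = parse_protocol_name(name)
    return ScanProtocol(
        name=name, direction=d, n_bscans=nb, n_ascans_per_bscan=na,
        width_mm=6.0, height_mm=6.0,
        axial_scale_um_per_px=CIRRUS_AXIAL_UM_PER_PX,
        device="cirrus", art_frames=None,
    )


def default_protocols() -> dict[str, ScanProtocol]:
    """Registry of the shipped scan settings.

    Five Spectralis macular designs plus the two standard Cirrus macular
    cubes (512x128 and 200x200 A x B over 6x6 mm).  Extents and ART counts
    other than the axial scales are implementation defaults and can be
    replaced by registering protocols of your own.
    """
    protocols = [
        _spectralis("V-25-1024", 6.0, 6.0, art=12),
        _spectralis("H-25-512", 6.0, 6.0, art=16),
        _spectralis("H-61-768", 6.0, 6.0, art=9),
        _spectralis("H-19-512", 9.0, 4.5, art=20),
        _spectralis("H-13-512", 6.0, 3.0, art=25),
        _cirrus("H-128-512"),
        _cirrus("H-200-200"),
    ]
    return {p.name: p for p in protocols}


def _axis_positions(n: int, extent: float) -> np.ndarray:
    """Positions of n samples spanning [0, extent] inclusive (fencepost)."""
    if n == 1:
        return np.array([extent / 2.0])
    return np.linspace(0.0, extent, n)


def grid_coordinates(
    protocol: ScanProtocol,
    fovea_center_mm: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fovea-centered (x, y) mm coordinates for every A-scan.

    ``fovea_center_mm`` is given in scan-area coordinates (x in [0, width],
    y in [0, height]) and defaults to the scan-area center.  The returned
    arrays have shape ``(n_bscans, n_ascans)``; x is horizontal, y vertical.
    """
    w, h = protocol.width_mm, protocol.height_mm
    if fovea_center_mm is None:
        fovea_center_mm = protocol.scan_center_mm
    fx, fy = fovea_center_mm
    if not (0.0 <= fx <= w and 0.0 <= fy <= h):
        raise ValueError(
            f"fovea center {fovea_center_mm} outside scan area {w}x{h} mm"
        )
    if protocol.direction == "horizontal":
        # rows = B-scans stacked along y, A-scans run along x
        xs = _axis_positions(protocol.n_ascans_per_bscan, w) - fx
        ys = _axis_positions(protocol.n_bscans, h) - fy
        x = np.broadcast_to(xs[None, :], protocol.shape).copy()
        y = np.broadcast_to(ys[:, None], protocol.shape).copy()
    else:
        # rows = B-scans stacked along x, A-scans run along y
        xs = _axis_positions(protocol.n_bscans, w) - fx
        ys = _axis_positions(protocol.n_ascans_per_bscan, h) - fy
        x = np.broadcast_to(xs[:, None], protocol.shape).copy()
        y = np.broadcast_to(ys[None, :], protocol.shape).copy()
    return x, y


@dataclass
class SegmentedVolume:
    """Per-boundary axial positions (px) for one eye x session x protocol.

    ``boundaries`` maps boundary names (a subset of :data:`BOUNDARIES`) to
    float arrays of shape ``protocol.shape``; NaN marks missing values.
    ``meta`` carries subject/eye/group/session tags used downstream.
    """

    protocol: ScanProtocol
    boundaries: dict[str, np.ndarray]
    fovea_center_mm: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.boundaries.items():
            if name not in BOUNDARIES:
                raise ValueError(f"unknown boundary {name!r}")
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.protocol.shape:
                raise ValueError(
                    f"boundary {name!r} shape {arr.shape} != protocol "
                    f"shape {self.protocol.shape}"
                )
            self.boundaries[name] = arr

    def validate_ordering(self) -> None:
        """Check inner->outer boundary ordering wherever all are present."""
        present = [b for b in BOUNDARIES if b in self.boundaries]
        for inner, outer in zip(present[:-1], present[1:]):
            a, b = self.boundaries[inner], self.boundaries[outer]
            bad = np.where(b - a < 0)
            if bad[0].size:
                i, j = int(bad[0][0]), int(bad[1][0])
                raise ValueError(
                    f"boundary {outer!r} above {inner!r} at "
                    f"B-scan {i}, A-scan {j}"
                )

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        return grid_coordinates(self.protocol, self.fovea_center_mm)


@dataclass
class ThicknessMap:
    """One layer's thickness (um) on the protocol grid, NaN = missing."""

    layer: str
    values_um: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    protocol: ScanProtocol | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        self.values_um = np.asarray(self.values_um, dtype=float)
        if self.values_um.shape != np.shape(self.x_mm):
            raise ValueError("values and coordinate grids must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values_um.shape


@dataclass(frozen=True)
class RegionMask:
    """Boolean grid selecting A-scans, with the rule that produced it."""

    mask: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def thickness_from_surfaces(volume: SegmentedVolume, layer: str) -> ThicknessMap:
    """Layer thickness map = (outer - inner boundary px) x axial scale.

    Missing wherever either boundary is missing.  Negative thickness raises,
    naming the offending B-scan/A-scan.  The GCIP composite is delimited by
    the RNFL/GCL and IPL/INL boundaries, so it equals the elementwise sum of
    the GCL and IPL maps wherever those exist.
    """
    if layer not in LAYER_BOUNDARIES:
        raise ValueError(f"unknown layer {layer!r}")
    inner_name, outer_name = LAYER_BOUNDARIES[layer]
    for b in (inner_name, outer_name):
        if b not in volume.boundaries:
            raise ValueError(
                f"volume lacks boundary {b!r} needed for layer {layer!r}"
            )
    inner = volume.boundaries[inner_name]
    outer = volume.boundaries[outer_name]
    thickness = (outer - inner) * volume.protocol.axial_scale_um_per_px
    bad = np.where(thickness < 0)
    if bad[0].size:
        i, j = int(bad[0][0]), int(bad[1][0])
        raise ValueError(
            f"inverted boundaries for layer {layer!r} at B-scan {i}, "
            f"A-scan {j}: {inner_name!r} below {outer_name!r}"
        )
    x, y = volume.grid()
    return ThicknessMap(layer=layer, values_um=thickness, x_mm=x, y_mm=y,
                        protocol=volume.protocol)


def circular_mask(
    x_mm: np.ndarray, y_mm: np.ndarray, diameter_mm: float
) -> RegionMask:
    """Fovea-centered disc: cell included iff x^2 + y^2 <= (d/2)^2 (closed)."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    r2 = (diameter_mm / 2.0) ** 2
    mask = (np.asarray(x_mm) ** 2 + np.asarray(y_mm) ** 2) <= r2
    if not mask.any():
        warnings.warn(
            f"circular mask (d={diameter_mm} mm) selects no cells on this grid",
            stacklevel=2,
        )
    return RegionMask(mask=mask, provenance={"kind": "circle",
                                             "diameter_mm": diameter_mm})


def elliptical_annulus_mask(
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    outer_h_mm: float,
    outer_v_mm: float,
    inner_h_mm: float,
    inner_v_mm: float,
) -> RegionMask:
    """Fovea-centered elliptical annulus (Cirrus ganglion-cell analysis ring).

    Included iff inside-or-on the outer ellipse and strictly outside the
    inner one, testing (x/r_h)^2 + (y/r_v)^2 against 1.  The shipped Cirrus
    estimates use outer radii 2.4 (horizontal) / 2.0 (vertical) mm and inner
    radii 0.6 / 0.5 mm.
    """
    if not (0 < inner_h_mm < outer_h_mm and 0 < inner_v_mm < outer_v_mm):
        raise ValueError(
            "annulus radii must satisfy 0 < inner < outer componentwise"
        )
    x = np.asarray(x_mm)
    y = np.asarray(y_mm)
    outer = (x / outer_h_mm) ** 2 + (y / outer_v_mm) ** 2 <= 1.0
    inner = (x / inner_h_mm) ** 2 + (y / inner_v_mm) ** 2 <= 1.0
    mask = outer & ~inner
    if not mask.any():
        warnings.warn("elliptical annulus selects no cells on this grid",
                      stacklevel=2)
    return RegionMask(
        mask=mask,
        provenance={
            "kind": "elliptical_annulus",
            "outer_h_mm": outer_h_mm, "outer_v_mm": outer_v_mm,
            "inner_h_mm": inner_h_mm, "inner_v_mm": inner_v_mm,
        },
    )


def full_area_mask(x_mm: np.ndarray, y_mm: np.ndarray) -> RegionMask:
    """Every A-scan of the grid."""
    return RegionMask(mask=np.ones(np.shape(x_mm), dtype=bool),
                      provenance={"kind": "full_area"})


def point_set_mask(
    x_mm: np.ndarray, y_mm: np.ndarray, points_mm: Iterable[tuple[float, float]]
) -> RegionMask:
    """The grid cell nearest (Euclidean) to each requested mm point."""
    points = [tuple(p) for p in points_mm]
    if not points:
        raise ValueError("point set must contain at least one point")
    x = np.asarray(x_mm)
    y = np.asarray(y_mm)
    mask = np.zeros(x.shape, dtype=bool)
    for px, py in points:
        d2 = (x - px) ** 2 + (y - py) ** 2
        mask[np.unravel_index(np.argmin(d2), x.shape)] = True
    return RegionMask(mask=mask, provenance={"kind": "point_set",
                                             "points_mm": points})


def _bscan_lateral_positions(
    protocol: ScanProtocol, fovea_center_mm: tuple[float, float] | None
) -> np.ndarray:
    """Fovea-relative lateral (across-stack) coordinate of each B-scan."""
    x, y = grid_coordinates(protocol, fovea_center_mm)
    return y[:, 0] if protocol.direction == "horizontal" else x[:, 0]


def nearest_bscan_index(
    protocol: ScanProtocol,
    offset_mm: float,
    fovea_center_mm: tuple[float, float] | None = None,
) -> int:
    """Index of the B-scan nearest to a fovea-relative lateral offset.

    Ties break toward the lower index.  Raises if the offset falls outside
    the scan extent.
    """
    pos = _bscan_lateral_positions(protocol, fovea_center_mm)
    lo, hi = min(pos[0], pos[-1]), max(pos[0], pos[-1])
    if not (lo <= offset_mm <= hi):
        raise ValueError(
            f"offset {offset_mm} mm outside B-scan range [{lo}, {hi}] mm"
        )
    dist = np.abs(pos - offset_mm)
    # ties (including float-rounding near-ties) break toward the lower index
    tol = 1e-9 * (1.0 + abs(hi - lo))
    return int(np.flatnonzero(dist <= dist.min() + tol)[0])


def extract_bscan(
    target: ThicknessMap | SegmentedVolume,
    index: int | None = None,
    offset_mm: float | None = None,
):
    """One B-scan's profile (or boundary rows) with its mm coordinates.

    Exactly one of ``index`` / ``offset_mm`` selects the B-scan; offsets are
    fovea-relative lateral positions resolved by :func:`nearest_bscan_index`.
    Returns ``(profile, x_row, y_row)`` for a ThicknessMap and
    ``(row_dict, x_row, y_row)`` for a SegmentedVolume.
    """
    if (index is None) == (offset_mm is None):
        raise ValueError("specify exactly one of index / offset_mm")
    if isinstance(target, ThicknessMap):
        protocol = target.protocol
        if protocol is None:
            raise ValueError("ThicknessMap lacks a protocol reference")
        fovea = None
        x, y = target.x_mm, target.y_mm
        n = target.shape[0]
    else:
        protocol = target.protocol
        fovea = target.fovea_center_mm
        x, y = target.grid()
        n = protocol.n_bscans
    if index is None:
        index = nearest_bscan_index(protocol, offset_mm, fovea)
    if not (0 <= index < n):
        raise IndexError(f"B-scan index {index} out of range [0, {n})")
    if isinstance(target, ThicknessMap):
        return target.values_um[index], x[index], y[index]
    rows = {b: arr[index] for b, arr in target.boundaries.items()}
    return rows, x[index], y[index]
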