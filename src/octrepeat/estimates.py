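"""The twelve published layer-thickness estimates (A-L) as declarative recipes.

A *thickness estimate* is a rule mapping one segmented macular scan to a
single mean layer thickness: a scan protocol, a B-scan selection, a spatial
region mask and unweighted averaging of the included A-scans.  The registry
encodes the twelve estimates found in the MS intra-retinal segmentation
literature:

=====  ==========  ==========  ===========================================
id     device      protocol    region / selection (defaults)
=====  ==========  ==========  ===========================================
A-C    Spectralis  3 volumes   6 mm-diameter disc around the fovea
D, E   Spectralis  2 volumes   full scan area
F      Spectralis  volume      reduced B-scan subset, full width
G      Spectralis  volume      single fovea-centered B-scan, full width
H      Spectralis  volume      paired near-fovea B-scans, full width
I      Spectralis  volume      single fovea-centered B-scan, central 6 mm
J      Spectralis  volume      3 sparse points on the central B-scan
K      Cirrus      512x128     elliptical annulus 2.4/2.0 - 0.6/0.5 mm
L      Cirrus      200x200     elliptical annulus 2.4/2.0 - 0.6/0.5 mm
=====  ==========  ==========  ===========================================

Only the broad strokes (A-C disc on three settings, A-E/K/L large areas,
G-J single-B-scan based, K/L annulus radii) are fixed by the source studies;
every remaining geometric parameter here is an overridable default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    LAYERS,
    RegionMask,
    ScanProtocol,
    SegmentedVolume,
    circular_mask,
    default_protocols,
    elliptical_annulus_mask,
    full_area_mask,
    nearest_bscan_index,
    point_set_mask,
    thickness_from_surfaces,
)

__all__ = [
    "REGISTRY_VERSION",
    "EstimateDefinition",
    "EstimateRecord",
    "builtin_estimates",
    "build_mask",
    "apply_estimate",
    "apply_all",
    "LONG_TABLE_COLUMNS",
]

REGISTRY_VERSION = "1"

#: Canonical column order of the long-format repeated-measures table.
LONG_TABLE_COLUMNS = (
    "subject_id", "eye", "group", "session", "device",
    "estimate", "layer", "thickness_um", "n_cells",
)

CIRRUS_LAYERS = ("RNFL", "GCIP")

#: Annulus radii of the Cirrus ganglion-cell analysis, mm.
CIRRUS_ANNULUS = {
    "kind": "elliptical_annulus",
    "outer_h_mm": 2.4, "outer_v_mm": 2.0,
    "inner_h_mm": 0.6, "inner_v_mm": 0.5,
}


@dataclass(frozen=True)
class EstimateDefinition:
    """One named thickness-estimate recipe.

    ``bscan_selector`` is one of ``{"kind": "all"}``,
    ``{"kind": "indices", "indices": [...]}``,
    ``{"kind": "single", "offset_mm": v}`` or
    ``{"kind": "offsets", "offsets_mm": [...]}`` (nearest-B-scan rule,
    ties toward the lower index).  ``mask`` is a provenance dict understood
    by :func:`build_mask`.
    """

    id: str
    device: str
    protocol_name: str
    bscan_selector: Mapping
    mask: Mapping
    layers: tuple[str, ...] = LAYERS

    def __post_init__(self) -> None:
        unknown = set(self.layers) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown layers {sorted(unknown)}")
        object.__setattr__(self, "bscan_selector", dict(self.bscan_selector))
        object.__setattr__(self, "mask", dict(self.mask))
        object.__setattr__(self, "layers", tuple(self.layers))


@dataclass(frozen=True)
class EstimateRecord:
    """One evaluated estimate for one eye x session x layer."""

    subject_id: str
    eye: str
    group: str
    session: int
    device: str
    estimate: str
    layer: str
    thickness_um: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be OD or OS, got {self.eye!r}")
        if self.session < 1:
            raise ValueError("session must be >= 1")
        if self.thickness_um < 0:
            raise ValueError("thickness must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def builtin_estimates(
    protocols: Mapping[str, ScanProtocol] | None = None,
    overrides: Mapping[str, EstimateDefinition] | None = None,
    j_points_mm: Sequence[tuple[float, float]] = ((0.0, -2.0), (0.0, 0.0),
                                                  (0.0, 2.0)),
) -> dict[str, EstimateDefinition]:
    """The versioned registry of the twelve estimates A-L.

    ``protocols``, when given, restricts the registry to estimates whose
    scan protocol is available (simulating only ``V-25-1024`` leaves A and
    J); the default is the full shipped protocol registry.  ``overrides``
    replaces or adds whole definitions by id (their protocols must
    resolve); ``j_points_mm`` sets the sparse sample points of estimate J
    (default: fovea and +-2 mm along the central vertical B-scan).
    """
    disc6 = {"kind": "circle", "diameter_mm": 6.0}
    full = {"kind": "full_area"}
    all_b = {"kind": "all"}
    central = {"kind": "single", "offset_mm": 0.0}

    defs = [
        EstimateDefinition("A", "spectralis", "V-25-1024", all_b, disc6),
        EstimateDefinition("B", "spectralis", "H-25-512", all_b, disc6),
        EstimateDefinition("C", "spectralis", "H-61-768", all_b, disc6),
        EstimateDefinition("D", "spectralis", "H-19-512", all_b, full),
        EstimateDefinition("E", "spectralis", "H-13-512", all_b, full),
        EstimateDefinition(
            "F", "spectralis", "H-61-768",
            {"kind": "indices", "indices": list(range(0, 61, 10))}, full),
        EstimateDefinition("G", "spectralis", "H-25-512", central, full),
        EstimateDefinition(
            "H", "spectralis", "H-61-768",
            {"kind": "offsets", "offsets_mm": [-0.1, 0.1]}, full),
        EstimateDefinition("I", "spectralis", "H-19-512", central, disc6),
        EstimateDefinition(
            "J", "spectralis", "V-25-1024", central,
            {"kind": "point_set", "points_mm": [tuple(p) for p in j_points_mm]}),
        EstimateDefinition("K", "cirrus", "H-128-512", all_b, CIRRUS_ANNULUS,
                           layers=CIRRUS_LAYERS),
        EstimateDefinition("L", "cirrus", "H-200-200", all_b, CIRRUS_ANNULUS,
                           layers=CIRRUS_LAYERS),
    ]
    registry = {d.id: d for d in defs}
    known = protocols if protocols is not None else default_protocols()
    if protocols is not None:
        registry = {k: d for k, d in registry.items()
                    if d.protocol_name in known}
    if overrides:
        for key, defn in overrides.items():
            if key != defn.id:
                raise ValueError(f"override key {key!r} != definition id {defn.id!r}")
            registry[key] = defn
    for d in registry.values():
        if d.protocol_name not in known:
            raise ValueError(
                f"estimate {d.id}: protocol {d.protocol_name!r} not registered"
            )
    if not registry:
        raise ValueError("no estimate applies to the available protocols")
    return registry


def build_mask(
    provenance: Mapping, x_mm: np.ndarray, y_mm: np.ndarray
) -> RegionMask:
    """Materialise a mask-provenance dict on a coordinate grid."""
    kind = provenance.get("kind")
    if kind == "circle":
        return circular_mask(x_mm, y_mm, provenance["diameter_mm"])
    if kind == "elliptical_annulus":
        return elliptical_annulus_mask(
            x_mm, y_mm, provenance["outer_h_mm"], provenance["outer_v_mm"],
            provenance["inner_h_mm"], provenance["inner_v_mm"])
    if kind == "full_area":
        return full_area_mask(x_mm, y_mm)
    if kind == "point_set":
        return point_set_mask(x_mm, y_mm, provenance["points_mm"])
    raise ValueError(f"unknown mask kind {kind!r}")


def _selected_rows(
    selector: Mapping, volume: SegmentedVolume
) -> np.ndarray:
    """Boolean row (B-scan) selection for a volume."""
    n = volume.protocol.n_bscans
    kind = selector.get("kind")
    rows = np.zeros(n, dtype=bool)
    if kind == "all":
        rows[:] = True
    elif kind == "indices":
        idx = list(selector["indices"])
        for i in idx:
            if not (0 <= i < n):
                raise IndexError(f"B-scan index {i} out of range [0, {n})")
        rows[idx] = True
    elif kind == "single":
        rows[nearest_bscan_index(volume.protocol, selector["offset_mm"],
                                 volume.fovea_center_mm)] = True
    elif kind == "offsets":
        for off in selector["offsets_mm"]:
            rows[nearest_bscan_index(volume.protocol, off,
                                     volume.fovea_center_mm)] = True
    else:
        raise ValueError(f"unknown B-scan selector kind {kind!r}")
    return rows


def apply_estimate(
    defn: EstimateDefinition,
    volume: SegmentedVolume,
    layer: str,
    missing_flag_fraction: float = 0.2,
) -> EstimateRecord:
    """Evaluate one estimate on one segmented volume for one layer.

    The value is the unweighted mean of the layer thickness map over the
    intersection of the B-scan selection and the region mask, excluding
    missing cells.  A warning is issued when more than
    ``missing_flag_fraction`` of the masked cells are missing.
    """
    if layer not in defn.layers:
        raise ValueError(
            f"layer {layer!r} not supported by estimate {defn.id} "
            f"(supports {defn.layers})"
        )
    if volume.protocol.device != defn.device:
        raise ValueError(
            f"estimate {defn.id} is a {defn.device} estimate; volume is "
            f"from {volume.protocol.device}"
        )
    if volume.protocol.name != defn.protocol_name:
        raise ValueError(
            f"estimate {defn.id} expects protocol {defn.protocol_name!r}, "
            f"volume uses {volume.protocol.name!r}"
        )
    tmap = thickness_from_surfaces(volume, layer)
    region = build_mask(defn.mask, tmap.x_mm, tmap.y_mm)
    rows = _selected_rows(defn.bscan_selector, volume)
    effective = region.mask & rows[:, None]
    if not effective.any():
        raise ValueError(
            f"estimate {defn.id}: empty effective mask (region ∩ B-scan "
            "selection selects no cells)"
        )
    vals = tmap.values_um[effective]
    finite = np.isfinite(vals)
    n_used = int(finite.sum())
    if n_used == 0:
        raise ValueError(
            f"estimate {defn.id}: all {vals.size} masked cells are missing"
        )
    missing_frac = 1.0 - n_used / vals.size
    if missing_frac > missing_flag_fraction:
        warnings.warn(
            f"estimate {defn.id} / layer {layer}: {missing_frac:.0%} of "
            "masked cells missing",
            stacklevel=2,
        )
    meta = volume.meta
    return EstimateRecord(
        subject_id=str(meta.get("subject_id", "?")),
        eye=str(meta.get("eye", "OD")),
        group=str(meta.get("group", "HC")),
        session=int(meta.get("session", 1)),
        device=volume.protocol.device,
        estimate=defn.id,
        layer=layer,
        thickness_um=float(np.mean(vals[finite])),
        n_cells=n_used,
    )


def apply_all(
    registry: Mapping[str, EstimateDefinition],
    volumes: Iterable[SegmentedVolume],
    layers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Evaluate every applicable estimate on a cohort of volumes.

    Each volume must carry subject/eye/group/session meta tags.  An estimate
    applies to a volume when device and protocol name match.  The result is
    the long-format repeated-measures table, deterministically ordered by
    (subject, eye, session, estimate, layer); duplicate
    (subject, eye, session, estimate, layer) combinations raise.
    """
    records: list[EstimateRecord] = []
    for volume in volumes:
        for defn in registry.values():
            if (defn.device != volume.protocol.device
                    or defn.protocol_name != volume.protocol.name):
                continue
            wanted = defn.layers if layers is None else [
                l for l in layers if l in defn.layers]
            for layer in wanted:
                records.append(apply_estimate(defn, volume, layer))
    if not records:
        return pd.DataFrame(columns=list(LONG_TABLE_COLUMNS))
    df = pd.DataFrame([r.__dict__ for r in records])
    df = df[list(LONG_TABLE_COLUMNS)]
    key = ["subject_id", "eye", "session", "estimate", "layer"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate record for (subject={subject_id}, eye={eye}, "
            "session={session}, estimate={estimate}, layer={layer})".format(
                **first.to_dict())
        )
    df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
    return df
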