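"""File interchange: surface-export CSVs and long repeated-measures TSVs.

Surface-export CSV (one file per eye x session x protocol): a ``#``-prefixed
header block carrying the protocol and acquisition metadata, followed by the
columns ``bscan_index, ascan_index, boundary_name, position_px``.

Long-table TSV: UTF-8, tab-separated, one header row with the columns
``subject_id, eye, group, session, device, estimate, layer, thickness_um,
n_cells``; the interchange format between the estimation and statistics
stages.  Unknown extra columns survive a round trip.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .estimates import LONG_TABLE_COLUMNS
from .geometry import BOUNDARIES, ScanProtocol, SegmentedVolume

__all__ = [
    "write_surface_csv",
    "read_surface_csv",
    "write_long_table",
    "read_long_table",
]

_REQUIRED_HEADER = ("protocol", "direction", "n_bscans", "n_ascans_per_bscan",
                    "width_mm", "height_mm", "axial_scale_um_per_px", "device")


def write_surface_csv(volume: SegmentedVolume, path: str | Path) -> None:
    """Write one volume's boundary positions with a metadata header block."""
    p = volume.protocol
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# protocol={p.name}\n")
        fh.write(f"# direction={p.direction}\n")
        fh.write(f"# n_bscans={p.n_bscans}\n")
        fh.write(f"# n_ascans_per_bscan={p.n_ascans_per_bscan}\n")
        fh.write(f"# width_mm={p.width_mm}\n")
        fh.write(f"# height_mm={p.height_mm}\n")
        fh.write(f"# axial_scale_um_per_px={p.axial_scale_um_per_px}\n")
        fh.write(f"# device={p.device}\n")
        if p.art_frames is not None:
            fh.write(f"# art_frames={p.art_frames}\n")
        for key, value in sorted(volume.meta.items()):
            fh.write(f"# meta.{key}={value}\n")
        writer = csv.writer(fh)
        writer.writerow(["bscan_index", "ascan_index", "boundary_name",
                         "position_px"])
        for name in BOUNDARIES:
            if name not in volume.boundaries:
                continue
            arr = volume.boundaries[name]
            for i in range(arr.shape[0]):
                row = arr[i]
                for j in range(arr.shape[1]):
                    v = row[j]
                    if np.isfinite(v):
                        writer.writerow([i, j, name, repr(float(v))])


def read_surface_csv(path: str | Path) -> SegmentedVolume:
    """Read a surface-export CSV back into a SegmentedVolume."""
    path = Path(path)
    header: dict[str, str] = {}
    meta: dict[str, str] = {}
    rows: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                key = key.strip()
                if key.startswith("meta."):
                    meta[key[5:]] = value.strip()
                else:
                    header[key] = value.strip()
            else:
                rows.append(line)
    missing = [k for k in _REQUIRED_HEADER if k not in header]
    if missing:
        raise ValueError(f"{path}: header lacks {missing}")
    protocol = ScanProtocol(
        name=header["protocol"],
        direction=header["direction"],
        n_bscans=int(header["n_bscans"]),
        n_ascans_per_bscan=int(header["n_ascans_per_bscan"]),
        width_mm=float(header["width_mm"]),
        height_mm=float(header["height_mm"]),
        axial_scale_um_per_px=float(header["axial_scale_um_per_px"]),
        device=header["device"],
        art_frames=int(header["art_frames"]) if "art_frames" in header
        else None,
    )
    boundaries: dict[str, np.ndarray] = {}
    reader = csv.reader(rows)
    head = next(reader, None)
    if head != ["bscan_index", "ascan_index", "boundary_name", "position_px"]:
        raise ValueError(f"{path}: unexpected column header {head}")
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        try:
            i, j, name, pos = int(row[0]), int(row[1]), row[2], float(row[3])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed data row {lineno}: {row}"
                             ) from exc
        if name not in BOUNDARIES:
            raise ValueError(f"{path}: unknown boundary {name!r} (row {lineno})")
        if name not in boundaries:
            boundaries[name] = np.full(protocol.shape, np.nan)
        boundaries[name][i, j] = pos
    # session/subject metadata, with numeric session restored
    if "session" in meta:
        meta["session"] = int(meta["session"])  # type: ignore[assignment]
    return SegmentedVolume(protocol=protocol, boundaries=boundaries,
                           meta=dict(meta))


def write_long_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the long repeated-measures table as TSV (lossless floats)."""
    missing = [c for c in LONG_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"long table lacks required columns {missing}")
    ordered = list(LONG_TABLE_COLUMNS) + [
        c for c in table.columns if c not in LONG_TABLE_COLUMNS]
    out = table[ordered].copy()
    out["thickness_um"] = out["thickness_um"].map(lambda v: repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


def read_long_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-table TSV.

    Schema violations (missing columns, non-numeric thickness, duplicate
    (subject, eye, session, estimate, layer) keys) raise with the offending
    row number (1-based, counting the header as row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LONG_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col, caster in (("session", int), ("n_cells", int),
                        ("thickness_um", float)):
        converted = []
        for idx, raw in df[col].items():
            try:
                converted.append(caster(raw))
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: row {idx + 2}: cannot parse {col}={raw!r}"
                ) from exc
        df[col] = converted
    key = ["subject_id", "eye", "session", "estimate", "layer"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"{path}: row {row + 2}: duplicate (subject, eye, session, "
            "estimate, layer) key "
            + str(tuple(df.iloc[row][k] for k in key))
        )
    return df
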