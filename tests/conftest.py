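"""Shared fixtures: tiny protocols and hand-built segmented volumes."""

from __future__ import annotations

import numpy as np
import pytest

from octrepeat.geometry import (
    BOUNDARIES,
    ScanProtocol,
    SegmentedVolume,
)


def make_protocol(
    name: str = "H-9-32",
    width: float = 6.0,
    height: float = 6.0,
    device: str = "spectralis",
    axial: float = 3.87,
) -> ScanProtocol:
    from octrepeat.geometry import parse_protocol_name

    d, nb, na = parse_protocol_name(name)
    return ScanProtocol(
        name=name, direction=d, n_bscans=nb, n_ascans_per_bscan=na,
        width_mm=width, height_mm=height, axial_scale_um_per_px=axial,
        device=device,
    )


def make_volume(
    protocol: ScanProtocol,
    thickness_px: dict[str, float | np.ndarray] | float = 10.0,
    ilm_px: float = 100.0,
    meta: dict | None = None,
) -> SegmentedVolume:
    """Stack boundaries from per-layer thicknesses given in pixels."""
    shape = protocol.shape
    if not isinstance(thickness_px, dict):
        thickness_px = {layer: thickness_px for layer in
                        ("RNFL", "GCL", "IPL", "INL", "OPL", "ONL")}
    boundaries = {"ILM": np.full(shape, float(ilm_px))}
    level = boundaries["ILM"]
    order = ["RNFL", "GCL", "IPL", "INL", "OPL", "ONL"]
    for layer, bname in zip(order, BOUNDARIES[1:]):
        t = thickness_px[layer]
        level = level + (np.full(shape, float(t)) if np.isscalar(t) else t)
        boundaries[bname] = level
    return SegmentedVolume(protocol=protocol, boundaries=boundaries,
                           meta=meta or {})


@pytest.fixture
def tiny_protocol() -> ScanProtocol:
    return make_protocol("H-9-32")


@pytest.fixture
def tiny_vertical_protocol() -> ScanProtocol:
    return make_protocol("V-9-32")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
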