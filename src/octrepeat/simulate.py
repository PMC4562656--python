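"""Synthetic repeated-measurement OCT cohorts with known variance components.

The generator emulates the test-retest study design: healthy-control
subjects scanned three times and MS/CIS patients twice, both eyes, on
Spectralis (all seven layers) and Cirrus (RNFL and GCIP only) scan
protocols, with at least the session-to-session perturbations that a real
re-examination (subject leaves the room, device reset, no follow-up
function) introduces:

* a per-eye *between-eye* deviation of each layer's mean thickness
  (SD ``sigma_between[layer]``, um) on top of a smooth population template;
* a per-session *global offset* of each layer (SD ``sigma_offset``, um);
* a per-session *spatially correlated segmentation-error field*
  (pointwise SD ``sigma_field`` um, Gaussian correlation length
  ``field_correlation_mm``);
* *scan-window translation jitter*: the session's sampling grid is shifted
  by a random (dx, dy) (SD ``jitter_sd_mm``), modelling imperfect scan
  re-placement over a fixed retina;
* the *Henle-fiber-layer (HFL) beam-angle artifact*: an antisymmetric shift
  of the OPL/ONL boundary proportional to a per-session beam-entry offset
  theta, which moves thickness between OPL and ONL without changing their
  sum (except where the 0.5 um thickness floor clips).

Offsets and fields are realised on the seven *boundary surfaces* with SD
``sigma/sqrt(2)`` each, so that every layer - a difference of two adjacent
boundary errors - has session SD exactly ``sigma``, and the GCIP composite
(also a two-boundary difference) is as repeatable as an elementary layer
rather than sqrt(2) times worse.  Adjacent layers consequently carry
anticorrelated errors, as real boundary mis-placements do.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .geometry import (
    BOUNDARIES,
    ELEMENTARY_LAYERS,
    LAYERS,
    ScanProtocol,
    SegmentedVolume,
    ThicknessMap,
    default_protocols,
    grid_coordinates,
)

__all__ = [
    "DEFAULT_SIGMA_BETWEEN",
    "CohortConfig",
    "GroundTruth",
    "layer_template",
    "hfl_artifact",
    "hfl_shape",
    "simulate_cohort",
    "iter_cohort_volumes",
]

#: Between-eye SD of each layer's mean thickness, um.  OPL is deliberately
#: the least heterogeneous layer across eyes, which - together with the HFL
#: artifact - makes it the least repeatable layer in relative (ICC) terms.
DEFAULT_SIGMA_BETWEEN = {
    "RNFL": 5.5, "GCL": 6.5, "IPL": 5.5, "INL": 5.5, "OPL": 2.0, "ONL": 7.0,
}

#: Minimum simulated layer thickness, um.
THICKNESS_FLOOR_UM = 0.5

_ILM_BASE_PX = 120.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and noise parameters of a simulated cohort.

    The defaults replicate the repeat-scan study design (15 + 15 healthy
    controls with three sessions, 13 MS/CIS patients with two, both eyes,
    all shipped protocols); ``seed`` fixes every random draw.
    """

    n_hc_subjects: int = 15
    n_ms_subjects: int = 13
    sessions_hc: int = 3
    sessions_ms: int = 2
    eyes_per_subject: int = 2
    protocols: tuple[str, ...] | None = None  # None = all registered
    layers: tuple[str, ...] = ELEMENTARY_LAYERS
    sigma_between: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_BETWEEN))
    sigma_offset: float = 0.6
    sigma_field: float = 6.5
    field_correlation_mm: float = 0.18
    jitter_sd_mm: float = 0.1
    hfl_amplitude_um: float = 50.0
    hfl_theta_range: tuple[float, float] = (-0.5, 0.5)
    ms_inner_scale: float = 0.85
    seed: int = 0
    #: additional ScanProtocol objects made available beyond the shipped
    #: registry (e.g. reduced grids for fast experiments)
    extra_protocols: tuple[ScanProtocol, ...] = ()

    def __post_init__(self) -> None:
        if self.sessions_hc < 2 or self.sessions_ms < 2:
            raise ValueError("sessions per group must be >= 2")
        for name in ("sigma_offset", "sigma_field", "jitter_sd_mm",
                     "hfl_amplitude_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for layer, sd in self.sigma_between.items():
            if layer not in LAYERS or sd < 0:
                raise ValueError(f"bad sigma_between entry {layer!r}: {sd}")
        unknown = set(self.layers) - set(ELEMENTARY_LAYERS)
        if unknown:
            raise ValueError(f"layers must be elementary, got {sorted(unknown)}")

    @property
    def record_layers(self) -> tuple[str, ...]:
        """Layers to tabulate: the configured set plus GCIP when derivable."""
        layers = list(self.layers)
        if "GCL" in layers and "IPL" in layers:
            layers.append("GCIP")
        return tuple(layers)

    def resolved_protocols(self) -> dict[str, ScanProtocol]:
        registry = default_protocols()
        for p in self.extra_protocols:
            registry[p.name] = p
        if self.protocols is None:
            return registry
        missing = set(self.protocols) - set(registry)
        if missing:
            raise ValueError(f"unknown protocols {sorted(missing)}")
        return {name: registry[name] for name in self.protocols}

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        for key in ("protocols", "layers", "hfl_theta_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("extra_protocols"):
            d["extra_protocols"] = tuple(
                ScanProtocol(**p) for p in d["extra_protocols"])
        else:
            d.pop("extra_protocols", None)
        return cls(**d)


# --------------------------------------------------------------------------
# population templates

def _radius(x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
    return np.sqrt(np.asarray(x_mm) ** 2 + np.asarray(y_mm) ** 2)


def layer_template(
    layer: str, x_mm: np.ndarray, y_mm: np.ndarray
) -> np.ndarray:
    """Population mean thickness (um) of a layer at fovea-centered mm coords.

    Smooth radially structured profiles with the canonical macular
    morphology: inner layers (RNFL/GCL/IPL/INL) show a foveal depression
    with a perifoveal ring (the GCL maximum sits near 1.7 mm eccentricity),
    the ONL peaks at the fovea, and the OPL is comparatively flat.  All
    values lie in [0, 120] um.
    """
    r = _radius(x_mm, y_mm)
    if layer == "RNFL":
        return 6.0 + 30.0 * (np.minimum(r, 3.5) / 3.5) ** 2.5
    if layer == "GCL":
        return 8.0 + 45.0 * np.exp(-(((r - 1.7) / 0.9) ** 2))
    if layer == "IPL":
        return 12.0 + 28.0 * np.exp(-(((r - 1.6) / 1.0) ** 2))
    if layer == "GCIP":
        return layer_template("GCL", x_mm, y_mm) + layer_template(
            "IPL", x_mm, y_mm)
    if layer == "INL":
        return 12.0 + 22.0 * np.exp(-(((r - 1.8) / 1.1) ** 2))
    if layer == "OPL":
        return 14.0 + 12.0 * np.exp(-(((r - 1.2) / 0.9) ** 2))
    if layer == "ONL":
        return 50.0 + 38.0 * np.exp(-((r / 1.1) ** 2))
    raise ValueError(f"unknown layer {layer!r}")


# --------------------------------------------------------------------------
# HFL beam-angle artifact

def hfl_shape(x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
    """Antisymmetric unit shape s(x, y) of the HFL boundary shift.

    Odd along the beam-offset (horizontal) direction, smooth, |s| <= 1 with
    extrema near +-1.3 mm eccentricity - where Henle fibers are obliquely
    sliced and their reflectivity flips between hyper- and hypointense as
    the beam entry point moves across the pupil.
    """
    a = 1.3
    x = np.asarray(x_mm, dtype=float)
    r2 = x**2 + np.asarray(y_mm, dtype=float) ** 2
    return (x / a) * np.exp(0.5 - r2 / (2.0 * a * a))


def hfl_artifact(
    opl_map: ThicknessMap,
    onl_map: ThicknessMap,
    theta: float,
    amplitude_um: float,
) -> tuple[ThicknessMap, ThicknessMap]:
    """Shift the OPL/ONL boundary by delta = amplitude * theta * s(x, y).

    Thickness moves from ONL into OPL (delta > 0) or back; both layers are
    floored at 0.5 um, and wherever no flooring occurs the OPL + ONL sum is
    conserved exactly.
    """
    if amplitude_um < 0:
        raise ValueError("amplitude must be >= 0")
    if (opl_map.shape != onl_map.shape
            or not np.array_equal(opl_map.x_mm, onl_map.x_mm)
            or not np.array_equal(opl_map.y_mm, onl_map.y_mm)):
        raise ValueError("OPL and ONL maps must share an aligned grid")
    delta = amplitude_um * theta * hfl_shape(opl_map.x_mm, opl_map.y_mm)
    opl = np.maximum(opl_map.values_um + delta, THICKNESS_FLOOR_UM)
    onl = np.maximum(onl_map.values_um - delta, THICKNESS_FLOOR_UM)
    return (
        replace(opl_map, values_um=opl),
        replace(onl_map, values_um=onl),
    )


# --------------------------------------------------------------------------
# correlated noise field

def _smoothing_sigmas_px(protocol: ScanProtocol, corr_mm: float
                         ) -> tuple[float, float]:
    """Per-axis Gaussian sigma in pixels matching an isotropic mm scale."""
    nb, na = protocol.shape
    if protocol.direction == "horizontal":
        row_extent, col_extent = protocol.height_mm, protocol.width_mm
    else:
        row_extent, col_extent = protocol.width_mm, protocol.height_mm
    d_row = row_extent / (nb - 1) if nb > 1 else row_extent
    d_col = col_extent / (na - 1)
    return corr_mm / d_row, corr_mm / d_col


def _kernel_l2(sigma_px: float, n: int) -> float:
    """L2 norm of the (wrapped) 1-D Gaussian kernel gaussian_filter1d uses."""
    if sigma_px <= 0:
        return 1.0
    impulse = np.zeros(n)
    impulse[0] = 1.0
    k = gaussian_filter1d(impulse, sigma_px, mode="wrap")
    return float(np.sqrt(np.sum(k**2)))


def correlated_field(
    rng: np.random.Generator,
    protocol: ScanProtocol,
    sigma_um: float,
    corr_mm: float,
) -> np.ndarray:
    """Stationary Gaussian field, pointwise SD ``sigma_um``, correlation
    exp(-d^2 / (4 corr_mm^2)) (wrap-around smoothing keeps the variance
    exact up to kernel truncation)."""
    shape = protocol.shape
    white = rng.standard_normal(shape)
    if sigma_um == 0.0:
        return np.zeros(shape)
    s_row, s_col = _smoothing_sigmas_px(protocol, corr_mm)
    out = gaussian_filter1d(white, s_row, axis=0, mode="wrap")
    out = gaussian_filter1d(out, s_col, axis=1, mode="wrap")
    norm = _kernel_l2(s_row, shape[0]) * _kernel_l2(s_col, shape[1])
    return out * (sigma_um / norm)


# --------------------------------------------------------------------------
# ground truth bookkeeping

@dataclass
class GroundTruth:
    """What the simulator knows: per-eye deviations and variance components.

    ``eye_deviations`` maps (subject_id, eye) -> {layer: um deviation added
    to the population template}; MS eyes additionally carry the inner-layer
    template scaling.  ``sigma_between_effective`` includes the GCIP
    composite (GCL and IPL deviations are independent, so variances add).
    """

    config: CohortConfig
    eye_deviations: dict[tuple[str, str], dict[str, float]]
    eye_groups: dict[tuple[str, str], str]

    @property
    def sigma_between_effective(self) -> dict[str, float]:
        sb = dict(self.config.sigma_between)
        sb["GCIP"] = float(np.hypot(sb.get("GCL", 0.0), sb.get("IPL", 0.0)))
        return sb

    def within_variance_closed_form(self, layer: str) -> float:
        """Session variance of any estimate when only offset noise is on."""
        cfg = self.config
        if cfg.sigma_field or cfg.jitter_sd_mm or cfg.hfl_amplitude_um:
            raise ValueError(
                "closed form only valid for offset-only noise; use "
                "within_variance_mc")
        var = cfg.sigma_offset**2
        return var

    def true_icc(self, layer: str, within_variance: float | None = None
                 ) -> float:
        """sigma_b^2 / (sigma_b^2 + sigma_w^2) for a single-group cohort."""
        if within_variance is None:
            within_variance = self.within_variance_closed_form(layer)
        sb2 = self.sigma_between_effective[layer] ** 2
        return sb2 / (sb2 + within_variance)

    def within_variance_mc(
        self,
        estimate_value_fn,
        n_sessions: int = 200,
        seed: int = 12345,
    ) -> float:
        """Monte-Carlo session variance of an estimate under the noise model.

        ``estimate_value_fn(volume) -> float | None`` evaluates the estimate
        on a simulated volume (returning None for volumes of other
        protocols); sessions are drawn for one fixed eye.
        """
        cfg = replace(self.config, n_hc_subjects=1, n_ms_subjects=0,
                      sessions_hc=2, eyes_per_subject=1, seed=seed)
        # hold the eye truth fixed, vary only session noise
        rng = np.random.default_rng(seed)
        values = []
        sim = _CohortSimulator(cfg)
        deviations = {l: 0.0 for l in ELEMENTARY_LAYERS}
        for _ in range(n_sessions):
            for vol in sim._session_volumes(rng, "S0", "OD", "HC", 1,
                                            deviations):
                v = estimate_value_fn(vol)
                if v is not None:
                    values.append(v)
        return float(np.var(values, ddof=1))


# --------------------------------------------------------------------------
# simulation engine

class _CohortSimulator:
    def __init__(self, config: CohortConfig):
        self.config = config
        self.protocols = config.resolved_protocols()
        # analytic template cache per protocol (unjittered grid)
        self._grid_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {
            name: grid_coordinates(p) for name, p in self.protocols.items()
        }

    def draw_eye_deviations(self, rng: np.random.Generator
                            ) -> tuple[dict, dict]:
        cfg = self.config
        deviations: dict[tuple[str, str], dict[str, float]] = {}
        groups: dict[tuple[str, str], str] = {}
        roster = [("HC", f"HC{i+1:03d}") for i in range(cfg.n_hc_subjects)]
        roster += [("MS", f"MS{i+1:03d}") for i in range(cfg.n_ms_subjects)]
        eyes = ("OD", "OS")[: cfg.eyes_per_subject]
        for group, subject in roster:
            for eye in eyes:
                dev = {
                    layer: rng.normal(0.0, cfg.sigma_between.get(layer, 0.0))
                    for layer in ELEMENTARY_LAYERS
                }
                deviations[(subject, eye)] = dev
                groups[(subject, eye)] = group
        return deviations, groups

    def _session_volumes(
        self,
        rng: np.random.Generator,
        subject: str,
        eye: str,
        group: str,
        session: int,
        deviations: Mapping[str, float],
    ) -> list[SegmentedVolume]:
        """All protocol volumes for one eye x session (shared session draws)."""
        cfg = self.config
        # session-level draws shared across protocols of the same sitting
        jx, jy = rng.normal(0.0, cfg.jitter_sd_mm, size=2)
        theta = rng.uniform(*cfg.hfl_theta_range)
        offsets = {
            b: rng.normal(0.0, cfg.sigma_offset / np.sqrt(2.0))
            for b in BOUNDARIES
        }
        volumes = []
        for name in sorted(self.protocols):
            protocol = self.protocols[name]
            x0, y0 = self._grid_cache[name]
            # jitter: the window lands offset on the retina, so the sampled
            # retinal coordinates are shifted by (jx, jy)
            if cfg.jitter_sd_mm > 0:
                x, y = x0 + jx, y0 + jy
            else:
                x, y = x0, y0
            if protocol.device == "cirrus":
                boundary_names = ["ILM", "RNFL/GCL", "IPL/INL"]
                layer_chain = [("RNFL", ("ILM", "RNFL/GCL")),
                               ("GCIP", ("RNFL/GCL", "IPL/INL"))]
            else:
                boundary_names = list(BOUNDARIES)
                layer_chain = [(l, None) for l in ELEMENTARY_LAYERS]
            # boundary error surfaces
            err = {}
            for b in boundary_names:
                e = np.full(protocol.shape, offsets[b])
                if cfg.sigma_field > 0:
                    e = e + correlated_field(
                        rng, protocol, cfg.sigma_field / np.sqrt(2.0),
                        cfg.field_correlation_mm)
                err[b] = e
            # HFL artifact: shift of the OPL/ONL boundary (Spectralis only;
            # Cirrus does not segment that boundary)
            if "OPL/ONL" in err:
                err["OPL/ONL"] = err["OPL/ONL"] + (
                    cfg.hfl_amplitude_um * theta * hfl_shape(x, y))
            inner_scale = (cfg.ms_inner_scale if group == "MS" else 1.0)

            def true_layer(layer: str) -> np.ndarray:
                base = layer_template(layer, x, y)
                if layer in ("GCL", "IPL"):
                    base = base * inner_scale
                return base + deviations.get(layer, 0.0)

            # observed layer thicknesses from boundary errors, floored
            if protocol.device == "cirrus":
                obs = {
                    "RNFL": true_layer("RNFL")
                    + (err["RNFL/GCL"] - err["ILM"]),
                    "GCIP": (true_layer("GCL") + true_layer("IPL"))
                    + (err["IPL/INL"] - err["RNFL/GCL"]),
                }
                chain = ["RNFL", "GCIP"]
            else:
                obs = {}
                for (layer, _), (inner_b, outer_b) in zip(
                        layer_chain,
                        zip(boundary_names[:-1], boundary_names[1:])):
                    obs[layer] = true_layer(layer) + (
                        err[outer_b] - err[inner_b])
                chain = [l for l, _ in layer_chain]
            for layer in chain:
                obs[layer] = np.maximum(obs[layer], THICKNESS_FLOOR_UM)
            # stack into boundary pixel positions
            scale = protocol.axial_scale_um_per_px
            boundaries = {boundary_names[0]: np.full(protocol.shape,
                                                     _ILM_BASE_PX)}
            level = boundaries[boundary_names[0]]
            for layer, b_out in zip(chain, boundary_names[1:]):
                level = level + obs[layer] / scale
                boundaries[b_out] = level
            volumes.append(SegmentedVolume(
                protocol=protocol,
                boundaries=boundaries,
                meta={"subject_id": subject, "eye": eye, "group": group,
                      "session": session, "device": protocol.device},
            ))
        return volumes

    def iter_volumes(self, deviations, groups) -> Iterator[SegmentedVolume]:
        cfg = self.config
        rng = np.random.default_rng(_derive_seed(cfg.seed, 1))
        for (subject, eye), dev in deviations.items():
            group = groups[(subject, eye)]
            n_sessions = cfg.sessions_hc if group == "HC" else cfg.sessions_ms
            for session in range(1, n_sessions + 1):
                yield from self._session_volumes(
                    rng, subject, eye, group, session, dev)


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0]
               % (2**31))


def iter_cohort_volumes(config: CohortConfig
                        ) -> tuple[Iterator[SegmentedVolume], GroundTruth]:
    """Streaming variant of :func:`simulate_cohort` (same draws, same order).

    Returns the volume generator together with the ground truth; volumes are
    produced lazily so a full multi-protocol cohort never resides in memory
    at once.
    """
    sim = _CohortSimulator(config)
    rng = np.random.default_rng(_derive_seed(config.seed, 0))
    deviations, groups = sim.draw_eye_deviations(rng)
    truth = GroundTruth(config=config, eye_deviations=deviations,
                        eye_groups=groups)
    return sim.iter_volumes(deviations, groups), truth


def simulate_cohort(config: CohortConfig
                    ) -> tuple[list[SegmentedVolume], GroundTruth]:
    """Generate the full cohort of segmented volumes plus its ground truth.

    Bit-for-bit reproducible from (config, seed): two calls with equal
    configs yield identical volumes.
    """
    volumes, truth = iter_cohort_volumes(config)
    return list(volumes), truth
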