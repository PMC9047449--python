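"""Synthetic time-lapse phase-image phantoms with known death dynamics.

Real QPI movies of dying cells are not publicly deposited, so every stage of
the analysis is exercised on rendered phantoms whose ground truth is known
exactly: each cell is an elliptical two-level phase object (a brighter
central region standing in for the nucleus and dense organelles on a dimmer
peripheral cytoplasm) whose geometric and phase parameters follow logistic
("sigmoid") time courses with class-specific signatures:

* **necrotic** cells swell slowly while the central phase collapses —
  accidental death with loss of intracellular mass density;
* **apoptotic** cells round up quickly and develop a sharp, bright
  two-pixel nuclear-edge ring — programmed death with nuclear condensation;
* **normal** cells only fluctuate around their baseline (zero-amplitude
  trajectories plus a small mean-reverting random walk).

Additive i.i.d. Gaussian phase noise emulates the temporal phase stability
of a common-path interferometer.  Everything is reproducible bit-exactly
from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from skimage.morphology import disk, erosion as _erosion

from .core import PhaseImage, TimeLapseStack

__all__ = [
    "FEATURE_NAMES",
    "RELATIVE_FEATURES",
    "SigmoidParams",
    "CellPhantomSpec",
    "RenderedFrame",
    "SimulatedCell",
    "CohortConfig",
    "sigmoid",
    "sigmoid_trajectory",
    "render_cell_frame",
    "render_multi_cell_frame",
    "sample_phantom",
    "simulate_cohort",
    "analytic_features",
]

#: Canonical order of the 11 per-cell features.
FEATURE_NAMES: tuple[str, ...] = (
    "cell_area",
    "circularity",
    "eccentricity",
    "solidity",
    "optical_volume",
    "phase_sd",
    "mean_central_phase",
    "mean_peripheral_phase",
    "peripheral_to_central_ratio",
    "fried_egg_score",
    "nuclear_edge_score",
)

#: Features normalized as relative change (x - x1) / x1 before sigmoid
#: fitting; all others are normalized additively (x - x1).
RELATIVE_FEATURES: frozenset[str] = frozenset(
    {"optical_volume", "cell_area", "mean_central_phase", "mean_peripheral_phase"}
)

CLASS_LABELS = ("normal", "apoptotic", "necrotic")


def sigmoid(t, amplitude: float, gain: float, cutoff: float):
    """Logistic transition ``amplitude / (1 + exp(gain * (cutoff - t)))``.

    ``amplitude`` is the total change (final minus initial value, signed),
    ``gain`` the rate in 1/h and ``cutoff`` the half-transition time in
    hours.  At ``t = cutoff`` the value is exactly ``amplitude / 2``.
    """
    t = np.asarray(t, dtype=float)
    x = np.clip(gain * (cutoff - t), -500.0, 500.0)
    return amplitude / (1.0 + np.exp(x))


def sigmoid_trajectory(
    amplitude: float,
    gain: float,
    cutoff: float,
    timepoints: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sample a noisy logistic time course at the given time points.

    Raises ``ValueError`` for non-finite parameters or non-increasing
    time points.
    """
    params = np.array([amplitude, gain, cutoff, noise_sd], dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("sigmoid parameters must be finite")
    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or t.size == 0 or not np.all(np.diff(t) > 0):
        raise ValueError("timepoints must be a strictly increasing 1-D sequence")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    values = sigmoid(t, amplitude, gain, cutoff)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=t.shape)
    return values


@dataclass(frozen=True)
class SigmoidParams:
    """True transition parameters of one driven phantom property."""

    amplitude: float
    gain: float  # 1/h
    cutoff: float  # h

    def at(self, t) -> np.ndarray:
        return sigmoid(t, self.amplitude, self.gain, self.cutoff)


# Phantom knobs that sigmoid dynamics may drive, keyed by the feature whose
# time course they shape.  "nuclear_edge_score" holds the final ring phase
# contrast in radians; "circularity" / "eccentricity" / "fried_egg_score"
# are additive in the dimensionless feature; the remaining three are
# relative (fractional) changes.
_DRIVABLE = (
    "cell_area",
    "mean_central_phase",
    "mean_peripheral_phase",
    "fried_egg_score",
    "circularity",
    "eccentricity",
    "nuclear_edge_score",
)

# Knobs that receive mean-reverting fluctuations in normal cells (relative).
_FLUCTUATING = (
    "cell_area",
    "mean_central_phase",
    "mean_peripheral_phase",
    "fried_egg_score",
)


@dataclass(frozen=True)
class CellPhantomSpec:
    """Full recipe for one synthetic cell.

    Geometry: an ellipse of initial area ``pi * initial_radius**2`` with
    minor/major axis ratio ``axis_ratio`` and an ``n_lobes``-fold boundary
    ripple tuned so the rendered circularity is close to ``circularity0``.
    The central region is a concentric smooth ellipse holding
    ``central_fraction`` of the cell area at phase ``central_phase``; the
    rest of the cell sits at ``peripheral_phase``.  When ``ring_contrast``
    dynamics are present, a two-pixel band just inside the central boundary
    is raised by the current ring contrast (the nuclear edge of apoptosis).
    """

    class_label: str
    center: tuple[float, float]  # (x, y) micrometres
    initial_radius: float  # micrometres
    central_fraction: float
    peripheral_phase: float  # radians
    central_phase: float  # radians
    axis_ratio: float = 1.0  # minor / major, in (0, 1]
    orientation: float = 0.0  # radians
    circularity0: float = 1.0
    n_lobes: int = 6
    dynamics: Mapping[str, SigmoidParams] = field(default_factory=dict)
    noise_sd: float = 0.0  # radians, additive phase noise
    fluctuation_sd: float = 0.02  # relative, normal-cell baseline wobble
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if not (self.central_phase > self.peripheral_phase > 0):
            raise ValueError("need central_phase > peripheral_phase > 0")
        if not (0 < self.central_fraction < 1):
            raise ValueError("central_fraction must lie in (0, 1)")
        if not (0 < self.axis_ratio <= 1):
            raise ValueError("axis_ratio is minor/major and must lie in (0, 1]")
        if not (0 < self.circularity0 <= 1.05):
            raise ValueError("circularity0 out of range")
        for name in self.dynamics:
            if name not in _DRIVABLE:
                raise ValueError(f"no phantom knob is driven by feature {name!r}")
        if self.class_label == "normal":
            if any(p.amplitude != 0 for p in self.dynamics.values()):
                raise ValueError("normal cells must have zero-amplitude dynamics")

    def _traj(self, name: str, t) -> np.ndarray:
        p = self.dynamics.get(name)
        if p is None:
            return np.zeros_like(np.asarray(t, dtype=float))
        return p.at(t)


def _waviness_for(circularity: float, n_lobes: int) -> float:
    # r(theta) = R (1 + b cos(m theta)) has circularity ~ 1 - b^2 (m^2-1)/2
    deficit = max(1.0 - circularity, 0.0)
    return float(np.sqrt(2.0 * deficit / (n_lobes**2 - 1)))


def _knobs_at(spec: CellPhantomSpec, t: float, fluct: Mapping[str, float] | None = None):
    """Instantaneous phantom parameters at time ``t`` (hours)."""
    fl = fluct or {}
    rel_area = float(spec._traj("cell_area", t)) + fl.get("cell_area", 0.0)
    radius = spec.initial_radius * np.sqrt(max(1.0 + rel_area, 0.05))
    central = spec.central_phase * (
        1.0 + float(spec._traj("mean_central_phase", t)) + fl.get("mean_central_phase", 0.0)
    )
    peripheral = spec.peripheral_phase * (
        1.0 + float(spec._traj("mean_peripheral_phase", t)) + fl.get("mean_peripheral_phase", 0.0)
    )
    fraction = spec.central_fraction * (1.0 + fl.get("fried_egg_score", 0.0)) + float(
        spec._traj("fried_egg_score", t)
    )
    fraction = float(np.clip(fraction, 0.02, 0.95))
    circ = float(np.clip(spec.circularity0 + spec._traj("circularity", t), 0.3, 1.0))
    q = float(np.clip(spec.axis_ratio + spec._traj("eccentricity", t), 0.2, 1.0))
    ring = float(spec._traj("nuclear_edge_score", t))
    return {
        "radius": float(radius),
        "central_phase": central,
        "peripheral_phase": max(peripheral, 1e-3),
        "central_fraction": fraction,
        "circularity": circ,
        "axis_ratio": q,
        "ring_contrast": max(ring, 0.0),
    }


@dataclass
class RenderedFrame:
    """One rendered phantom frame plus its ground-truth masks."""

    image: PhaseImage
    cell_mask: np.ndarray
    central_mask: np.ndarray
    ring_mask: np.ndarray


def _cell_geometry(spec, knobs, grid_shape, pixel_size):
    """Boolean masks (cell, central, ring) for the current knob values."""
    h, w = grid_shape
    radius_px = knobs["radius"] / pixel_size
    if radius_px <= 2:
        raise ValueError("cell radius <= 2 pixels: unresolvable phantom")
    q = knobs["axis_ratio"]
    a = radius_px / np.sqrt(q)  # semi-major, px
    b = radius_px * np.sqrt(q)  # semi-minor, px
    wav = _waviness_for(knobs["circularity"], spec.n_lobes)
    cx = spec.center[0] / pixel_size
    cy = spec.center[1] / pixel_size
    if not (
        a * (1 + wav) < min(cx, w - 1 - cx) and a * (1 + wav) < min(cy, h - 1 - cy)
    ):
        raise ValueError("cell does not fit inside the grid")
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(spec.orientation), np.sin(spec.orientation)
    xr = ct * dx + st * dy
    yr = -st * dx + ct * dy
    u = xr / a
    v = yr / b
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    cell = rho <= 1.0 + wav * np.cos(spec.n_lobes * theta)
    central = rho <= np.sqrt(knobs["central_fraction"])
    ring = central & ~_erosion(central, disk(2))
    return cell, central, ring


def render_cell_frame(
    spec: CellPhantomSpec,
    t: float,
    grid_shape: tuple[int, int] = (96, 96),
    pixel_size: float = 0.48,
    wavelength: float = 0.532,
    rng: np.random.Generator | None = None,
    fluctuations: Mapping[str, float] | None = None,
) -> RenderedFrame:
    """Render one phantom frame at time ``t`` hours.

    With ``noise_sd == 0`` the background is exactly zero and the cell has
    exactly two (or, with an active ring, three) positive phase levels.
    ``fluctuations`` are per-knob relative offsets (used by the cohort
    simulator to add the normal-cell random walk consistently over time).
    """
    knobs = _knobs_at(spec, t, fluctuations)
    cell, central, ring = _cell_geometry(spec, knobs, grid_shape, pixel_size)
    phase = np.zeros(grid_shape, dtype=float)
    phase[cell] = knobs["peripheral_phase"]
    phase[central] = knobs["central_phase"]
    if knobs["ring_contrast"] > 0:
        phase[ring] += knobs["ring_contrast"]
    else:
        ring = np.zeros_like(ring)
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        phase = phase + rng.normal(0.0, spec.noise_sd, size=grid_shape)
    image = PhaseImage(phase, pixel_size, wavelength)
    return RenderedFrame(image, cell, central, ring)


def render_multi_cell_frame(
    specs: Sequence[CellPhantomSpec],
    t: float,
    grid_shape: tuple[int, int],
    pixel_size: float = 0.48,
    wavelength: float = 0.532,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[PhaseImage, np.ndarray]:
    """Render several phantoms into one field.

    Overlapping phase values combine by maximum (cells touching, not
    stacking), which produces thin necks between adjacent cells for
    watershed testing.  Returns the field and a ground-truth label map
    (later specs win overlapping pixels).
    """
    phase = np.zeros(grid_shape, dtype=float)
    labels = np.zeros(grid_shape, dtype=np.int32)
    for k, spec in enumerate(specs, start=1):
        noiseless = dataclasses.replace(spec, noise_sd=0.0)
        frame = render_cell_frame(noiseless, t, grid_shape, pixel_size, wavelength)
        phase = np.maximum(phase, frame.image.phase)
        labels[frame.cell_mask] = k
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        phase = phase + rng.normal(0.0, noise_sd, size=grid_shape)
    return PhaseImage(phase, pixel_size, wavelength), labels


def analytic_features(spec: CellPhantomSpec, t: float) -> dict[str, float]:
    """Closed-form expected feature values of a noiseless, ring-free phantom.

    Rasterization is ignored, so rendered-and-extracted features should
    agree with these to within a few percent.  Only features with an exact
    closed form are returned; ring-bearing phantoms additionally perturb the
    central statistics and are not covered.
    """
    k = _knobs_at(spec, t)
    area = np.pi * k["radius"] ** 2
    f = k["central_fraction"]
    c, p = k["central_phase"], k["peripheral_phase"]
    lam = 0.532  # informational only; optical volume is reported per unit lambda below
    return {
        "cell_area": area,
        "eccentricity": k["axis_ratio"],
        "circularity": k["circularity"],
        "mean_central_phase": c,
        "mean_peripheral_phase": p,
        "peripheral_to_central_ratio": p / c,
        "fried_egg_score": f,
        "phase_sd": float(np.sqrt(f * (1 - f)) * (c - p)),
        # multiply by (wavelength / 2 pi) to get micrometres^3
        "optical_volume_per_wavelength": area * (c * f + p * (1 - f)) / (2 * np.pi),
    }


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


#: Nominal class signatures: feature -> (amplitude, (gain_lo, gain_hi)).
#: Amplitudes are relative for the relative-kind features, additive in the
#: dimensionless features, and (for "nuclear_edge_score") the final nuclear
#: ring contrast as a multiple of the cell's mean phase.  Per-cell values
#: jitter +/-30 % around the nominal amplitude.
DEFAULT_SIGNATURES: dict[str, dict[str, tuple[float, tuple[float, float]]]] = {
    "necrotic": {
        "mean_central_phase": (-0.30, (1.0, 2.0)),
        "mean_peripheral_phase": (-0.20, (1.0, 2.0)),
        "cell_area": (+0.25, (1.0, 2.0)),
        "fried_egg_score": (-0.10, (1.0, 2.0)),
    },
    "apoptotic": {
        "nuclear_edge_score": (+0.50, (2.0, 4.0)),
        "circularity": (+0.15, (2.0, 4.0)),
        "eccentricity": (+0.08, (2.0, 4.0)),
        "cell_area": (+0.08, (2.0, 4.0)),
        "mean_central_phase": (-0.10, (2.0, 4.0)),
        "mean_peripheral_phase": (-0.05, (2.0, 4.0)),
        "fried_egg_score": (+0.05, (2.0, 4.0)),
    },
    "normal": {},
}


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the acquisition described for the real experiment
    (0.48 um pixels, 532 nm illumination, one frame every 6 min) and its
    cohort composition (149 normal, 103 apoptotic, 103 necrotic cells).
    """

    n_normal: int = 149
    n_apoptotic: int = 103
    n_necrotic: int = 103
    duration_h: float = 4.0
    interval_min: float = 6.0
    grid_shape: tuple[int, int] = (96, 96)
    pixel_size: float = 0.48  # micrometres
    wavelength: float = 0.532  # micrometres
    noise_sd: float = 0.02  # radians
    fluctuation_sd: float = 0.02  # relative, normal cells
    fluctuation_tau_h: float = 0.15  # mean-reversion time of the wobble
    jitter_sd: float = 0.01  # relative, iid per-frame measurement jitter
    radius_range: tuple[float, float] = (8.0, 12.0)  # micrometres
    central_fraction_range: tuple[float, float] = (0.15, 0.25)
    peripheral_phase_range: tuple[float, float] = (0.8, 1.2)  # radians
    central_phase_range: tuple[float, float] = (2.2, 3.0)  # radians
    axis_ratio_range: tuple[float, float] = (0.6, 0.95)
    circularity_range: tuple[float, float] = (0.75, 0.9)
    cutoff_range_h: tuple[float, float] = (1.0, 2.2)
    cutoff_lag_h: float = 0.8  # max per-feature onset delay
    amplitude_jitter: float = 0.3
    signatures: dict = field(default_factory=lambda: DEFAULT_SIGNATURES)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg._normalize()
        return cfg

    def _normalize(self) -> None:
        """Coerce YAML lists back to the tuples the dataclass declares."""
        self.grid_shape = tuple(self.grid_shape)  # type: ignore[assignment]
        for name in (
            "radius_range",
            "central_fraction_range",
            "peripheral_phase_range",
            "central_phase_range",
            "axis_ratio_range",
            "circularity_range",
            "cutoff_range_h",
        ):
            setattr(self, name, tuple(getattr(self, name)))
        self.signatures = {
            cls: {
                feat: (float(amp), tuple(gain_range))
                for feat, (amp, gain_range) in sig.items()
            }
            for cls, sig in self.signatures.items()
        }

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @property
    def timepoints_h(self) -> np.ndarray:
        n = int(round(self.duration_h * 60.0 / self.interval_min)) + 1
        return np.arange(n) * self.interval_min / 60.0


def sample_phantom(
    class_label: str, rng: np.random.Generator, config: CohortConfig, seed: int = 0
) -> CellPhantomSpec:
    """Draw one phantom recipe for the given class."""
    cfg = config
    u = rng.uniform
    h, w = cfg.grid_shape
    center = (
        (w / 2 + u(-2.0, 2.0)) * cfg.pixel_size,
        (h / 2 + u(-2.0, 2.0)) * cfg.pixel_size,
    )
    peripheral = u(*cfg.peripheral_phase_range)
    central = u(*cfg.central_phase_range)
    fraction = u(*cfg.central_fraction_range)
    mean_phase = central * fraction + peripheral * (1 - fraction)
    dynamics: dict[str, SigmoidParams] = {}
    if class_label != "normal":
        t0 = u(*cfg.cutoff_range_h)
        for feat, (amp0, gain_range) in cfg.signatures[class_label].items():
            amp = amp0 * u(1 - cfg.amplitude_jitter, 1 + cfg.amplitude_jitter)
            if feat == "nuclear_edge_score":
                amp *= mean_phase  # final ring contrast in radians
            gain = u(*gain_range)
            cutoff = t0 + u(0.0, cfg.cutoff_lag_h)
            dynamics[feat] = SigmoidParams(amp, gain, cutoff)
    return CellPhantomSpec(
        class_label=class_label,
        center=center,
        initial_radius=u(*cfg.radius_range),
        central_fraction=fraction,
        peripheral_phase=peripheral,
        central_phase=central,
        axis_ratio=u(*cfg.axis_ratio_range),
        orientation=u(0.0, np.pi),
        circularity0=u(*cfg.circularity_range),
        dynamics=dynamics,
        noise_sd=cfg.noise_sd,
        fluctuation_sd=cfg.fluctuation_sd,
        seed=seed,
    )


def _ou_path(
    rng: np.random.Generator, n: int, sd: float, tau_h: float, dt_h: float
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path: sd is the marginal sd."""
    if sd <= 0:
        return np.zeros(n)
    rho = np.exp(-dt_h / tau_h)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=n - 1)
    for k in range(1, n):
        x[k] = rho * x[k - 1] + innov[k - 1]
    return x


@dataclass
class SimulatedCell:
    """One simulated cell: recipe, movie and per-frame ground truth."""

    cell_id: int
    spec: CellPhantomSpec
    stack: TimeLapseStack | None
    cell_masks: list[np.ndarray] | None
    central_masks: list[np.ndarray] | None
    ring_masks: list[np.ndarray] | None


def simulate_cell(
    cell_id: int,
    spec: CellPhantomSpec,
    config: CohortConfig,
    render: bool = True,
) -> SimulatedCell:
    """Render one phantom across all time points of the configured movie."""
    times = config.timepoints_h
    if not render:
        return SimulatedCell(cell_id, spec, None, None, None, None)
    rng = np.random.default_rng(spec.seed)
    fluct_paths: dict[str, np.ndarray] = {}
    for name in _FLUCTUATING:
        # slow homeostatic wander (normal cells only, D-style zero-amplitude
        # dynamics) plus fast iid frame-to-frame measurement jitter that the
        # uniform-level phantom otherwise lacks (all classes)
        path = np.zeros(len(times))
        if spec.class_label == "normal" and spec.fluctuation_sd > 0:
            path = _ou_path(
                rng,
                len(times),
                spec.fluctuation_sd,
                config.fluctuation_tau_h,
                config.interval_min / 60.0,
            )
        if config.jitter_sd > 0:
            path = path + rng.normal(0.0, config.jitter_sd, size=len(times))
        if np.any(path):
            fluct_paths[name] = path
    frames, cmasks, nmasks, rmasks = [], [], [], []
    for i, t in enumerate(times):
        fl = {name: path[i] for name, path in fluct_paths.items()}
        fr = render_cell_frame(
            spec,
            t,
            config.grid_shape,
            config.pixel_size,
            config.wavelength,
            rng=rng,
            fluctuations=fl,
        )
        frames.append(fr.image)
        cmasks.append(fr.cell_mask)
        nmasks.append(fr.central_mask)
        rmasks.append(fr.ring_mask)
    stack = TimeLapseStack(frames, interval=config.interval_min)
    return SimulatedCell(cell_id, spec, stack, cmasks, nmasks, rmasks)


def _truth_row(cell_id: int, spec: CellPhantomSpec) -> dict:
    row = {
        "cell_id": cell_id,
        "class_label": spec.class_label,
        "initial_radius_um": spec.initial_radius,
        "central_fraction": spec.central_fraction,
        "peripheral_phase_rad": spec.peripheral_phase,
        "central_phase_rad": spec.central_phase,
        "axis_ratio": spec.axis_ratio,
        "circularity0": spec.circularity0,
        "seed": spec.seed,
    }
    for feat in _DRIVABLE:
        p = spec.dynamics.get(feat)
        row[f"true_amplitude_{feat}"] = p.amplitude if p else 0.0
        row[f"true_gain_{feat}"] = p.gain if p else 0.0
        row[f"true_cutoff_{feat}"] = p.cutoff if p else np.nan
    return row


def simulate_cohort(
    n_normal: int | None = None,
    n_apoptotic: int | None = None,
    n_necrotic: int | None = None,
    duration_h: float | None = None,
    interval_min: float | None = None,
    seed: int | None = None,
    config: CohortConfig | None = None,
    render: bool = True,
) -> tuple[list[SimulatedCell], pd.DataFrame]:
    """Simulate a labelled cohort of single-cell phantom movies.

    One movie per cell (cells are analysed individually; multi-cell fields
    are available separately for segmentation/tracking tests).  Returns the
    cells and a ground-truth table with one row per cell holding the class
    label and every true sigmoid parameter.  Fully reproducible from
    ``seed``; with ``render=False`` only recipes and the truth table are
    produced (cheap for large cohorts).
    """
    cfg = dataclasses.replace(config) if config is not None else CohortConfig()
    if n_normal is not None:
        cfg.n_normal = n_normal
    if n_apoptotic is not None:
        cfg.n_apoptotic = n_apoptotic
    if n_necrotic is not None:
        cfg.n_necrotic = n_necrotic
    if duration_h is not None:
        cfg.duration_h = duration_h
    if interval_min is not None:
        cfg.interval_min = interval_min
    if seed is not None:
        cfg.seed = seed
    if min(cfg.n_normal, cfg.n_apoptotic, cfg.n_necrotic) < 0:
        raise ValueError("cohort counts must be non-negative")
    if cfg.duration_h * 60.0 < 13 * cfg.interval_min - cfg.interval_min:
        raise ValueError(
            "movie shorter than the 13-point fitting window; increase duration"
        )
    labels = (
        ["normal"] * cfg.n_normal
        + ["apoptotic"] * cfg.n_apoptotic
        + ["necrotic"] * cfg.n_necrotic
    )
    root = np.random.default_rng(cfg.seed)
    cells: list[SimulatedCell] = []
    rows: list[dict] = []
    for cell_id, label in enumerate(labels):
        cell_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(cell_seed)
        spec = sample_phantom(label, rng, cfg, seed=cell_seed)
        cells.append(simulate_cell(cell_id, spec, cfg, render=render))
        rows.append(_truth_row(cell_id, spec))
    truth = pd.DataFrame(rows)
    return cells, truth


def write_cohort(outdir: str | Path, cells: Sequence[SimulatedCell], truth: pd.DataFrame) -> None:
    """Write cell movies as float TIFF stacks, masks and the truth CSV."""
    from .core import write_label_tiff

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth.to_csv(out / "ground_truth.csv", index=False)
    for cell in cells:
        if cell.stack is None:
            continue
        cell.stack.write_tiff(out / f"cell_{cell.cell_id:04d}.tif")
        write_label_tiff(
            out / f"cell_{cell.cell_id:04d}_mask.tif",
            [m.astype(np.uint16) for m in cell.cell_masks],
        )
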