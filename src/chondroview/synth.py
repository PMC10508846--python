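"""Synthetic micrograph and trace generation with exact ground truth.

Every downstream quantification stage (viability imaging, calcium trace
scoring, immunofluorescence integrated density) is testable against these
generators without any real microscopy data. The generators emulate:

* disc-shaped chondrocytes scattered over a cap-shaped field (the convex
  apex of a humeral head pressed against a glass dish), imaged as a small
  Z-stack with per-plane defocus, in two channels — calcein-AM (live) and
  ethidium homodimer-1 (dead);
* a focal impact that flips cells inside a circular region to the dead
  state with some probability, plus a rigid translation of the post-impact
  frame to exercise region-of-interest registration;
* Fura-2 style ratiometric traces: white-noise baseline plus, for a
  random subset of responder cells, an agonist-evoked transient of known
  amplitude;
* immunofluorescence fields of elliptical cells in two anatomical
  compartments (humeral / glenoid) with per-cell intensity drawn from
  compartment-specific normal distributions.

Determinism contract: every generator draws from ``numpy`` Generators
seeded as ``default_rng([seed, stream])`` with fixed stream numbers
(0 = placement, 1 = state/label draws, 2 = noise, 3 = shape/intensity),
so identical specs produce byte-identical outputs and any individual
random decision can be replayed independently.

Cells are rendered as uniform-intensity discs (ellipses in IF fields,
to exercise the circularity filter); noise is additive Gaussian clipped
at zero. Neither partial live/dead transitions nor photophysics are
modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .calcium import TraceSet
from .stack import MicrographStack

# random stream indices; see module docstring
_STREAM_PLACE, _STREAM_STATE, _STREAM_NOISE, _STREAM_SHAPE = 0, 1, 2, 3


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement cannot be satisfied."""


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Geometry and photometry of a simulated confocal field.

    Units: lengths in μm except ``width``/``height`` (pixels); intensities
    in arbitrary units. ``cap_mask``, if given, is a boolean (height,
    width) array restricting cell centers — it models the exclusion of
    cells outside the spherical cap of the humeral head.
    """

    width: int = 512
    height: int = 512
    pixel_size: float = 0.5          # μm / pixel
    n_cells: int = 60
    cell_radius_range: tuple[float, float] = (4.0, 7.0)   # μm
    cap_mask: np.ndarray | None = None
    background_level: float = 10.0
    cell_level: float = 200.0
    noise_sd: float = 8.0
    n_planes: int = 5
    defocus_per_plane: float = 1.2   # px of Gaussian sigma per plane away from focus
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad cell_radius_range {self.cell_radius_range}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.cap_mask is not None:
            self.cap_mask = np.asarray(self.cap_mask, dtype=bool)
            if self.cap_mask.shape != (self.height, self.width):
                raise ValueError("cap_mask shape must be (height, width)")


@dataclass
class ImpactSpec:
    """A pre/post impact experiment on one field.

    The impact flips each cell to the dead state with probability
    ``death_probability_inside`` if its center lies within
    ``impact_radius`` (μm) of ``impact_center`` (pixel row, col), else
    ``death_probability_outside``. ``post_shift`` is an integer (dy, dx)
    pixel translation applied to the post-impact frame.
    """

    field: FieldSpec = field(default_factory=FieldSpec)
    impact_center: tuple[float, float] | None = None   # (row, col) px; None = field center
    impact_radius: float = 60.0                        # μm
    death_probability_inside: float = 0.8
    death_probability_outside: float = 0.02
    post_shift: tuple[int, int] = (0, 0)               # (dy, dx) px

    def center(self) -> tuple[float, float]:
        """Impact center in pixels; defaults to the center of the field.

        Resolved lazily so that replacing the field on a spec (e.g. a
        config override) re-centers a default impact automatically.
        """
        if self.impact_center is not None:
            return tuple(self.impact_center)
        return (self.field.height / 2.0, self.field.width / 2.0)

    def __post_init__(self) -> None:
        for p in (self.death_probability_inside, self.death_probability_outside):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"death probability {p} outside [0, 1]")
        if self.field.cap_mask is not None:
            row, col = self.center()
            rr, cc = np.nonzero(self.field.cap_mask)
            r_px = self.impact_radius / self.field.pixel_size
            d2 = (rr - row) ** 2 + (cc - col) ** 2
            if not np.any(d2 <= r_px**2):
                raise ValueError("impact region does not intersect the cap mask")


@dataclass
class TraceSimSpec:
    """Simulated ratiometric trace experiment.

    Defaults mirror the assay design: a 6-minute recording sampled at
    1 Hz, agonist added at 1 minute, responder transients peaking
    ``response_amplitude_in_sd`` baseline SDs above the resting level.
    Concentrations are in nM.
    """

    n_cells: int = 100
    duration: float = 360.0          # s
    sample_interval: float = 1.0     # s
    baseline_mean: float = 100.0     # nM
    baseline_sd: float = 5.0         # nM (also the trace noise SD)
    treatment_time: float = 60.0     # s
    responder_fraction: float = 0.7
    response_amplitude_in_sd: float = 8.0
    response_shape: tuple[float, float] = (5.0, 30.0)   # (rise s, decay s)
    sd_floor: float = 0.5            # nM; amplitude reference when baseline_sd ~ 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if not self.treatment_time < self.duration:
            raise ValueError("treatment_time must precede duration")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction outside [0, 1]")


@dataclass
class IFFieldSpec:
    """Simulated immunofluorescence field with two anatomical compartments.

    The left half of the field is the humeral compartment, the right half
    glenoid. Per-cell signal intensity is drawn from the compartment's
    normal distribution; cell outlines are ellipses whose target
    circularity (4πA/P²) is drawn uniformly from ``circularity_range``.
    Background is zero by default so that each cell's true integrated
    density is exactly intensity × pixel area.
    """

    n_cells_humeral: int = 25
    n_cells_glenoid: int = 25
    intensity_humeral: tuple[float, float] = (100.0, 15.0)   # (mean, sd)
    intensity_glenoid: tuple[float, float] = (100.0, 15.0)
    circularity_range: tuple[float, float] = (0.85, 1.0)
    width: int = 512
    height: int = 512
    pixel_size: float = 0.5
    cell_radius_range: tuple[float, float] = (4.0, 7.0)      # μm, equivalent-area radius
    background_level: float = 0.0
    noise_sd: float = 2.0
    nucleus_radius: float = 2.0                               # μm
    nucleus_level: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.circularity_range
        if not (0 < lo <= hi <= 1.0):
            raise ValueError(f"circularity_range {self.circularity_range} outside (0, 1]")
        if self.n_cells_humeral < 0 or self.n_cells_glenoid < 0:
            raise ValueError("cell counts must be >= 0")


# --------------------------------------------------------------------------
# truth records
# --------------------------------------------------------------------------

@dataclass
class CellTruth:
    row: float
    col: float
    radius_um: float
    pre_state: str
    post_state: str
    inside_impact: bool

    @property
    def true_area_um2(self) -> float:
        return float(np.pi * self.radius_um**2)


@dataclass
class ImpactTruth:
    cells: list[CellTruth]
    impact_center: tuple[float, float]
    impact_radius_um: float
    post_shift: tuple[int, int]
    seed: int

    def n_dead_post(self) -> int:
        return sum(c.post_state == "dead" for c in self.cells)

    def true_death_area_um2(self) -> float:
        """Summed analytic areas (πr²) of cells newly dead after impact."""
        return float(
            sum(
                c.true_area_um2
                for c in self.cells
                if c.post_state == "dead" and c.pre_state == "live"
            )
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "impact_center": list(self.impact_center),
            "impact_radius_um": self.impact_radius_um,
            "post_shift": list(self.post_shift),
            "seed": self.seed,
            "cells": [asdict(c) for c in self.cells],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


@dataclass
class IFCellTruth:
    row: float
    col: float
    a_px: float                # semi-major axis, px
    b_px: float                # semi-minor axis, px
    theta: float               # orientation, rad
    intensity: float
    area_px: int               # rasterized pixel count
    integrated_density: float  # intensity * area_px (noise-free signal sum)
    compartment: str           # "humeral" | "glenoid"


@dataclass
class IFTruth:
    cells: list[IFCellTruth]
    compartment_masks: dict[str, np.ndarray]
    seed: int

    def compartment_mean_density(self, compartment: str) -> float:
        vals = [c.integrated_density for c in self.cells if c.compartment == compartment]
        return float(np.mean(vals)) if vals else float("nan")


# --------------------------------------------------------------------------
# placement and rendering
# --------------------------------------------------------------------------

def _place_cells(
    rng: np.random.Generator,
    n_cells: int,
    shape: tuple[int, int],
    radius_px_range: tuple[float, float],
    cap_mask: np.ndarray | None,
    margin_px: float = 2.0,
    max_attempts_per_cell: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping disc centers and radii (pixels).

    Overlap rule: center distance must exceed the sum of radii. Raises
    :class:`PlacementError` naming the constraint if a cell cannot be
    placed within the attempt budget.
    """
    h, w = shape
    centers = np.empty((0, 2))
    radii = np.empty(0)
    for i in range(n_cells):
        r = rng.uniform(*radius_px_range)
        for _ in range(max_attempts_per_cell):
            row = rng.uniform(r + margin_px, h - r - margin_px)
            col = rng.uniform(r + margin_px, w - r - margin_px)
            if cap_mask is not None and not cap_mask[int(row), int(col)]:
                continue
            if centers.size:
                d = np.hypot(centers[:, 0] - row, centers[:, 1] - col)
                if np.any(d <= radii + r):
                    continue
            centers = np.vstack([centers, [row, col]])
            radii = np.append(radii, r)
            break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{n_cells} without overlap "
                f"(center distance must exceed sum of radii) within "
                f"{max_attempts_per_cell} attempts; reduce n_cells or cell radii"
            )
    return centers, radii


def render_discs(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii_px: np.ndarray,
    level: float,
    background: float = 0.0,
    intensities: np.ndarray | None = None,
) -> np.ndarray:
    """Rasterize uniform discs: pixel centers within radius get the cell level."""
    img = np.full(shape, float(background))
    h, w = shape
    for i, ((row, col), r) in enumerate(zip(np.atleast_2d(centers), np.atleast_1d(radii_px))):
        lvl = level if intensities is None else float(intensities[i])
        r0, r1 = max(0, int(row - r) - 1), min(h, int(row + r) + 2)
        c0, c1 = max(0, int(col - r) - 1), min(w, int(col + r) + 2)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        mask = (yy - row) ** 2 + (xx - col) ** 2 <= r**2
        img[r0:r1, c0:c1][mask] = lvl
    return img


def ellipse_mask(
    shape: tuple[int, int], row: float, col: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Boolean mask of a rotated ellipse (semi-axes a, b px; rotation theta rad)."""
    h, w = shape
    r = max(a, b)
    r0, r1 = max(0, int(row - r) - 1), min(h, int(row + r) + 2)
    c0, c1 = max(0, int(col - r) - 1), min(w, int(col + r) + 2)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - row, xx - col
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def make_zstack(
    plane: np.ndarray, n_planes: int, defocus_per_plane: float
) -> np.ndarray:
    """Emulate a Z-stack: Gaussian defocus grows away from the focal plane.

    With an odd ``n_planes`` the central plane is unblurred, so the
    maximum-intensity projection recovers the sharp image exactly.
    """
    focus = (n_planes - 1) / 2.0
    planes = []
    for k in range(n_planes):
        sigma = defocus_per_plane * abs(k - focus)
        planes.append(plane if sigma == 0 else ndimage.gaussian_filter(plane, sigma))
    return np.stack(planes)


def _add_noise(stack: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd <= 0:
        return stack
    return np.clip(stack + rng.normal(0.0, noise_sd, size=stack.shape), 0.0, None)


def disc_cap_mask(
    height: int, width: int, radius_fraction: float = 0.45
) -> np.ndarray:
    """Centered circular mask emulating the spherical cap of the humeral head."""
    yy, xx = np.mgrid[0:height, 0:width]
    r = radius_fraction * min(height, width)
    return (yy - height / 2.0) ** 2 + (xx - width / 2.0) ** 2 <= r**2


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def render_impact_frames(
    fs: FieldSpec, truth: ImpactTruth
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (channels, h, w) sharp frames for pre and post from a truth record.

    This is the rasterization the truth-consistency invariant checks: the
    generator and any replay of the truth go through this single path.
    """
    shape = (fs.height, fs.width)
    centers = np.array([[c.row, c.col] for c in truth.cells]).reshape(-1, 2)
    radii = np.array([c.radius_um for c in truth.cells]) / fs.pixel_size
    pre_live = np.array([c.pre_state == "live" for c in truth.cells], dtype=bool)

    def frame(live_mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
        dy, dx = offset
        ctr = centers + np.array([dy, dx], dtype=float)
        live = render_discs(shape, ctr[live_mask], radii[live_mask],
                            fs.cell_level, fs.background_level)
        dead = render_discs(shape, ctr[~live_mask], radii[~live_mask],
                            fs.cell_level, fs.background_level)
        return np.stack([live, dead])

    pre = frame(pre_live, (0, 0))
    post_live = np.array([c.post_state == "live" for c in truth.cells], dtype=bool)
    post = frame(post_live, truth.post_shift)
    return pre, post


def generate_impact_pair(
    spec: ImpactSpec,
) -> tuple[MicrographStack, MicrographStack, ImpactTruth]:
    """Simulate one pre/post impact micrograph pair.

    All cells start live; after the impact each cell is dead with the
    probability set by its position relative to the impact region. Death
    states are drawn as ``default_rng([seed, 1]).random(n) < p_cell`` in
    placement order, so they can be replayed independently.
    """
    fs = spec.field
    place_rng = np.random.default_rng([fs.seed, _STREAM_PLACE])
    state_rng = np.random.default_rng([fs.seed, _STREAM_STATE])
    noise_rng = np.random.default_rng([fs.seed, _STREAM_NOISE])

    r_px_range = tuple(r / fs.pixel_size for r in fs.cell_radius_range)
    centers, radii_px = _place_cells(
        place_rng, fs.n_cells, (fs.height, fs.width), r_px_range, fs.cap_mask
    )

    impact_r_px = spec.impact_radius / fs.pixel_size
    impact_center = spec.center()
    d = np.hypot(centers[:, 0] - impact_center[0],
                 centers[:, 1] - impact_center[1]) if len(centers) else np.empty(0)
    inside = d <= impact_r_px
    p = np.where(inside, spec.death_probability_inside, spec.death_probability_outside)
    dead = state_rng.random(fs.n_cells) < p

    cells = [
        CellTruth(
            row=float(centers[i, 0]),
            col=float(centers[i, 1]),
            radius_um=float(radii_px[i] * fs.pixel_size),
            pre_state="live",
            post_state="dead" if dead[i] else "live",
            inside_impact=bool(inside[i]),
        )
        for i in range(fs.n_cells)
    ]
    truth = ImpactTruth(
        cells=cells,
        impact_center=impact_center,
        impact_radius_um=spec.impact_radius,
        post_shift=tuple(spec.post_shift),
        seed=fs.seed,
    )

    pre_sharp, post_sharp = render_impact_frames(fs, truth)

    def to_stack(sharp: np.ndarray) -> MicrographStack:
        planes = np.stack(
            [make_zstack(sharp[c], fs.n_planes, fs.defocus_per_plane)
             for c in range(sharp.shape[0])],
            axis=1,
        )  # (planes, channels, h, w)
        planes = _add_noise(planes, fs.noise_sd, noise_rng)
        return MicrographStack(planes, ("live", "dead"), fs.pixel_size)

    return to_stack(pre_sharp), to_stack(post_sharp), truth


def response_profile(
    time: np.ndarray, treatment_time: float, rise: float, decay: float
) -> np.ndarray:
    """Unit-peak agonist transient: (1 − e^(−τ/rise)) e^(−τ/decay), τ = t − t₀.

    Normalized by its maximum on the sampled grid so a responder's
    noise-free sampled peak equals the nominal amplitude exactly.
    """
    tau = np.asarray(time, dtype=float) - treatment_time
    s = np.where(tau > 0, (1.0 - np.exp(-np.maximum(tau, 0) / rise))
                 * np.exp(-np.maximum(tau, 0) / decay), 0.0)
    m = s.max()
    return s / m if m > 0 else s


def generate_traces(spec: TraceSimSpec) -> tuple[TraceSet, np.ndarray]:
    """Simulate a trace set; returns ``(traces, responder_labels)``.

    Responder labels are drawn as
    ``default_rng([seed, 1]).random(n_cells) < responder_fraction``.
    The transient amplitude is ``response_amplitude_in_sd × max(baseline_sd,
    sd_floor)`` — the floor keeps the amplitude defined in the degenerate
    zero-noise limit.

    Baseline fluctuation is *bounded* white noise: uniform on
    ±√3·``baseline_sd`` (so its SD is exactly ``baseline_sd``). Resting
    ratiometric traces fluctuate within a band set by the readout
    resolution rather than with Gaussian tails, and boundedness is the
    regime in which a raw-peak-over-k·SD responder criterion is
    statistically meaningful — the maximum of hundreds of independent
    Gaussian deviations would exceed 3 SD in a large fraction of
    resting cells.
    """
    label_rng = np.random.default_rng([spec.seed, _STREAM_STATE])
    noise_rng = np.random.default_rng([spec.seed, _STREAM_NOISE])

    time = np.arange(0.0, spec.duration, spec.sample_interval)
    responders = label_rng.random(spec.n_cells) < spec.responder_fraction
    amplitude = spec.response_amplitude_in_sd * max(spec.baseline_sd, spec.sd_floor)
    profile = response_profile(time, spec.treatment_time, *spec.response_shape)

    half_width = np.sqrt(3.0) * spec.baseline_sd
    values = np.full((time.size, spec.n_cells), spec.baseline_mean)
    values = values + noise_rng.uniform(-half_width, half_width, size=values.shape)
    values[:, responders] += amplitude * profile[:, None]

    traces = TraceSet(time=time, values=values, treatment_time=spec.treatment_time)
    return traces, responders


_Q_GRID = np.linspace(0.05, 1.0, 400)


def _ellipse_circularity(q: np.ndarray) -> np.ndarray:
    """Analytic circularity 4πA/P² of an ellipse with axis ratio q = b/a.

    Perimeter by Ramanujan's first approximation.
    """
    a, b = 1.0, q
    p = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    return 4 * np.pi * (np.pi * a * b) / p**2


_CIRC_OF_Q = _ellipse_circularity(_Q_GRID)


def axis_ratio_for_circularity(c: float) -> float:
    """Invert circularity → ellipse axis ratio b/a (monotone interpolation)."""
    return float(np.interp(c, _CIRC_OF_Q, _Q_GRID))


def generate_if_field(spec: IFFieldSpec) -> tuple[MicrographStack, IFTruth]:
    """Simulate an immunofluorescence field with compartment ground truth.

    Returns a two-channel single-plane stack (``expression``, ``nuclei``)
    and a truth record whose per-cell integrated density is the exact
    noise-free signal sum (intensity × rasterized pixel count).
    """
    place_rng = np.random.default_rng([spec.seed, _STREAM_PLACE])
    noise_rng = np.random.default_rng([spec.seed, _STREAM_NOISE])
    shape_rng = np.random.default_rng([spec.seed, _STREAM_SHAPE])

    shape = (spec.height, spec.width)
    half = spec.width // 2
    masks = {
        "humeral": np.zeros(shape, dtype=bool),
        "glenoid": np.zeros(shape, dtype=bool),
    }
    masks["humeral"][:, :half] = True
    masks["glenoid"][:, half:] = True

    r_px_range = tuple(r / spec.pixel_size for r in spec.cell_radius_range)
    margin = r_px_range[1] + 2

    expression = np.full(shape, float(spec.background_level))
    nuclei = np.zeros(shape)
    cells: list[IFCellTruth] = []
    placed_centers: list[tuple[float, float]] = []
    placed_radii: list[float] = []

    plan = [("humeral", spec.n_cells_humeral, spec.intensity_humeral, (0, half)),
            ("glenoid", spec.n_cells_glenoid, spec.intensity_glenoid, (half, spec.width))]
    for compartment, n, (mu, sd), (c_lo, c_hi) in plan:
        for i in range(n):
            r_eq = shape_rng.uniform(*r_px_range)          # equivalent-area radius, px
            circ = shape_rng.uniform(*spec.circularity_range)
            q = axis_ratio_for_circularity(circ)
            a = r_eq / np.sqrt(q)                           # preserve area πab = πr²
            b = r_eq * np.sqrt(q)
            theta = shape_rng.uniform(0, np.pi)
            intensity = max(float(shape_rng.normal(mu, sd)), 1.0)
            for _ in range(500):
                row = place_rng.uniform(margin, spec.height - margin)
                col = place_rng.uniform(max(c_lo + margin, margin),
                                        min(c_hi - margin, spec.width - margin))
                if placed_centers:
                    pc = np.asarray(placed_centers)
                    d = np.hypot(pc[:, 0] - row, pc[:, 1] - col)
                    if np.any(d <= np.asarray(placed_radii) + a):
                        continue
                break
            else:
                raise PlacementError(
                    f"could not place {compartment} cell {i + 1}/{n} without overlap "
                    "within 500 attempts; reduce counts or radii"
                )
            placed_centers.append((row, col))
            placed_radii.append(a)
            mask = ellipse_mask(shape, row, col, a, b, theta)
            expression[mask] = intensity
            nuc = ellipse_mask(shape, row, col,
                               spec.nucleus_radius / spec.pixel_size,
                               spec.nucleus_radius / spec.pixel_size, 0.0)
            nuclei[nuc] = spec.nucleus_level
            area = int(mask.sum())
            cells.append(
                IFCellTruth(
                    row=float(row), col=float(col),
                    a_px=float(a), b_px=float(b), theta=float(theta),
                    intensity=intensity,
                    area_px=area,
                    integrated_density=intensity * area,
                    compartment=compartment,
                )
            )

    data = np.stack([expression, nuclei])[None]  # (1, 2, h, w)
    data = _add_noise(data, spec.noise_sd, noise_rng)
    stack = MicrographStack(data, ("expression", "nuclei"), spec.pixel_size)
    return stack, IFTruth(cells=cells, compartment_masks=masks, seed=spec.seed)
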