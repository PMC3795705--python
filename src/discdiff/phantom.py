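"""Synthetic post-contrast spine phantom with known transport ground truth.

The generator emulates the measurement situation of a serial post-contrast
lumbar MRI protocol: a vascularized vertebral compartment whose contrast
concentration follows a blood-pool curve that peaks shortly after injection
and then decays with renal clearance, an avascular disc into which the
agent penetrates from both endplates by diffusion, an optional perfusion
source for vascularized (Modic-change / irregular-endplate) discs, a
bright CSF band on the T2 image, and additive Gaussian pixel noise.

Each synthetic "subject" carries one disc rendered on its own image grid:
one T1 slice per acquisition time point (PRE plus five post-contrast
points at 5 min, 10 min, 2 h, 4 h and 6 h by default) and one T2 slice.
Ground truth — landmark coordinates, layer masks, the continuous
concentration field c(x, t) and the generating kinetic parameters — is
emitted alongside, so segmentation, quantification and the cohort
statistics can all be validated without patient data.

Model summary
-------------
Blood pool:  C_b(t) = A (exp(-t/tau_e) - exp(-t/tau_a)),  tau_a < tau_e.
Disc:        dc/dt = D d2c/dx2 + v (C_b(t) - c)  on x in [0, h],
             with Robin endplate boundaries
             -D dc/dx|_0 = P (C_b - c(0)),  +D dc/dx|_h = -P (C_b - c(h)),
             c(x, 0) = 0.
Signal:      T1 intensity = baseline + alpha * concentration + noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .segmentation import LandmarkSet, build_disc_rois

__all__ = [
    "KineticsParams",
    "DiscSpec",
    "PhantomConfig",
    "GroundTruth",
    "ImageSeries",
    "PhantomCohort",
    "DiffusionSolution",
    "DEFAULT_TIME_POINTS",
    "minutes_to_label",
    "simulate_blood_curve",
    "blood_peak_time",
    "solve_disc_diffusion",
    "render_series",
    "generate_cohort",
]

#: Acquisition schedule in minutes: PRE, 5 min, 10 min, 2 h, 4 h, 6 h.
DEFAULT_TIME_POINTS = (0.0, 5.0, 10.0, 120.0, 240.0, 360.0)

_CANONICAL_LABELS = {
    0.0: "PRE",
    5.0: "POST_5MIN",
    10.0: "POST_10MIN",
    120.0: "POST_2H",
    240.0: "POST_4H",
    360.0: "POST_6H",
}


def minutes_to_label(t: float) -> str:
    """Canonical time-point label for a time in minutes."""
    if t in _CANONICAL_LABELS:
        return _CANONICAL_LABELS[t]
    if t == 0:
        return "PRE"
    if t < 60 or t % 60:
        return f"POST_{t:g}MIN"
    return f"POST_{t / 60:g}H"


@dataclass(frozen=True)
class KineticsParams:
    """Contrast kinetics of one disc and its adjacent blood pool.

    Parameters
    ----------
    blood_amplitude : A, arbitrary concentration units; scales C_b(t).
    uptake_time : tau_a (min), blood-pool rise time after injection.
    decay_time : tau_e (min), clearance time constant; must exceed tau_a.
    diffusivity : D (mm^2/min), apparent diffusivity of the agent in disc
        tissue.
    endplate_permeability : P (mm/min), Robin transfer coefficient of the
        endplates.
    perfusion_rate : v (1/min), volumetric exchange with blood inside the
        disc; 0 for an avascular disc, positive for vascularized
        (Modic-change / irregular-endplate) discs.
    signal_gain : alpha, T1 signal units per concentration unit.
    """

    blood_amplitude: float = 1.0
    uptake_time: float = 1.0
    decay_time: float = 120.0
    diffusivity: float = 0.012
    endplate_permeability: float = 0.04
    perfusion_rate: float = 0.0
    signal_gain: float = 260.0

    def __post_init__(self) -> None:
        for name in ("blood_amplitude", "uptake_time", "decay_time",
                     "diffusivity", "endplate_permeability", "perfusion_rate",
                     "signal_gain"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if self.uptake_time >= self.decay_time:
            raise ValueError("uptake_time must be < decay_time (rise then decay)")
        for name in ("blood_amplitude", "diffusivity", "endplate_permeability",
                     "perfusion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class DiscSpec:
    """Morphology and radiological status of one synthetic disc."""

    height_mm: float = 10.0
    ap_width_mm: float = 38.0
    pfirrmann: int = 1
    hydration: float = 1.0  # in [0, 1]; drives T2 brightness
    mc_upper: str = "0"  # one of {"0", "I", "II", "I/II"}
    mc_lower: str = "0"
    defect_upper: bool = False
    defect_lower: bool = False
    irregular: bool = False
    spondylolisthesis: bool = False

    def __post_init__(self) -> None:
        if self.height_mm <= 0:
            raise ValueError("height_mm must be positive")
        if not 0.0 <= self.hydration <= 1.0:
            raise ValueError("hydration must lie in [0, 1]")
        if self.pfirrmann not in (1, 2, 3, 4, 5):
            raise ValueError("pfirrmann grade must be in 1..5")
        for mc in (self.mc_upper, self.mc_lower):
            if mc not in ("0", "I", "II", "I/II"):
                raise ValueError(f"unknown Modic type {mc!r}")

    @property
    def has_mc(self) -> bool:
        return self.mc_upper != "0" or self.mc_lower != "0"


@dataclass(frozen=True)
class PhantomConfig:
    """Global phantom settings (grid, schedule, intensities, noise)."""

    grid_shape: tuple[int, int] = (96, 96)
    pixel_spacing: float = 0.83  # mm / pixel
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    noise_sd: float = 60.0  # per-pixel Gaussian sigma, signal units
    baseline: float = 99.0  # PRE T1 intensity inside disc and vertebra
    background: float = 60.0  # T1 intensity outside anatomy
    csf_columns: tuple[int, int] = (68, 76)  # half-open column band
    csf_t2_intensity: float = 250.0
    csf_t1_intensity: float = 30.0
    t2_background: float = 40.0
    t2_disc_gain: float = 180.0  # disc T2 = t2_background + gain * hydration
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    n_nodes: int = 61
    dt: float = 0.5  # solver time step, minutes
    seed: int = 0
    discs: tuple[DiscSpec, ...] = ()

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points)
        object.__setattr__(self, "time_points", tp)
        if len(tp) < 2 or tp[0] != 0.0 or np.any(np.diff(tp) <= 0):
            raise ValueError("time_points must be strictly increasing, starting at 0")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def time_labels(self) -> tuple[str, ...]:
        return tuple(minutes_to_label(t) for t in self.time_points)


@dataclass
class DiffusionSolution:
    """Concentration field c(x, t) on a uniform node grid over [0, h]."""

    x: np.ndarray  # node positions, mm, x[0]=0, x[-1]=h
    times: np.ndarray  # output times, minutes
    c: np.ndarray  # shape (len(times), len(x))

    @property
    def height(self) -> float:
        return float(self.x[-1])

    def at_depth(self, depth: np.ndarray, time_index: int) -> np.ndarray:
        """Interpolate the field at arbitrary depths (mm) for one time."""
        return np.interp(depth, self.x, self.c[time_index])

    def band_mean(self, u_lo: float, u_hi: float, time_index: int,
                  n_samples: int = 201) -> float:
        """Mean concentration over the normalized-depth band [u_lo, u_hi]."""
        u = np.linspace(u_lo, u_hi, n_samples)
        return float(np.mean(self.at_depth(u * self.height, time_index)))


@dataclass
class ImageSeries:
    """One synthetic subject: T1 slice per time point plus one T2 slice."""

    disc_id: str
    times: tuple[float, ...]
    images: dict[str, np.ndarray]  # keyed by time label, PRE included
    t2: np.ndarray
    pixel_spacing: float

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(minutes_to_label(t) for t in self.times)


@dataclass
class GroundTruth:
    """Everything the generator knows about one disc."""

    disc_id: str
    spec: DiscSpec
    params: KineticsParams
    landmarks: LandmarkSet
    masks: dict[str, np.ndarray]
    field: DiffusionSolution
    csf_rect: tuple[int, int]  # top-left (row, col) of the 5x3 CSF ROI


@dataclass
class PhantomCohort:
    """A generated cohort: images, landmarks, metadata and ground truth."""

    config: PhantomConfig
    series: dict[str, ImageSeries]
    landmarks: dict[str, LandmarkSet]
    metadata: pd.DataFrame
    ground_truth: dict[str, GroundTruth]

    @property
    def disc_ids(self) -> list[str]:
        return list(self.series)


# ---------------------------------------------------------------------------
# Blood-pool kinetics
# ---------------------------------------------------------------------------

def simulate_blood_curve(params: KineticsParams, times) -> np.ndarray:
    """Blood-pool contrast concentration C_b(t) at the given times (min).

    C_b(t) = A (exp(-t/tau_e) - exp(-t/tau_a)): zero at injection, a peak
    within minutes (before the first 5-min acquisition with the default
    tau_a = 1, tau_e = 120), then clearance decay to just above zero at
    6 h.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return params.blood_amplitude * (
        np.exp(-t / params.decay_time) - np.exp(-t / params.uptake_time)
    )


def blood_peak_time(params: KineticsParams) -> float:
    """Closed-form stationary point of the blood curve (minutes)."""
    ta, te = params.uptake_time, params.decay_time
    return ta * te / (te - ta) * math.log(te / ta)


# ---------------------------------------------------------------------------
# 1-D disc diffusion solver
# ---------------------------------------------------------------------------

def _build_operator(n: int, dx: float, D: float, v: float, P: float,
                    boundary: str):
    """Spatial operator L and source weight b with L c + b C_b = dc/dt.

    Node-centred second-order finite differences; the Robin condition is
    imposed through a ghost node, which keeps the scheme second-order and
    exactly symmetric under x -> h - x.
    """
    main = np.full(n, -2.0 * D / dx**2 - v, dtype=float)
    off = np.full(n - 1, D / dx**2, dtype=float)
    b = np.full(n, v, dtype=float)
    if boundary == "robin":
        # ghost elimination: c_-1 = c_1 + 2 dx P / D (C_b - c_0)
        main[0] = -2.0 * D / dx**2 - 2.0 * P / dx - v
        main[-1] = main[0]
        off_u = off.copy()
        off_l = off.copy()
        off_u[0] = 2.0 * D / dx**2
        off_l[-1] = 2.0 * D / dx**2
        b[0] += 2.0 * P / dx
        b[-1] += 2.0 * P / dx
    elif boundary == "dirichlet":
        # boundary nodes are forced to C_b directly: row is identity-like,
        # handled by zeroing the ODE there and assigning after each step.
        main[0] = main[-1] = 0.0
        off_u = off.copy()
        off_l = off.copy()
        off_u[0] = 0.0
        off_l[-1] = 0.0
        b[0] = b[-1] = 0.0
    else:
        raise ValueError("boundary must be 'robin' or 'dirichlet'")
    L = sp.diags([off_l, main, off_u], offsets=[-1, 0, 1], format="csc")
    return L, b


def solve_disc_diffusion(
    spec: DiscSpec | float,
    params: KineticsParams,
    times=DEFAULT_TIME_POINTS,
    n_nodes: int = 61,
    dt: float = 0.5,
    scheme: str = "crank-nicolson",
    boundary: str = "robin",
    boundary_concentration=None,
) -> DiffusionSolution:
    """Solve the axial transport PDE through the disc and sample it.

    dc/dt = D d2c/dx2 + v (C_b(t) - c) on [0, h] with c(x, 0) = 0 and
    Robin endplate boundaries -D dc/dx|_0 = P (C_b - c(0)) (mirrored at
    x = h).  ``boundary="dirichlet"`` instead clamps both boundary nodes
    to the driving concentration (used for validation against the
    analytic slab series).  ``boundary_concentration`` may override the
    blood curve with an arbitrary callable of time.

    Default time stepping is Crank–Nicolson (unconditionally stable) with
    dt = 0.5 min; ``scheme="explicit"`` offers forward Euler for
    cross-checking and rejects unstable step sizes.
    """
    h = spec.height_mm if isinstance(spec, DiscSpec) else float(spec)
    if h <= 0:
        raise ValueError("disc height must be positive")
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    t_out = np.asarray(times, dtype=float)
    if t_out[0] != 0 or np.any(np.diff(t_out) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")

    D = params.diffusivity
    v = params.perfusion_rate
    P = params.endplate_permeability
    x = np.linspace(0.0, h, n_nodes)
    dx = x[1] - x[0]

    if boundary_concentration is None:
        cb = lambda t: float(simulate_blood_curve(params, [t])[0])
    else:
        cb = lambda t: float(boundary_concentration(t))

    if D == 0.0:
        # No diffusive transport: uniform perfusion ODE (sealed endplates).
        c_out = np.zeros((len(t_out), n_nodes))
        if v > 0:
            cval = 0.0
            t_prev = 0.0
            for k, t in enumerate(t_out[1:], start=1):
                n_steps = max(1, math.ceil((t - t_prev) / dt))
                step = (t - t_prev) / n_steps
                for s in range(n_steps):
                    tm = t_prev + (s + 0.5) * step
                    cval += step * v * (cb(tm) - cval)
                c_out[k] = cval
                t_prev = t
        return DiffusionSolution(x=x, times=t_out, c=c_out)

    L, b = _build_operator(n_nodes, dx, D, v, P, boundary)

    if scheme == "explicit":
        r = D * dt / dx**2
        if r > 0.5:
            raise ValueError(
                f"explicit scheme unstable: D*dt/dx^2 = {r:.3f} > 0.5; "
                "reduce dt or use the crank-nicolson scheme"
            )
    elif scheme != "crank-nicolson":
        raise ValueError("scheme must be 'crank-nicolson' or 'explicit'")

    eye = sp.identity(n_nodes, format="csc")
    c = np.zeros(n_nodes)
    if boundary == "dirichlet":
        c[0] = c[-1] = cb(0.0)
    c_out = np.zeros((len(t_out), n_nodes))
    c_out[0] = c

    solver_cache: dict[float, spla.SuperLU] = {}
    t_now = 0.0
    for k, t_next in enumerate(t_out[1:], start=1):
        n_steps = max(1, math.ceil((t_next - t_now) / dt))
        step = (t_next - t_now) / n_steps
        if scheme == "crank-nicolson":
            if step not in solver_cache:
                solver_cache[step] = spla.splu((eye - (step / 2.0) * L).tocsc())
            lu = solver_cache[step]
            A_exp = eye + (step / 2.0) * L
            for s in range(n_steps):
                t0 = t_now + s * step
                t1 = t0 + step
                src = (step / 2.0) * b * (cb(t0) + cb(t1))
                c = lu.solve(A_exp @ c + src)
                if boundary == "dirichlet":
                    c[0] = c[-1] = cb(t1)
        else:
            for s in range(n_steps):
                t0 = t_now + s * step
                c = c + step * (L @ c + b * cb(t0))
                if boundary == "dirichlet":
                    c[0] = c[-1] = cb(t0 + step)
        t_now = t_next
        c_out[k] = c
    return DiffusionSolution(x=x, times=t_out, c=c_out)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_VERTEBRA_EXTENT_PX = 24  # vertebral body depth rendered beyond each border


def _disc_geometry_layout(
    config: PhantomConfig, spec: DiscSpec, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower (A, B, C) landmark arrays for one centred disc.

    The disc is a quadrilateral with piecewise-linear endplate borders: a
    mild random tilt and a per-border bulge of the middle point exercise
    the segmenter while keeping the true landmarks exact.
    """
    rows, cols = config.grid_shape
    h_px = spec.height_mm / config.pixel_spacing
    w_px = spec.ap_width_mm / config.pixel_spacing
    c0 = 10.0
    c1 = min(c0 + w_px, config.csf_columns[0] - 6.0)
    c_mid = 0.5 * (c0 + c1)
    r_mid = rows / 2.0
    if rng is None:
        tilt, bulge_u, bulge_l = 0.0, 0.0, 0.0
    else:
        tilt = rng.uniform(-0.05, 0.05)  # rows per column
        bulge_u = rng.uniform(-1.5, 0.5)  # cranial bulge of upper border
        bulge_l = rng.uniform(-0.5, 1.5)
    r_u0 = r_mid - h_px / 2.0 + tilt * (c0 - c_mid)
    r_u1 = r_mid - h_px / 2.0 + tilt * (c1 - c_mid)
    upper = np.array([
        [r_u0, c0],
        [0.5 * (r_u0 + r_u1) + bulge_u, c_mid],
        [r_u1, c1],
    ])
    lower = np.array([
        [r_u0 + h_px, c0],
        [0.5 * (r_u0 + r_u1) + h_px + bulge_l, c_mid],
        [r_u1 + h_px, c1],
    ])
    return upper, lower


def _render_one(
    config: PhantomConfig,
    spec: DiscSpec,
    params: KineticsParams,
    field: DiffusionSolution,
    landmarks: LandmarkSet,
    rng: np.random.Generator | None,
    disc_id: str,
) -> tuple[ImageSeries, GroundTruth]:
    rows, cols = config.grid_shape
    rois = build_disc_rois(landmarks, config.grid_shape)
    geom = rois.geometry
    col_idx = geom.columns
    up, lo = geom.upper_rows, geom.lower_rows

    rr = np.arange(rows, dtype=float)[:, None]
    inside = np.zeros((rows, cols), dtype=bool)
    depth = np.zeros((rows, cols))
    sub_in = (rr >= up[None, :]) & (rr <= lo[None, :])
    inside[:, col_idx] = sub_in
    u_sub = np.where(sub_in, (rr - up[None, :]) / (lo - up)[None, :], 0.0)
    dcol = np.zeros((rows, cols))
    dcol[:, col_idx] = u_sub * field.height
    depth = dcol

    vert = np.zeros((rows, cols), dtype=bool)
    vert_u = (rr < up[None, :] - 1.0) & (rr >= up[None, :] - 1.0 - _VERTEBRA_EXTENT_PX)
    vert_l = (rr > lo[None, :] + 1.0) & (rr <= lo[None, :] + 1.0 + _VERTEBRA_EXTENT_PX)
    vert[:, col_idx] = vert_u | vert_l

    csf = np.zeros((rows, cols), dtype=bool)
    csf[:, config.csf_columns[0]:config.csf_columns[1]] = True
    csf &= ~inside & ~vert

    cb = simulate_blood_curve(params, config.time_points)
    alpha = params.signal_gain

    images: dict[str, np.ndarray] = {}
    for k, (t, label) in enumerate(zip(config.time_points, config.time_labels)):
        img = np.full((rows, cols), config.background)
        img[vert] = config.baseline + alpha * cb[k]
        conc = field.at_depth(depth[inside], k)
        img_disc = config.baseline + alpha * conc
        img[inside] = img_disc
        img[csf] = config.csf_t1_intensity
        if config.noise_sd > 0 and rng is not None:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        images[label] = img

    t2 = np.full((rows, cols), config.t2_background)
    t2[vert] = config.baseline
    t2[inside] = config.t2_background + config.t2_disc_gain * spec.hydration
    t2[csf] = config.csf_t2_intensity
    if config.noise_sd > 0 and rng is not None:
        t2 = t2 + rng.normal(0.0, config.noise_sd, size=t2.shape)

    # CSF reference ROI: 5 rows x 3 cols, centred in the CSF band at
    # mid-disc height.
    csf_c = (config.csf_columns[0] + config.csf_columns[1]) // 2 - 1
    csf_r = int(round((up.mean() + lo.mean()) / 2.0)) - 2
    csf_rect = (csf_r, csf_c)

    series = ImageSeries(
        disc_id=disc_id,
        times=config.time_points,
        images=images,
        t2=t2,
        pixel_spacing=config.pixel_spacing,
    )
    truth = GroundTruth(
        disc_id=disc_id,
        spec=spec,
        params=params,
        landmarks=landmarks,
        masks=rois.masks,
        field=field,
        csf_rect=csf_rect,
    )
    return series, truth


def render_series(
    config: PhantomConfig,
    fields: dict[str, DiffusionSolution],
    params: dict[str, KineticsParams] | KineticsParams,
    landmarks: dict[str, LandmarkSet] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, ImageSeries], dict[str, GroundTruth]]:
    """Render image series for every disc in ``config.discs``.

    ``fields`` maps disc_id to a solved concentration field; ``params``
    is either one KineticsParams for all discs or a per-disc mapping.
    Landmarks default to the deterministic centred layout (no tilt);
    supply a mapping (e.g. from :func:`generate_cohort`) for randomized
    geometry.  Noise is drawn from ``rng``; pass None for a noise-free
    render regardless of ``config.noise_sd``.
    """
    disc_ids = list(fields)
    specs = dict(zip(disc_ids, config.discs)) if config.discs else {}
    out_series: dict[str, ImageSeries] = {}
    out_truth: dict[str, GroundTruth] = {}
    for disc_id in disc_ids:
        spec = specs.get(disc_id, DiscSpec())
        p = params[disc_id] if isinstance(params, dict) else params
        if landmarks is not None and disc_id in landmarks:
            lms = landmarks[disc_id]
        else:
            upr, lwr = _disc_geometry_layout(config, spec, None)
            lms = LandmarkSet(disc_id=disc_id, upper=upr, lower=lwr,
                              pixel_spacing=config.pixel_spacing)
        series, truth = _render_one(config, spec, p, fields[disc_id], lms,
                                    rng, disc_id)
        out_series[disc_id] = series
        out_truth[disc_id] = truth
    return out_series, out_truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Pfirrmann grade frequencies of the reference cohort (grades 1..5).
GRADE_FREQUENCIES = (50, 43, 58, 48, 15)

#: Endplate-defect pattern frequencies (none / one endplate / both).
_DEFECT_PROBS = (0.634, 0.19, 0.176)
#: Disc-level Modic status (none / one endplate / both endplates).
_MC_PROBS = (159 / 214, 19 / 214, 36 / 214)
#: Modic type mix among affected endplates (I, II, I/II).
_MC_TYPE_PROBS = (27 / 91, 56 / 91, 8 / 91)
_SPONDY_PROB = 2 / 222

#: Multiplier on endplate permeability per Pfirrmann grade above 1.
PERMEABILITY_GRADE_FACTOR = 0.30
#: Perfusion rate (1/min) planted in Modic-change discs.
MC_PERFUSION_RATE = 0.0022
#: Endplate permeability multiplier for Modic-change discs.
MC_PERMEABILITY_FACTOR = 1.2
#: Irregular-endplate discs are more extensively vascularized.
IRREGULAR_PERFUSION_FACTOR = 2.0


def _draw_disc_spec(rng: np.random.Generator, grade_probs: np.ndarray,
                    height_distribution: str,
                    height_range: tuple[float, float]) -> DiscSpec:
    grade = int(rng.choice(5, p=grade_probs)) + 1
    if height_distribution == "uniform":
        h = float(rng.uniform(*height_range))
    else:  # grade-coupled: degenerated discs are thinner
        h = float(np.clip(rng.normal(11.5 - 1.5 * (grade - 1), 0.8), 2.5, 14.0))
    w = float(np.clip(rng.normal(1.0 - 0.17 * (grade - 1), 0.04), 0.05, 1.0))
    ap = float(np.clip(rng.normal(38.0, 3.0), 30.0, 46.0))

    n_def = int(rng.choice(3, p=_DEFECT_PROBS))
    if n_def == 0:
        d_up = d_lo = False
    elif n_def == 2:
        d_up = d_lo = True
    else:
        d_up = bool(rng.random() < 0.5)
        d_lo = not d_up

    n_mc = int(rng.choice(3, p=_MC_PROBS))
    mc_up = mc_lo = "0"
    types = ("I", "II", "I/II")
    if n_mc >= 1:
        first = types[int(rng.choice(3, p=_MC_TYPE_PROBS))]
        if n_mc == 2:
            second = types[int(rng.choice(3, p=_MC_TYPE_PROBS))]
            mc_up, mc_lo = first, second
        elif rng.random() < 0.5:
            mc_up = first
        else:
            mc_lo = first
    # Irregular endplates occur only on severely degenerated, Modic-positive
    # discs.
    irregular = bool(grade >= 4 and rng.random() < 0.17)
    if irregular and mc_up == "0" and mc_lo == "0":
        mc_up = types[int(rng.choice(3, p=_MC_TYPE_PROBS))]
    spondy = bool(rng.random() < _SPONDY_PROB)
    return DiscSpec(
        height_mm=h, ap_width_mm=ap, pfirrmann=grade, hydration=w,
        mc_upper=mc_up, mc_lower=mc_lo, defect_upper=d_up, defect_lower=d_lo,
        irregular=irregular, spondylolisthesis=spondy,
    )


def _disc_kinetics(base: KineticsParams, spec: DiscSpec) -> KineticsParams:
    """Per-disc kinetic parameters planting the cohort effect structure.

    Endplate permeability rises with degeneration grade; Modic-change and
    irregular-endplate discs receive a perfusion source (vascularization),
    twice as strong for irregular endplates.
    """
    perm = base.endplate_permeability * (
        1.0 + PERMEABILITY_GRADE_FACTOR * (spec.pfirrmann - 1)
    )
    v = 0.0
    if spec.has_mc or spec.irregular:
        perm *= MC_PERMEABILITY_FACTOR
        v = MC_PERFUSION_RATE * (IRREGULAR_PERFUSION_FACTOR if spec.irregular
                                 else 1.0)
    return replace(base, endplate_permeability=perm, perfusion_rate=v)


def generate_cohort(
    config: PhantomConfig,
    n_discs: int,
    seed: int | None = None,
    grade_counts: tuple[int, ...] | None = None,
    height_distribution: str = "grade-coupled",
    height_range: tuple[float, float] = (5.0, 14.0),
) -> PhantomCohort:
    """Generate a reproducible synthetic cohort of ``n_discs`` discs.

    Grades are drawn from the reference cohort frequencies (or, when
    ``grade_counts`` is given and sums to ``n_discs``, assigned exactly in
    those proportions).  ``height_distribution`` is either
    ``"grade-coupled"`` (default: degenerated discs are thinner and
    drier) or ``"uniform"`` over ``height_range``.  The same seed yields
    bit-identical output.
    """
    if n_discs < 1:
        raise ValueError("n_discs must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grade_probs = np.asarray(GRADE_FREQUENCIES, dtype=float)
    grade_probs /= grade_probs.sum()

    specs: list[DiscSpec] = []
    if grade_counts is not None:
        if sum(grade_counts) != n_discs:
            raise ValueError("grade_counts must sum to n_discs")
        fixed_grades = np.repeat(np.arange(1, 6), grade_counts)
    else:
        fixed_grades = None
    for i in range(n_discs):
        s = _draw_disc_spec(rng, grade_probs, height_distribution, height_range)
        if fixed_grades is not None:
            s = replace(s, pfirrmann=int(fixed_grades[i]))
        specs.append(s)

    cfg = replace(config, discs=tuple(specs))
    disc_ids = [f"disc_{i:04d}" for i in range(n_discs)]

    fields: dict[str, DiffusionSolution] = {}
    params: dict[str, KineticsParams] = {}
    lms: dict[str, LandmarkSet] = {}
    for disc_id, spec in zip(disc_ids, specs):
        p = _disc_kinetics(cfg.kinetics, spec)
        params[disc_id] = p
        fields[disc_id] = solve_disc_diffusion(
            spec, p, cfg.time_points, n_nodes=cfg.n_nodes, dt=cfg.dt
        )
        upr, lwr = _disc_geometry_layout(cfg, spec, rng)
        lms[disc_id] = LandmarkSet(disc_id=disc_id, upper=upr, lower=lwr,
                                   pixel_spacing=cfg.pixel_spacing)

    series, truth = render_series(cfg, fields, params, landmarks=lms, rng=rng)

    ages = np.clip(rng.normal(42.4, 9.3, size=n_discs), 18.0, 60.0)
    rows = []
    for disc_id, spec, age in zip(disc_ids, specs, ages):
        p = params[disc_id]
        rows.append({
            "disc_id": disc_id,
            "age": float(age),
            "pfirrmann": spec.pfirrmann,
            "height_mm": spec.height_mm,
            "hydration": spec.hydration,
            "mc_upper": spec.mc_upper,
            "mc_lower": spec.mc_lower,
            "defect_upper": spec.defect_upper,
            "defect_lower": spec.defect_lower,
            "irregular": spec.irregular,
            "spondylolisthesis": spec.spondylolisthesis,
            "true_permeability": p.endplate_permeability,
            "true_perfusion": p.perfusion_rate,
            "true_diffusivity": p.diffusivity,
        })
    metadata = pd.DataFrame(rows)
    return PhantomCohort(config=cfg, series=series, landmarks=lms,
                         metadata=metadata, ground_truth=truth)
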