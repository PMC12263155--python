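"""Synthetic-data generators for the three assay classes.

Three experiment families are emulated, each with known ground truth so
every downstream quantification can be validated by parameter recovery:

* **Bulk pyrene assembly** — either a minimal nucleation/elongation ODE
  (:func:`simulate_bulk_assembly`) or an exact logistic construction
  (:func:`simulate_bulk_from_slopes`) whose slope at one-eighth
  completion is set analytically.
* **Seeded elongation** — initial rates follow the tight-binding
  (quadratic) occupancy of barbed ends by formin
  (:func:`simulate_seeded_elongation`).
* **Single-filament TIRF** — piecewise-linear growth with
  pause→burst→detach formin engagements planted at exponential waiting
  times (:func:`simulate_filament_trace`), optionally rendered to a
  kymograph image (:func:`render_kymograph`).
* **Co-sedimentation gels** — pellet/supernatant band intensities with
  lognormal loading noise (:func:`simulate_cosedimentation`).

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    SUBUNITS_PER_UM,
    AssemblyTrace,
    BundlingGel,
    FilamentTrace,
    PlantedEvent,
)

__all__ = [
    "BulkKineticsParams",
    "FilamentKineticsParams",
    "simulate_bulk_assembly",
    "simulate_bulk_from_slopes",
    "simulate_seeded_elongation",
    "simulate_filament_trace",
    "render_kymograph",
    "track_kymograph_edge",
    "simulate_cosedimentation",
]


# ---------------------------------------------------------------------------
# bulk pyrene assembly
# ---------------------------------------------------------------------------


@dataclass
class BulkKineticsParams:
    """Parameters of the minimal bulk assembly model.

    The model is deliberately simple: spontaneous trinucleus formation
    proportional to C^3, formin-assisted nucleation proportional to
    C^2 x [formin], and elongation partitioned between free and
    formin-bound (partially capped) barbed ends.  The dose-dependent
    plateau reduction seen in pyrene traces is modelled as a
    multiplicative fluorescence artifact proportional to the bound-end
    fraction, not as polymer loss.
    """

    actin_total: float = 4.0  # µM
    k_nuc_spont: float = 2e-8  # µM^-2 s^-1
    k_nuc_formin: float = 1e-7  # µM^-1 nM^-1 s^-1
    k_elong_plus: float = 11.6  # subunits µM^-1 s^-1 per end
    k_elong_minus: float = 1.4  # subunits s^-1 per end
    critical_conc: float = 0.12  # µM (= k_minus / k_plus)
    formin_kd_ends: float = 0.028  # nM
    capped_elong_factor: float = 0.25  # dimensionless
    plateau_artifact_coeff: float = 0.5  # x bound-end fraction
    signal_scale: float = 100.0  # a.u. per µM polymer
    signal_offset: float = 5.0  # a.u.

    def __post_init__(self):
        for name in (
            "k_nuc_spont",
            "k_nuc_formin",
            "k_elong_plus",
            "k_elong_minus",
            "plateau_artifact_coeff",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.capped_elong_factor < 0:
            raise ValueError("capped_elong_factor must be >= 0")
        if not self.critical_conc < self.actin_total:
            raise ValueError("critical_conc must be below actin_total")
        if self.formin_kd_ends <= 0:
            raise ValueError("formin_kd_ends must be > 0")


def _bulk_rhs(y: np.ndarray, p: BulkKineticsParams, formin_nM: float) -> np.ndarray:
    n_nuc, polymer, monomer = y
    c = max(monomer, 0.0)
    d_nuc = p.k_nuc_spont * c**3 + p.k_nuc_formin * c**2 * formin_nM
    bound_frac = formin_nM / (formin_nM + p.formin_kd_ends) if formin_nM > 0 else 0.0
    per_end = max(p.k_elong_plus * c - p.k_elong_minus, 0.0)
    d_pol = per_end * n_nuc * ((1.0 - bound_frac) + p.capped_elong_factor * bound_frac)
    return np.array([d_nuc, d_pol, -d_pol - 3.0 * d_nuc])


def simulate_bulk_assembly(
    params: BulkKineticsParams,
    formin_series,
    t_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 0.1,
    return_state: bool = False,
):
    """Simulate a family of bulk assembly traces over a formin dose series.

    The (nuclei, polymer, monomer) state is integrated with fixed-step
    RK4 at ``dt`` and interpolated onto ``t_grid``; fluorescence is
    ``offset + scale * polymer * (1 - artifact * bound_end_fraction)``.

    Returns a list of :class:`AssemblyTrace` (one per dose); with
    ``return_state=True`` also a list of state dictionaries suitable for
    conservation checks.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must be a 1-D array with at least two points")
    if not (t_grid[0] == 0 and np.all(np.diff(t_grid) > 0)):
        raise ValueError("t_grid must be strictly increasing and start at 0")
    formin_series = [float(f) for f in formin_series]
    if any(f < 0 for f in formin_series):
        raise ValueError("formin concentrations must be >= 0")

    rng = np.random.default_rng(seed)
    traces, states = [], []
    t_end = float(t_grid[-1])
    n_steps = int(math.ceil(t_end / dt))
    for formin in formin_series:
        y = np.array([0.0, 0.0, params.actin_total])
        t_fine = np.empty(n_steps + 1)
        y_fine = np.empty((n_steps + 1, 3))
        t_fine[0], y_fine[0] = 0.0, y
        t = 0.0
        for i in range(n_steps):
            h = min(dt, t_end - t)
            k1 = _bulk_rhs(y, params, formin)
            k2 = _bulk_rhs(y + 0.5 * h * k1, params, formin)
            k3 = _bulk_rhs(y + 0.5 * h * k2, params, formin)
            k4 = _bulk_rhs(y + h * k3, params, formin)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            t_fine[i + 1], y_fine[i + 1] = t, y
        bound_frac = formin / (formin + params.formin_kd_ends) if formin > 0 else 0.0
        polymer = np.interp(t_grid, t_fine, y_fine[:, 1])
        signal = params.signal_offset + params.signal_scale * polymer * (
            1.0 - params.plateau_artifact_coeff * bound_frac
        )
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        traces.append(
            AssemblyTrace(
                trace_id=f"bulk_{formin:g}nM",
                formin_nM=formin,
                time_s=t_grid.copy(),
                signal_au=signal,
            )
        )
        if return_state:
            states.append(
                {
                    "time_s": t_fine.copy(),
                    "nuclei_uM": y_fine[:, 0].copy(),
                    "polymer_uM": y_fine[:, 1].copy(),
                    "monomer_uM": y_fine[:, 2].copy(),
                    "actin_total_uM": params.actin_total,
                }
            )
    return (traces, states) if return_state else traces


def simulate_bulk_from_slopes(
    target_slopes,
    plateau: float,
    t_grid=None,
    dt: float = 0.5,
    crossing_margin: float = 5.0,
):
    """Deterministic logistic fixtures with exact slopes at 1/8 completion.

    For a logistic ``F(t) = P / (1 + exp(-k (t - t0)))`` the derivative
    at ``F = P/8`` is ``7 k P / 64``; choosing ``k = 64 s / (7 P)``
    therefore makes the analytic slope at one-eighth completion equal
    the requested slope ``s`` exactly.  ``t0`` is placed so the crossing
    occurs ``crossing_margin`` logistic time-constants into the trace,
    keeping the initial signal negligible.

    Parameters
    ----------
    target_slopes : sequence of (formin_nM, slope_au_per_s)
    plateau : float
        Common plateau P (a.u.); must be > 0.
    t_grid : array, optional
        Shared time base; by default each trace gets its own grid
        extending one slope window past its crossing.
    """
    if plateau <= 0:
        raise ValueError("plateau must be > 0")
    traces = []
    for formin, slope in target_slopes:
        if slope <= 0:
            raise ValueError("target slopes must be > 0")
        k = 64.0 * slope / (7.0 * plateau)
        # F crosses P/8 at t0 - ln(7)/k; put that at crossing_margin/k.
        t_cross = crossing_margin / k
        t0 = t_cross + math.log(7.0) / k
        if t_grid is None:
            t_end = t_cross + 60.0
            grid = np.arange(0.0, t_end + dt, dt)
        else:
            grid = np.asarray(t_grid, dtype=float)
        signal = plateau / (1.0 + np.exp(-k * (grid - t0)))
        traces.append(
            AssemblyTrace(
                trace_id=f"logistic_{formin:g}nM",
                formin_nM=float(formin),
                time_s=grid,
                signal_au=signal,
                baseline_au=0.0,
                plateau_au=plateau,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# seeded elongation
# ---------------------------------------------------------------------------


def quadratic_occupancy_rate(F, B: float, kd: float, a: float, b: float):
    """Normalized elongation rate under tight-binding end occupancy.

    ``r = a + b * ((B + F + Kd) - sqrt((B + F + Kd)^2 - 4 B F))``
    with the discriminant clipped at zero against floating-point
    underflow.  Shared by the generator and (re-exported by) the
    fitting module so the model is written down once.
    """
    F = np.asarray(F, dtype=float)
    s = B + F + kd
    disc = s * s - 4.0 * B * F
    neg = disc < 0
    if np.any(neg):
        worst = float(np.min(disc))
        if worst < -1e-8:
            raise FloatingPointError(
                f"quadratic-binding discriminant {worst:g} below rounding tolerance"
            )
        disc = np.where(neg, 0.0, disc)
    return a + b * (s - np.sqrt(disc))


def simulate_seeded_elongation(
    kd: float,
    a_offset: float,
    b_scale: float,
    barbed_ends: float,
    formin_series,
    v0: float = 1.0,
    duration: float = 300.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    tau_s: float = 4000.0,
    dt: float = 1.0,
    baseline_au: float = 10.0,
):
    """Seeded-elongation traces whose initial rates obey the quadratic model.

    Each trace is ``baseline + v0 * r(F) * tau * (1 - exp(-t / tau))``:
    the noise-free slope at t=0 equals ``v0 * r(F)`` and the trace
    flattens smoothly on the monomer-depletion timescale ``tau``.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if barbed_ends <= 0:
        raise ValueError("barbed_ends must be > 0")
    if duration < 90:
        warnings.warn(
            "trace duration below 90 s: the standard initial-rate regression "
            "window will be truncated",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    traces = []
    for formin in formin_series:
        if formin < 0:
            raise ValueError("formin concentrations must be >= 0")
        r = float(quadratic_occupancy_rate(formin, barbed_ends, kd, a_offset, b_scale))
        signal = baseline_au + v0 * r * tau_s * (1.0 - np.exp(-t / tau_s))
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        traces.append(
            AssemblyTrace(
                trace_id=f"seeded_{formin:g}nM",
                formin_nM=float(formin),
                time_s=t.copy(),
                signal_au=signal,
                baseline_au=baseline_au if noise_sd == 0 else None,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# single-filament TIRF
# ---------------------------------------------------------------------------


@dataclass
class FilamentKineticsParams:
    """Ground-truth kinetics for one simulated TIRF filament.

    Free growth at ``v_free`` is interrupted at exponential waiting
    times (rate ``k_attach``) by a formin engagement: a pause of
    exponential duration ``pause_mean``, then a processive burst whose
    added length is exponential with mean ``runlength_char`` and whose
    rate is drawn from a truncated normal floored at ``v_free``.
    Burst-grown length carries ``dim_factor`` of the bright intensity.
    """

    v_free: float = 10.0  # subunits/s
    v_burst_mean: float = 39.0  # subunits/s
    v_burst_sd: float = 13.0  # subunits/s
    pause_mean: float = 12.0  # s
    runlength_char: float = 1.10  # µm
    k_attach: float = 0.01  # s^-1
    dim_factor: float = 0.5  # dimensionless in (0, 1]
    frame_interval: float = 2.5  # s
    length_noise_sd: float = 0.03  # µm
    duration: float = 600.0  # s

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pause_mean < 0:
            raise ValueError("pause_mean must be >= 0")
        if self.runlength_char <= 0:
            raise ValueError("runlength_char must be > 0")
        if not (0 < self.dim_factor <= 1):
            raise ValueError("dim_factor must be in (0, 1]")
        if self.v_free < 0 or self.v_burst_mean < 0 or self.v_burst_sd < 0:
            raise ValueError("rates must be >= 0")
        if self.k_attach < 0:
            raise ValueError("k_attach must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def _draw_burst_rate(rng: np.random.Generator, p: FilamentKineticsParams) -> float:
    """Truncated normal, floored at the free rate (bursts never slow growth)."""
    if p.v_burst_sd == 0:
        return max(p.v_burst_mean, p.v_free)
    for _ in range(1000):
        v = rng.normal(p.v_burst_mean, p.v_burst_sd)
        if v >= p.v_free:
            return v
    return max(p.v_burst_mean, p.v_free)  # pragma: no cover


def simulate_filament_trace(
    params: FilamentKineticsParams,
    seed: int = 0,
    filament_id: str = "fil_0",
) -> FilamentTrace:
    """Simulate one filament trace with planted pause/burst events.

    Length is piecewise linear in continuous time; frames are sampled at
    ``frame_interval`` with additive Gaussian length noise.  The tip
    intensity channel records 1.0 (bright) during free growth and
    pauses, ``dim_factor`` during bursts.  Planted events are returned
    exactly in ``truth_events``.
    """
    rng = np.random.default_rng(seed)
    p = params
    # Build the continuous-time schedule of (t_start, t_end, rate, dim) pieces.
    pieces = []  # (t0, t1, rate_sub_per_s, is_burst)
    events = []
    t = 0.0
    while t < p.duration:
        wait = rng.exponential(1.0 / p.k_attach) if p.k_attach > 0 else np.inf
        t_attach = min(t + wait, p.duration)
        if t_attach > t:
            pieces.append((t, t_attach, p.v_free, False))
        t = t_attach
        if t >= p.duration:
            break
        pause = rng.exponential(p.pause_mean) if p.pause_mean > 0 else 0.0
        run_um = rng.exponential(p.runlength_char)
        rate = _draw_burst_rate(rng, p)
        t_pause_end = min(t + pause, p.duration)
        if t_pause_end > t:
            pieces.append((t, t_pause_end, 0.0, False))
        burst_dur = run_um * SUBUNITS_PER_UM / rate
        t_burst_end = min(t_pause_end + burst_dur, p.duration)
        if t_burst_end > t_pause_end:
            pieces.append((t_pause_end, t_burst_end, rate, True))
        events.append(
            PlantedEvent(
                t_pause_start=t,
                t_pause_end=t_pause_end,
                t_burst_end=t_burst_end,
                burst_rate=rate,
                run_length=rate * (t_burst_end - t_pause_end) / SUBUNITS_PER_UM,
            )
        )
        t = t_burst_end

    n_frames = int(math.floor(p.duration / p.frame_interval)) + 1
    t_frames = np.arange(n_frames) * p.frame_interval
    # Integrate the piecewise-constant rate up to each frame instant.
    starts = np.array([pc[0] for pc in pieces])
    ends = np.array([pc[1] for pc in pieces])
    rates = np.array([pc[2] for pc in pieces])
    length_sub = np.zeros(n_frames)
    if pieces:
        overlap = np.clip(
            np.minimum(t_frames[:, None], ends[None, :]) - starts[None, :], 0.0, None
        )
        length_sub = overlap @ rates
    length_um = length_sub / SUBUNITS_PER_UM
    # Tip state at each frame instant: dim while inside a burst piece.
    intensity = np.ones(n_frames)
    for t0, t1, _, is_burst in pieces:
        if is_burst:
            inside = (t_frames >= t0) & (t_frames < t1)
            intensity[inside] = p.dim_factor
    if p.length_noise_sd > 0:
        length_um = length_um + rng.normal(0.0, p.length_noise_sd, size=n_frames)
        length_um = np.clip(length_um, 0.0, None)
    return FilamentTrace(
        filament_id=filament_id,
        time_s=t_frames,
        length_um=length_um,
        intensity_au=intensity,
        truth_events=events,
    )


def simulate_filament_ensemble(params: FilamentKineticsParams, n_traces: int, seed: int = 0):
    """Convenience: n independent filament traces with per-trace child seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_traces)
    return [
        simulate_filament_trace(
            params, seed=child, filament_id=f"fil_{i}"
        )
        for i, child in enumerate(children)
    ]


# ---------------------------------------------------------------------------
# kymograph rendering (artifact of the TIRF movie, rows = frames)
# ---------------------------------------------------------------------------


def render_kymograph(
    trace: FilamentTrace,
    pixel_size: float = 0.16,
    psf_sigma: float = 1.0,
    background: float = 100.0,
    bright_level: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a filament trace as a time x position intensity matrix.

    Each row is one frame; pixels covered by the filament carry the
    bright level, except stretches grown during dim (burst) frames,
    which carry ``dim_factor x bright``.  The image is Gaussian-blurred
    with ``psf_sigma`` pixels and additive noise, and is writable as a
    16-bit TIFF.
    """
    from scipy.ndimage import gaussian_filter1d

    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    rng = np.random.default_rng(seed)
    lengths = trace.length_um
    n_frames = lengths.size
    n_px = int(math.ceil(float(np.max(lengths)) / pixel_size)) + 10
    img = np.full((n_frames, n_px), float(background))
    # Per-stretch intensity from frame-to-frame growth and the frame's tip state.
    ratio = (
        trace.intensity_au / float(np.max(trace.intensity_au))
        if trace.intensity_au is not None
        else np.ones(n_frames)
    )
    levels = np.full(n_px, np.nan)  # intensity of filament material per pixel
    prev_len = 0.0
    for i in range(n_frames):
        cur = float(lengths[i])
        lo_px = int(prev_len / pixel_size)
        hi_px = int(cur / pixel_size)
        if hi_px > lo_px:
            levels[lo_px:hi_px] = background + (bright_level - background) * ratio[i]
        prev_len = max(prev_len, cur)
        cov = int(cur / pixel_size)
        row = img[i]
        filled = np.nan_to_num(levels[:cov], nan=bright_level)
        row[:cov] = filled
    if psf_sigma > 0:
        img = gaussian_filter1d(img, psf_sigma, axis=1)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 65535)


def track_kymograph_edge(
    image: np.ndarray, pixel_size: float, background: float, rel_threshold: float = 0.3
) -> np.ndarray:
    """Recover per-frame filament lengths from a kymograph by edge tracking.

    The filament tip is taken as the farthest pixel whose intensity
    exceeds ``background + rel_threshold x (row max - background)``.
    The default 0.3 sits below typical dim-segment levels so a dim tip
    is still tracked.
    """
    image = np.asarray(image, dtype=float)
    lengths = np.zeros(image.shape[0])
    for i, row in enumerate(image):
        peak = float(np.max(row))
        if peak <= background:
            continue
        thresh = background + rel_threshold * (peak - background)
        above = np.nonzero(row > thresh)[0]
        if above.size:
            lengths[i] = (above[-1] + 1) * pixel_size
    return lengths


# ---------------------------------------------------------------------------
# co-sedimentation gels
# ---------------------------------------------------------------------------


def simulate_cosedimentation(
    fraction_curve,
    total_intensity: float = 10000.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    actin_uM: float = 5.0,
) -> BundlingGel:
    """Simulate pellet/supernatant band intensities for a dose series.

    Per lane, the loaded total is ``total_intensity`` times a lognormal
    factor with coefficient of variation ``noise_cv``; the pellet share
    is the true fraction plus symmetric densitometry noise (zero mean,
    so the expected share equals the truth; exact when ``noise_cv=0``).
    """
    rng = np.random.default_rng(seed)
    lanes = []
    for formin, frac in fraction_curve:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"true fraction {frac} outside [0, 1]")
        if noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + noise_cv**2))
            total = total_intensity * rng.lognormal(-0.5 * sigma**2, sigma)
            share = float(
                np.clip(frac + rng.normal(0.0, noise_cv * frac * (1.0 - frac)), 0.0, 1.0)
            )
        else:
            total = total_intensity
            share = frac
        lanes.append((float(formin), total * share, total * (1.0 - share)))
    return BundlingGel(lanes=lanes, actin_uM=actin_uM)
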