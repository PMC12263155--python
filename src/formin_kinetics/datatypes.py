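"""Core containers shared across the assay-quantification modules.

Units follow the conventions of in vitro actin biochemistry: time in
seconds, bulk fluorescence in arbitrary units (a.u.), formin
concentrations in nM, actin in µM, filament lengths in µm, and
elongation rates in subunits/s.  The canonical actin geometry of 370
subunits per µm of filament converts between the last two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Actin subunits per µm of filament (13/6 helix, 2.7 nm rise per subunit).
SUBUNITS_PER_UM = 370.0


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class AssemblyTrace:
    """One bulk fluorescence (polymer-mass proxy) time course.

    Parameters
    ----------
    trace_id : str
        Identifier, unique within an experiment.
    formin_nM : float
        Formin concentration in the reaction.
    time_s, signal_au : array-like
        Time base (strictly increasing) and fluorescence signal.
    baseline_au, plateau_au : float, optional
        Known baseline / plateau.  When absent, the baseline defaults to
        the first sample and the plateau is estimated from the tail.
    """

    trace_id: str
    formin_nM: float
    time_s: np.ndarray
    signal_au: np.ndarray
    baseline_au: Optional[float] = None
    plateau_au: Optional[float] = None

    def __post_init__(self):
        self.time_s = _as_1d(self.time_s, "time_s")
        self.signal_au = _as_1d(self.signal_au, "signal_au")
        if self.time_s.shape != self.signal_au.shape:
            raise ValueError(
                f"trace {self.trace_id!r}: time_s and signal_au lengths differ "
                f"({self.time_s.size} vs {self.signal_au.size})"
            )
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError(f"trace {self.trace_id!r}: time_s is not strictly increasing")
        if self.formin_nM < 0:
            raise ValueError(f"trace {self.trace_id!r}: formin_nM must be >= 0")
        if (
            self.baseline_au is not None
            and self.plateau_au is not None
            and not self.plateau_au > self.baseline_au
        ):
            raise ValueError(f"trace {self.trace_id!r}: plateau_au must exceed baseline_au")


@dataclass
class PlantedEvent:
    """Ground truth for one simulated formin engagement (pause then burst)."""

    t_pause_start: float
    t_pause_end: float
    t_burst_end: float
    burst_rate: float  # subunits/s
    run_length: float  # µm

    def __post_init__(self):
        if not (self.t_pause_start <= self.t_pause_end <= self.t_burst_end):
            raise ValueError("event times must satisfy pause_start <= pause_end <= burst_end")
        if self.run_length < 0:
            raise ValueError("run_length must be >= 0")


@dataclass
class FilamentTrace:
    """One filament's sampled length (and optional tip intensity) vs time."""

    filament_id: str
    time_s: np.ndarray
    length_um: np.ndarray
    intensity_au: Optional[np.ndarray] = None
    truth_events: Optional[list] = None  # list[PlantedEvent]

    def __post_init__(self):
        self.time_s = _as_1d(self.time_s, "time_s")
        self.length_um = _as_1d(self.length_um, "length_um")
        if self.time_s.shape != self.length_um.shape:
            raise ValueError(
                f"filament {self.filament_id!r}: time_s and length_um lengths differ"
            )
        if self.intensity_au is not None:
            self.intensity_au = _as_1d(self.intensity_au, "intensity_au")
            if self.intensity_au.shape != self.time_s.shape:
                raise ValueError(
                    f"filament {self.filament_id!r}: intensity_au length mismatch"
                )

    @property
    def frame_interval_s(self) -> float:
        dts = np.diff(self.time_s)
        if dts.size == 0:
            raise ValueError("trace has fewer than two samples")
        dt = float(np.median(dts))
        if np.any(np.abs(dts - dt) > 0.01 * dt):
            raise ValueError(
                f"filament {self.filament_id!r}: sampling is not uniform within 1%"
            )
        return dt


@dataclass
class GrowthSegment:
    """One tile of a segmented filament trace: free growth, pause, or burst."""

    kind: str  # {"free", "pause", "burst"}
    t_start: float
    t_end: float
    slope: float  # subunits/s
    slope_se: float
    r2: float
    mean_intensity_ratio: Optional[float] = None
    i_start: int = 0  # sample index range [i_start, i_end] inclusive
    i_end: int = 0

    def __post_init__(self):
        if self.kind not in ("free", "pause", "burst"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.t_end > self.t_start:
            raise ValueError("segment must have t_end > t_start")

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass
class FormEvent:
    """A detected formin engagement: optional pause followed by a burst."""

    filament_id: str
    burst_rate_sub_per_s: float
    run_length_um: float
    burst_r2: float
    pause_duration_s: Optional[float] = None
    baseline_return: Optional[bool] = None
    censored: bool = False
    t_burst_start_s: Optional[float] = None
    t_burst_end_s: Optional[float] = None
    t_pause_start_s: Optional[float] = None

    def __post_init__(self):
        if self.run_length_um < 0:
            raise ValueError("run_length_um must be >= 0")


@dataclass
class BindingFit:
    """Fitted tight-binding (quadratic) model of barbed-end occupancy."""

    kd_nM: float
    a_offset: float
    b_scale: float
    barbed_ends_nM: float
    kd_se: float = float("nan")
    a_se: float = float("nan")
    b_se: float = float("nan")
    residual_ss: float = float("nan")
    n_points: int = 0
    kd_at_bound: bool = False

    def to_dict(self) -> dict:
        return {
            "kd_nM": self.kd_nM,
            "a_offset": self.a_offset,
            "b_scale_per_nM": self.b_scale,
            "barbed_ends_nM": self.barbed_ends_nM,
            "kd_se_nM": self.kd_se,
            "a_se": self.a_se,
            "b_se_per_nM": self.b_se,
            "residual_ss": self.residual_ss,
            "n_points": self.n_points,
            "kd_at_bound": self.kd_at_bound,
        }


@dataclass
class NucleationResult:
    """Dose series of t_1/8 slopes and the slope-vs-dose regression."""

    per_dose: list  # list of (formin_nM, t_one_eighth_s, slope_au_per_s)
    strength: float  # a.u./s per nM
    strength_se: float
    intercept: float  # a.u./s

    def to_dict(self) -> dict:
        return {
            "per_dose": [
                {"formin_nM": d, "t_one_eighth_s": t, "slope_au_per_s": s}
                for d, t, s in self.per_dose
            ],
            "strength_au_per_s_per_nM": self.strength,
            "strength_se": self.strength_se,
            "intercept_au_per_s": self.intercept,
        }


@dataclass
class BundlingGel:
    """Band intensities from one low-speed co-sedimentation gel."""

    lanes: list  # list of (formin_nM, pellet_au, supernatant_au)
    actin_uM: float = 5.0

    def __post_init__(self):
        if len(self.lanes) == 0:
            raise ValueError("gel must have at least one lane")
        for dose, pel, sup in self.lanes:
            if pel < 0 or sup < 0:
                raise ValueError("band intensities must be >= 0")


@dataclass
class BundlingResult:
    per_dose: list  # list of (formin_nM, mean_pct, sd_pct or None, n)
    monotone: bool = True

    def to_dict(self) -> dict:
        return {
            "per_dose": [
                {"formin_nM": d, "pct_pelleted_mean": m, "pct_pelleted_sd": s, "n": n}
                for d, m, s, n in self.per_dose
            ],
            "monotone": self.monotone,
        }


@dataclass
class TIRFSummary:
    """Population summary of segmented single-filament traces.

    ``*_char`` fields are detection-floor-corrected exponential-mean
    estimates (see :mod:`formin_kinetics.tirf`); the plain mean/sd pairs
    are raw statistics over detected events.
    """

    n_filaments: int = 0
    n_events: int = 0
    burst_frequency_per_filament: float = 0.0
    avg_rate_mean: float = float("nan")
    avg_rate_sd: float = float("nan")
    burst_rate_mean: float = float("nan")
    burst_rate_sd: float = float("nan")
    burst_rate_char: float = float("nan")
    run_length_mean: float = float("nan")
    run_length_sd: float = float("nan")
    run_length_char: float = float("nan")
    pause_mean: float = float("nan")
    pause_sd: float = float("nan")
    pause_char: float = float("nan")
    n_uncensored: int = 0
    n_paired_pauses: int = 0

    def to_dict(self) -> dict:
        return {
            "n_filaments": self.n_filaments,
            "n_events": self.n_events,
            "burst_frequency_per_filament": self.burst_frequency_per_filament,
            "avg_rate_mean_sub_per_s": self.avg_rate_mean,
            "avg_rate_sd_sub_per_s": self.avg_rate_sd,
            "burst_rate_mean_sub_per_s": self.burst_rate_mean,
            "burst_rate_sd_sub_per_s": self.burst_rate_sd,
            "burst_rate_char_sub_per_s": self.burst_rate_char,
            "run_length_mean_um": self.run_length_mean,
            "run_length_sd_um": self.run_length_sd,
            "run_length_char_um": self.run_length_char,
            "pause_mean_s": self.pause_mean,
            "pause_sd_s": self.pause_sd,
            "pause_char_s": self.pause_char,
            "n_uncensored": self.n_uncensored,
            "n_paired_pauses": self.n_paired_pauses,
        }
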