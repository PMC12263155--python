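"""Bulk pyrene-assay quantification.

Two readouts are implemented:

* **Nucleation strength** — for each trace the time to one-eighth
  completion (t_1/8) is found and the local assembly slope there is
  measured; the ordinary-least-squares slope of those slopes against
  formin dose is the construct's specific nucleation activity
  (a.u./s per nM).
* **Barbed-end affinity** — seeded-elongation initial rates, normalized
  to actin alone, are fit to the tight-binding (quadratic) occupancy
  model ``r = a + b ((B + F + Kd) - sqrt((B + F + Kd)^2 - 4 B F))``
  with the barbed-end concentration B fixed.  Because ligand and sites
  are comparable in concentration, the simple hyperbolic isotherm does
  not apply and the quadratic (ligand-depletion) form is required.

The two fitting surfaces are sklearn-style estimators
(:class:`NucleationStrength`, :class:`BarbedEndAffinityFit`); the
module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import AssemblyTrace, BindingFit, NucleationResult
from .simulate import quadratic_occupancy_rate

__all__ = [
    "IncompleteReactionError",
    "time_to_fraction",
    "slope_at_time",
    "initial_rate",
    "normalize_rates",
    "quadratic_binding_rate",
    "NucleationStrength",
    "nucleation_strength",
    "BarbedEndAffinityFit",
    "fit_barbed_end_affinity",
]


class IncompleteReactionError(ValueError):
    """The trace never reaches the requested completion level."""


def _smoothed(signal: np.ndarray, window: int) -> np.ndarray:
    """Light Savitzky-Golay smoothing; falls back to the raw signal when short."""
    if window is None or window < 3 or signal.size < window:
        return signal
    if window % 2 == 0:
        window += 1
    return savgol_filter(signal, window, polyorder=2)


def _plateau_estimate(trace: AssemblyTrace, smooth: np.ndarray) -> float:
    """Tail-mean plateau with a still-rising guard.

    The plateau defaults to the mean of the final 5% of samples; if the
    terminal slope still exceeds 1% of the maximum observed slope, the
    reaction has not plateaued and the caller must supply one.
    """
    n = smooth.size
    k = max(int(round(0.05 * n)), 2)
    tail = smooth[-k:]
    t = trace.time_s
    dt = np.diff(t)
    slopes = np.diff(smooth) / dt
    max_rate = float(np.max(np.abs(slopes))) if slopes.size else 0.0
    tail_slope = float(np.polyfit(t[-k:], tail, 1)[0]) if k >= 2 else 0.0
    if max_rate > 0 and abs(tail_slope) > 0.01 * max_rate:
        raise ValueError(
            f"trace {trace.trace_id!r}: signal still rising at the end of the "
            "record; supply an explicit plateau_au or acquire a longer trace"
        )
    return float(np.mean(tail))


def time_to_fraction(
    trace: AssemblyTrace,
    fraction: float = 1.0 / 8.0,
    smooth_window: int = 5,
) -> float:
    """Earliest time the trace reaches ``baseline + fraction x amplitude``.

    The signal is lightly smoothed and the crossing is linearly
    interpolated between frames.  Raises
    :class:`IncompleteReactionError` when the level is never reached.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    smooth = _smoothed(trace.signal_au, smooth_window)
    baseline = trace.baseline_au if trace.baseline_au is not None else float(smooth[0])
    plateau = (
        trace.plateau_au
        if trace.plateau_au is not None
        else _plateau_estimate(trace, smooth)
    )
    if not plateau > baseline:
        raise IncompleteReactionError(
            f"trace {trace.trace_id!r}: plateau ({plateau:g}) does not exceed "
            f"baseline ({baseline:g}); reaction incomplete"
        )
    level = baseline + fraction * (plateau - baseline)
    above = smooth >= level
    if not np.any(above):
        raise IncompleteReactionError(
            f"trace {trace.trace_id!r}: signal never reaches the "
            f"{fraction:g}-completion level ({level:g})"
        )
    i = int(np.argmax(above))
    if i == 0:
        return float(trace.time_s[0])
    t0, t1 = trace.time_s[i - 1], trace.time_s[i]
    y0, y1 = smooth[i - 1], smooth[i]
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def slope_at_time(trace: AssemblyTrace, t: float, window_s: float = 20.0) -> float:
    """Least-squares slope of signal vs time over a centered window."""
    mask = np.abs(trace.time_s - t) <= window_s / 2.0
    if int(np.count_nonzero(mask)) < 4:
        raise ValueError(
            f"trace {trace.trace_id!r}: fewer than 4 samples in the "
            f"{window_s:g} s window around t={t:g} s"
        )
    return float(np.polyfit(trace.time_s[mask], trace.signal_au[mask], 1)[0])


def initial_rate(trace: AssemblyTrace, window_s: float = 90.0) -> float:
    """Least-squares slope over the first ``window_s`` seconds of the trace."""
    rel = trace.time_s - trace.time_s[0]
    if rel[-1] < window_s:
        warnings.warn(
            f"trace {trace.trace_id!r} spans only {rel[-1]:g} s; "
            f"initial-rate window truncated below {window_s:g} s",
            stacklevel=2,
        )
    mask = rel <= window_s
    if int(np.count_nonzero(mask)) < 4:
        raise ValueError(
            f"trace {trace.trace_id!r}: fewer than 4 samples in the first "
            f"{window_s:g} s"
        )
    return float(np.polyfit(trace.time_s[mask], trace.signal_au[mask], 1)[0])


def normalize_rates(rates, actin_alone_rate: float):
    """Divide raw rates by the same experiment's actin-alone control rate."""
    if not actin_alone_rate > 0:
        raise ValueError("actin_alone_rate must be > 0")
    return [(float(f), float(rate) / actin_alone_rate) for f, rate in rates]


#: Exact evaluation of the tight-binding occupancy model (r(0) = a,
#: r(inf) = a + 2 b B; monotone in F, decreasing when b < 0).
quadratic_binding_rate = quadratic_occupancy_rate


# ---------------------------------------------------------------------------
# nucleation strength
# ---------------------------------------------------------------------------


class NucleationStrength(BaseEstimator):
    """Slope-of-slopes nucleation statistic over a formin dose series.

    For each trace the assembly slope at t_1/8 is measured over a
    centered ``window_s`` window; ``fit`` then regresses those per-dose
    slopes on formin concentration.  The fitted line's slope
    (``strength_``, a.u./s per nM) is the dose-normalized specific
    nucleation activity.

    Attributes (after ``fit``)
    --------------------------
    per_dose_ : list of (formin_nM, t_one_eighth_s, slope_au_per_s)
    strength_, strength_se_, intercept_ : float
    result_ : :class:`NucleationResult`
    """

    def __init__(self, fraction: float = 1.0 / 8.0, window_s: float = 20.0,
                 smooth_window: int = 5):
        self.fraction = fraction
        self.window_s = window_s
        self.smooth_window = smooth_window

    def fit(self, traces: Sequence[AssemblyTrace], y=None):
        doses = sorted({t.formin_nM for t in traces})
        if len(doses) < 3:
            raise ValueError(
                f"nucleation strength needs >= 3 distinct formin doses, got {len(doses)}"
            )
        per_dose = []
        for trace in traces:
            try:
                t18 = time_to_fraction(trace, self.fraction, self.smooth_window)
                slope = slope_at_time(trace, t18, self.window_s)
            except ValueError as exc:
                raise ValueError(f"trace {trace.trace_id!r}: {exc}") from exc
            per_dose.append((trace.formin_nM, t18, slope))
        x = np.array([d for d, _, _ in per_dose])
        y_ = np.array([s for _, _, s in per_dose])
        reg = stats.linregress(x, y_)
        self.per_dose_ = per_dose
        self.strength_ = float(reg.slope)
        self.strength_se_ = float(reg.stderr)
        self.intercept_ = float(reg.intercept)
        self.result_ = NucleationResult(
            per_dose=per_dose,
            strength=self.strength_,
            strength_se=self.strength_se_,
            intercept=self.intercept_,
        )
        return self


def nucleation_strength(traces, **params) -> NucleationResult:
    """Functional wrapper over :class:`NucleationStrength`."""
    return NucleationStrength(**params).fit(traces).result_


# ---------------------------------------------------------------------------
# barbed-end affinity (tight-binding fit)
# ---------------------------------------------------------------------------


def _profiled_ab(F: np.ndarray, r: np.ndarray, B: float, kd: float):
    """For fixed Kd the model is linear in (a, b): solve by least squares."""
    g = (B + F + kd) - np.sqrt(np.clip((B + F + kd) ** 2 - 4.0 * B * F, 0.0, None))
    X = np.column_stack([np.ones_like(F), g])
    coef, *_ = np.linalg.lstsq(X, r, rcond=None)
    resid = r - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


class BarbedEndAffinityFit(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the quadratic binding model.

    ``fit(F, r)`` takes formin concentrations (nM) and normalized
    elongation rates.  The barbed-end concentration ``barbed_ends_nM``
    is a fixed experimental input, not a fitted parameter.  The solver
    multi-starts from a log-spaced Kd grid (``n_starts`` points over
    ``kd_bounds``); for each start, the conditionally-linear (a, b) pair
    is profiled out before the full 3-parameter refinement, and the
    global best is kept.  Standard errors come from the Jacobian at the
    optimum.

    Attributes (after ``fit``)
    --------------------------
    kd_, a_, b_ : float
    kd_se_, a_se_, b_se_ : float
    residual_ss_ : float
    kd_at_bound_ : bool
        Set when Kd lands on a box bound (affinity unidentifiable from
        the data, e.g. no dose dependence).
    """

    def __init__(
        self,
        barbed_ends_nM: float = 0.1,
        kd_bounds=(1e-3, 1e2),
        n_starts: int = 13,
    ):
        self.barbed_ends_nM = barbed_ends_nM
        self.kd_bounds = kd_bounds
        self.n_starts = n_starts

    def _validate(self, F, r):
        F = np.asarray(F, dtype=float).reshape(-1)
        r = np.asarray(r, dtype=float).reshape(-1)
        if F.shape != r.shape:
            raise ValueError("F and r must have equal length")
        if F.size < 4:
            raise ValueError(f"affinity fit needs >= 4 points, got {F.size}")
        if np.any(F < 0):
            raise ValueError("formin concentrations must be >= 0")
        pos = F[F > 0]
        if pos.size and pos.max() / pos.min() < 10:
            warnings.warn(
                "formin doses span less than one decade; Kd may be poorly "
                "constrained",
                stacklevel=3,
            )
        return F, r

    def fit(self, F, r):
        F, r = self._validate(F, r)
        B = float(self.barbed_ends_nM)
        lo, hi = self.kd_bounds
        starts = np.geomspace(lo, hi, self.n_starts)
        best = None
        for kd0 in starts:
            a0, b0, _ = _profiled_ab(F, r, B, kd0)

            def resid(p):
                return quadratic_occupancy_rate(F, B, p[0], p[1], p[2]) - r

            try:
                sol = optimize.least_squares(
                    resid,
                    x0=[kd0, a0, b0],
                    bounds=([lo, -np.inf, -np.inf], [hi, np.inf, np.inf]),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:
                continue
            sse = float(sol.fun @ sol.fun)
            if best is None or sse < best[0] - 1e-15:
                best = (sse, sol)
        if best is None:
            raise RuntimeError(
                "barbed-end affinity fit failed to converge from all "
                f"{self.n_starts} starts (B={B} nM, bounds={self.kd_bounds})"
            )
        sse, sol = best
        kd, a, b = (float(v) for v in sol.x)
        n = F.size
        dof = max(n - 3, 1)
        s2 = sse / dof
        try:
            jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
            ses = np.sqrt(np.clip(np.diag(jtj_inv) * s2, 0.0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            ses = np.full(3, np.nan)
        rtol = 1e-6
        at_bound = kd <= lo * (1 + rtol) or kd >= hi * (1 - rtol)
        # Flat dose response: Kd carries no information regardless of bounds.
        if np.ptp(r) < 1e-12:
            at_bound = True
        self.kd_ = kd
        self.a_ = a
        self.b_ = b
        self.kd_se_, self.a_se_, self.b_se_ = (float(s) for s in ses)
        self.residual_ss_ = sse
        self.n_points_ = n
        self.kd_at_bound_ = bool(at_bound)
        if abs(a - 1.0) > 0.1:
            warnings.warn(
                f"fitted offset a={a:.3f} deviates from 1; check the "
                "normalization control",
                stacklevel=2,
            )
        return self

    def predict(self, F):
        return quadratic_occupancy_rate(
            np.asarray(F, dtype=float), self.barbed_ends_nM, self.kd_, self.a_, self.b_
        )

    @property
    def result_(self) -> BindingFit:
        return BindingFit(
            kd_nM=self.kd_,
            a_offset=self.a_,
            b_scale=self.b_,
            barbed_ends_nM=self.barbed_ends_nM,
            kd_se=self.kd_se_,
            a_se=self.a_se_,
            b_se=self.b_se_,
            residual_ss=self.residual_ss_,
            n_points=self.n_points_,
            kd_at_bound=self.kd_at_bound_,
        )


def fit_barbed_end_affinity(points, barbed_ends_nM: float = 0.1, **params) -> BindingFit:
    """Functional wrapper over :class:`BarbedEndAffinityFit`.

    ``points`` is a sequence of (formin_nM, normalized_rate) pairs.
    """
    F = np.array([p[0] for p in points], dtype=float)
    r = np.array([p[1] for p in points], dtype=float)
    est = BarbedEndAffinityFit(barbed_ends_nM=barbed_ends_nM, **params).fit(F, r)
    return est.result_
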