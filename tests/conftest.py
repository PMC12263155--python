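import numpy as np
import pytest

from formin_kinetics import AssemblyTrace
from formin_kinetics.simulate import quadratic_occupancy_rate


def logistic_trace(plateau=64.0, k=1.0, t0=50.0, dt=0.5, t_end=100.0,
                   trace_id="logistic", formin_nM=0.0, explicit=True):
    t = np.arange(0.0, t_end + dt / 2, dt)
    sig = plateau / (1.0 + np.exp(-k * (t - t0)))
    return AssemblyTrace(
        trace_id,
        formin_nM,
        t,
        sig,
        baseline_au=0.0 if explicit else None,
        plateau_au=plateau if explicit else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def kd_grid_oracle(F, r, B, kd_grid, a_grid, b_grid):
    """Exhaustive 3-D grid search for the quadratic-binding fit.

    Independent of the NLS fitter: evaluates the sum of squared errors
    on the full (kd, a, b) grid using sufficient statistics (SSE is
    quadratic in a, b for fixed kd) and returns the arg-min triple.
    """
    F = np.asarray(F, float)
    r = np.asarray(r, float)
    n = F.size
    Sr = float(np.sum(r))
    Srr = float(np.sum(r * r))
    best = (np.inf, None)
    A = a_grid[:, None]
    Bg = b_grid[None, :]
    for kd in kd_grid:
        s = B + F + kd
        g = s - np.sqrt(np.clip(s * s - 4.0 * B * F, 0.0, None))
        Sg = float(np.sum(g))
        Sgg = float(np.sum(g * g))
        Sgr = float(np.sum(g * r))
        sse = (
            n * A**2
            + (Bg**2) * Sgg
            + 2.0 * A * Bg * Sg
            - 2.0 * A * Sr
            - 2.0 * Bg * Sgr
            + Srr
        )
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        if sse[i, j] < best[0]:
            best = (float(sse[i, j]), (float(kd), float(a_grid[i]), float(b_grid[j])))
    return best[1]
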