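"""Low-speed co-sedimentation (bundling) quantification.

Bundled actin pellets at low centrifugal speed while single filaments
stay in the supernatant; with pellet and supernatant loaded in equal
volumes, the percent of actin pelleted per lane is simply the pellet
band's share of the summed band intensities.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datatypes import BundlingGel, BundlingResult

__all__ = ["fraction_pelleted", "bundling_curve"]


def fraction_pelleted(
    pellet_au: float, supernatant_au: float, total_load_au: float = None
) -> float:
    """Percent of actin pelleted from one lane pair.

    ``100 * pellet / (pellet + supernatant)`` by default; when
    ``total_load_au`` is given (pellet-only gels) the denominator is the
    total load instead.  Scale-invariant in the band intensities.
    """
    if pellet_au < 0 or supernatant_au < 0:
        raise ValueError("band intensities must be >= 0")
    denom = total_load_au if total_load_au is not None else pellet_au + supernatant_au
    if not denom > 0:
        raise ValueError("cannot compute a pelleted fraction from zero total intensity")
    return 100.0 * pellet_au / denom


def bundling_curve(gels: Sequence[BundlingGel], noise_sd_tol: float = 2.0) -> BundlingResult:
    """Per-dose mean ± SD of percent pelleted across replicate gels.

    All replicates must share the same dose grid.  The result carries a
    monotonicity flag: False when the mean dose response decreases
    between consecutive doses by more than ``noise_sd_tol`` pooled
    standard errors (a non-monotone response beyond noise).
    """
    if len(gels) == 0:
        raise ValueError("need at least one gel")
    grids = [tuple(lane[0] for lane in g.lanes) for g in gels]
    if len(set(grids)) != 1:
        raise ValueError(
            f"replicate gels have mismatched dose grids: {sorted(set(grids))}"
        )
    doses = grids[0]
    per_dose = []
    means, ses = [], []
    single = len(gels) == 1
    for i, dose in enumerate(doses):
        pcts = [fraction_pelleted(g.lanes[i][1], g.lanes[i][2]) for g in gels]
        mean = float(np.mean(pcts))
        sd = float(np.std(pcts, ddof=1)) if len(pcts) > 1 else None
        per_dose.append((float(dose), mean, sd, len(pcts)))
        means.append(mean)
        ses.append((sd / np.sqrt(len(pcts))) if sd is not None else 0.0)
    monotone = True
    for i in range(1, len(means)):
        tol = noise_sd_tol * max(ses[i], ses[i - 1])
        if means[i] < means[i - 1] - tol:
            monotone = False
    return BundlingResult(per_dose=per_dose, monotone=monotone)
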