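"""Four-parameter logistic (4PL) dose-response fitting.

The model is the standard Hill curve

    y(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)

with the IC50 optimized on the log10 scale. Fits use bounded least squares
with a small multistart grid (IC50 starts at the dose quartiles, Hill at
+/-1), so a single bad start cannot trap the fit in a local minimum.
Non-identifiable fits (flat response, too few doses) are flagged rather
than forced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = ["four_pl", "DoseResponseFit", "fit_four_parameter_logistic"]


def four_pl(x, top: float, bottom: float, ic50: float, hill: float):
    """Evaluate the 4PL curve at dose(s) x (> 0)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


@dataclass
class DoseResponseFit:
    """Result of a 4PL fit. Parameters are None when the fit did not converge."""

    top: Optional[float]
    bottom: Optional[float]
    ic50: Optional[float]
    hill: Optional[float]
    rss: Optional[float]
    converged: bool
    n_points: int
    flags: tuple[str, ...] = ()


def _residuals(theta: np.ndarray, logx: np.ndarray, y: np.ndarray) -> np.ndarray:
    top, bottom, log_ic50, hill = theta
    # 1/(1+(x/ic50)^hill) = expit(-hill * (log x - log ic50) * ln 10)
    z = hill * (logx - log_ic50) * np.log(10.0)
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
    return bottom + (top - bottom) * frac - y


def fit_four_parameter_logistic(
    doses: np.ndarray,
    effects: np.ndarray,
    top_bounds: tuple[float, float] = (50.0, 150.0),
    bottom_bounds: tuple[float, float] = (-20.0, 50.0),
) -> DoseResponseFit:
    """Fit a 4PL curve to (dose, effect) data.

    Parameters
    ----------
    doses : array of dose values (µM), > 0.
    effects : array of responses, conventionally percent effect.
    top_bounds, bottom_bounds : box constraints on the plateau parameters
        (percent scale by default).

    Returns a :class:`DoseResponseFit`. Requires >= 4 distinct doses; a flat
    response within bounds is reported as converged but flagged
    ``non_identifiable`` when the fitted Hill slope is ~0.
    """
    doses = np.asarray(doses, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if doses.shape != effects.shape:
        raise ValueError("doses and effects must have the same shape")
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    n_distinct = np.unique(doses).size
    if n_distinct < 4:
        raise ValueError(f"need >= 4 distinct doses, got {n_distinct}")

    logx = np.log10(doses)
    lo = np.array([top_bounds[0], bottom_bounds[0], logx.min() - 2.0, -10.0])
    hi = np.array([top_bounds[1], bottom_bounds[1], logx.max() + 2.0, 10.0])

    top0 = float(np.clip(np.max(effects), *top_bounds))
    bot0 = float(np.clip(np.min(effects), *bottom_bounds))
    ic50_starts = np.quantile(logx, [0.25, 0.5, 0.75])
    best = None
    for log_ic50_0 in ic50_starts:
        for hill0 in (1.0, -1.0):
            theta0 = np.clip([top0, bot0, log_ic50_0, hill0], lo, hi)
            try:
                res = least_squares(
                    _residuals, theta0, bounds=(lo, hi), args=(logx, effects),
                    method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res

    n = int(doses.size)
    if best is None:
        return DoseResponseFit(None, None, None, None, None, False, n, ("no_convergence",))

    top, bottom, log_ic50, hill = best.x
    rss = float(2 * best.cost)
    flags: list[str] = []
    if abs(hill) < 1e-3 or abs(top - bottom) < 1e-6:
        flags.append("non_identifiable")
    if not (logx.min() <= log_ic50 <= logx.max()):
        flags.append("ic50_outside_dose_range")
    return DoseResponseFit(
        top=float(top),
        bottom=float(bottom),
        ic50=float(10.0**log_ic50),
        hill=float(hill),
        rss=rss,
        converged=True,
        n_points=n,
        flags=tuple(flags),
    )
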