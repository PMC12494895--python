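"""Relative-fitness estimation, epistasis, adaptation rates and power-law fits.

A competition assay co-cultures a test strain against a fluorescent
reference. At each daily timepoint the flow cytometer yields the event
ratio r = nonfluorescent / fluorescent, and total-cell counts at 0 h and
24 h give the generations elapsed in that passage. Relative fitness w is
the ordinary-least-squares slope of ln r on cumulative generations — the
per-generation selection coefficient of the test strain against the
reference.

Generations per passage default to log2 of the 24 h expansion factor
(population doublings); ``gen_log="e"`` reproduces the natural-log
convention, which rescales the slope by ln 2 but changes nothing else.

Long-term fitness trajectories w̄(t) are summarised by the power law
w̄ = (b·t)^a + w0 with the ancestral fitness w0 held fixed; b acts as a
proxy for the global adaptation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConfigError, DomainError, InsufficientDataError, UndefinedRatioError


@dataclass(frozen=True)
class FitnessEstimate:
    w: float
    stderr: float
    intercept: float
    r2: float
    n_timepoints: int
    normalized_w: float | None = None


def estimate_fitness(timepoints: pd.DataFrame, gen_log: str = "log2") -> FitnessEstimate:
    """OLS slope of ln(ratio) on cumulative generations.

    ``timepoints`` needs columns day, fluorescent_events,
    nonfluorescent_events, total_events_t0, total_events_t24. The earliest
    sample anchors generation 0; each row's passage contributes
    log2(t24/t0) generations (or ln with ``gen_log="e"``). All rows enter
    the regression unweighted.
    """
    if gen_log not in ("log2", "e"):
        raise ConfigError(f"gen_log must be 'log2' or 'e', got {gen_log!r}")
    tp = timepoints.sort_values("day").reset_index(drop=True)
    if len(tp) < 2:
        raise InsufficientDataError("estimate_fitness needs >= 2 timepoints")
    fluor = tp["fluorescent_events"].to_numpy(dtype=float)
    nonfluor = tp["nonfluorescent_events"].to_numpy(dtype=float)
    if np.any(fluor <= 0):
        raise UndefinedRatioError("ratio undefined: zero fluorescent events at a timepoint")
    log = np.log2 if gen_log == "log2" else np.log
    g = log(tp["total_events_t24"].to_numpy(dtype=float) / tp["total_events_t0"].to_numpy(dtype=float))
    x = np.cumsum(g) - g[0]  # earliest sample at generation 0
    y = np.log(nonfluor / fluor)
    fit = stats.linregress(x, y)
    return FitnessEstimate(
        w=float(fit.slope),
        stderr=float(fit.stderr),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n_timepoints=len(tp),
    )


def normalize_fitness(w, reference_w: float) -> float:
    """Fitness relative to a same-condition reference: w − reference (subtraction)."""
    w_val = w.w if isinstance(w, FitnessEstimate) else float(w)
    return w_val - float(reference_w)


def epistasis(w_double: float, w_a: float, w_b: float) -> float:
    """Observed minus expected-additive fitness: w_ab − (w_a + w_b).

    Positive values mean the double mutant is fitter than the additive
    expectation. All three inputs must be normalized to the same reference.
    """
    return float(w_double) - (float(w_a) + float(w_b))


def adaptation_rate(w_evolved: float, w_ancestor: float, generations: float) -> float:
    """Fitness gain per generation: (w_evolved − w_ancestor) / generations."""
    if generations <= 0:
        raise DomainError("generations must be > 0")
    return (float(w_evolved) - float(w_ancestor)) / float(generations)


def recovery_fraction(w_evolved: float, w_ancestor: float) -> float:
    """Proportion of the ancestral fitness defect recovered: Δ / |w_ancestor|."""
    if w_ancestor == 0:
        raise DomainError("ancestor has no fitness defect to recover")
    return (float(w_evolved) - float(w_ancestor)) / abs(float(w_ancestor))


@dataclass(frozen=True)
class TrajectoryFit:
    a: float
    b: float
    w0: float
    r2: float
    linear_slope: float
    linear_r2: float
    converged: bool
    degenerate: bool = False


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def fit_power_law(
    t,
    w,
    w0: float,
    a_starts: tuple[float, ...] = (0.25, 0.5, 1.0),
    a_max: float = 2.0,
) -> TrajectoryFit:
    """Nonlinear least squares for w̄ = (b·t)^a + w0 with w0 fixed.

    Multi-start over ``a_starts`` with b seeded from a crude linear slope;
    bounds a ∈ (0, a_max], b ≥ 0. A companion straight-line fit through the
    same points is reported for model comparison. Non-convergence is
    reported through the ``converged`` flag, never raised; an all-flat
    trajectory returns b = 0 with the ``degenerate`` flag.
    """
    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(t < 0):
        raise DomainError("generations must be >= 0")
    if len(t) < 3:
        raise InsufficientDataError("fit_power_law needs >= 3 timepoints")

    lin = np.polyfit(t, w, 1)
    linear_slope = float(lin[0])
    linear_r2 = _r2(w, np.polyval(lin, t))

    if np.ptp(w) < 1e-12:  # flat trajectory: model reduces to w0
        return TrajectoryFit(a=1.0, b=0.0, w0=w0, r2=np.nan,
                             linear_slope=linear_slope, linear_r2=linear_r2,
                             converged=True, degenerate=True)

    def resid(p):
        a, b = p
        return (b * t) ** a + w0 - w

    t_end = t[t > 0].max() if np.any(t > 0) else 1.0
    dw_end = max(w[-1] - w0, 1e-8)
    best = None
    for a0 in a_starts:
        b0 = float(dw_end ** (1.0 / a0) / t_end)
        try:
            sol = optimize.least_squares(
                resid, x0=[a0, max(b0, 1e-10)],
                bounds=([1e-8, 0.0], [a_max, np.inf]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return TrajectoryFit(a=np.nan, b=np.nan, w0=w0, r2=np.nan,
                             linear_slope=linear_slope, linear_r2=linear_r2,
                             converged=False)
    a_hat, b_hat = best.x
    return TrajectoryFit(
        a=float(a_hat), b=float(b_hat), w0=w0,
        r2=_r2(w, (b_hat * t) ** a_hat + w0),
        linear_slope=linear_slope, linear_r2=linear_r2,
        converged=bool(best.success),
    )
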