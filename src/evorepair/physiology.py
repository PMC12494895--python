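"""Growth-curve parameters and cell-cycle phase durations.

Growth rate is the maximum slope of ln(OD) over a sliding window of
consecutive readings — the classical max-specific-growth-rate extraction
from plate-reader OD600 series — with doubling time ln2/rate and maximum OD
read from a lightly smoothed curve. An optional background (a float, or
``"min3"`` for the minimum of the first three readings) is subtracted
before taking logs; the default is 0 so that a pure exponential is
recovered exactly.

Cell-cycle phase fractions come from a DNA-content sample: the 1C and 2C
(= 2 × 1C) peaks are located on a histogram, events are gated at fixed
multiples of the 1C position (G1 below ``g1_gate``·1C, G2/M above
``g2_gate``·1C, S between), and — because hard gates claim the flanks of
the S bridge for G1 and G2/M — the default estimator unmixes the gated
fractions assuming a uniform S bridge between the peaks. Phase durations
are fractions × doubling time and sum to the doubling time exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import ConfigError, DomainError, InsufficientDataError, ValidationError


@dataclass(frozen=True)
class GrowthFit:
    growth_rate: float
    doubling_time: float
    max_od: float
    t_max_slope: float
    no_growth: bool
    window: int


def fit_growth(
    times,
    od,
    window: int = 8,
    background: float | str = 0.0,
    min_rate: float = 1e-6,
) -> GrowthFit:
    """Maximum sliding-window slope of ln(OD − background).

    ``window`` consecutive points (default 8, i.e. 80 min at 10-min
    sampling) enter each regression; points where OD − background ≤ 0 are
    dropped. A curve whose best slope falls below ``min_rate`` is flagged
    ``no_growth`` (rate and doubling time are NaN).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if window < 3:
        raise ConfigError("window must be >= 3 points")
    if len(t) < window:
        raise InsufficientDataError(f"need at least {window} readings")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    bg = float(np.min(y[:3])) if background == "min3" else float(background)
    keep = y - bg > 0
    tt, yy = t[keep], np.log(y[keep] - bg)
    max_od = float(pd.Series(y).rolling(3, center=True, min_periods=1).mean().max())
    if len(tt) < window:
        return GrowthFit(np.nan, np.nan, max_od, np.nan, True, window)
    best_slope, best_t = -np.inf, np.nan
    for i in range(len(tt) - window + 1):
        fit = stats.linregress(tt[i : i + window], yy[i : i + window])
        if fit.slope > best_slope:
            best_slope, best_t = float(fit.slope), float(np.mean(tt[i : i + window]))
    if best_slope < min_rate:
        return GrowthFit(np.nan, np.nan, max_od, np.nan, True, window)
    return GrowthFit(
        growth_rate=best_slope,
        doubling_time=float(np.log(2) / best_slope),
        max_od=max_od,
        t_max_slope=best_t,
        no_growth=False,
        window=window,
    )


@dataclass(frozen=True)
class CellCycleFractions:
    g1: float
    s: float
    g2m: float
    c1_position: float
    gating_ok: bool

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.g1, self.s, self.g2m)


def _find_c1(x: np.ndarray, n_bins: int = 128) -> tuple[float, bool]:
    """Locate the 1C peak; returns (position, gating_ok)."""
    lo, hi = np.percentile(x, [0.5, 99.5])
    counts, edges = np.histogram(x[(x >= lo) & (x <= hi)], bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    peaks, props = signal.find_peaks(counts, prominence=0.05 * counts.max())
    if len(peaks) == 0:
        return float(centers[np.argmax(counts)]), False
    # order candidate peaks by height
    order = peaks[np.argsort(counts[peaks])[::-1]]
    main = centers[order[0]]
    for p in order[1:]:
        ratio = max(centers[p], main) / min(centers[p], main)
        if 1.7 <= ratio <= 2.3:  # found a consistent 1C/2C pair
            return float(min(centers[p], main)), True
    # single usable peak: treat it as 1C (e.g. a pure-G1 sample)
    return float(main), True


def phase_fractions(
    intensities,
    g1_gate: float = 1.5,
    g2_gate: float = 1.75,
    s_bridge_correction: bool = True,
    min_events: int = 1000,
) -> CellCycleFractions:
    """(G1, S, G2/M) fractions from DNA-content intensities.

    Gates sit at fixed multiples of the detected 1C position. With
    ``s_bridge_correction`` (default) the raw gated fractions are unmixed
    under a uniform S bridge spanning 1C→2C: the S density is read from the
    pure-S band between the gates and the bridge mass misassigned to the
    G1/G2M gates is returned to S. Fractions are clipped at 0 and sum to 1.
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) < min_events:
        raise InsufficientDataError(f"need >= {min_events} events, got {len(x)}")
    if not 1.0 < g1_gate < g2_gate < 2.0:
        raise ConfigError("gates must satisfy 1 < g1_gate < g2_gate < 2 (in 1C units)")
    c1, ok = _find_c1(x)
    raw_g1 = float(np.mean(x < g1_gate * c1))
    raw_g2 = float(np.mean(x > g2_gate * c1))
    raw_s = 1.0 - raw_g1 - raw_g2
    if s_bridge_correction:
        s = raw_s / (g2_gate - g1_gate)  # bridge width is 1.0 in 1C units
        g1 = raw_g1 - s * (g1_gate - 1.0)
        g2 = raw_g2 - s * (2.0 - g2_gate)
    else:
        g1, s, g2 = raw_g1, raw_s, raw_g2
    vals = np.clip([g1, s, g2], 0.0, None)
    vals = vals / vals.sum()
    return CellCycleFractions(float(vals[0]), float(vals[1]), float(vals[2]), c1, ok)


def phase_durations(fractions, doubling_time: float) -> dict[str, float]:
    """Minutes per phase: fraction × doubling time, conserving the doubling time.

    ``fractions`` is a (G1, S, G2M) triple or :class:`CellCycleFractions`.
    The G2/M duration is defined as the remainder ``doubling_time − G1 − S``,
    so the three durations always reconstruct the doubling time (the
    identity ``doubling_time − G1 − S == G2M`` is exact in floating point).
    """
    if doubling_time <= 0:
        raise DomainError("doubling_time must be > 0")
    if isinstance(fractions, CellCycleFractions):
        fractions = fractions.as_tuple()
    f = np.asarray(fractions, dtype=float)
    if f.shape != (3,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValidationError("fractions must be three nonnegative values summing to 1")
    g1 = f[0] * doubling_time
    s = f[1] * doubling_time
    # G2/M is the exact remainder, so the doubling time is reconstructed
    # without drift: doubling_time - G1 - S == G2M holds bit-for-bit
    g2m = doubling_time - g1 - s
    return {"G1": g1, "S": s, "G2M": max(g2m, 0.0)}
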