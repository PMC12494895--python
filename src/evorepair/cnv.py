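"""Copy-number analysis of 100-bp read-depth tracks.

The pipeline mirrors the visual CNV-scan it was designed to reproduce:
depth per 100-bp window is normalized to the genome-wide median (so the
euploid baseline is 1), the ancestor's normalized track is subtracted from
the evolved line's (baseline 0, a clean 2× amplification is +1), the
difference is smoothed by a centered 5-window moving average, amplified
segments are maximal runs of windows above a threshold, and recurrence of
amplification at a locus across independent populations is assessed with
an exact binomial upper tail.

Tracks are bedGraph-like frames: chrom, start (0-based half-open), end,
depth — fixed 100-bp windows, sorted, non-overlapping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, CoordinateError, DomainError, NormalizationError

WINDOW = 100
TRACK_COLUMNS = ["chrom", "start", "end", "depth"]


def validate_track(track: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRACK_COLUMNS) - set(track.columns)
    if missing:
        raise CoordinateError(f"track lacks columns {sorted(missing)}")
    if ((track["end"] - track["start"]) != WINDOW).any():
        raise CoordinateError(f"track windows must be exactly {WINDOW} bp wide")
    for chrom, grp in track.groupby("chrom", observed=True):
        starts = grp["start"].to_numpy()
        if np.any(np.diff(starts) <= 0):
            raise CoordinateError(f"{chrom}: windows must be sorted and non-overlapping")
    return track


def normalize_track(track: pd.DataFrame) -> pd.DataFrame:
    """Divide every depth by the genome-wide median; output median is 1."""
    validate_track(track)
    med = float(track["depth"].median())
    if med <= 0:
        raise NormalizationError("genome-wide median depth is zero; cannot normalize")
    out = track.copy()
    out["depth"] = track["depth"] / med
    return out


def subtract_ancestor_track(evolved_norm: pd.DataFrame, ancestor_norm: pd.DataFrame) -> pd.DataFrame:
    """Window-wise evolved − ancestor difference on identical grids."""
    validate_track(evolved_norm)
    validate_track(ancestor_norm)
    if len(evolved_norm) != len(ancestor_norm) or not (
        evolved_norm[["chrom", "start", "end"]].reset_index(drop=True)
        .equals(ancestor_norm[["chrom", "start", "end"]].reset_index(drop=True))
    ):
        raise CoordinateError("evolved and ancestor tracks are on different window grids")
    out = evolved_norm.reset_index(drop=True).copy()
    out["depth"] = (
        evolved_norm["depth"].to_numpy() - ancestor_norm["depth"].to_numpy()
    )
    return out


def smooth_track(track: pd.DataFrame, span: int = 5) -> pd.DataFrame:
    """Centered moving average over ``span`` windows, per chromosome.

    Chromosome ends use shrinking windows (no padding), so the value at
    every position remains an average of observed windows only.
    """
    if span < 1 or span % 2 == 0:
        raise ConfigError(f"span must be odd and >= 1, got {span}")
    validate_track(track)
    out = track.copy()
    out["depth"] = (
        track.groupby("chrom", observed=True)["depth"]
        .transform(lambda s: s.rolling(span, center=True, min_periods=1).mean())
    )
    return out


def call_amplified_segments(
    difference: pd.DataFrame,
    threshold: float = 0.5,
    min_windows: int = 5,
) -> pd.DataFrame:
    """Maximal runs of ≥ ``min_windows`` consecutive windows ≥ ``threshold``.

    Input is the smoothed, ancestor-subtracted normalized difference track.
    The default threshold 0.5 is the midpoint between the euploid baseline
    (0) and a clean single-copy gain (+1). Returns a BED-like frame (chrom,
    start, end, n_windows, mean_diff); an empty frame is a valid result.
    """
    validate_track(difference)
    segments = []
    for chrom, grp in difference.groupby("chrom", observed=True, sort=False):
        grp = grp.reset_index(drop=True)
        above = (grp["depth"] >= threshold).to_numpy()
        # breaks also at genomic gaps between consecutive windows
        contiguous = np.concatenate(
            [[True], grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]]
        )
        run_id = np.cumsum(~(above & contiguous))
        for _, run in grp[above].groupby(run_id[above]):
            if len(run) >= min_windows:
                segments.append(
                    {"chrom": chrom, "start": int(run["start"].iloc[0]),
                     "end": int(run["end"].iloc[-1]), "n_windows": len(run),
                     "mean_diff": float(run["depth"].mean())}
                )
    return pd.DataFrame(segments, columns=["chrom", "start", "end", "n_windows", "mean_diff"])


def recurrence_test(n_hit_populations: int, n_populations: int, null_prob: float) -> float:
    """Exact binomial upper tail P(X ≥ n_hit | n_populations, null_prob).

    ``null_prob`` — the chance a random segmental event lands on the locus,
    e.g. locus bp / genome bp — is a mandatory, explicit parameter.
    """
    if not 0 < null_prob < 1:
        raise DomainError("null_prob must lie strictly in (0,1)")
    if not 0 <= n_hit_populations <= n_populations:
        raise DomainError("need 0 <= n_hit <= n_populations")
    if n_hit_populations == 0:
        return 1.0
    return float(
        stats.binomtest(n_hit_populations, n_populations, null_prob, alternative="greater").pvalue
    )


def locus_null_probability(locus_bp: int, genome_bp: int) -> float:
    """Default recurrence null: probability a random event hits the locus."""
    if not 0 < locus_bp < genome_bp:
        raise DomainError("need 0 < locus_bp < genome_bp")
    return locus_bp / genome_bp


def read_track(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_track(df)


def write_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False)


def write_bed(segments: pd.DataFrame, path) -> None:
    segments[["chrom", "start", "end"]].assign(
        name=[f"amp_{i + 1}" for i in range(len(segments))],
        score=segments["mean_diff"].round(4),
    ).to_csv(path, sep="\t", index=False, header=False)
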