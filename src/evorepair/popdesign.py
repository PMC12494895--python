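"""Serial-dilution bookkeeping: generations, effective size, bottleneck planning.

Each daily passage dilutes a saturated culture by a factor D; the
population regrows to its final size, passing through n = log2(D)
doublings. The effective population size of such a bottlenecked regime is
Ne ~ N0 × n, the bottleneck size times the generations per passage. The
planner inverts these two formulas to choose a dilution that holds Ne at a
target — the bookkeeping used to keep Ne within one order of magnitude
across conditions whose final densities differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, PlanningError


def generations_per_passage(dilution_factor: float) -> float:
    """Population doublings per passage: log2 of the dilution factor.

    A 1:1000 dilution gives log2(1000) ≈ 9.97 ≈ 10 generations.
    """
    if dilution_factor <= 1:
        raise DomainError("dilution factor must be > 1")
    return float(np.log2(dilution_factor))


def effective_size(bottleneck_cells: float, generations: float) -> float:
    """Ne ~ N0 × n for a serially bottlenecked population."""
    if bottleneck_cells <= 0 or generations <= 0:
        raise DomainError("bottleneck_cells and generations must be > 0")
    return float(bottleneck_cells) * float(generations)


@dataclass(frozen=True)
class PassageDesign:
    dilution_factor: float
    bottleneck_cells: float
    generations_per_passage: float
    effective_size: float


def evaluate_design(dilution_factor: float, final_pop_size: float) -> PassageDesign:
    """Ne achieved by diluting 1:D from a culture of ``final_pop_size`` cells."""
    n = generations_per_passage(dilution_factor)
    n0 = final_pop_size / dilution_factor
    return PassageDesign(dilution_factor, n0, n, effective_size(n0, n))


def plan_bottleneck(
    target_ne: float,
    final_pop_size: float,
    d_max: float = 1e12,
    rel_tol: float = 1e-6,
) -> PassageDesign:
    """Choose the dilution factor D whose regime attains ``target_ne``.

    Solves final/D × log2(D) = target_ne on the large-dilution branch
    (D ≥ e), where Ne decreases monotonically in D, by log-grid bracketing
    plus bisection. Raises :class:`PlanningError` when the target exceeds
    the attainable maximum (final × log2(e)/e ≈ 0.53 × final).
    """
    if target_ne <= 0 or final_pop_size <= 0:
        raise DomainError("target_ne and final_pop_size must be > 0")

    def ne_at(d: float) -> float:
        return final_pop_size / d * np.log2(d)

    d_lo = float(np.e)  # Ne is maximal here and decreases beyond
    if target_ne > ne_at(d_lo):
        raise PlanningError(
            f"target Ne {target_ne:.3g} exceeds the attainable maximum "
            f"{ne_at(d_lo):.3g} for final size {final_pop_size:.3g}"
        )
    # bracket on a log grid, then bisect (Ne(D) is monotone decreasing here)
    grid = np.logspace(np.log10(d_lo), np.log10(d_max), 400)
    hi_idx = np.searchsorted(-np.array([ne_at(d) for d in grid]), -target_ne)
    if hi_idx >= len(grid):
        raise PlanningError(f"target Ne {target_ne:.3g} not attainable below D={d_max:.3g}")
    lo = grid[max(hi_idx - 1, 0)]
    hi = grid[hi_idx]
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if ne_at(mid) > target_ne:
            lo = mid
        else:
            hi = mid
        if hi / lo - 1 < rel_tol:
            break
    d = float(np.sqrt(lo * hi))
    design = evaluate_design(d, final_pop_size)
    if abs(design.effective_size - target_ne) > 0.1 * target_ne:
        raise PlanningError("bisection failed to reach the target within 10%")
    return design


def passage_schedule(
    target_ne: float,
    final_pop_size: float,
    n_passages: int = 10,
) -> list[PassageDesign]:
    """Constant-regime schedule: one row per daily passage."""
    design = plan_bottleneck(target_ne, final_pop_size)
    return [design] * n_passages
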