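"""Sparsity-induced spot selection (SISS) — phase 1 of plan generation.

Before the full lexicographic optimization, the candidate spot set is pruned
by solving the scalarized wish-list surrogate with an added L1 term
``coefficient * sum(w)`` (exact L1 for nonnegative weights) under all hard
constraints; spots whose weight survives above an activity threshold form
the support passed to MCO. Because the penalized solve itself satisfies the
hard constraints, MCO restricted to the selected support is feasible
whenever the SISS solve was.
"""

from __future__ import annotations

import numpy as np

from .beamline import DoseInfluence
from .mco import WishList, build_surrogate
from .phantom import Phantom

__all__ = ["select_spots", "ACTIVITY_THRESHOLD"]

ACTIVITY_THRESHOLD = 1e-3  # spot active if weight > threshold * max weight


def _active_ids(dij: DoseInfluence, w: np.ndarray, threshold: float) -> list[int]:
    wmax = w.max(initial=0.0)
    if wmax <= 0.0:
        return []
    keep = w > threshold * wmax
    return [s.id for s, k in zip(dij.spots, keep) if k]


def select_spots(
    dij: DoseInfluence,
    phantom: Phantom,
    wishlist: WishList,
    sparsity_coefficient: float = 0.0,
    target_count: int | None = None,
    threshold: float = ACTIVITY_THRESHOLD,
    target_tol: float = 0.05,
    max_bisect: int = 30,
) -> list[int]:
    """Spot ids selected by the L1-penalized surrogate solve.

    With ``target_count`` given, the coefficient is bisected (on a log scale)
    until the selected count is within ±``target_tol`` of the target.
    """
    if sparsity_coefficient < 0:
        raise ValueError("sparsity coefficient must be nonnegative")
    prob = build_surrogate(dij, phantom, wishlist)

    def run(coeff: float) -> list[int]:
        x, _ = prob.solve(extra_linear_cost=np.full(dij.n_spots, coeff) if coeff else None)
        return _active_ids(dij, x[: dij.n_spots], threshold)

    if target_count is None:
        return run(sparsity_coefficient)

    lo, hi = 1e-6, 1e3
    sel_lo, sel_hi = run(lo), run(hi)
    if not (len(sel_hi) <= target_count <= len(sel_lo)):
        raise ValueError(
            f"target spot count {target_count} outside bisection bracket: "
            f"coefficient {lo:g} -> {len(sel_lo)} spots, {hi:g} -> {len(sel_hi)} spots"
        )
    best = sel_lo if abs(len(sel_lo) - target_count) < abs(len(sel_hi) - target_count) else sel_hi
    for _ in range(max_bisect):
        if abs(len(best) - target_count) <= target_tol * target_count:
            return best
        mid = float(np.sqrt(lo * hi))
        sel = run(mid)
        if abs(len(sel) - target_count) < abs(len(best) - target_count):
            best = sel
        if len(sel) > target_count:
            lo = mid
        else:
            hi = mid
    return best
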