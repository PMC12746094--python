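"""Plan finalization: monitor-unit limits and plan normalization.

Deliverable plans must respect the machine's minimum and maximum MU per
spot. Spots whose optimized weight falls below MUmin are removed, and one
re-optimization of the scalarized wish-list surrogate on the reduced
support, with box constraints ``mu_min <= w <= mu_max`` and all hard
constraints re-imposed, restores the constraints (a single-solve
simplification of full reference-point constraint restoration). Final
weights are therefore in ``{0} ∪ [mu_min, mu_max]``.

Normalization then rescales all weights so that the high-dose target's D98%
in the 21-scenario voxel-wise minimum dose distribution equals 95% of the
prescription — the clinical robust-coverage convention that puts every plan
of a comparison on the same footing. Dose is linear in the weights, so the
scaling is exact; MU-limit compliance is re-checked afterwards and
violations are reported as warnings rather than re-looped (guaranteeing
termination).
"""

from __future__ import annotations

import warnings

import numpy as np

from ._opt import InfeasibleProblemError, solve_lp
from .beamline import DoseInfluence
from .evaluate import dvh_metric
from .mco import Plan, WishList, build_surrogate
from .phantom import Phantom
from .scenarios import voxelwise_aggregate

__all__ = ["enforce_mu_limits", "normalize_plan", "MU_MIN_DEFAULT", "MU_MAX_DEFAULT"]

MU_MIN_DEFAULT = 0.02
MU_MAX_DEFAULT = 50.0


def enforce_mu_limits(
    plan: Plan,
    dij: DoseInfluence,
    phantom: Phantom,
    wishlist: WishList,
    mu_min: float = MU_MIN_DEFAULT,
    mu_max: float = MU_MAX_DEFAULT,
) -> Plan:
    """Drop sub-MUmin spots and re-optimize on the reduced support with
    MU box constraints and all hard constraints re-imposed."""
    if not (0 < mu_min <= mu_max):
        raise ValueError("need 0 < mu_min <= mu_max")

    w_full = plan.weights_on(dij)
    keep_cols = np.flatnonzero(w_full >= mu_min)
    if keep_cols.size == 0:
        raise InfeasibleProblemError(
            f"MU restoration infeasible: no spot reaches mu_min = {mu_min}"
        )

    # Re-optimize with the MU ceiling, dropping any spot that still falls
    # below MUmin, until the support is stable; the final box-constrained
    # solve (mu_min <= w <= mu_max) is then feasible by construction.
    sub = dij.restrict(keep_cols)
    for _ in range(8):
        prob = build_surrogate(sub, phantom, wishlist)
        n = sub.n_spots
        n_aux = len(prob.c) - n
        try:
            x = solve_lp(
                prob.c,
                prob.A_ub,
                prob.b_ub,
                bounds=[(0, mu_max)] * n + [(0, None)] * n_aux,
                row_groups=prob.row_groups,
                context="MU restoration",
            )
        except InfeasibleProblemError as e:
            raise InfeasibleProblemError(
                f"MU restoration infeasible with mu_min={mu_min}, mu_max={mu_max}: {e}",
                e.violated,
            ) from e
        low = x[:n] < mu_min
        if not low.any():
            break
        keep = np.flatnonzero(~low)
        if keep.size == 0:
            raise InfeasibleProblemError(
                f"MU restoration infeasible: every spot falls below mu_min = {mu_min}"
            )
        sub = sub.restrict(keep)
    prob = build_surrogate(sub, phantom, wishlist)
    n = sub.n_spots
    n_aux = len(prob.c) - n
    try:
        x = solve_lp(
            prob.c,
            prob.A_ub,
            prob.b_ub,
            bounds=[(mu_min, mu_max)] * n + [(0, None)] * n_aux,
            row_groups=prob.row_groups,
            context="MU restoration (box)",
        )
    except InfeasibleProblemError as e:
        raise InfeasibleProblemError(
            f"MU restoration infeasible with mu_min={mu_min}, mu_max={mu_max}: {e}",
            e.violated,
        ) from e
    return Plan(
        weights=x[:n],
        spots=sub.spots,
        mode=plan.mode,
        beams=plan.beams,
        achieved=dict(plan.achieved),
        meta={**plan.meta, "mu_min": mu_min, "mu_max": mu_max},
    )


def normalize_plan(
    plan: Plan,
    dij: DoseInfluence,
    phantom: Phantom,
    prescription_gy: float = 70.0,
    coverage_fraction: float = 0.95,
    target: str | None = None,
) -> Plan:
    """Scale weights so target D98%(VWmin) = coverage_fraction * prescription."""
    if target is None:
        (target,) = phantom.structures_with_role("target_high")
    mask = phantom.masks[target]
    if not mask.any():
        raise ValueError(f"target mask {target!r} is empty")

    w_full = plan.weights_on(dij)
    vwmin = voxelwise_aggregate(dij.scenario_doses(w_full), "min").reshape(dij.grid.shape)
    d98 = dvh_metric(vwmin, mask, "D98%")
    if d98 <= 0:
        raise ZeroDivisionError("target D98%(VWmin) is zero; normalization undefined")
    s = coverage_fraction * prescription_gy / d98

    new = Plan(
        weights=plan.weights * s,
        spots=plan.spots,
        mode=plan.mode,
        beams=plan.beams,
        achieved=dict(plan.achieved),
        meta={**plan.meta, "normalization_scale": s * plan.meta.get("normalization_scale", 1.0)},
    )
    mu_min = plan.meta.get("mu_min")
    mu_max = plan.meta.get("mu_max")
    if mu_min is not None and new.weights[new.weights > 0].size:
        wpos = new.weights[new.weights > 0]
        if wpos.min() < mu_min - 1e-9 or wpos.max() > mu_max + 1e-9:
            warnings.warn(
                f"normalization scale {s:.4f} moved spot weights outside "
                f"[{mu_min}, {mu_max}]; plan left as scaled",
                stacklevel=2,
            )
    return new
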