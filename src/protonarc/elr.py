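"""Energy-layer reduction (ELR) for discrete proton arc therapy.

Delivering 36 fields with the full candidate energy-layer (EL) set would be
prohibitively slow: EL switches, especially energy up-switches, dominate
discrete-arc delivery time. ELR therefore selects a small EL subset *before*
spot selection and spot-weight optimization, by group-regularized
sparsification: all candidate spots of one (field, energy layer) pair form a
group, and the scalarized wish-list surrogate is solved with the classical
group-lasso penalty ``lam * sum_g sqrt(|g|) * ||w_g||_2`` under all hard
constraints. ELs whose group weight norm survives above an activity
threshold are kept; every candidate spot of an unselected EL is removed from
the problem passed downstream (SISS, then MCO).

The regularization coefficient trades EL count against plan quality: larger
``lam`` means fewer layers and a weakly worse surrogate objective.
:func:`tune_lambda` bisects the coefficient to hit a requested EL count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beamline import DoseInfluence, Spot
from .mco import WishList, build_surrogate
from .phantom import Phantom

__all__ = ["ELGroup", "ELRResult", "build_el_groups", "reduce_energy_layers", "tune_lambda"]

EL_ACTIVITY_THRESHOLD = 1e-3  # group active if ||w_g|| > threshold * max group norm


@dataclass(frozen=True)
class ELGroup:
    """All candidate spots sharing one (field, energy layer)."""

    group_id: int
    field_index: int
    el_index: int
    spot_ids: tuple[int, ...]


@dataclass
class ELRResult:
    lam: float
    selected_els: list[tuple[int, int]]  # (field_index, el_index)
    group_norms: dict[tuple[int, int], float]
    selected_spot_ids: list[int]
    surrogate_objective: float

    @property
    def el_count(self) -> int:
        return len(self.selected_els)

    def counts_per_field(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for f, _ in self.selected_els:
            out[f] = out.get(f, 0) + 1
        return out


def build_el_groups(spots: list[Spot]) -> list[ELGroup]:
    """Partition candidate spots into one group per distinct (field, EL)."""
    if not spots:
        raise ValueError("no spots to group")
    members: dict[tuple[int, int], list[int]] = {}
    for s in spots:
        members.setdefault((s.field_index, s.el_index), []).append(s.id)
    return [
        ELGroup(i, f, e, tuple(ids))
        for i, ((f, e), ids) in enumerate(sorted(members.items()))
    ]


def _group_columns(dij: DoseInfluence, groups: list[ELGroup]) -> list[np.ndarray]:
    col_of = {s.id: j for j, s in enumerate(dij.spots)}
    return [np.array([col_of[i] for i in g.spot_ids], int) for g in groups]


def reduce_energy_layers(
    dij: DoseInfluence,
    phantom: Phantom,
    wishlist: WishList,
    groups: list[ELGroup] | None = None,
    lam: float = 1.0,
    threshold: float = EL_ACTIVITY_THRESHOLD,
    norm: str = "l2",
) -> ELRResult:
    """Group-lasso EL selection on the scalarized wish-list surrogate.

    ``norm="l2"`` uses the classical sqrt-group-size weighted L2 group norm;
    ``norm="linf"`` is available as a config switch (penalizes the group max,
    here through the same machinery after per-group weight rescaling).
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if groups is None:
        groups = build_el_groups(dij.spots)
    cols = _group_columns(dij, groups)
    prob = build_surrogate(dij, phantom, wishlist)

    if norm == "l2":
        gw = np.array([np.sqrt(len(g.spot_ids)) for g in groups])
    elif norm == "linf":
        gw = np.ones(len(groups))
    else:
        raise ValueError(f"unknown group norm {norm!r}")

    if lam == 0.0:
        x, val = prob.solve()
    else:
        x, val = prob.solve_group(cols, gw, lam)
    w = x[: dij.n_spots]

    norms = {(g.field_index, g.el_index): float(np.linalg.norm(w[c])) for g, c in zip(groups, cols)}
    max_norm = max(norms.values(), default=0.0)
    selected = sorted(k for k, v in norms.items() if max_norm > 0 and v > threshold * max_norm)
    sel_set = set(selected)
    spot_ids = [s.id for s in dij.spots if (s.field_index, s.el_index) in sel_set]
    return ELRResult(lam, selected, norms, spot_ids, val)


def tune_lambda(
    dij: DoseInfluence,
    phantom: Phantom,
    wishlist: WishList,
    groups: list[ELGroup] | None = None,
    target_els: int = 0,
    bracket: tuple[float, float] = (1e-4, 1e3),
    tol: float = 0.05,
    max_bisect: int = 25,
) -> tuple[float, "ELRResult"]:
    """Bisect log-lambda until the selected EL count is within ±tol of target."""
    if groups is None:
        groups = build_el_groups(dij.spots)
    lo, hi = bracket
    res_lo = reduce_energy_layers(dij, phantom, wishlist, groups, lo)
    res_hi = reduce_energy_layers(dij, phantom, wishlist, groups, hi)
    if not (res_hi.el_count <= target_els <= res_lo.el_count):
        raise ValueError(
            f"target EL count {target_els} outside bracket: lambda {lo:g} -> "
            f"{res_lo.el_count} ELs, lambda {hi:g} -> {res_hi.el_count} ELs"
        )
    best = res_lo if abs(res_lo.el_count - target_els) <= abs(res_hi.el_count - target_els) else res_hi
    for _ in range(max_bisect):
        if abs(best.el_count - target_els) <= tol * target_els:
            break
        mid = float(np.sqrt(lo * hi))
        res = reduce_energy_layers(dij, phantom, wishlist, groups, mid)
        if abs(res.el_count - target_els) < abs(best.el_count - target_els):
            best = res
        if res.el_count > target_els:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.01:
            break
    return best.lam, best
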