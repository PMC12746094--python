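"""Wish-list driven multi-criteria spot-weight optimization.

A wish-list is the single optimization recipe shared by every planning mode:
an ordered set of hard dose constraints plus prioritized objectives with
goal values. Plans are generated by lexicographic (epsilon-constraint)
optimization: objectives are minimized one priority at a time, each solve
keeping all hard constraints and bounding the already-optimized objectives
at their achieved values relaxed by a small slack factor ``delta``. Robust
items are enforced in every scenario of the scenario set; everything else
uses the nominal scenario. The result is a single Pareto-optimal plan per
phantom, with no manual Pareto navigation, and using the same wish-list for
all delivery approaches removes planning bias from their comparison.

All stages are linear programs: mean dose is linear in the spot weights and
max dose enters through an epigraph auxiliary variable. A scalarized
surrogate (inverse-priority weighted sum of the same objective terms under
the same hard constraints) is provided for the sparsification stages, which
need a single convex solve per regularization coefficient.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from ._opt import FEAS_TOL_GY, RowGroups, solve_lp, solve_group_penalized
from .beamline import BeamConfig, DoseInfluence, Spot
from .phantom import Phantom

__all__ = [
    "HardConstraint",
    "Objective",
    "WishList",
    "Plan",
    "parse_wishlist",
    "default_wishlist",
    "solve_lexicographic",
    "per_field_max_dose",
    "SurrogateProblem",
    "build_surrogate",
    "surrogate_value",
]

CONSTRAINT_METRICS = ("max_dose", "min_dose", "mean_dose", "per_field_max_dose")
OBJECTIVE_METRICS = ("mean_dose", "max_dose")
PER_FIELD_CAP_GY = 47.0  # clinical per-field max dose contribution
DEFAULT_DELTA = 0.03  # slack when bounding already-optimized objectives


@dataclass(frozen=True)
class HardConstraint:
    structure: str
    metric: str
    bound: float
    robust: bool = False

    def __post_init__(self) -> None:
        if self.metric not in CONSTRAINT_METRICS:
            raise ValueError(f"unknown constraint metric {self.metric!r}")
        if self.bound < 0:
            raise ValueError(f"negative bound for {self.structure}/{self.metric}")

    @property
    def label(self) -> str:
        tag = "robust " if self.robust else ""
        return f"{tag}{self.metric} {self.structure} <= {self.bound} Gy".replace(
            "min_dose", "min_dose >="
        )


@dataclass(frozen=True)
class Objective:
    priority: int
    structure: str
    metric: str
    goal: float
    sufficient: bool = False
    robust: bool = False

    def __post_init__(self) -> None:
        if self.metric not in OBJECTIVE_METRICS:
            raise ValueError(f"unknown objective metric {self.metric!r}")
        if self.priority < 1:
            raise ValueError("priorities start at 1")
        if self.goal < 0:
            raise ValueError("negative goal")


@dataclass
class WishList:
    constraints: list[HardConstraint]
    objectives: list[Objective]

    def __post_init__(self) -> None:
        prios = sorted(o.priority for o in self.objectives)
        if len(set(prios)) != len(prios):
            dup = [p for p in prios if prios.count(p) > 1][0]
            raise ValueError(f"duplicate objective priority {dup}")
        if prios and prios != list(range(1, len(prios) + 1)):
            raise ValueError(f"priorities must be contiguous from 1, got {prios}")
        self.objectives = sorted(self.objectives, key=lambda o: o.priority)

    def to_json(self) -> str:
        return json.dumps(
            {
                "constraints": [asdict(c) for c in self.constraints],
                "objectives": [asdict(o) for o in self.objectives],
            },
            indent=2,
        )

    def digest(self) -> str:
        """Stable hash — every report in one study must carry the same one."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def parse_wishlist(text: str) -> WishList:
    d = json.loads(text)
    return WishList(
        constraints=[HardConstraint(**c) for c in d.get("constraints", [])],
        objectives=[Objective(**o) for o in d.get("objectives", [])],
    )


def default_wishlist() -> WishList:
    """Illustrative head-and-neck wish-list shipped with the package.

    Robust min/max constraints on the targets, a robust serial-OAR (cord)
    max, the per-field dose cap, and nominal-scenario mean-dose objectives
    ordered parotids -> constrictor -> cord -> low-dose bath. Goal values
    are schematic for the synthetic phantoms, not a clinical protocol.
    """
    from importlib.resources import files

    return parse_wishlist(files("protonarc.data").joinpath("wishlist_default.json").read_text())


# ---------------------------------------------------------------------------
# plans


@dataclass
class Plan:
    """Nonnegative spot weights (MU) over a selected spot support."""

    weights: np.ndarray
    spots: list[Spot]
    mode: str = ""
    beams: list[BeamConfig] = field(default_factory=list)
    achieved: dict[int, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.spots):
            raise ValueError("one weight per support spot required")
        if (self.weights < -1e-9).any():
            raise ValueError("spot weights must be nonnegative")

    @property
    def spot_ids(self) -> list[int]:
        return [s.id for s in self.spots]

    def active(self, tol: float = 1e-9) -> np.ndarray:
        return self.weights > tol

    def selected_els(self, tol: float = 1e-9) -> list[tuple[int, int]]:
        """Distinct (field, energy layer) pairs carrying weight."""
        keys = {(s.field_index, s.el_index) for s, a in zip(self.spots, self.active(tol)) if a}
        return sorted(keys)

    @property
    def total_mu(self) -> float:
        return float(self.weights.sum())

    def weights_on(self, dij: DoseInfluence) -> np.ndarray:
        """Scatter the support weights onto a candidate Dij's spot columns."""
        by_id = {s.id: w for s, w in zip(self.spots, self.weights)}
        return np.array([by_id.get(s.id, 0.0) for s in dij.spots])

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "beams": [asdict(b) for b in self.beams],
                "spots": [asdict(s) for s in self.spots],
                "weights": [[s.id, float(w)] for s, w in zip(self.spots, self.weights)],
                "achieved": {str(k): v for k, v in self.achieved.items()},
                "meta": self.meta,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Plan":
        d = json.loads(text)
        spots = [
            Spot(s["field_index"], s["el_index"], s["nominal_range_mm"], tuple(s["lateral_mm"]), s["id"])
            for s in d["spots"]
        ]
        w = dict(d["weights"])
        return cls(
            weights=np.array([w[s.id] for s in spots]),
            spots=spots,
            mode=d.get("mode", ""),
            beams=[BeamConfig(**b) for b in d.get("beams", [])],
            achieved={int(k): v for k, v in d.get("achieved", {}).items()},
            meta=d.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# constraint / objective assembly


def _structure_voxels(phantom: Phantom, structure: str) -> np.ndarray:
    if structure not in phantom.masks:
        raise KeyError(f"unknown structure {structure!r}")
    idx = np.flatnonzero(phantom.masks[structure].ravel())
    if idx.size == 0:
        raise ValueError(f"structure {structure!r} has an empty mask")
    return idx


def _scenario_indices(dij: DoseInfluence, robust: bool) -> list[int]:
    return list(range(len(dij.scenario_set))) if robust else [dij.scenario_set.nominal_index]


def build_hard_constraints(
    dij: DoseInfluence, phantom: Phantom, wishlist: WishList
) -> tuple[sp.csr_matrix, np.ndarray, RowGroups]:
    """Stack all hard constraints as ``A w <= b`` over the Dij spot columns."""
    n = dij.n_spots
    blocks: list[sp.spmatrix] = []
    bs: list[np.ndarray] = []
    names: list[tuple[str, int]] = []
    for c in wishlist.constraints:
        idx = _structure_voxels(phantom, c.structure)
        scens = _scenario_indices(dij, c.robust)
        n_before = sum(len(x) for x in bs)
        if c.metric == "max_dose":
            for s in scens:
                rows = dij.matrices[s][idx, :]
                blocks.append(rows)
                bs.append(np.full(rows.shape[0], c.bound))
        elif c.metric == "min_dose":
            for s in scens:
                rows = -dij.matrices[s][idx, :]
                blocks.append(rows)
                bs.append(np.full(rows.shape[0], -c.bound))
        elif c.metric == "mean_dose":
            for s in scens:
                row = sp.csr_matrix(dij.matrices[s][idx, :].mean(axis=0))
                blocks.append(row)
                bs.append(np.array([c.bound]))
        elif c.metric == "per_field_max_dose":
            nominal = dij.nominal[idx, :].tocsc()
            for fi in range(len(dij.beams)):
                cols = dij.field_columns(fi)
                if cols.size == 0:
                    continue
                ind = np.zeros((1, n))
                ind[0, cols] = 1.0
                rows = nominal.multiply(sp.csr_matrix(ind)).tocsr()
                blocks.append(rows)
                bs.append(np.full(rows.shape[0], c.bound))
        names.append((c.label, sum(len(x) for x in bs) - n_before))
    A = sp.vstack(blocks, format="csr") if blocks else sp.csr_matrix((0, n))
    b = np.concatenate(bs) if bs else np.zeros(0)
    return A, b, RowGroups.stack(names)


def _objective_rows(
    dij: DoseInfluence, phantom: Phantom, obj: Objective
) -> tuple[str, sp.csr_matrix]:
    """Rows whose max (epigraph) or single row (linear) is the objective value."""
    idx = _structure_voxels(phantom, obj.structure)
    scens = _scenario_indices(dij, obj.robust)
    if obj.metric == "mean_dose":
        rows = sp.vstack(
            [sp.csr_matrix(dij.matrices[s][idx, :].mean(axis=0)) for s in scens], format="csr"
        )
        kind = "linear" if rows.shape[0] == 1 else "epigraph"
        return kind, rows
    rows = sp.vstack([dij.matrices[s][idx, :] for s in scens], format="csr")
    return "epigraph", rows


def objective_value(rows_kind: str, rows: sp.csr_matrix, w: np.ndarray) -> float:
    vals = np.asarray(rows @ w).ravel()
    return float(vals[0]) if rows_kind == "linear" else float(vals.max())


# ---------------------------------------------------------------------------
# lexicographic solve


def solve_lexicographic(
    dij: DoseInfluence,
    phantom: Phantom,
    wishlist: WishList,
    support: list[int] | None = None,
    extra_penalty: dict | None = None,
    delta: float = DEFAULT_DELTA,
    mode: str = "",
) -> Plan:
    """Sequential per-priority solves under hard + epsilon constraints.

    ``support``: optional list of spot ids to restrict the problem to.
    ``extra_penalty``: optional ``{"kind": "l1"|"group", "coefficient": x,
    "groups": [...], "group_weights": [...]}`` added to every stage's cost.
    """
    work = dij
    if support is not None:
        cols = work.columns_for_ids(set(support))
        if cols.size == 0:
            raise ValueError("support is empty on this Dij")
        work = work.restrict(cols)
    n = work.n_spots

    A_hard, b_hard, row_groups = build_hard_constraints(work, phantom, wishlist)
    eps_rows: list[sp.csr_matrix] = []
    eps_b: list[np.ndarray] = []
    achieved: dict[int, float] = {}
    w = np.zeros(n)

    pen = extra_penalty or {}
    pen_kind = pen.get("kind")
    pen_coeff = float(pen.get("coefficient", 0.0))

    if not wishlist.objectives:
        # pure feasibility problem
        w = solve_lp(np.zeros(n), A_hard, b_hard, row_groups=row_groups, context="feasibility")
        return Plan(w, work.spots, mode=mode, beams=work.beams, achieved={})

    for obj in wishlist.objectives:
        kind, rows = _objective_rows(work, phantom, obj)
        use_aux = kind == "epigraph"
        n_var = n + (1 if use_aux else 0)

        c = np.zeros(n_var)
        if use_aux:
            c[n] = 1.0
        else:
            c[:n] = np.asarray(rows.todense()).ravel()
        if pen_kind == "l1":
            c[:n] += pen_coeff

        A_parts = [A_hard] + eps_rows
        b_parts = [b_hard] + eps_b
        group_parts: list[tuple[str, int]] = [("hard+eps", A_hard.shape[0] + sum(r.shape[0] for r in eps_rows))]
        A_stage = sp.vstack(A_parts, format="csr") if A_parts else sp.csr_matrix((0, n))
        b_stage = np.concatenate(b_parts) if b_parts else np.zeros(0)
        if use_aux:
            A_stage = sp.hstack([A_stage, sp.csr_matrix((A_stage.shape[0], 1))], format="csr")
            epi = sp.hstack([rows, -sp.csr_matrix(np.ones((rows.shape[0], 1)))], format="csr")
            A_stage = sp.vstack([A_stage, epi], format="csr")
            b_stage = np.concatenate([b_stage, np.zeros(rows.shape[0])])

        ctx = f"priority {obj.priority} ({obj.structure} {obj.metric})"
        rg = RowGroups(
            row_groups.names + [f"epsilon bound priority <= {obj.priority - 1}", "epigraph"],
            row_groups.slices
            + [
                slice(A_hard.shape[0], A_hard.shape[0] + sum(r.shape[0] for r in eps_rows)),
                slice(A_stage.shape[0] - rows.shape[0], A_stage.shape[0]),
            ],
        )
        if pen_kind == "group" and pen_coeff > 0:
            x = solve_group_penalized(
                c,
                A_stage,
                b_stage,
                groups=[np.asarray(g, int) for g in pen["groups"]],
                group_weights=np.asarray(pen["group_weights"], float),
                lam=pen_coeff,
                row_groups=rg,
                context=ctx,
            )
        else:
            x = solve_lp(c, A_stage, b_stage, row_groups=rg, context=ctx)
        w = x[:n]

        value = objective_value(kind, rows, w)
        recorded = max(value, obj.goal) if obj.sufficient else value
        achieved[obj.priority] = recorded
        bound = recorded * (1.0 + delta) + 10.0 * FEAS_TOL_GY
        eps_rows.append(rows)
        eps_b.append(np.full(rows.shape[0], bound))

    return Plan(w, work.spots, mode=mode, beams=work.beams, achieved=achieved)


def per_field_max_dose(plan: Plan, dij: DoseInfluence, field_index: int) -> float:
    """Max voxel dose from one field's spots alone, nominal scenario."""
    if field_index < 0 or field_index >= len(dij.beams):
        raise KeyError(f"unknown field {field_index}")
    w = plan.weights_on(dij)
    cols = dij.field_columns(field_index)
    if cols.size == 0:
        return 0.0
    dose = np.asarray(dij.nominal[:, cols] @ w[cols]).ravel()
    return float(dose.max(initial=0.0))


# ---------------------------------------------------------------------------
# scalarized surrogate (for SISS / ELR / BAO)


@dataclass
class SurrogateProblem:
    """Weighted-sum surrogate of the wish-list under its hard constraints.

    Variables are ``[w, t_1..t_m]`` with one epigraph auxiliary per max-type
    objective; the cost is the inverse-priority weighted sum (priority k gets
    weight ``10**(1-k)``).
    """

    c: np.ndarray
    A_ub: sp.csr_matrix
    b_ub: np.ndarray
    n_spots: int
    row_groups: RowGroups

    def pad_groups(self, groups: list[np.ndarray]) -> list[np.ndarray]:
        return [np.asarray(g, int) for g in groups]

    def solve(self, extra_linear_cost: np.ndarray | None = None) -> tuple[np.ndarray, float]:
        c = self.c.copy()
        if extra_linear_cost is not None:
            c[: self.n_spots] += extra_linear_cost
        x = solve_lp(c, self.A_ub, self.b_ub, row_groups=self.row_groups, context="surrogate LP")
        return x, float(self.c @ x)

    def solve_group(
        self, groups: list[np.ndarray], group_weights: np.ndarray, lam: float,
        x0: np.ndarray | None = None,
    ) -> tuple[np.ndarray, float]:
        x = solve_group_penalized(
            self.c,
            self.A_ub,
            self.b_ub,
            groups=self.pad_groups(groups),
            group_weights=group_weights,
            lam=lam,
            x0=x0,
            row_groups=self.row_groups,
            context="surrogate group solve",
        )
        return x, float(self.c @ x)


def build_surrogate(dij: DoseInfluence, phantom: Phantom, wishlist: WishList) -> SurrogateProblem:
    n = dij.n_spots
    A_hard, b_hard, row_groups = build_hard_constraints(dij, phantom, wishlist)
    c_w = np.zeros(n)
    epi_blocks: list[sp.csr_matrix] = []
    aux_costs: list[float] = []
    for obj in wishlist.objectives:
        weight = 10.0 ** (1 - obj.priority)
        kind, rows = _objective_rows(dij, phantom, obj)
        if kind == "linear":
            c_w += weight * np.asarray(rows.todense()).ravel()
        else:
            epi_blocks.append(rows)
            aux_costs.append(weight)

    m = len(epi_blocks)
    A = sp.hstack([A_hard, sp.csr_matrix((A_hard.shape[0], m))], format="csr")
    b = b_hard
    names = list(row_groups.names)
    slices = list(row_groups.slices)
    for k, rows in enumerate(epi_blocks):
        aux_cols = sp.csr_matrix(
            (-np.ones(rows.shape[0]), (np.arange(rows.shape[0]), np.full(rows.shape[0], k))),
            shape=(rows.shape[0], m),
        )
        block = sp.hstack([rows, aux_cols], format="csr")
        names.append(f"epigraph aux {k}")
        slices.append(slice(A.shape[0], A.shape[0] + rows.shape[0]))
        A = sp.vstack([A, block], format="csr")
        b = np.concatenate([b, np.zeros(rows.shape[0])])

    c = np.concatenate([c_w, np.asarray(aux_costs)])
    return SurrogateProblem(c, A, b, n, RowGroups(names, slices))


def surrogate_value(prob: SurrogateProblem, w: np.ndarray) -> float:
    """Surrogate cost of given spot weights (auxiliaries evaluated tight)."""
    val = float(prob.c[: prob.n_spots] @ w)
    # evaluate each epigraph aux at its tight value
    aux_i = 0
    for name, sl in zip(prob.row_groups.names, prob.row_groups.slices):
        if name.startswith("epigraph aux"):
            rows = prob.A_ub[sl, : prob.n_spots]
            val += prob.c[prob.n_spots + aux_i] * float(np.asarray(rows @ w).max(initial=0.0))
            aux_i += 1
    return val
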