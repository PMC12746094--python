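"""Deterministic toy problems with independently computed optima.

Every registry entry bundles a hand-sized planning problem (a few voxels and
spots wrapped in real :class:`Phantom` / :class:`DoseInfluence` containers)
together with brute-force oracle *code* — dense grid search or exhaustive
enumeration written against raw numpy/scipy, independent of the package's
solver stack — so tests regenerate the expected optima instead of trusting
frozen constants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .beamline import BeamConfig, DoseInfluence, Spot
from .mco import HardConstraint, Objective, WishList
from .phantom import GridSpec, Phantom
from .scenarios import build_scenarios

__all__ = ["ToyProblem", "toy_lp", "list_toys", "slab_phantom", "toy_problem"]


@dataclass
class ToyProblem:
    name: str
    dij: DoseInfluence
    phantom: Phantom
    wishlist: WishList
    notes: str = ""
    extras: dict = field(default_factory=dict)

    # ---- independent dense oracles -------------------------------------

    def dense_matrix(self) -> np.ndarray:
        return np.asarray(self.dij.nominal.todense())

    def _structure_rows(self, structure: str) -> np.ndarray:
        return np.flatnonzero(self.phantom.masks[structure].ravel())

    def oracle_feasible(self, w: np.ndarray, tol: float = 1e-6) -> bool:
        D = self.dense_matrix()
        dose = D @ w
        for c in self.wishlist.constraints:
            dv = dose[self._structure_rows(c.structure)]
            if c.metric == "max_dose" and dv.max() > c.bound + tol:
                return False
            if c.metric == "min_dose" and dv.min() < c.bound - tol:
                return False
            if c.metric == "mean_dose" and dv.mean() > c.bound + tol:
                return False
        return True

    def oracle_objective_vector(self, w: np.ndarray) -> list[float]:
        D = self.dense_matrix()
        dose = D @ w
        out = []
        for o in self.wishlist.objectives:
            dv = dose[self._structure_rows(o.structure)]
            out.append(float(dv.mean() if o.metric == "mean_dose" else dv.max()))
        return out

    def oracle_grid_search(self, w_max: float, n_grid: int) -> tuple[np.ndarray, list[float]]:
        """Lexicographic optimum by dense search over the feasible weight box."""
        axes = [np.linspace(0.0, w_max, n_grid)] * self.dij.n_spots
        best_w, best_vec = None, None
        for w in itertools.product(*axes):
            w = np.asarray(w)
            if not self.oracle_feasible(w, tol=1e-9):
                continue
            vec = self.oracle_objective_vector(w)
            if best_vec is None or vec < best_vec:
                best_w, best_vec = w, vec
        if best_w is None:
            raise RuntimeError("grid search found no feasible point")
        return best_w, best_vec

    def oracle_constrained_lp(
        self, support: np.ndarray | None = None, extra_cost: np.ndarray | None = None
    ) -> tuple[np.ndarray | None, float]:
        """Weighted-sum optimum on a spot support, assembled densely from
        scratch (independent of the package's constraint builder)."""
        D = self.dense_matrix()
        n = D.shape[1]
        sub = np.arange(n) if support is None else np.asarray(support, int)
        Ds = D[:, sub]
        A_ub, b_ub = [], []
        for c in self.wishlist.constraints:
            rows = Ds[self._structure_rows(c.structure)]
            if c.metric == "max_dose":
                A_ub.append(rows)
                b_ub.append(np.full(rows.shape[0], c.bound))
            elif c.metric == "min_dose":
                A_ub.append(-rows)
                b_ub.append(np.full(rows.shape[0], -c.bound))
            elif c.metric == "mean_dose":
                A_ub.append(rows.mean(axis=0, keepdims=True))
                b_ub.append(np.array([c.bound]))
        cvec = np.zeros(len(sub))
        for o in self.wishlist.objectives:
            rows = Ds[self._structure_rows(o.structure)]
            wgt = 10.0 ** (1 - o.priority)
            if o.metric == "mean_dose":
                cvec += wgt * rows.mean(axis=0)
            else:  # bound the max through per-voxel rows and an epigraph var
                cvec = np.concatenate([cvec, [wgt]])
                pad = [np.hstack([a, np.zeros((a.shape[0], 1))]) for a in A_ub]
                A_ub = pad + [np.hstack([rows, -np.ones((rows.shape[0], 1))])]
                b_ub.append(np.zeros(rows.shape[0]))
                Ds = np.hstack([Ds, np.zeros((Ds.shape[0], 1))])
        res = linprog(
            cvec,
            A_ub=np.vstack(A_ub) if A_ub else None,
            b_ub=np.concatenate(b_ub) if b_ub else None,
            bounds=(0, None),
            method="highs",
        )
        if res.status == 2:
            return None, np.inf
        return res.x, float(res.fun)

    def oracle_el_subsets(self, lam: float, group_weight_fn=np.sqrt) -> list[tuple[int, int]]:
        """Best EL subset by exhaustive enumeration: for every subset solve
        the support-restricted weighted-sum LP and add the group penalty of
        its solution; return the subset of lowest total score (ties to the
        smaller subset)."""
        keys = sorted({(s.field_index, s.el_index) for s in self.dij.spots})
        cols = {
            k: np.array([j for j, s in enumerate(self.dij.spots)
                         if (s.field_index, s.el_index) == k], int)
            for k in keys
        }
        best_keys, best_score = None, np.inf
        for r in range(1, len(keys) + 1):
            for subset in itertools.combinations(keys, r):
                sub = np.concatenate([cols[k] for k in subset])
                x, val = self.oracle_constrained_lp(support=sub)
                if x is None:
                    continue
                w = x[: len(sub)]
                pen = 0.0
                start = 0
                for k in subset:
                    nk = len(cols[k])
                    pen += group_weight_fn(nk) * float(np.linalg.norm(w[start : start + nk]))
                    start += nk
                score = val + lam * pen
                if score < best_score - 1e-9 or (
                    best_keys is not None
                    and abs(score - best_score) <= 1e-9
                    and len(subset) < len(best_keys)
                ):
                    best_keys, best_score = list(subset), score
        if best_keys is None:
            raise RuntimeError("no feasible EL subset")
        return sorted(best_keys)

    def oracle_support_enumeration(self, coeff: float) -> tuple[tuple[int, ...], float]:
        """Best spot support for the L1-penalized problem by enumerating all
        nonempty supports; score = restricted LP value + coeff * sum(w)."""
        n = self.dij.n_spots
        best, best_score = None, np.inf
        for r in range(1, n + 1):
            for sub in itertools.combinations(range(n), r):
                x, val = self.oracle_constrained_lp(support=np.array(sub))
                if x is None:
                    continue
                score = val + coeff * float(x[: len(sub)].sum())
                if score < best_score - 1e-12:
                    best, best_score = sub, score
        if best is None:
            raise RuntimeError("no feasible support")
        return best, best_score


# ---------------------------------------------------------------------------
# construction helpers


def toy_problem(
    name: str,
    matrix: np.ndarray,
    masks: dict[str, list[int]],
    wishlist: WishList,
    el_of_spot: list[tuple[int, int]] | None = None,
    notes: str = "",
) -> ToyProblem:
    """Wrap a dense (voxels x spots) matrix as a single-scenario problem."""
    D = np.asarray(matrix, float)
    n_vox, n_spots = D.shape
    grid = GridSpec((n_vox, 1, 1), (1.0, 1.0, 1.0))
    mask_arrays: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    body = np.ones(grid.shape, bool)
    mask_arrays["body"] = body
    roles["body"] = "body"
    for mname, vox in masks.items():
        m = np.zeros(grid.shape, bool)
        m.ravel()[list(vox)] = True
        mask_arrays[mname] = m
        roles[mname] = "target_high" if mname.startswith("t") else "oar_parallel"
    phantom = Phantom(grid, np.ones(grid.shape), mask_arrays, roles)

    if el_of_spot is None:
        el_of_spot = [(0, j) for j in range(n_spots)]
    spots = [
        Spot(f, e, 100.0, (float(j), 0.0), j) for j, (f, e) in enumerate(el_of_spot)
    ]
    beams = [BeamConfig(0.0)] * (max(f for f, _ in el_of_spot) + 1)
    dij = DoseInfluence(
        grid, beams, spots, build_scenarios(mode="nominal_only"), [sp.csc_matrix(D)]
    )
    return ToyProblem(name, dij, phantom, wishlist, notes)


# ---------------------------------------------------------------------------
# registry


def _two_spot_lex() -> ToyProblem:
    D = np.array([[1.0, 1.0], [1.0, 0.2], [0.2, 1.0]])
    wl = WishList(
        constraints=[HardConstraint("t", "min_dose", 60.0)],
        objectives=[
            Objective(1, "oar_a", "mean_dose", 5.0),
            Objective(2, "oar_b", "mean_dose", 5.0),
        ],
    )
    return toy_problem(
        "two_spot_lex",
        D,
        {"t": [0], "oar_a": [1], "oar_b": [2]},
        wl,
        notes="two prioritized mean-dose objectives; grid-search checkable",
    )


def _one_el_sufficient() -> ToyProblem:
    # three ELs, two spots each; only EL (0, 2) covers the target efficiently
    D = np.array(
        [
            [0.20, 0.20, 0.50, 0.50, 1.00, 0.95],  # target voxel
            [0.80, 0.70, 0.50, 0.40, 0.10, 0.12],  # OAR voxel
            [0.50, 0.60, 0.30, 0.30, 0.05, 0.08],  # OAR voxel
        ]
    )
    wl = WishList(
        constraints=[HardConstraint("t", "min_dose", 60.0)],
        objectives=[Objective(1, "oar", "mean_dose", 5.0)],
    )
    return toy_problem(
        "one_el_sufficient",
        D,
        {"t": [0], "oar": [1, 2]},
        wl,
        el_of_spot=[(0, 0), (0, 0), (0, 1), (0, 1), (0, 2), (0, 2)],
        notes="unique minimal EL subset {(0, 2)} at large lambda",
    )


def _infeasible_minmax() -> ToyProblem:
    D = np.array([[1.0]])
    wl = WishList(
        constraints=[
            HardConstraint("t", "min_dose", 70.0),
            HardConstraint("t", "max_dose", 60.0),
        ],
        objectives=[Objective(1, "t", "mean_dose", 0.0)],
    )
    return toy_problem("infeasible_minmax", D, {"t": [0]}, wl, notes="contradictory bounds")


def _five_spot_l1() -> ToyProblem:
    # two target voxels individually covered by cheap spots 0/1 or jointly by
    # the L1-favoured spot 2; spots 3/4 are dominated
    D = np.array(
        [
            [1.00, 0.05, 0.55, 0.30, 0.20],  # target voxel 0
            [0.05, 1.00, 0.55, 0.20, 0.30],  # target voxel 1
            [0.05, 0.05, 0.30, 0.60, 0.60],  # OAR voxel
            [0.10, 0.10, 0.30, 0.60, 0.60],  # OAR voxel
        ]
    )
    wl = WishList(
        constraints=[HardConstraint("t", "min_dose", 50.0)],
        objectives=[Objective(1, "oar", "mean_dose", 5.0)],
    )
    return toy_problem(
        "five_spot_l1",
        D,
        {"t": [0, 1], "oar": [2, 3]},
        wl,
        notes="L1 sweep: support {0,1} at small coefficients collapses to {2}",
    )


def _three_el_ladder() -> ToyProblem:
    # ELs 0/1/2 each cover one target voxel; EL 3 covers voxels 0+1 jointly.
    # Group-sparsified solutions walk 3 ELs -> 2 ELs along lambda (EL 2 is
    # always needed for voxel 2).
    D = np.array(
        [
            [1.00, 0.05, 0.05, 0.60],  # target voxel 0
            [0.05, 1.00, 0.05, 0.60],  # target voxel 1
            [0.05, 0.05, 1.00, 0.05],  # target voxel 2
            [0.05, 0.05, 0.05, 0.30],  # OAR voxel
        ]
    )
    wl = WishList(
        constraints=[HardConstraint("t", "min_dose", 60.0)],
        objectives=[Objective(1, "oar", "mean_dose", 5.0)],
    )
    return toy_problem(
        "three_el_ladder",
        D,
        {"t": [0, 1, 2], "oar": [3]},
        wl,
        el_of_spot=[(0, 0), (0, 1), (0, 2), (0, 3)],
        notes="EL-count path 3 -> 2 along the group-lasso coefficient",
    )


_REGISTRY = {
    "two_spot_lex": _two_spot_lex,
    "one_el_sufficient": _one_el_sufficient,
    "infeasible_minmax": _infeasible_minmax,
    "five_spot_l1": _five_spot_l1,
    "three_el_ladder": _three_el_ladder,
}


def list_toys() -> list[str]:
    return sorted(_REGISTRY)


def toy_lp(name: str) -> ToyProblem:
    if name not in _REGISTRY:
        raise KeyError(f"unknown toy problem {name!r}; known: {list_toys()}")
    return _REGISTRY[name]()


# ---------------------------------------------------------------------------
# slab phantom (dose-engine verification bed)


def slab_phantom(
    depth_mm: float = 160.0,
    target_span: tuple[float, float] = (80.0, 120.0),
    spacing_mm: float = 2.0,
    width_mm: float = 60.0,
    density: float = 1.0,
    air_margin_mm: float = 10.0,
) -> Phantom:
    """Homogeneous slab with a box target: beam gantry 0 enters at y = 0.

    With uniform density the water-equivalent depth of a point at geometric
    depth y is ``density * y`` — the closed-form check for the ray marcher.
    """
    nx = max(int(round(width_mm / spacing_mm)), 1)
    ny = int(round((depth_mm + air_margin_mm) / spacing_mm))
    grid = GridSpec((nx, ny, 1), (spacing_mm,) * 3, (-width_mm / 2.0, -air_margin_mm, -spacing_mm / 2.0))
    ys = grid.axis_centers(1)
    in_body = (ys >= 0.0) & (ys <= depth_mm)
    in_target = (ys >= target_span[0]) & (ys <= target_span[1])
    body = np.zeros(grid.shape, bool)
    body[:, in_body, :] = True
    target = np.zeros(grid.shape, bool)
    target[:, in_target, :] = True
    target &= body
    dens = np.where(body, float(density), 0.0)
    return Phantom(
        grid,
        dens,
        {"body": body, "ctv70": target},
        {"body": "body", "ctv70": "target_high"},
    )
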