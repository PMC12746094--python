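"""Patient-tailored beam-angle optimization (BAO).

Beam selection follows the total-beam-space paradigm: build a (coarse)
dose-influence matrix for 72 coplanar equiangular candidate beams, solve the
scalarized wish-list surrogate with a beam-level group-lasso penalty (every
spot of one beam forms a group), rank beams by their group weight norm and
keep the ``n_beams`` strongest. Ties are broken toward the smaller gantry
angle. The selected configuration is then planned at full resolution through
the ordinary pipeline, once with and once without range shifters in all
fields, and the better of the two plans is kept (lower summed NTCP, then
lower integral dose).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beamline import (
    BeamConfig,
    BeamlineSettings,
    DoseInfluence,
    compute_dose_influence,
    make_beam_set,
)
from .mco import WishList, build_surrogate
from .phantom import Phantom
from .scenarios import ScenarioSet

__all__ = [
    "BeamRanking",
    "rank_beams",
    "optimize_beam_angles",
    "plan_with_selected_beams",
    "coarse_settings",
]


def plan_with_selected_beams(phantom, beams, config, with_rs=None, mode="explicit"):
    """Full downstream pipeline (spots -> blocking -> SISS -> MCO -> finalize)
    on a fixed beam set; see :func:`protonarc.pipeline.plan_with_selected_beams`."""
    from .pipeline import plan_with_selected_beams as _impl

    return _impl(phantom, beams, config, with_rs=with_rs, mode=mode)


@dataclass
class BeamRanking:
    """Candidate beams ordered by decreasing group weight norm."""

    candidates: list[BeamConfig]
    norms: np.ndarray  # per candidate beam
    order: np.ndarray  # candidate indices, best first

    def top(self, n_beams: int) -> list[BeamConfig]:
        if not (1 <= n_beams <= len(self.candidates)):
            raise ValueError(f"n_beams must be in [1, {len(self.candidates)}]")
        return [self.candidates[i] for i in self.order[:n_beams]]


def coarse_settings(settings: BeamlineSettings, factor: float = 2.0) -> BeamlineSettings:
    """Coarsened spot/EL spacings for the 72-beam total-beam-space solve."""
    from dataclasses import replace

    return replace(
        settings,
        lateral_spacing_mm=settings.lateral_spacing_mm * factor,
        el_spacing_mm=settings.el_spacing_mm * factor,
    )


def rank_beams(
    phantom: Phantom,
    wishlist: WishList,
    scenario_set: ScenarioSet,
    lambda_beam: float = 1.0,
    settings: BeamlineSettings | None = None,
    candidates: list[BeamConfig] | None = None,
    dij: DoseInfluence | None = None,
) -> BeamRanking:
    """Solve the total-beam-space group-sparsified surrogate and rank beams."""
    st = settings or BeamlineSettings()
    if candidates is None:
        candidates = make_beam_set("bao_candidates")
    if dij is None:
        dij = compute_dose_influence(phantom, candidates, scenario_set, st)
    prob = build_surrogate(dij, phantom, wishlist)

    groups = [dij.field_columns(fi) for fi in range(len(candidates))]
    nonempty = [g for g in groups if g.size]
    gw = np.array([np.sqrt(g.size) for g in nonempty])
    if lambda_beam == 0.0:
        x, _ = prob.solve()
    else:
        x, _ = prob.solve_group(nonempty, gw, lambda_beam)
    w = x[: dij.n_spots]

    norms = np.array([float(np.linalg.norm(w[g])) if g.size else 0.0 for g in groups])
    # stable sort on (-norm, gantry): ties go to the smaller gantry angle
    gantry = np.array([b.gantry_deg for b in candidates])
    order = np.lexsort((gantry, -norms))
    return BeamRanking(list(candidates), norms, order)


def optimize_beam_angles(
    phantom: Phantom,
    wishlist: WishList,
    scenario_set: ScenarioSet,
    n_beams: int,
    lambda_beam: float = 1.0,
    settings: BeamlineSettings | None = None,
    coarsen: float = 2.0,
    ranking: BeamRanking | None = None,
) -> list[BeamConfig]:
    """Top-``n_beams`` candidate beams from the group-sparsified solve.

    A precomputed :class:`BeamRanking` may be passed to share one
    total-beam-space solve across several ``n_beams`` choices (the rankings
    are nested by construction, so 6-, 8- and 10-beam configurations from
    one solve are supersets of each other).
    """
    if ranking is None:
        st = coarse_settings(settings or BeamlineSettings(), coarsen)
        ranking = rank_beams(phantom, wishlist, scenario_set, lambda_beam, st)
    return ranking.top(n_beams)
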