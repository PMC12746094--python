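"""Shared fixtures: one session-scoped multi-phantom study feeds the
per-field-cap, ordering-law and statistics checks without re-solving."""

import numpy as np
import pytest

import protonarc as pa
from protonarc.bao import rank_beams
from protonarc.mco import build_surrogate
from protonarc.pipeline import run_study, study_config, study_spec


@pytest.fixture(scope="session")
def study_phantom():
    return pa.generate_phantom(study_spec(), seed=1)


@pytest.fixture(scope="session")
def study_result():
    """10-seed quasi-2D study over all four fixed-beam delivery approaches."""
    return run_study(
        10,
        ["utopia36", "pat36", "cs4", "cs6"],
        config=study_config(),
        base_spec=study_spec(),
        seed=1,
    )


@pytest.fixture(scope="session")
def bao_artifacts(study_phantom):
    """Shared 72-candidate solve: ranking + restricted surrogate objectives."""
    cfg = study_config()
    wl = cfg.resolved_wishlist()
    scen = cfg.scenario_set()
    candidates = pa.make_beam_set("bao_candidates", range_shifter=True)
    dij = pa.compute_dose_influence(study_phantom, candidates, scen, cfg.beamline)
    ranking = rank_beams(
        study_phantom, wl, scen, lambda_beam=cfg.bao_lambda,
        settings=cfg.beamline, candidates=candidates, dij=dij,
    )
    objectives = {}
    for n_beams in (6, 8, 10):
        gantries = {b.gantry_deg for b in ranking.top(n_beams)}
        cols = np.concatenate(
            [dij.field_columns(fi) for fi, b in enumerate(dij.beams) if b.gantry_deg in gantries]
        )
        _, val = build_surrogate(dij.restrict(cols), study_phantom, wl).solve()
        objectives[n_beams] = val
    return {"ranking": ranking, "objectives": objectives, "dij": dij}
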