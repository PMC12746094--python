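"""End-to-end pipeline: beam selection -> (ELR) -> SISS -> MCO -> finalize
-> evaluate, plus multi-phantom comparison studies.

Planning modes
--------------
``pat36``      36 equiangular fields, group-regularized energy-layer
               reduction, then spot selection and MCO.
``utopia36``   identical pipeline with the ELR stage skipped — the
               dosimetric best-case benchmark.
``cs4``/``cs6``  the printed clinical beam-angle class solutions with their
               range-shifter rules.
``bao6``/``bao8``/``bao10``  beam-angle optimization over 72 candidates,
               then full planning of the selected configuration with and
               without range shifters, keeping the better plan.

Every mode is driven by the same wish-list instance; each report carries the
wish-list digest so a study can assert the bias-free-comparison contract.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from ._opt import InfeasibleProblemError
from .bao import rank_beams, coarse_settings
from .beamline import BeamConfig, BeamlineSettings, DoseInfluence, compute_dose_influence, make_beam_set
from .elr import build_el_groups, reduce_energy_layers, tune_lambda
from .evaluate import EvalReport, NTCPModel, compare_plans, evaluate_plan
from .finalize import MU_MAX_DEFAULT, MU_MIN_DEFAULT, enforce_mu_limits, normalize_plan
from .mco import Plan, WishList, build_surrogate, default_wishlist, solve_lexicographic
from .phantom import Phantom, PhantomSpec, default_quasi2d_spec, generate_phantom
from .scenarios import build_scenarios
from .siss import select_spots

__all__ = [
    "PipelineConfig",
    "desk_config",
    "study_spec",
    "study_config",
    "run_mode",
    "plan_with_selected_beams",
    "run_study",
    "StudyResult",
]

log = logging.getLogger("protonarc")

MODES = ("pat36", "utopia36", "cs4", "cs6", "bao6", "bao8", "bao10")


@dataclass
class PipelineConfig:
    beamline: BeamlineSettings = field(default_factory=BeamlineSettings)
    setup_mm: float = 3.0
    range_pct: float = 3.0
    scenario_mode: str = "robust"
    wishlist: WishList | None = None  # None -> packaged default
    ntcp_models: list[NTCPModel] | None = None
    siss_coefficient: float = 0.005
    elr_lambda: float = 0.3
    elr_target_els: int | None = None  # overrides elr_lambda via tuning
    bao_lambda: float = 1.0
    bao_coarsen: float = 2.0
    bao_rs_candidates: bool = True  # range shifters during the 72-beam solve
    mu_min: float = MU_MIN_DEFAULT
    mu_max: float = MU_MAX_DEFAULT
    prescription_gy: float = 70.0
    delta: float = 0.03

    def resolved_wishlist(self) -> WishList:
        return self.wishlist if self.wishlist is not None else default_wishlist()

    def scenario_set(self):
        return build_scenarios(self.setup_mm, self.range_pct, self.scenario_mode)


def desk_config(**overrides) -> PipelineConfig:
    """Desk-scale planning configuration for quasi-2D studies.

    Coarser spot/energy-layer lattices (7 mm) and a higher dose-matrix
    sparsity floor than the machine-resolution defaults, chosen so a full
    robust plan solves in seconds on one CPU while keeping every pipeline
    stage and constraint exactly as in a full-resolution run.
    """
    from .beamline import DoseModel

    cfg = PipelineConfig(
        beamline=BeamlineSettings(
            lateral_spacing_mm=7.0,
            el_spacing_mm=7.0,
            margin_mm=7.0,
            raymarch_step_mm=2.5,
            model=DoseModel(sparsity_floor=1e-3),
        ),
        bao_coarsen=1.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def study_spec(n: int = 28, spacing_mm: float = 4.0) -> PhantomSpec:
    """Jittered quasi-2D phantom spec used for multi-phantom studies."""
    spec = default_quasi2d_spec(n, spacing_mm)
    spec.jitter_mm = 3.0
    spec.radius_jitter_frac = 0.05
    return spec


def study_config(**overrides) -> PipelineConfig:
    """Planning configuration matched to :func:`study_spec` phantoms:
    9 mm spot/EL lattices and uncoarsened beam-angle candidates, so a full
    robust 36-field plan solves in tens of seconds."""
    from .beamline import DoseModel

    cfg = PipelineConfig(
        beamline=BeamlineSettings(
            lateral_spacing_mm=9.0,
            el_spacing_mm=9.0,
            margin_mm=7.0,
            raymarch_step_mm=3.0,
            model=DoseModel(sparsity_floor=2e-3),
        ),
        bao_coarsen=1.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _plan_on_dij(
    phantom: Phantom,
    dij: DoseInfluence,
    config: PipelineConfig,
    mode: str,
    apply_elr: bool,
) -> tuple[Plan, EvalReport]:
    """Shared back half of every mode: (ELR) -> SISS -> MCO -> finalize -> eval."""
    wl = config.resolved_wishlist()
    t0 = time.perf_counter()

    elr_meta: dict = {}
    if apply_elr and (config.elr_lambda > 0 or config.elr_target_els is not None):
        groups = build_el_groups(dij.spots)
        if config.elr_target_els is not None:
            lam, res = tune_lambda(dij, phantom, wl, groups, target_els=config.elr_target_els)
        else:
            res = reduce_energy_layers(dij, phantom, wl, groups, config.elr_lambda)
        elr_meta = {"elr_lambda": res.lam, "elr_selected_els": res.el_count}
        dij = dij.restrict(dij.columns_for_ids(set(res.selected_spot_ids)))
        log.info("%s: ELR kept %d ELs (%d spots), lambda=%g, %.1fs",
                 mode, res.el_count, dij.n_spots, res.lam, time.perf_counter() - t0)

    # exact surrogate value on the (possibly EL-restricted) candidate set:
    # the quantity that orders utopia <= pat and bao6 >= bao8 >= bao10
    prob = build_surrogate(dij, phantom, wl)
    _, surrogate_objective = prob.solve()

    support = select_spots(dij, phantom, wl, config.siss_coefficient)
    log.info("%s: SISS kept %d / %d spots", mode, len(support), dij.n_spots)
    plan = solve_lexicographic(dij, phantom, wl, support=support, delta=config.delta, mode=mode)
    plan = enforce_mu_limits(plan, dij, phantom, wl, config.mu_min, config.mu_max)
    plan = normalize_plan(plan, dij, phantom, config.prescription_gy)
    plan.meta.update(elr_meta)

    report = evaluate_plan(
        plan, dij, phantom,
        ntcp_models=config.ntcp_models,
        wishlist_digest=wl.digest(),
        surrogate_objective=surrogate_objective,
    )
    report.meta.update(elr_meta)
    log.info("%s: done in %.1fs (surrogate objective %.4f)",
             mode, time.perf_counter() - t0, surrogate_objective)
    return plan, report


def plan_with_selected_beams(
    phantom: Phantom,
    beams: list[BeamConfig],
    config: PipelineConfig,
    with_rs: bool | None = None,
    mode: str = "explicit",
    apply_elr: bool = False,
) -> tuple[Plan, EvalReport]:
    """Full downstream pipeline on a fixed beam set.

    ``with_rs``: force range shifters on/off in all fields (None keeps the
    per-beam flags as given, e.g. the class-solution rules).
    """
    if not beams:
        raise ValueError("beam set is empty")
    if with_rs is not None:
        beams = [replace(b, range_shifter=with_rs) for b in beams]
    dij = compute_dose_influence(phantom, beams, config.scenario_set(), config.beamline)
    return _plan_on_dij(phantom, dij, config, mode, apply_elr)


def _better_plan(a: tuple[Plan, EvalReport], b: tuple[Plan, EvalReport]) -> tuple[Plan, EvalReport]:
    """RS / no-RS arbitration: lower total summed NTCP, then integral dose."""
    sa = sum(a[1].summed_ntcp.values())
    sb = sum(b[1].summed_ntcp.values())
    if abs(sa - sb) > 1e-12:
        return a if sa < sb else b
    return a if a[1].integral_dose_gyl <= b[1].integral_dose_gyl else b


def run_mode(phantom: Phantom, mode: str, config: PipelineConfig | None = None) -> tuple[Plan, EvalReport]:
    """Generate and evaluate one plan for one phantom in one delivery mode."""
    config = config or PipelineConfig()
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; known: {MODES}")

    if mode in ("cs4", "cs6"):
        beams = make_beam_set(mode)
        return plan_with_selected_beams(phantom, beams, config, mode=mode)
    if mode in ("pat36", "utopia36"):
        beams = make_beam_set(mode)
        return plan_with_selected_beams(
            phantom, beams, config, mode=mode, apply_elr=(mode == "pat36")
        )
    # baoN: beam-angle selection, then both range-shifter variants
    n_beams = int(mode[3:])
    wl = config.resolved_wishlist()
    candidates = make_beam_set("bao_candidates", range_shifter=config.bao_rs_candidates)
    ranking = rank_beams(
        phantom, wl, config.scenario_set(), config.bao_lambda,
        settings=coarse_settings(config.beamline, config.bao_coarsen),
        candidates=candidates,
    )
    beams = ranking.top(n_beams)
    variants = []
    errors = []
    for with_rs in (False, True):
        try:
            variants.append(
                plan_with_selected_beams(phantom, beams, config, with_rs=with_rs, mode=mode)
            )
        except InfeasibleProblemError as exc:
            # few-field no-shifter configurations may simply not cover the
            # target robustly — the clinical argument for shifter use
            errors.append((with_rs, exc))
            log.info("%s: %s-shifter variant infeasible (%s)", mode,
                     "with" if with_rs else "no", exc)
    if not variants:
        raise errors[0][1]
    plan, report = _better_plan(*variants) if len(variants) == 2 else variants[0]
    report.meta["range_shifter"] = bool(plan.beams[0].range_shifter)
    return plan, report


# ---------------------------------------------------------------------------
# studies


@dataclass
class StudyResult:
    reports: dict[str, list[EvalReport]]  # mode -> per-phantom reports
    plans: dict[str, list[Plan]]
    seeds: list[int]
    metrics: pd.DataFrame  # long format: seed, mode, metric, value
    comparisons: pd.DataFrame  # pairwise Wilcoxon tables
    failures: list[tuple[int, str, str]] = field(default_factory=list)


def run_study(
    n_phantoms: int,
    modes: list[str],
    config: PipelineConfig | None = None,
    base_spec: PhantomSpec | None = None,
    seed: int = 1,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Seeded multi-phantom study: generate phantoms from jittered spec
    perturbations, run every mode on each, and emit paired comparisons.

    Per-phantom failures are isolated and logged; the study continues.
    """
    if n_phantoms < 5:
        raise ValueError("need at least 5 phantoms for paired statistics")
    config = config or study_config()
    if base_spec is None:
        base_spec = study_spec()
    seeds = [int(seed) + i for i in range(n_phantoms)]

    reports: dict[str, list[EvalReport]] = {m: [] for m in modes}
    plans: dict[str, list[Plan]] = {m: [] for m in modes}
    rows = []
    failures: list[tuple[int, str, str]] = []
    out_path = Path(out_dir) if out_dir is not None else None

    for s in seeds:
        phantom = generate_phantom(base_spec, seed=s)
        for mode in modes:
            try:
                plan, report = run_mode(phantom, mode, config)
            except Exception as exc:  # isolate per-phantom failures
                log.error("phantom seed %d mode %s failed: %s", s, mode, exc)
                failures.append((s, mode, str(exc)))
                continue
            reports[mode].append(report)
            plans[mode].append(plan)
            for metric, value in report.flat_metrics().items():
                rows.append({"seed": s, "mode": mode, "metric": metric, "value": value})
            if out_path is not None:
                d = out_path / str(s) / mode
                d.mkdir(parents=True, exist_ok=True)
                (d / "plan.json").write_text(plan.to_json())
                (d / "report.json").write_text(report.to_json())

    metrics = pd.DataFrame(rows)
    comp_rows = []
    for i, ma in enumerate(modes):
        for mb in modes[i + 1 :]:
            if len(reports[ma]) != len(reports[mb]) or len(reports[ma]) < 5:
                continue
            fa = {k: [r.flat_metrics()[k] for r in reports[ma]] for k in reports[ma][0].flat_metrics()}
            fb = {k: [r.flat_metrics()[k] for r in reports[mb]] for k in reports[mb][0].flat_metrics()}
            for metric, res in compare_plans(fa, fb).items():
                comp_rows.append({"mode_a": ma, "mode_b": mb, "metric": metric, **res})
    comparisons = pd.DataFrame(comp_rows)

    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out_path / "metrics.csv", index=False)
        comparisons.to_csv(out_path / "compare.csv", index=False)
        (out_path / "study.json").write_text(
            json.dumps({"seeds": seeds, "modes": modes,
                        "wishlist_digest": config.resolved_wishlist().digest()}, indent=2)
        )
    return StudyResult(reports, plans, seeds, metrics, comparisons, failures)
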