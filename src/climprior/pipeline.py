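"""End-to-end pipeline driver: simulate -> enm -> ensemble -> dispersal ->
prioritize -> report.

Each stage is a function over an in-memory :class:`RunState` (so tests and
scripts can chain them without touching disk) that optionally persists its
outputs into a run directory in the package's text formats; matching
``load_*`` helpers let the CLI resume from a directory. A manifest records
the full configuration, library versions and output checksums; identical
config + seed gives byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import subseed
from .config import PipelineConfig
from .dispersal import DispersalSpec, build_dispersal_features
from .ensemble import (
    TurnoverMap,
    UncertaintyMap,
    consensus_map,
    ensemble_frequency,
    range_change_summary,
    richness,
    turnover,
    uncertainty_anova,
)
from .enm import ENMResult, run_enm
from .grid import ClimateLayerSet, CLIMATE_VARS, GridDomain, OccupancyMatrix, SpeciesRecord, rasterize_domain
from .io import (
    FLOAT_FORMAT,
    domain_from_asc,
    read_layer,
    read_occupancy_csv,
    read_species_csv,
    write_asc,
    write_occupancy_csv,
    write_species_csv,
    write_table,
)
from .prioritize import RankResult, build_problem, performance_curves, rank_cells, top_fraction
from .synth import (
    NicheTruth,
    generate_current_climate,
    generate_future_climate,
    generate_landscape,
    generate_species,
)

log = logging.getLogger("climprior")


@dataclass
class RunState:
    """Everything produced so far in one pipeline run."""

    config: PipelineConfig
    domain: GridDomain | None = None
    climate: dict[str, ClimateLayerSet] = field(default_factory=dict)
    occupancy: dict[str, OccupancyMatrix] = field(default_factory=dict)
    species: list[SpeciesRecord] = field(default_factory=list)
    truth: NicheTruth | None = None
    protected: np.ndarray | None = None
    vegetation: np.ndarray | None = None
    enm: ENMResult | None = None
    # ensemble stage
    consensus_current: np.ndarray | None = None  # (S, N) bool
    consensus_future: np.ndarray | None = None
    frequency_current: np.ndarray | None = None
    frequency_future: np.ndarray | None = None
    richness_stack: np.ndarray | None = None  # (M, K, N) future richness
    uncertainty: UncertaintyMap | None = None
    turnover_map: TurnoverMap | None = None
    range_change: pd.DataFrame | None = None
    range_summary: dict | None = None
    # dispersal stage
    dispersal_specs: list[DispersalSpec] = field(default_factory=list)
    dispersal_features: np.ndarray | None = None  # (S, N)
    # prioritize stage
    solutions: dict[str, RankResult] = field(default_factory=dict)
    selected: dict[str, np.ndarray] = field(default_factory=dict)
    coverage: dict[str, object] = field(default_factory=dict)
    union_map: np.ndarray | None = None

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    @property
    def future_scenarios(self) -> list[str]:
        return [d.scenario_id for d in self.config.climate.deltas()]


# ---------------------------------------------------------------------------
# stage: simulate


def stage_simulate(config: PipelineConfig, outdir: str | Path | None = None) -> RunState:
    """Generate domain, climate, species, protected areas and vegetation."""
    state = RunState(config=config)
    g = config.grid
    state.domain = rasterize_domain(g.n_rows, g.n_cols, g.cell_size, g.origin)
    current = generate_current_climate(
        state.domain, noise_sd=config.climate.noise_sd,
        seed=subseed(config.seed, "climate"),
    )
    futures = generate_future_climate(current, config.climate.deltas())
    state.climate = {c.scenario_id: c for c in [current, *futures]}
    sp = config.species
    state.occupancy, state.species, state.truth = generate_species(
        state.domain, current, futures,
        n_species=sp.n_species,
        breadth_log_mean=sp.breadth_log_mean,
        breadth_log_sd=sp.breadth_log_sd,
        iucn_mix=sp.iucn_mix,
        min_range_cells=sp.min_range_cells,
        seed=subseed(config.seed, "species"),
    )
    lc = config.landscape
    state.protected, state.vegetation = generate_landscape(
        state.domain, lc.pa_fraction,
        veg_smooth_width=lc.veg_smooth_width,
        veg_logit_scale=lc.veg_logit_scale,
        seed=subseed(config.seed, "landscape"),
    )
    log.info(
        "simulate: %d cells, %d species, %d future scenarios, %d protected cells",
        state.domain.n_cells, len(state.species), len(futures),
        int(state.protected.sum()),
    )
    if outdir is not None:
        _write_simulate(state, Path(outdir))
    return state


def _write_simulate(state: RunState, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    domain = state.domain
    write_asc(outdir / "domain.asc", np.ones(domain.n_cells), domain)
    for scen, clim in state.climate.items():
        for var in CLIMATE_VARS:
            write_asc(outdir / f"climate_{scen}_{var}.asc", clim.layer(var), domain)
    for scen, occ in state.occupancy.items():
        write_occupancy_csv(outdir / f"occupancy_truth_{scen}.csv", occ)
    write_species_csv(outdir / "species.csv", state.species)
    write_asc(outdir / "protected.asc", state.protected.astype(float), domain)
    write_asc(outdir / "vegetation.asc", state.vegetation, domain)
    truth = state.truth
    write_table(outdir / "niche_truth.csv", pd.DataFrame({
        "species_id": state.species_ids,
        **{f"center_{v}": truth.centers[:, k] for k, v in enumerate(CLIMATE_VARS)},
        **{f"breadth_{v}": truth.breadths[:, k] for k, v in enumerate(CLIMATE_VARS)},
    }))
    state.config.to_yaml(outdir / "config.yaml")


def load_simulated(outdir: str | Path, config: PipelineConfig | None = None) -> RunState:
    """Rebuild a RunState from a simulate-stage directory (user data entry
    point: any directory in these formats works)."""
    outdir = Path(outdir)
    config = config or PipelineConfig.from_yaml(outdir / "config.yaml")
    state = RunState(config=config)
    state.domain = domain_from_asc(outdir / "domain.asc")
    scen_ids = ["current"] + [d.scenario_id for d in config.climate.deltas()]
    for scen in scen_ids:
        values = np.column_stack([
            read_layer(outdir / f"climate_{scen}_{var}.asc", state.domain)
            for var in CLIMATE_VARS
        ])
        state.climate[scen] = ClimateLayerSet(scen, state.domain, values)
    state.species = read_species_csv(outdir / "species.csv")
    for scen in scen_ids:
        path = outdir / f"occupancy_truth_{scen}.csv"
        if path.exists():
            state.occupancy[scen] = read_occupancy_csv(
                path, scen, state.domain.n_cells, state.species_ids
            )
    state.protected = read_layer(outdir / "protected.asc", state.domain) > 0.5
    state.vegetation = read_layer(outdir / "vegetation.asc", state.domain)
    return state


# ---------------------------------------------------------------------------
# stage: enm


def stage_enm(state: RunState, outdir: str | Path | None = None) -> RunState:
    cfg = state.config
    state.enm = run_enm(
        state.occupancy["current"],
        state.climate,
        state.species,
        methods=list(cfg.enm.methods),
        n_reps=cfg.enm.n_reps,
        calib_frac=cfg.enm.calib_frac,
        envelope_pct=cfg.enm.envelope_pct,
        seed=subseed(cfg.seed, "enm"),
    )
    log.info("enm: mean validation TSS %.3f over %d evaluations",
             state.enm.evaluations.tss.mean(), len(state.enm.evaluations))
    if outdir is not None:
        _write_enm(state, Path(outdir))
    return state


def _write_enm(state: RunState, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(outdir / "evaluations.csv", state.enm.evaluations)
    tss_df = pd.DataFrame(
        [(s, m, v) for (s, m), v in sorted(state.enm.tss.items())],
        columns=["species_id", "method_id", "tss"],
    )
    write_table(outdir / "tss.csv", tss_df)
    scen_ids = ["current"] + state.future_scenarios
    for method in state.config.enm.methods:
        for scen in scen_ids:
            matrix = np.stack([
                state.enm.binaries[(sid, method, scen)]
                for sid in state.species_ids
            ]).astype(np.uint8)
            occ = OccupancyMatrix(scen, state.species_ids, matrix)
            write_occupancy_csv(outdir / f"enm_binary_{method}_{scen}.csv", occ)


def load_enm(state: RunState, outdir: str | Path) -> RunState:
    outdir = Path(outdir)
    evaluations = pd.read_csv(outdir / "evaluations.csv")
    tss_df = pd.read_csv(outdir / "tss.csv")
    tss = {(r.species_id, r.method_id): float(r.tss) for r in tss_df.itertuples()}
    binaries = {}
    scen_ids = ["current"] + state.future_scenarios
    for method in state.config.enm.methods:
        for scen in scen_ids:
            occ = read_occupancy_csv(
                outdir / f"enm_binary_{method}_{scen}.csv", scen,
                state.domain.n_cells, state.species_ids,
            )
            for i, sid in enumerate(state.species_ids):
                binaries[(sid, method, scen)] = occ.matrix[i].astype(bool)
    state.enm = ENMResult(binaries=binaries, tss=tss, evaluations=evaluations)
    return state


# ---------------------------------------------------------------------------
# stage: ensemble


def stage_ensemble(state: RunState, outdir: str | Path | None = None) -> RunState:
    """TSS-weighted consensus maps, richness, turnover, range change and the
    ANOVA uncertainty/cost layer.

    The current consensus combines the M methods; the future consensus
    combines all M x K (method, scenario) projections, each method weighted
    by its TSS. The ANOVA richness stack uses future richness only, where
    the method x scenario table is complete.
    """
    cfg = state.config
    methods = list(cfg.enm.methods)
    scenarios = state.future_scenarios
    sids = state.species_ids
    n = state.domain.n_cells
    thr = cfg.ensemble.consensus_threshold

    freq_cur = np.zeros((len(sids), n))
    freq_fut = np.zeros((len(sids), n))
    for i, sid in enumerate(sids):
        tss_w = np.array([state.enm.tss[(sid, m)] for m in methods])
        cur_stack = np.stack([state.enm.binaries[(sid, m, "current")] for m in methods])
        freq_cur[i] = ensemble_frequency(cur_stack, tss_w)
        fut_stack = np.stack([
            state.enm.binaries[(sid, m, scen)] for m in methods for scen in scenarios
        ])
        fut_w = np.repeat(tss_w, len(scenarios))
        freq_fut[i] = ensemble_frequency(fut_stack, fut_w)
    state.frequency_current = freq_cur
    state.frequency_future = freq_fut
    state.consensus_current = np.stack([consensus_map(f, thr) for f in freq_cur])
    state.consensus_future = np.stack([consensus_map(f, thr) for f in freq_fut])

    stack = np.empty((len(methods), len(scenarios), n))
    for mi, m in enumerate(methods):
        for ki, scen in enumerate(scenarios):
            stack[mi, ki] = richness(np.stack([
                state.enm.binaries[(sid, m, scen)] for sid in sids
            ]))
    state.richness_stack = stack
    state.uncertainty = uncertainty_anova(stack, numerator=cfg.ensemble.anova_numerator)
    state.turnover_map = turnover(state.consensus_current, state.consensus_future)
    state.range_change, state.range_summary = range_change_summary(
        state.consensus_current, state.consensus_future, sids
    )
    log.info("ensemble: mean contraction %.1f%%, %.0f%% regionally extinct",
             state.range_summary["mean_contraction_pct"],
             state.range_summary["pct_extinct"])
    if outdir is not None:
        _write_ensemble(state, Path(outdir))
    return state


def _write_ensemble(state: RunState, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    domain = state.domain
    sids = state.species_ids
    for label, cons, freq in [
        ("current", state.consensus_current, state.frequency_current),
        ("future", state.consensus_future, state.frequency_future),
    ]:
        write_occupancy_csv(
            outdir / f"consensus_{label}.csv",
            OccupancyMatrix(label, sids, cons.astype(np.uint8)),
        )
        freq_df = pd.DataFrame(freq.T, columns=sids)
        freq_df.insert(0, "cell_id", np.arange(domain.n_cells))
        write_table(outdir / f"frequency_{label}.csv", freq_df)
        write_asc(outdir / f"richness_{label}.asc", richness(cons), domain)
    for mi, m in enumerate(state.config.enm.methods):
        for ki, scen in enumerate(state.future_scenarios):
            write_asc(outdir / f"richness_{m}_{scen}.asc",
                      state.richness_stack[mi, ki], domain)
    write_asc(outdir / "turnover.asc", state.turnover_map.turnover, domain)
    write_asc(outdir / "uncertainty.asc", state.uncertainty.proportion, domain)
    write_asc(outdir / "cost.asc", state.uncertainty.cost, domain)
    write_table(outdir / "range_change.csv", state.range_change)
    write_table(outdir / "range_change_summary.csv",
                pd.DataFrame([state.range_summary]))


def load_ensemble(state: RunState, outdir: str | Path) -> RunState:
    outdir = Path(outdir)
    n = state.domain.n_cells
    sids = state.species_ids
    for label, attr in [("current", "consensus_current"), ("future", "consensus_future")]:
        occ = read_occupancy_csv(outdir / f"consensus_{label}.csv", label, n, sids)
        setattr(state, attr, occ.matrix.astype(bool))
        freq = pd.read_csv(outdir / f"frequency_{label}.csv")
        setattr(state, f"frequency_{label}", freq[sids].to_numpy().T)
    cost = read_layer(outdir / "cost.asc", state.domain)
    proportion = read_layer(outdir / "uncertainty.asc", state.domain)
    state.uncertainty = UncertaintyMap(
        ss_method=None, ss_gcm=None, ss_residual=None, ss_total=None,
        proportion=proportion, cost=cost,
    )
    state.range_change = pd.read_csv(outdir / "range_change.csv")
    state.range_summary = pd.read_csv(outdir / "range_change_summary.csv").iloc[0].to_dict()
    state.turnover_map = turnover(state.consensus_current, state.consensus_future)
    return state


# ---------------------------------------------------------------------------
# stage: dispersal


def stage_dispersal(state: RunState, outdir: str | Path | None = None) -> RunState:
    cfg = state.config.dispersal
    state.dispersal_specs, state.dispersal_features = build_dispersal_features(
        state.consensus_current, state.consensus_future, state.species_ids,
        state.domain,
        truncation_factor=cfg.truncation_factor,
        alpha_coefficient=cfg.alpha_coefficient,
        combine=cfg.combine,
    )
    shifts = [s.shift_km for s in state.dispersal_specs if not s.extinct_in_future]
    log.info("dispersal: mean centroid shift %.1f km over %d species",
             float(np.mean(shifts)) if shifts else float("nan"), len(shifts))
    if outdir is not None:
        _write_dispersal(state, Path(outdir))
    return state


def _write_dispersal(state: RunState, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in state.dispersal_specs:
        cf = s.centroid_future or (float("nan"), float("nan"))
        rows.append((s.species_id, s.centroid_now[0], s.centroid_now[1],
                     cf[0], cf[1], s.shift_km,
                     s.alpha if np.isfinite(s.alpha) else float("nan"),
                     s.extinct_in_future))
    write_table(outdir / "dispersal.csv", pd.DataFrame(rows, columns=[
        "species_id", "centroid_now_x", "centroid_now_y",
        "centroid_fut_x", "centroid_fut_y", "D_km", "alpha", "extinct_in_future",
    ]))
    feat = pd.DataFrame(state.dispersal_features.T, columns=state.species_ids)
    feat.insert(0, "cell_id", np.arange(state.domain.n_cells))
    write_table(outdir / "features_dispersal.csv", feat)


def load_dispersal(state: RunState, outdir: str | Path) -> RunState:
    outdir = Path(outdir)
    feat = pd.read_csv(outdir / "features_dispersal.csv")
    state.dispersal_features = feat[state.species_ids].to_numpy().T
    disp = pd.read_csv(outdir / "dispersal.csv")
    state.dispersal_specs = [
        DispersalSpec(
            species_id=r.species_id,
            centroid_now=(r.centroid_now_x, r.centroid_now_y),
            centroid_future=None if np.isnan(r.centroid_fut_x)
            else (r.centroid_fut_x, r.centroid_fut_y),
            shift_km=r.D_km,
            alpha=r.alpha if not np.isnan(r.alpha) else float("inf"),
            truncation_km=state.config.dispersal.truncation_factor * r.D_km,
            extinct_in_future=bool(r.extinct_in_future),
        )
        for r in disp.itertuples()
    ]
    return state


# ---------------------------------------------------------------------------
# stage: prioritize


def _solution_features(state: RunState, solution: str) -> dict[str, np.ndarray]:
    """Feature layers for one published solution variant.

    ``current`` and ``future`` use the respective consensus maps; species
    regionally extinct in the future are dropped from the future-only
    solution (they have no future distribution to represent). ``dispersal``
    uses the combined smoothed layers.
    """
    sids = state.species_ids
    if solution == "current":
        layers = {sid: state.consensus_current[i].astype(float)
                  for i, sid in enumerate(sids)}
    elif solution == "future":
        layers = {sid: state.consensus_future[i].astype(float)
                  for i, sid in enumerate(sids)
                  if state.consensus_future[i].any()}
    elif solution == "dispersal":
        layers = {sid: state.dispersal_features[i]
                  for i, sid in enumerate(sids)}
    else:
        raise ValueError(f"unknown solution {solution!r}")
    layers["vegetation"] = state.vegetation
    return layers


def stage_prioritize(state: RunState, outdir: str | Path | None = None) -> RunState:
    cfg = state.config.prioritizer
    for solution in ("current", "future", "dispersal"):
        problem = build_problem(
            _solution_features(state, solution),
            species=state.species,
            cost=state.uncertainty.cost,
            locked=state.protected,
            extra_weights={"vegetation": cfg.vegetation_weight},
            rule=cfg.rule,
            z=cfg.z,
        )
        result = rank_cells(problem)
        selected, report = top_fraction(result, cfg.fraction)
        state.solutions[solution] = result
        state.selected[solution] = selected
        state.coverage[solution] = report
        log.info("prioritize[%s]: top %.0f%% = %d cells, additional %.1f%%",
                 solution, 100 * cfg.fraction, report.n_selected,
                 report.additional_pct)
    state.union_map = (
        state.selected["current"] | state.selected["future"] | state.selected["dispersal"]
    )
    if outdir is not None:
        _write_prioritize(state, Path(outdir))
    return state


def _write_prioritize(state: RunState, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    domain = state.domain
    cov_rows = []
    for solution, result in state.solutions.items():
        write_asc(outdir / f"rank_{solution}.asc", result.rank_fraction, domain)
        write_asc(outdir / f"top_{solution}.asc",
                  state.selected[solution].astype(float), domain)
        write_table(outdir / f"removal_order_{solution}.csv", pd.DataFrame({
            "position": np.arange(result.removal_order.size) + 1,
            "cell_id": result.removal_order,
            "rank_fraction": result.rank_fraction[result.removal_order],
        }))
        write_table(outdir / f"performance_curves_{solution}.csv",
                    pd.DataFrame(performance_curves(result)))
        rep = state.coverage[solution]
        cov_rows.append({"solution": solution, **rep.__dict__})
    write_table(outdir / "coverage.csv", pd.DataFrame(cov_rows))
    write_asc(outdir / "top_union.asc", state.union_map.astype(float), domain)


# ---------------------------------------------------------------------------
# stage: report


def stage_report(state: RunState, outdir: str | Path) -> Path:
    """Render performance-curve and richness plots plus a run summary."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    colors = {"current": "tab:blue", "future": "tab:green", "dispersal": "m"}
    for solution, result in state.solutions.items():
        ax.plot(result.curve_landscape, result.curve_mean,
                color=colors.get(solution), label=solution)
    ax.axvline(state.config.prioritizer.fraction, ls="--", c="k", lw=0.8)
    ax.set_xlabel("fraction of landscape remaining")
    ax.set_ylabel("mean fraction of feature distributions remaining")
    ax.legend(title="solution")
    fig.tight_layout()
    fig.savefig(outdir / "performance_curves.png", dpi=150)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    panels = [
        ("current richness", richness(state.consensus_current)),
        ("future richness", richness(state.consensus_future)),
        ("turnover", state.turnover_map.turnover),
    ]
    for ax, (title, layer) in zip(axes, panels):
        im = ax.imshow(state.domain.to_grid(layer), origin="lower")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(outdir / "maps.png", dpi=150)
    plt.close(fig)

    summary = dict(state.range_summary or {})
    summary["turnover_min"] = float(state.turnover_map.turnover.min())
    summary["turnover_max"] = float(state.turnover_map.turnover.max())
    for solution, rep in state.coverage.items():
        summary[f"additional_pct_{solution}"] = rep.additional_pct
    write_table(outdir / "summary.csv", pd.DataFrame([summary]))
    return outdir


# ---------------------------------------------------------------------------
# full run


def _checksums(outdir: Path) -> dict[str, str]:
    out = {}
    for path in sorted(outdir.rglob("*.csv")):
        out[str(path.relative_to(outdir))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunState:
    """Execute every stage into ``outdir`` and write the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: RunState | None = None
    try:
        state = stage_simulate(config, outdir)
        stage_enm(state, outdir)
        stage_ensemble(state, outdir)
        stage_dispersal(state, outdir)
        stage_prioritize(state, outdir)
        stage_report(state, outdir)
    except Exception as exc:
        done = [] if state is None else [
            n for n, flag in [
                ("simulate", state.domain is not None),
                ("enm", state.enm is not None),
                ("ensemble", state.consensus_current is not None),
                ("dispersal", state.dispersal_features is not None),
                ("prioritize", bool(state.solutions)),
            ] if flag
        ]
        nxt = ["simulate", "enm", "ensemble", "dispersal", "prioritize", "report"]
        failing = nxt[len(done)] if len(done) < len(nxt) else "report"
        raise RuntimeError(f"pipeline stage {failing!r} failed: {exc}") from exc
    manifest = {
        "package": "climprior",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "float_format": FLOAT_FORMAT,
        "checksums": _checksums(outdir),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return state
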