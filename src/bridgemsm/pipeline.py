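"""End-to-end orchestration: simulate/ingest -> features -> tICA ->
cluster -> MSM -> validate -> lump -> TPT/MFPT -> structural observables
-> report.

The configuration mirrors the analysis protocol's parameters (tICA lag,
cluster count, MSM lag, GMRQ splits, residence-test settings, MCMC chain
settings, kink threshold, hydrogen-bond criterion, bootstrap settings);
all times are physical units converted to frames via the trajectory
frame interval. Defaults follow the published protocol (tICA lag 2,
800 clusters, MSM lag 45, five 1:1 splits, 12 residence states, ten
1e5-step chains with 20% burn-in, 35 deg kink threshold, 0.35 nm / 30
deg hydrogen bonds, 1000 bootstrap resamples); the synthetic preset
scales the problem so a full run takes seconds, not microseconds of MD.

In synthetic mode the run carries planted structural ground truth:
per-frame helix straight/kinked flags and hydrogen-bond geometries whose
probabilities depend on the free-energy basin, so MSM-weighted straight
fractions, bond percentages and odds ratios have known expectations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from ._seeding import child_seed
from .features import FeatureTrajectory
from .kinetics import (
    coarse_grain_flux,
    decompose_pathways,
    macrostate_count_by_gap,
    mfpt_linear,
    reactive_flux,
    spectral_lump,
)
from .microstates import assign, kcenters
from .msm import (
    count_transitions,
    estimate_markov_model,
    mcmc_mfpt,
    residence_probability_test,
    sample_observable_mcmc,
    trim_to_connected,
)
from .structmetrics import (
    HBondCriterion,
    HingeMap,
    aggregate_hinges,
    detect_hbond_array,
    kink_profile,
    per_state_observable,
)
from .synthgen import HelixSpec, Landscape, LangevinConfig, make_helix, simulate_overdamped
from .tica import fit_tica, transform

logger = logging.getLogger("bridgemsm")

SCHEMA_VERSION = 1

# Planted structural ground truth per free-energy basin (synthetic mode):
# probability of a straight helix, mean donor-acceptor distance (nm) and
# hydrogen-deviation scale (deg) of the sampled bond geometries. The
# middle basin is bond-rich but kink-prone, the flanking basins the
# reverse, so straight fractions and odds ratios vary across macrostates.
SYNTH_STRAIGHT_PROB = (0.30, 0.15, 0.30)
SYNTH_HBOND_DIST_MEAN = (0.320, 0.335, 0.365)
SYNTH_HBOND_DIST_SD = 0.015
SYNTH_HBOND_ANGLE_SD = (12.0, 15.0, 14.0)
SYNTH_ANGLE_SHRINK_STRAIGHT = 0.7  # straight frames get tighter bond geometry

_STAGE_CACHE: dict[str, object] = {}


def _cache_key(*parts) -> str:
    return hashlib.sha256(repr(parts).encode()).hexdigest()


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run (YAML-serializable)."""

    mode: str = "synthetic"  # synthetic | external
    landscape: str = "triple_well_2d"
    landscape_params: dict = field(default_factory=dict)
    langevin_dt: float = 0.01
    langevin_diffusion: float = 1.0
    langevin_kT: float = 1.0
    langevin_n_steps: int = 20000
    langevin_n_trajectories: int = 10
    input_manifest: str | None = None  # external mode
    tica_lag: float = 2.0
    n_tics: int = 2
    n_clusters: int = 800
    cluster_seed_index: int = 0
    msm_lag: float = 45.0
    reversible: bool = True
    run_residence_test: bool = False
    residence_n_top: int = 12
    residence_lag_multiples: tuple[int, ...] = (0, 1, 2)
    residence_min_start_spacing: float = 4.5
    residence_smoothing_window: float = 1.0
    residence_n_boot: int = 100
    n_macro: int | None = None  # None -> eigenvalue-gap decision
    max_macro: int = 6
    mcmc_n_chains: int = 10
    mcmc_n_steps: int = 100_000
    mcmc_burn_in: float = 0.2
    mcmc_n_boot: int = 1000
    pathway_coverage: float = 0.95
    kink_threshold: float = 35.0
    hinge_map: dict | None = None
    hbond_max_distance: float = 0.35
    hbond_max_angle: float = 30.0
    bootstrap_block_length: float = 4.0
    bootstrap_n_resamples: int = 1000
    n_synthetic_helices: int = 30
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "external"):
            raise ValueError("mode must be 'synthetic' or 'external'")
        if self.mode == "external" and not self.input_manifest:
            raise ValueError("external mode needs input_manifest")
        for name in ("tica_lag", "msm_lag", "pathway_coverage", "kink_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.n_macro is not None and self.n_macro < 2:
            raise ValueError("n_macro must be >= 2")
        if not 0 <= self.mcmc_burn_in < 1:
            raise ValueError("mcmc_burn_in must be in [0, 1)")

    @classmethod
    def synthetic_default(cls, **overrides) -> "RunConfig":
        """Scaled-down synthetic preset: full run in tens of seconds.

        Times are in the Langevin simulation's own units (dt = 0.01):
        tICA lag 0.2 (20 frames), MSM lag 0.25 (25 frames), residence
        spacing 0.45 / smoothing 0.1, bootstrap blocks of 1.0.
        """
        base = dict(
            mode="synthetic",
            landscape="triple_well_2d",
            langevin_n_steps=20000,
            langevin_n_trajectories=10,
            tica_lag=0.2,
            n_clusters=120,
            msm_lag=0.25,
            residence_min_start_spacing=0.45,
            residence_smoothing_window=0.1,
            mcmc_n_steps=20000,
            mcmc_n_boot=1000,
            bootstrap_block_length=1.0,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("residence_lag_multiples") is not None:
            data["residence_lag_multiples"] = tuple(data["residence_lag_multiples"])
        return cls(**data)


def _to_frames(time: float, frame_interval: float, name: str) -> int:
    frames = int(round(time / frame_interval))
    if frames < 1:
        raise ValueError(f"{name}={time} is below one frame interval {frame_interval}")
    err = abs(frames * frame_interval - time) / time
    if err > 0.01:
        warnings.warn(
            f"{name}={time} rounded to {frames} frames ({err:.1%} error)",
            stacklevel=2,
        )
    return frames


@dataclass
class RunReport:
    """Results of one pipeline run; every number traces to a stage artifact."""

    schema_version: int
    config: dict
    n_macrostates: int
    gap_ratios: list[float]
    gap_confident: bool
    macro_populations: list[float]  # MCMC means, ordered along tIC1
    macro_population_sd: list[float]
    macro_population_ci: list[list[float]]
    stationary_populations: list[float]  # direct pi sums, same order
    mfpt_linear: list[list[float]]  # [i][j] = MFPT macro i -> macro j
    mfpt_mcmc: list[list[float]]
    mfpt_mcmc_sd: list[list[float]]
    pathways: list[dict]  # {states, flux, fraction}
    pathway_coverage: float
    total_flux: float
    macro_mean_features: list[list[float]]
    straight_fraction: dict | None = None
    hbond_percentage: dict | None = None
    odds_ratio: dict | None = None
    hinge_summary: dict | None = None
    residence: dict | None = None
    implied_timescales: list[float] | None = None
    artifacts: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "RunReport":
        return cls(**json.loads(Path(path).read_text()))

    def summary(self) -> str:
        lines = [
            f"macrostates: {self.n_macrostates} "
            f"(gap confident: {self.gap_confident})",
            "populations (MCMC mean +/- SD): "
            + ", ".join(
                f"{m:.3f}+/-{s:.3f}"
                for m, s in zip(self.macro_populations, self.macro_population_sd)
            ),
            f"total reactive flux (per lag): {self.total_flux:.3e}",
            f"pathway coverage: {self.pathway_coverage:.3f}",
        ]
        for p in self.pathways:
            arrow = "->".join(str(s + 1) for s in p["states"])
            lines.append(f"  pathway {arrow}: {p['fraction']:.1%} of flux")
        m = np.array(self.mfpt_linear)
        if m.size:
            lines.append(f"MFPT 1->{self.n_macrostates} (linear): {m[0, -1]:.3g}")
            lines.append(
                f"MFPT 1->{self.n_macrostates} (MCMC): "
                f"{np.array(self.mfpt_mcmc)[0, -1]:.3g}"
            )
        if self.straight_fraction:
            sf = self.straight_fraction["per_macrostate"]
            lines.append(
                "straight helix fraction per state: "
                + ", ".join(f"{v:.2f}" for v in sf)
            )
        if self.odds_ratio and self.odds_ratio.get("overall") is not None:
            lines.append(f"kink-bond odds ratio (overall): {self.odds_ratio['overall']:.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Synthetic structural channel
# ---------------------------------------------------------------------------


def _basin_labels(trajs: Sequence[FeatureTrajectory], landscape: Landscape):
    """Ground-truth basin of every frame: nearest landscape minimum."""
    out = []
    for tr in trajs:
        d2 = ((tr.values[:, None, :] - landscape.minima[None]) ** 2).sum(axis=2)
        out.append(d2.argmin(axis=1))
    return out


def _plant_structural_indicators(
    basins: Sequence[np.ndarray],
    criterion: HBondCriterion,
    seed: int,
):
    """Per-frame straight flags and hydrogen-bond indicators by basin."""
    rng = np.random.default_rng(seed)
    straight, bonded = [], []
    n_basins = max(int(b.max()) for b in basins) + 1
    p_straight = np.resize(SYNTH_STRAIGHT_PROB, n_basins)
    d_mean = np.resize(SYNTH_HBOND_DIST_MEAN, n_basins)
    a_sd = np.resize(SYNTH_HBOND_ANGLE_SD, n_basins)
    for b in basins:
        s = rng.random(len(b)) < p_straight[b]
        d = np.maximum(rng.normal(d_mean[b], SYNTH_HBOND_DIST_SD), 0.05)
        shrink = np.where(s, SYNTH_ANGLE_SHRINK_STRAIGHT, 1.0)
        theta = np.minimum(np.abs(rng.normal(0.0, a_sd[b] * shrink)), 89.0)
        # realize the (d, theta) pairs as explicit D/H/A triples
        th = np.radians(theta)
        donors = np.zeros((len(b), 3))
        acceptors = np.column_stack([d, np.zeros(len(b)), np.zeros(len(b))])
        hydrogens = np.column_stack(
            [0.10 * np.cos(th), 0.10 * np.sin(th), np.zeros(len(b))]
        )
        bonded.append(detect_hbond_array(donors, hydrogens, acceptors, criterion))
        straight.append(s)
    return straight, bonded


def _synthetic_helix_ensemble(
    macro_populations: np.ndarray,
    hinge_map: HingeMap,
    n_helices: int,
    threshold: float,
    seed: int,
):
    """A small helix ensemble with basin-dependent kink statistics."""
    rng = np.random.default_rng(seed)
    profiles = []
    n_basins = len(macro_populations)
    p_straight = np.resize(SYNTH_STRAIGHT_PROB, n_basins)
    hinge_residues = np.concatenate(
        [np.arange(lo, hi + 1) for lo, hi in hinge_map.hinges.values()]
    )
    for i in range(n_helices):
        basin = rng.choice(n_basins, p=macro_populations / macro_populations.sum())
        kinks = []
        if rng.random() >= p_straight[basin]:
            residue = int(rng.choice(hinge_residues))
            angle = float(np.clip(rng.normal(45.0, 8.0), threshold + 3.0, 80.0))
            azimuth = float(rng.uniform(0, 360))
            kinks = [(residue, angle, azimuth)]
        spec = HelixSpec(n_residues=30, kinks=kinks, noise_sigma=0.05)
        coords = make_helix(spec, seed=int(rng.integers(2**31 - 1)))
        profiles.append(kink_profile(coords, threshold=threshold))
    return profiles


def _default_hinge_map() -> HingeMap:
    # three hinge windows inside the kink-profile support of a 30-residue helix
    return HingeMap({"hinge14": (12, 15), "hinge18": (16, 19), "hinge22": (20, 23)})


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and return the run report.

    Reruns with an identical config reproduce all stochastic outputs
    exactly: every stage derives its own seed from the master seed and
    its stage name.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # -- stage: trajectories -------------------------------------------------
    landscape = None
    if config.mode == "synthetic":
        landscape = Landscape.by_name(config.landscape, **config.landscape_params)
        key = _cache_key(
            "simulate", config.landscape, tuple(sorted(config.landscape_params.items())),
            config.langevin_dt, config.langevin_diffusion, config.langevin_kT,
            config.langevin_n_steps, config.langevin_n_trajectories, config.seed,
        )
        if key not in _STAGE_CACHE:
            logger.info("simulating %d Langevin trajectories", config.langevin_n_trajectories)
            _STAGE_CACHE[key] = simulate_overdamped(
                landscape,
                LangevinConfig(
                    dt=config.langevin_dt,
                    diffusion=config.langevin_diffusion,
                    kT=config.langevin_kT,
                    n_steps=config.langevin_n_steps,
                    n_trajectories=config.langevin_n_trajectories,
                    seed=child_seed(config.seed, "simulate"),
                ),
            )
        trajs = _STAGE_CACHE[key]
    else:
        trajs = bio.read_trajectories(config.input_manifest)
    interval = trajs[0].frame_interval
    if outdir:
        artifacts["trajectories"] = str(bio.write_trajectories(trajs, outdir / "trajs"))

    # -- stage: tICA ---------------------------------------------------------
    logger.info("fitting tICA at lag %s", config.tica_lag)
    model_tica = fit_tica(trajs, config.tica_lag)
    projections = [transform(model_tica, tr, config.n_tics) for tr in trajs]
    if outdir:
        model_tica.to_json(outdir / "tica_model.json")
        artifacts["tica_model"] = str(outdir / "tica_model.json")

    # -- stage: clustering ---------------------------------------------------
    all_points = np.vstack(projections)
    k = min(config.n_clusters, len(all_points))
    logger.info("K-centers clustering into %d microstates", k)
    micro = kcenters(all_points, k, config.cluster_seed_index)
    dtrajs = [assign(micro, p) for p in projections]
    if outdir:
        artifacts["dtrajs"] = str(
            bio.write_dtrajs(dtrajs, outdir / "dtrajs", {"k": k})
        )

    # -- stage: MSM ----------------------------------------------------------
    msm_lag_frames = _to_frames(config.msm_lag, interval, "msm_lag")
    cm = trim_to_connected(count_transitions(dtrajs, msm_lag_frames))
    model = estimate_markov_model(cm, interval, reversible=config.reversible)
    logger.info(
        "MSM: %d of %d microstates in the connected set", model.n_states, k
    )
    its = model.implied_timescales(5)

    residence_payload = None
    if config.run_residence_test:
        rep = residence_probability_test(
            model,
            dtrajs,
            n_top=config.residence_n_top,
            lag_multiples=config.residence_lag_multiples,
            min_start_spacing=_to_frames(
                config.residence_min_start_spacing, interval, "residence spacing"
            ),
            smoothing_window=_to_frames(
                config.residence_smoothing_window, interval, "residence smoothing"
            ),
            n_boot=config.residence_n_boot,
            seed=child_seed(config.seed, "residence"),
        )
        residence_payload = {
            "states": rep.states.tolist(),
            "passed": rep.passed.tolist(),
            "all_passed": rep.all_passed,
            "excluded": rep.excluded,
        }

    # -- stage: coarse-graining ----------------------------------------------
    gap = macrostate_count_by_gap(model, config.max_macro)
    n_macro = config.n_macro or gap.n_macro
    macro = spectral_lump(model, n_macro, seed=child_seed(config.seed, "lump"))

    # order macrostates along mean tIC1 (the translocation-like coordinate)
    frames_per_state = per_state_observable(
        dtrajs, [p[:, 0] for p in projections], n_states=k
    )[0]
    tic1_macro = np.array(
        [
            np.average(
                frames_per_state[model.active_set[macro.members(c)]],
                weights=model.pi[macro.members(c)],
            )
            for c in range(n_macro)
        ]
    )
    order = np.argsort(tic1_macro)
    relabel = np.empty(n_macro, dtype=int)
    relabel[order] = np.arange(n_macro)
    assignments = relabel[macro.assignments]
    macro = dataclasses.replace(
        macro,
        assignments=assignments,
        populations=macro.populations[order],
    )

    # mean original-feature coordinates per macrostate (for interpretation
    # and for matching macrostates to known landscape basins in tests)
    mean_feats = []
    feat_means = [
        per_state_observable(dtrajs, [tr.values[:, j] for tr in trajs], n_states=k)[0]
        for j in range(trajs[0].n_features)
    ]
    for c in range(n_macro):
        members_orig = model.active_set[macro.members(c)]
        w = model.pi[macro.members(c)]
        mean_feats.append(
            [float(np.average(fm[members_orig], weights=w)) for fm in feat_means]
        )

    # -- stage: TPT + MFPT ---------------------------------------------------
    src, snk = 0, n_macro - 1
    net_micro = reactive_flux(
        model, macro.members(src), macro.members(snk)
    )
    net_macro = coarse_grain_flux(net_micro, macro)
    paths = decompose_pathways(net_macro, config.pathway_coverage)
    pathway_payload = [
        {
            "states": [int(s) for s in states],
            "flux": float(fluxv),
            "fraction": float(fluxv / net_macro.total_flux),
        }
        for states, fluxv in paths.pathways
    ]

    mf_lin = np.zeros((n_macro, n_macro))
    mf_mc = np.zeros((n_macro, n_macro))
    mf_mc_sd = np.zeros((n_macro, n_macro))
    for a in range(n_macro):
        for b in range(n_macro):
            if a == b:
                continue
            A, B = macro.members(a), macro.members(b)
            mf_lin[a, b] = mfpt_linear(model, A, B)
            res = mcmc_mfpt(
                model,
                A,
                B,
                n_chains=config.mcmc_n_chains,
                n_steps=config.mcmc_n_steps,
                seed=child_seed(config.seed, f"mfpt_{a}_{b}"),
            )
            mf_mc[a, b] = res["mfpt"]
            mf_mc_sd[a, b] = res["sd"]

    # -- stage: MSM-weighted populations -------------------------------------
    indicators = np.zeros((model.n_states, n_macro))
    indicators[np.arange(model.n_states), macro.assignments] = 1.0
    pop = sample_observable_mcmc(
        model,
        indicators,
        n_chains=config.mcmc_n_chains,
        n_steps=config.mcmc_n_steps,
        burn_in_fraction=config.mcmc_burn_in,
        seed=child_seed(config.seed, "populations"),
        n_boot=config.mcmc_n_boot,
    )

    # -- stage: structural observables (synthetic channel) -------------------
    straight_payload = hbond_payload = or_payload = hinge_payload = None
    if config.mode == "synthetic" and landscape is not None:
        criterion = HBondCriterion(config.hbond_max_distance, config.hbond_max_angle)
        basins = _basin_labels(trajs, landscape)
        straight, bonded = _plant_structural_indicators(
            basins, criterion, child_seed(config.seed, "structural")
        )
        cells = {
            "B_s": [b & s for s, b in zip(straight, bonded)],
            "B_k": [b & ~s for s, b in zip(straight, bonded)],
            "NB_s": [~b & s for s, b in zip(straight, bonded)],
            "NB_k": [~b & ~s for s, b in zip(straight, bonded)],
        }
        per_state = {
            name: per_state_observable(
                dtrajs, [v.astype(float) for v in vals], n_states=k
            )[0][model.active_set]
            for name, vals in cells.items()
        }
        per_state["straight"] = per_state["B_s"] + per_state["NB_s"]
        per_state["bonded"] = per_state["B_s"] + per_state["B_k"]
        # a microstate never visited by a cell keeps NaN only if it has no
        # frames at all, which cannot happen inside the active set
        stacked = np.column_stack([np.nan_to_num(v) for v in per_state.values()])
        names = list(per_state.keys())
        macro_cells = {}
        for c in range(n_macro):
            ind = indicators[:, c]
            vals = stacked * ind[:, None]
            est = sample_observable_mcmc(
                model,
                np.column_stack([vals, ind]),
                n_chains=config.mcmc_n_chains,
                n_steps=config.mcmc_n_steps,
                burn_in_fraction=config.mcmc_burn_in,
                seed=child_seed(config.seed, f"structural_macro_{c}"),
            )
            weight = est["mean"][-1]
            macro_cells[c] = {
                nm: float(est["mean"][i] / weight) for i, nm in enumerate(names)
            }
        overall = sample_observable_mcmc(
            model,
            stacked,
            n_chains=config.mcmc_n_chains,
            n_steps=config.mcmc_n_steps,
            burn_in_fraction=config.mcmc_burn_in,
            seed=child_seed(config.seed, "structural_overall"),
            n_boot=config.mcmc_n_boot,
        )
        overall_cells = {nm: float(overall["mean"][i]) for i, nm in enumerate(names)}

        def _or(cells_dict):
            try:
                from .structmetrics import KinkHBondTable, odds_ratio as _odds

                return float(
                    _odds(
                        KinkHBondTable(
                            cells_dict["B_s"],
                            cells_dict["B_k"],
                            cells_dict["NB_s"],
                            cells_dict["NB_k"],
                        )
                    )
                )
            except (ZeroDivisionError, ValueError):
                return None

        straight_payload = {
            "overall": overall_cells["straight"],
            "overall_ci": [
                float(overall["ci_low"][names.index("straight")]),
                float(overall["ci_high"][names.index("straight")]),
            ],
            "per_macrostate": [macro_cells[c]["straight"] for c in range(n_macro)],
        }
        hbond_payload = {
            "overall": overall_cells["bonded"],
            "per_macrostate": [macro_cells[c]["bonded"] for c in range(n_macro)],
        }
        or_payload = {
            "overall": _or(overall_cells),
            "per_macrostate": [_or(macro_cells[c]) for c in range(n_macro)],
        }

        hinge_map = (
            HingeMap({k_: tuple(v) for k_, v in config.hinge_map.items()})
            if config.hinge_map
            else _default_hinge_map()
        )
        profiles = _synthetic_helix_ensemble(
            macro.populations,
            hinge_map,
            config.n_synthetic_helices,
            config.kink_threshold,
            child_seed(config.seed, "helices"),
        )
        agg = aggregate_hinges(profiles, hinge_map)
        hinge_payload = {
            "hinge_kink_frequency": agg.hinge_kink_frequency,
            "ensemble_straight_fraction": float(
                np.mean([p.straight for p in profiles])
            ),
        }

    report = RunReport(
        schema_version=SCHEMA_VERSION,
        config=dataclasses.asdict(config),
        n_macrostates=n_macro,
        gap_ratios=[float(r) if np.isfinite(r) else -1.0 for r in gap.ratios],
        gap_confident=gap.confident,
        macro_populations=[float(v) for v in pop["mean"]],
        macro_population_sd=[float(v) for v in pop["sd"]],
        macro_population_ci=[
            [float(lo), float(hi)]
            for lo, hi in zip(pop["ci_low"], pop["ci_high"])
        ],
        stationary_populations=[float(v) for v in macro.populations],
        mfpt_linear=mf_lin.tolist(),
        mfpt_mcmc=mf_mc.tolist(),
        mfpt_mcmc_sd=mf_mc_sd.tolist(),
        pathways=pathway_payload,
        pathway_coverage=float(paths.coverage),
        total_flux=float(net_macro.total_flux),
        macro_mean_features=mean_feats,
        straight_fraction=straight_payload,
        hbond_percentage=hbond_payload,
        odds_ratio=or_payload,
        hinge_summary=hinge_payload,
        residence=residence_payload,
        implied_timescales=[float(t) if np.isfinite(t) else -1.0 for t in its],
        artifacts=artifacts,
    )
    if outdir:
        report.to_json(outdir / "report.json")
        (outdir / "summary.txt").write_text(report.summary() + "\n")
    return report


def compare_runs(report_a: RunReport, report_b: RunReport) -> pd.DataFrame:
    """Aligned difference table of two run reports.

    Macrostates are aligned by label when the counts match, otherwise by
    population rank (flagged in the ``aligned_by`` column). Combined
    uncertainty is the quadrature sum of the per-run SDs.
    """
    na, nb = report_a.n_macrostates, report_b.n_macrostates
    by_rank = na != nb
    n = min(na, nb)
    idx_a = np.argsort(-np.asarray(report_a.macro_populations))[:n]
    idx_b = np.argsort(-np.asarray(report_b.macro_populations))[:n]
    if not by_rank:
        idx_a = idx_b = np.arange(n)
    rows = []
    for i, (a, b) in enumerate(zip(idx_a, idx_b)):
        pa, pb = report_a.macro_populations[a], report_b.macro_populations[b]
        sa, sb = report_a.macro_population_sd[a], report_b.macro_population_sd[b]
        row = {
            "quantity": f"population_macro{i + 1}",
            "a": pa,
            "b": pb,
            "difference": pa - pb,
            "combined_sd": float(np.hypot(sa, sb)),
            "aligned_by": "rank" if by_rank else "label",
        }
        rows.append(row)
        if report_a.straight_fraction and report_b.straight_fraction:
            fa = report_a.straight_fraction["per_macrostate"][a]
            fb = report_b.straight_fraction["per_macrostate"][b]
            rows.append(
                {
                    "quantity": f"straight_fraction_macro{i + 1}",
                    "a": fa,
                    "b": fb,
                    "difference": fa - fb,
                    "combined_sd": np.nan,
                    "aligned_by": "rank" if by_rank else "label",
                }
            )
    ma = np.asarray(report_a.mfpt_linear)
    mb = np.asarray(report_b.mfpt_linear)
    if ma.shape == mb.shape and ma.size:
        rows.append(
            {
                "quantity": "mfpt_linear_first_to_last",
                "a": float(ma[0, -1]),
                "b": float(mb[0, -1]),
                "difference": float(ma[0, -1] - mb[0, -1]),
                "combined_sd": np.nan,
                "aligned_by": "label",
            }
        )
    return pd.DataFrame(rows)
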