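"""End-to-end experiment archetypes on synthetic data.

Three orchestrations chain the generator and the analysis stages the way
the corresponding wet-lab experiments are analyzed:

* :func:`run_surface_marker_experiment` — epifluorescence comparison of a
  per-cell surface marker (or uptake probe) between conditions: render one
  cell field per (condition, experiment), quantify background-subtracted
  per-cell means, aggregate cells -> experiments -> conditions, test, and
  report the effect size against the injected truth.
* :func:`run_tirf_ccp_experiment` — TIRF comparison of per-structure
  (clathrin-coated-pit) Gaussian amplitude and structure density between
  conditions at matched spot density.
* :func:`run_uptake_experiment` — fluid-phase uptake time course with
  linear-accumulation fits, per-timepoint tests and fold changes.

Each returns a JSON-serializable report carrying the configuration hash
and master seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import cellquant, io, simgen, spotfit, stats, uptake
from ._rng import derive_seed
from .config import RunConfig

__all__ = [
    "run_surface_marker_experiment",
    "run_tirf_ccp_experiment",
    "run_uptake_experiment",
]


def _condition_tests(exp_table: pd.DataFrame, alpha: float) -> dict:
    """Pairwise tests across experiment means: pooled t for 2 conditions,
    one-way ANOVA + Newman-Keuls for 3 or more."""
    groups = {
        cond: grp["mean"].to_numpy(float)
        for cond, grp in exp_table.groupby("condition", sort=True)
    }
    labels = list(groups)
    if len(labels) < 2 or any(len(v) < 2 for v in groups.values()):
        return {"test": "refused", "reason": "need >= 2 conditions with >= 2 experiments"}
    if len(labels) == 2:
        t_stat, p = stats.students_t(groups[labels[0]], groups[labels[1]])
        sig = bool(np.isfinite(p) and p < alpha)
        return {
            "test": "students_t", "alpha": alpha, "statistic": t_stat, "p": p,
            "pairwise": {f"{labels[0]}|{labels[1]}": {"p": p, "significant": sig}},
        }
    f, p = stats.one_way_anova(list(groups.values()))
    nk = stats.newman_keuls(list(groups.values()), alpha=alpha, labels=labels)
    pairwise = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sig = bool(np.isfinite(p) and p < alpha and nk.loc[a, b])
            pairwise[f"{a}|{b}"] = {"significant": sig}
    return {"test": "anova+newman_keuls", "alpha": alpha, "F": f, "p": p,
            "pairwise": pairwise}


def run_surface_marker_experiment(
    config: RunConfig,
    effect: float = -0.353,
    control_net_mean: float = 1000.0,
    cell_cv: float = 0.15,
    background_level: float = 100.0,
    measure: str = "surface-marker",
) -> dict:
    """Two-or-more-condition per-cell intensity comparison.

    ``effect`` is the injected fractional change of the *net* (background
    subtracted) per-cell mean in each non-control condition relative to the
    control (-0.353 = a 35.3% reduction).  With several treated conditions
    the same effect is applied to each unless ``effect`` is a sequence.
    """
    conditions = list(config.conditions)
    if conditions[0] != "control":
        conditions = ["control"] + [c for c in conditions if c != "control"]
    effects = list(np.broadcast_to(effect, len(conditions) - 1).astype(float))

    cond_means: dict[str, tuple[str, dict]] = {}
    truth_percent: dict[str, float] = {}
    for i, cond in enumerate(conditions):
        net = control_net_mean if i == 0 else control_net_mean * (1.0 + effects[i - 1])
        raw = background_level + net
        cond_means[cond] = ("normal", {"mean": raw, "sd": cell_cv * net})
        if i > 0:
            truth_percent[cond] = 100.0 * effects[i - 1]

    measurements = []
    for e in range(config.n_experiments):
        exp_id = f"exp{e + 1}"
        for cond in conditions:
            spec = simgen.CellFieldSpec(
                n_cells=config.n_cells,
                condition_means=cond_means,
                background_level=background_level,
                bit_depth=config.bit_depth,
                seed=derive_seed(config.seed, f"surface:{exp_id}"),
            )
            image, mask, _truth = simgen.render_cell_field(spec, cond)
            rois = cellquant.rois_from_labels(mask)
            table = cellquant.measure_cells(
                image, rois, condition=cond, experiment_id=exp_id,
                measure=measure, bit_depth=config.bit_depth,
            )
            measurements.append(table)
    cells = pd.concat(measurements, ignore_index=True)

    exp_table, cond_table = stats.aggregate(cells, value="net_mean")
    tests = _condition_tests(exp_table, config.stats_alpha)

    control_row = cond_table[cond_table["condition"] == "control"].iloc[0]
    effects_out = {}
    for cond in conditions[1:]:
        row = cond_table[cond_table["condition"] == cond].iloc[0]
        es = stats.effect_size(
            control_row["mean"], row["mean"],
            control_sem=control_row["sem"], treated_sem=row["sem"],
        )
        es["true_percent_change"] = truth_percent[cond]
        effects_out[cond] = es

    return {
        "archetype": "surface-marker",
        "config_hash": config.hash(),
        "seed": config.seed,
        "conditions": conditions,
        "n_cells": config.n_cells,
        "n_experiments": config.n_experiments,
        "condition_summary": cond_table.to_dict(orient="records"),
        "experiment_summary": exp_table.to_dict(orient="records"),
        "tests": tests,
        "effects": effects_out,
        "_cells": cells,  # stripped before JSON serialization
    }


def run_tirf_ccp_experiment(
    config: RunConfig,
    amplitude_factor: float = 1.3,
    frames_per_condition: int = 4,
    n_spots: int = 30,
    base_amplitude: float = 300.0,
    amplitude_cv: float = 0.3,
) -> dict:
    """Two-condition TIRF comparison of per-CCP amplitude and density.

    Both conditions are simulated at identical spot density; the treated
    condition's per-spot amplitudes are scaled by ``amplitude_factor``.
    Each frame stands for one cell; per-frame mean accepted amplitude and
    accepted-spot density are compared across frames with a pooled t test.
    """
    optical = simgen.OpticalModel(
        psf_sigma=config.psf_sigma, image_shape=config.image_shape,
        bit_depth=config.bit_depth,
    )
    noise = simgen.NoiseModel(
        read_noise_sd=config.read_noise_sd, photon_scale=config.photon_scale,
        baseline_offset=config.baseline_offset,
    )
    area = float(np.prod(config.image_shape))
    per_frame: list[dict] = []
    counts = {}
    for cond, factor in (("control", 1.0), ("usmb", amplitude_factor)):
        n_ccps = 0
        for f in range(frames_per_condition):
            spec = simgen.SceneSpec(
                optical=optical, noise=noise, n_spots=n_spots,
                amplitude_distribution=(
                    "lognormal", {"mean": base_amplitude * factor, "cv": amplitude_cv}
                ),
                seed=derive_seed(config.seed, f"tirf:{cond}:{f}"),
            )
            channels, _truth = simgen.render_spot_field(spec)
            dets = spotfit.detect_spots(
                channels["ch1"], config.psf_sigma, alpha=config.detection_alpha,
                candidate_k=config.candidate_k, fit_sigma=config.fit_sigma,
                image_id=f"{cond}_frame{f}", cell_mask_area=area,
            )
            accepted = dets.accepted()
            n_ccps += len(accepted)
            per_frame.append({
                "condition": cond, "frame": f,
                "mean_amplitude": float(np.mean([d.amplitude for d in accepted]))
                if accepted else float("nan"),
                "density": spotfit.spot_density(dets),
                "n_accepted": len(accepted),
            })
        counts[cond] = {"n_ccps": n_ccps, "k_cells": frames_per_condition}
    frames = pd.DataFrame(per_frame)

    def _ttest(col: str) -> dict:
        g = {c: grp[col].dropna().to_numpy(float) for c, grp in frames.groupby("condition")}
        t_stat, p = stats.students_t(g["control"], g["usmb"])
        return {"statistic": t_stat, "p": p,
                "significant": bool(np.isfinite(p) and p < config.stats_alpha)}

    amp_test = _ttest("mean_amplitude")
    den_test = _ttest("density")
    cond_mean = frames.groupby("condition")[["mean_amplitude", "density"]].mean()
    return {
        "archetype": "tirf-ccp",
        "config_hash": config.hash(),
        "seed": config.seed,
        "amplitude_factor_true": amplitude_factor,
        "counts": counts,
        "per_frame": frames.to_dict(orient="records"),
        "amplitude_ratio": float(cond_mean.loc["usmb", "mean_amplitude"]
                                 / cond_mean.loc["control", "mean_amplitude"]),
        "density_ratio": float(cond_mean.loc["usmb", "density"]
                               / cond_mean.loc["control", "density"]),
        "amplitude_test": amp_test,
        "density_test": den_test,
    }


def run_uptake_experiment(
    config: RunConfig,
    spec: simgen.UptakeModelSpec | None = None,
) -> dict:
    """Fluid-phase uptake time course: simulate, fit, compare, fold-change."""
    if spec is None:
        spec = simgen.UptakeModelSpec(seed=derive_seed(config.seed, "uptake"))
    else:
        spec = replace(spec, seed=derive_seed(config.seed, "uptake"))
    frames = simgen.simulate_uptake_series(spec)
    series = {c: uptake.UptakeSeries.from_frame(f) for c, f in frames.items()}
    fits = {c: uptake.fit_linear_accumulation(s) for c, s in series.items()}
    comparison = uptake.per_timepoint_comparison(
        series, control="control", alpha=config.stats_alpha
    )
    return {
        "archetype": "uptake",
        "config_hash": config.hash(),
        "seed": config.seed,
        "timepoints": list(spec.timepoints),
        "fits": {
            c: {"slope": f.slope, "intercept": f.intercept,
                "slope_se": f.slope_se, "r_squared": f.r_squared}
            for c, f in fits.items()
        },
        "per_timepoint": comparison.to_dict(orient="records"),
        "_tables": frames,  # stripped before JSON serialization
    }


def report_for_json(report: dict) -> dict:
    """Drop in-memory tables (keys starting with '_') for serialization."""
    return {k: v for k, v in report.items() if not k.startswith("_")}


def write_report(report: dict, path) -> None:
    io.write_json(path, report_for_json(report))
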