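"""Orchestration: recipes, configuration, and per-experiment aggregation.

Each recipe runs one stage chain end to end on synthetic inputs (or a
user manifest), writes tidy CSV/JSON results plus the resolved
configuration and a log next to them, and is byte-reproducible for a fixed
seed.  Aggregation follows the hierarchical convention used for
"SuperPlot"-style reporting: cell-level values are averaged per
independent experiment, and conditions are compared on the per-experiment
means; no significance testing is performed here.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import afm, enrichment, morphology, spt, states, synapse, synth

__all__ = ["RunConfig", "run_recipe", "aggregate_by_experiment", "RECIPES"]


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Recipe-specific parameters live in ``params``; everything is
    serializable and the resolved config is written next to the outputs so
    any result can be regenerated from its sidecar.
    """

    recipe: str
    seed: int = 0
    out_dir: str = "results"
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _recipe_enrichment(cfg: RunConfig, out: Path):
    p = {"n_cells": 5, "n_spots": 48, "on_fraction": 0.5, **cfg.params}
    rows = []
    for c in range(p["n_cells"]):
        stack, truth = synth.make_spot_filament_stack(
            n_spots=p["n_spots"], on_fraction=p["on_fraction"],
            seed=cfg.seed * 1000 + c)
        res = enrichment.per_cell_enrichment(stack)
        for ri, (r, n) in enumerate(zip(res.roi_ratios, res.n_spots)):
            rows.append({"cell_id": c, "roi_id": ri, "n_spots": n,
                         "R": np.nan if r is None else r,
                         "cell_mean": res.cell_mean,
                         "truth_fraction": truth.intensity_on_fraction})
    df = pd.DataFrame(rows)
    df.to_csv(out / "enrichment.csv", index=False)
    summary = df.groupby("cell_id")["cell_mean"].first()
    return {"cell_means": summary.tolist(),
            "grand_mean": float(summary.mean())}


def _recipe_spt_states(cfg: RunConfig, out: Path):
    p = {"n_traj": 200, "n_frames": 50, "D": [0.001, 0.1], "pi": [0.6, 0.4],
         "T": [[0.95, 0.05], [0.075, 0.925]], "n_iter": 2000, "burn_in": 600,
         **cfg.params}
    model = synth.SwitchingModel(D=np.array(p["D"]), pi=np.array(p["pi"]),
                                 T=np.array(p["T"]))
    trajs, _ = synth.simulate_trajectories(model, p["n_traj"], p["n_frames"],
                                           seed=cfg.seed)
    curves = [spt.msd(t, max_lag=12) for t in trajs]
    fit = spt.fit_alpha(curves, n_lags=10)
    st = states.decompose(trajs, n_iter=p["n_iter"], burn_in=p["burn_in"],
                          seed=cfg.seed + 1)
    from .io import save_trajectories
    save_trajectories(trajs, out / "trajectories.csv")
    result = {"alpha": fit.alpha, "D_apparent": fit.D_apparent,
              "n_states": st.n_states, "D": st.D.tolist(),
              "pi": st.pi.tolist(), "T": st.T.tolist(), "D_bar": st.D_bar}
    pd.DataFrame(states.transition_summary(st),
                 columns=["source", "target", "value"]).to_csv(
        out / "transitions_chord.csv", index=False)
    return result


def _recipe_afm(cfg: RunConfig, out: Path):
    p = {"E_kpa": [2, 16, 24, 180], "n_gels": 2, "n_areas": 4,
         "curves_per_area": 16, "noise_fraction": 0.05, "n_samples": 2048,
         **cfg.params}
    rows = []
    rng = np.random.default_rng(cfg.seed)
    model = afm.IndenterModel()
    for e_kpa in p["E_kpa"]:
        # noise referenced to the force at the 1 um fit depth, so the
        # relative measurement error is the same for every gel stiffness
        noise_sd = p["noise_fraction"] * model.prefactor * e_kpa * 1000.0 * (1e-6) ** 2
        fits = []
        for gel in range(p["n_gels"]):
            for area in range(p["n_areas"]):
                for i in range(p["curves_per_area"]):
                    truth = synth.ForceCurveTruth(
                        E_true=e_kpa * 1000.0,
                        contact_index=int(rng.integers(p["n_samples"] // 4,
                                                       p["n_samples"] // 2)),
                        noise_sd=noise_sd)
                    curve = synth.make_force_curve(truth, n_samples=p["n_samples"],
                                                   seed=int(rng.integers(2**31)))
                    try:
                        fit = afm.fit_young_modulus(curve)
                        fits.append({"gel": gel, "area": area, "E": fit.E})
                    except ValueError:
                        fits.append({"gel": gel, "area": area, "E": np.nan})
        summ = afm.grid_summary(fits)
        for (gel, area), row in summ["per_area"].iterrows():
            rows.append({"E_nominal_kpa": e_kpa, "gel": gel, "area": area,
                         "E_mean_pa": row["mean"], "E_sd_pa": row["std"],
                         "n": row["count"]})
    df = pd.DataFrame(rows)
    df.to_csv(out / "afm_grid.csv", index=False)
    per_gel = df.groupby("E_nominal_kpa")["E_mean_pa"].mean()
    return {"per_condition_mean_pa": per_gel.to_dict()}


def _recipe_morphology(cfg: RunConfig, out: Path):
    from skimage import draw
    p = {"n_cells": 4, "radius_px": 60, **cfg.params}
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for c in range(p["n_cells"]):
        r = int(p["radius_px"] * rng.uniform(0.8, 1.2))
        size = 4 * r
        img = np.zeros((5, size, size))
        rr, cc = draw.ellipse(size // 2, size // 2, r, int(r * rng.uniform(0.7, 1.0)))
        for z in range(5):
            plane = np.zeros((size, size))
            plane[rr, cc] = 100.0 * np.exp(-((z - 2) / 1.5) ** 2)
            img[z] = plane + rng.normal(0, 2, (size, size))
        fp, m3 = morphology.segment_cell(img)
        cm = morphology.shape_metrics(fp, m3)
        rows.append({"cell_id": c, "area_um2": cm.area,
                     "roundness_pct": cm.roundness, "volume_um3": cm.volume})
    df = pd.DataFrame(rows)
    df.to_csv(out / "morphology.csv", index=False)
    return {"mean_area_um2": float(df["area_um2"].mean()),
            "mean_roundness_pct": float(df["roundness_pct"].mean())}


def _recipe_synapse(cfg: RunConfig, out: Path):
    p = {"intervals": [[(10, 20)], [(25, 30)]], "n_frames": 40, **cfg.params}
    intervals = [[tuple(iv) for iv in cell] for cell in p["intervals"]]
    stack, truth = synth.make_contact_movie(intervals, n_frames=p["n_frames"],
                                            seed=cfg.seed)
    tracks = synapse.track_bcells(stack, cell_channel=0)
    events = synapse.contact_metrics(tracks, truth["footprint_mask"],
                                     stack.pixel_size, truth["frame_interval_s"],
                                     cell_radius_um=truth["cell_radius_um"])
    df = pd.DataFrame([{"track_id": e.track_id, "t_start_s": e.start_frame
                        * truth["frame_interval_s"], "duration_s": e.duration,
                        "velocity_um_min": e.mean_velocity} for e in events])
    df.to_csv(out / "contact_events.csv", index=False)
    return {"n_events": len(events),
            "mean_contact_time_s": synapse.mean_contact_time(events)}


def _recipe_demo(cfg: RunConfig, out: Path):
    results = {}
    for name in ["enrichment", "spt_states", "afm", "morphology", "synapse"]:
        sub = RunConfig(recipe=name, seed=cfg.seed,
                        params=cfg.params.get(name, {}))
        results[name] = RECIPES[name](sub, out)
    return results


RECIPES = {
    "enrichment": _recipe_enrichment,
    "spt_states": _recipe_spt_states,
    "afm": _recipe_afm,
    "morphology": _recipe_morphology,
    "synapse": _recipe_synapse,
    "all_synthetic_demo": _recipe_demo,
}


def run_recipe(name: str, config: RunConfig | dict | None = None,
               out_dir=None) -> dict:
    """Run a named stage chain and write results, config and log to disk."""
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; valid: {sorted(RECIPES)}")
    if config is None:
        config = RunConfig(recipe=name)
    elif isinstance(config, dict):
        config = RunConfig(recipe=name, **config)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    result = RECIPES[name](config, out)
    config.to_yaml(out / "config_resolved.yaml")
    with open(out / "result.json", "w") as fh:
        json.dump(result, fh, indent=2, default=float)
    with open(out / "run.log", "w") as fh:
        fh.write(f"recipe={name}\nseed={config.seed}\n"
                 f"python={platform.python_version()}\n"
                 f"numpy={np.__version__}\n")
    return result


def aggregate_by_experiment(table: pd.DataFrame, value: str,
                            experiment: str = "experiment",
                            condition: str | None = None):
    """Hierarchical means: cells -> per-experiment means -> grand mean.

    Returns a dict with the per-experiment means (optionally nested per
    condition) and the grand mean of those means, so each experiment
    carries equal weight regardless of its cell count.
    """
    if experiment not in table.columns:
        raise ValueError(f"missing experiment id column {experiment!r}")
    df = table.dropna(subset=[value])
    group_cols = [condition, experiment] if condition else [experiment]
    per_exp = df.groupby(group_cols)[value].mean()
    if condition:
        grand = per_exp.groupby(level=0).mean()
    else:
        grand = float(per_exp.mean())
    return {"per_experiment": per_exp, "grand_mean": grand}
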