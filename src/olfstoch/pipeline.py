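"""Pipeline orchestration: one call runs synthetic data → statistics →
circuit sweep → learning → decoding and writes a report bundle."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, circuit as circuit_mod, decoders, learning, synthetic
from .io import save_hdf5

log = logging.getLogger("olfstoch")

DEFAULT_CONFIG = {
    "seed": 0,
    "species": "fly",
    "stages": {
        "generate": True,
        "analyze": True,
        "circuit": True,
        "sweep": False,
        "discriminate": True,
        "decode": True,
    },
    "generate": {"n_cells": 124, "pair_targets": [0.6, 0.1]},
    "circuit": {
        "n_kc": 150,
        "n_odors": 6,
        "n_trials": 6,
        "wta_variant": "multi",
        "gain_target": 0.08,
        "noise": {"sigma_kc": 1.0, "sigma_apl": 0.30},
    },
    "sweep": {"replicates": 5},
    "discriminate": {"n_trials_normal": 12, "n_trials_extended": 100,
                     "delta": 0.5},
    "decode": {"models": ["lda", "knn", "svm"], "fold_fraction": 0.2},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    if "seed" not in cfg or cfg["seed"] is None:
        raise ValueError("a seed is mandatory for stochastic stages")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages in dependency order.

    Every output file carries the config hash and seed; the JSON summary
    gathers the five stochastic-code characteristics, Gamma fits,
    discrimination contributions and decoder scores.  A stage failure
    aborts with a diagnostic naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    seed = int(config["seed"])
    chash = config_hash(config)
    summary: dict = {"config_hash": chash, "seed": seed}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)  # effective config, no hidden defaults

    state: dict = {}
    order = ["generate", "analyze", "circuit", "sweep", "discriminate", "decode"]
    runners = {
        "generate": _stage_generate,
        "analyze": _stage_analyze,
        "circuit": _stage_circuit,
        "sweep": _stage_sweep,
        "discriminate": _stage_discriminate,
        "decode": _stage_decode,
    }
    needs = {
        "analyze": ["generate"],
        "discriminate": ["analyze"],
        "decode": ["analyze"],
    }
    for name in order:
        if not stages.get(name, False):
            continue
        for dep in needs.get(name, []):
            if dep not in state:
                raise RuntimeError(
                    f"stage '{name}' requires stage '{dep}', which is disabled"
                )
        t0 = time.time()
        try:
            runners[name](config, seed, outdir, state, summary)
        except Exception as exc:  # noqa: BLE001 — diagnostic names the stage
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        log.info("stage %s finished in %.2fs", name, time.time() - t0)
        state[name] = True

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def _stage_generate(cfg, seed, outdir, state, summary):
    gen = cfg["generate"]
    config = synthetic.config_from_preset(
        cfg["species"], n_cells=int(gen["n_cells"])
    )
    tensor = synthetic.generate_responses(config, seed)
    save_hdf5(tensor, outdir / "synthetic_tensor.h5")
    state["tensor"] = tensor
    state["gen_config"] = config
    pairs = {}
    for k, target in enumerate(gen.get("pair_targets", [])):
        pairs[target] = synthetic.generate_correlated_pair(
            config, float(target), seed + 1000 + k
        )
    state["pairs"] = pairs
    summary["generate"] = {
        "n_cells": config.n_cells,
        "n_odors": config.n_odors,
        "n_trials": config.n_trials,
        "pair_targets": list(pairs),
    }


def _stage_analyze(cfg, seed, outdir, state, summary):
    tensor = state["tensor"]
    mask = analysis.detect_significant(tensor)
    table = analysis.classify_cells(mask)
    table.to_csv(outdir / "reliability_table.csv", index=False)
    fr = analysis.population_fractions(table, mask)
    fr["summary"].to_csv(outdir / "population_fractions.csv", index=False)
    overlap = analysis.pairwise_overlap(table)
    overlap["per_pair"].to_csv(outdir / "overlap_matrix.csv", index=False)
    fits = {}
    p_vals = table.p_response[table.p_response > 0].to_numpy()
    if p_vals.size >= 10 and np.unique(p_vals).size > 1:
        g = analysis.fit_gamma(p_vals)
        fits["reliability"] = {"shape": g.shape, "scale": g.scale}
    sizes = table.expected_response[table.p_response > 0].to_numpy()
    sizes = sizes[sizes > 0]
    if sizes.size >= 10:
        g = analysis.fit_gamma(sizes)
        fits["expected_response"] = {"shape": g.shape, "scale": g.scale}
    pd.DataFrame(fits).to_csv(outdir / "gamma_fits.csv")
    state["mask"], state["table"] = mask, table
    summ = fr["summary"]
    pick = summ[summ.reduction == "odor_trial_pairs"].set_index("statistic")["mean"]
    per_odor = summ[summ.statistic.str.startswith("per_odor")].set_index("statistic")["mean"]
    summary["analyze"] = {
        "per_trial_reliable_pct": 100 * pick["per_trial_reliable"],
        "per_trial_unreliable_pct": 100 * pick["per_trial_unreliable"],
        "per_odor_reliable_pct": 100 * per_odor["per_odor_reliable"],
        "per_odor_unreliable_pct": 100 * per_odor["per_odor_unreliable"],
        "gamma_fits": fits,
    }


def _circuit_params(cfg) -> circuit_mod.CircuitParams:
    c = cfg["circuit"]
    return circuit_mod.CircuitParams(
        n_kc=int(c["n_kc"]),
        wta_variant=c["wta_variant"],
        target_active_fraction=float(c["gain_target"]),
    )


def _stage_circuit(cfg, seed, outdir, state, summary):
    c = cfg["circuit"]
    params = _circuit_params(cfg)
    noise = circuit_mod.NoiseConfig(**c["noise"])
    circ = circuit_mod.build_circuit(params, seed)
    panel = circuit_mod.make_odor_panel(int(c["n_odors"]), params.n_pn_types, seed + 1)
    circuit_mod.calibrate_apl_gain(circ, panel)
    activity = circuit_mod.run_experiment(circ, panel, noise, int(c["n_trials"]), seed + 2)
    res = circuit_mod.evaluate_characteristics(activity)
    pd.DataFrame([res]).to_csv(outdir / "circuit_characteristics.csv", index=False)
    summary["circuit"] = res


def _stage_sweep(cfg, seed, outdir, state, summary):
    params = _circuit_params(cfg)
    grid = circuit_mod.default_sweep_grid()
    sweep = circuit_mod.parameter_sweep(
        params, grid, replicates=int(cfg["sweep"]["replicates"]), seed=seed
    )
    sweep.to_csv(outdir / "sweep.csv", index=False)
    best = circuit_mod.summarize_sweep(sweep).iloc[0]
    summary["sweep"] = {
        "n_configs": int(sweep.config.nunique()),
        "best_max_rel_error": float(best.max_rel_error),
        "best_sigma_kc": float(best.sigma_kc),
        "best_sigma_apl": float(best.sigma_apl),
        "best_gain_target": float(best.gain_target),
    }


def _stage_discriminate(cfg, seed, outdir, state, summary):
    table = state["table"]
    d = cfg["discriminate"]
    tc = learning.TrainingConfig(
        n_trials_normal=int(d["n_trials_normal"]),
        n_trials_extended=int(d["n_trials_extended"]),
        simplified_saturation=bool(d.get("simplified", False)),
    )
    n_trials = int(table.n_trials.iloc[0])
    rows = []
    sim = analysis.odor_similarity(state["mask"])
    for _, pair in sim.iterrows():
        a, b = int(pair.odor_i), int(pair.odor_j)
        reports = {}
        for regime in ("normal", "extended"):
            w = learning.train_association(
                table, a, b, tc, regime=regime, seed=seed, delta=float(d["delta"])
            )
            reports[regime] = learning.discrimination_score(w, table, a, regime)
        contrib = learning.contribution_by_reliability(
            reports["normal"], reports["extended"], n_trials
        )
        for _, r in contrib.iterrows():
            rows.append(
                {"odor_a": a, "odor_b": b, "pair_label": pair.label,
                 **r.to_dict()}
            )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "discrimination_contributions.csv", index=False)
    by_level = df.groupby("reliability_level")["change"].sum()
    summary["discriminate"] = {
        "change_by_level": {int(k): float(v) for k, v in by_level.items()}
    }


def _stage_decode(cfg, seed, outdir, state, summary):
    mask, table = state["mask"], state["table"]
    d = cfg["decode"]
    rows = []
    for cls in ("reliable", "unreliable", "all"):
        feats = decoders.mask_by_class(mask, table, cls)
        for model in d["models"]:
            acc, pred = decoders.kfold_evaluate(
                feats, decoder=model, fold_fraction=float(d["fold_fraction"]),
                seed=seed,
            )
            rows.append(
                {"mask": cls, "model": model, "accuracy": acc,
                 "a2a_auc": decoders.a2a_auc(pred)}
            )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "decoder_scores.csv", index=False)
    summary["decode"] = df.to_dict(orient="records")
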