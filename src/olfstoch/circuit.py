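"""Linear rate-firing model of the PN→KC→APL winner-take-all circuit.

Each Kenyon cell (KC) sums exponentially distributed projection-neuron (PN)
rates through a sparse random connectivity matrix (claw counts Binomial,
synapse strengths Gamma), all KCs excite the single inhibitory APL neuron
through multiple synapses, and APL feeds back subtractive inhibition scaled
by a gain calibrated so that a target fraction of KCs stays active without
noise.  Multiplicative Gaussian noise can be injected at six loci; the
single- and multi-synapse variants differ in whether APL→KC synaptic noise
is correlated or independent across a KC's feedback synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .analysis import SignificanceMask, classify_cells, population_fractions


@dataclass
class CircuitParams:
    """Connectivity statistics of the modelled mushroom body."""

    n_pn_types: int = 50
    n_kc: int = 150
    claw_n: int = 8            # Binomial n for claw counts
    claw_p: float = 0.85       # Binomial p; mean claw count 6.8
    pn_kc_gamma: tuple = (4.0, 4.0)  # synapse strength Gamma (shape, scale)
    pn_type_weights: np.ndarray | None = None  # claw-sampling popularity; uniform if None
    apl_synapse_range: tuple = (2, 38)  # per-KC APL<->KC contact count
    kc_threshold_t: float = 0.0
    target_active_fraction: float = 0.08  # noiseless top-active calibration
    wta_variant: str = "multi"  # "single" | "multi"

    def __post_init__(self) -> None:
        if self.n_pn_types <= 0 or self.n_kc <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 < self.target_active_fraction < 1.0:
            raise ValueError("target_active_fraction must lie in (0, 1)")
        if self.wta_variant not in ("single", "multi"):
            raise ValueError("wta_variant must be 'single' or 'multi'")
        lo, hi = self.apl_synapse_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid APL synapse count range")


@dataclass
class NoiseConfig:
    """Gaussian sd of multiplicative noise x -> x*(1+N(0, sigma)) per locus."""

    sigma_pn: float = 0.0
    sigma_pn_kc: float = 0.0
    sigma_kc: float = 0.0
    sigma_kc_apl: float = 0.0
    sigma_apl: float = 0.0
    sigma_apl_kc: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")

    def any_noise(self) -> bool:
        return any(v > 0 for v in self.__dict__.values())


@dataclass
class OdorPanel:
    """Per-odor PN firing rates, drawn from an exponential distribution."""

    pn_rates: np.ndarray  # (n_odors, n_pn_types)

    def __post_init__(self) -> None:
        self.pn_rates = np.asarray(self.pn_rates, dtype=float)
        if np.any(self.pn_rates < 0):
            raise ValueError("PN rates must be non-negative")

    @property
    def n_odors(self) -> int:
        return self.pn_rates.shape[0]


@dataclass
class CharacteristicTargets:
    """The five experimental statistics of the stochastic code (fly)."""

    ratio_reliable_unreliable_per_trial: float = 0.72
    reliable_per_trial_pct: float = 5.3
    unreliable_per_trial_pct: float = 7.2
    reliable_per_odor_pct: float = 6.1
    unreliable_per_odor_pct: float = 29.0
    rel_tolerance: float = 0.25

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.ratio_reliable_unreliable_per_trial,
                self.reliable_per_trial_pct,
                self.unreliable_per_trial_pct,
                self.reliable_per_odor_pct,
                self.unreliable_per_odor_pct,
            ]
        )

    def __post_init__(self) -> None:
        if np.any(self.as_array() <= 0):
            raise ValueError("targets must be positive")
        if not 0.0 < self.rel_tolerance:
            raise ValueError("tolerance must be positive")


@dataclass
class Circuit:
    """A realized circuit: connectivity plus (once calibrated) the APL gain."""

    params: CircuitParams
    pn_kc_weights: np.ndarray  # (n_kc, n_pn_types)
    apl_counts: np.ndarray     # per-KC synapse count, same in both directions
    apl_gain: float | None = None


def build_circuit(params: CircuitParams, seed: int) -> Circuit:
    """Realize connectivity from the configured distributions.

    Claw counts are Binomial(n, p) with zero draws redrawn so every KC has
    at least one input; each claw connects to a uniformly sampled PN type
    with a Gamma-distributed strength.  One APL synapse count per KC is
    drawn uniformly on the configured range and used for both the KC→APL
    and APL→KC directions (the two directions' counts are correlated in
    the connectome; perfect correlation is assumed here).
    """
    rng = np.random.default_rng(seed)
    n_kc, n_pn = params.n_kc, params.n_pn_types
    claws = rng.binomial(params.claw_n, params.claw_p, size=n_kc)
    while np.any(claws == 0):
        redo = claws == 0
        claws[redo] = rng.binomial(params.claw_n, params.claw_p, size=int(redo.sum()))
    shape, scale = params.pn_kc_gamma
    popularity = params.pn_type_weights
    if popularity is not None:
        popularity = np.asarray(popularity, dtype=float)
        if popularity.shape != (n_pn,) or np.any(popularity < 0):
            raise ValueError("pn_type_weights must be non-negative, one per PN type")
        popularity = popularity / popularity.sum()
    weights = np.zeros((n_kc, n_pn))
    for i, c in enumerate(claws):
        if popularity is None:
            types = rng.integers(0, n_pn, size=c)
        else:
            types = rng.choice(n_pn, size=c, p=popularity)
        np.add.at(weights[i], types, rng.gamma(shape, scale, size=c))
    lo, hi = params.apl_synapse_range
    counts = rng.integers(lo, hi + 1, size=n_kc)
    return Circuit(params=params, pn_kc_weights=weights, apl_counts=counts)


def make_odor_panel(
    n_odors: int, n_pn_types: int, seed: int, rate_scale: float = 1.0
) -> OdorPanel:
    """Exponentially distributed PN rates for a panel of odors."""
    rng = np.random.default_rng(seed)
    return OdorPanel(rng.exponential(rate_scale, size=(n_odors, n_pn_types)))


def simulate_trial(
    circuit: Circuit,
    pn_rates: np.ndarray,
    noise: NoiseConfig,
    rng: np.random.Generator,
    gain: float | None = None,
) -> np.ndarray:
    """One feedforward-inhibit-rectify pass; returns final KC activity.

    Order of operations: (1) feedforward drive with PN, PN→KC and KC noise;
    (2) rectify at the KC threshold t; (3) APL drive through noisy KC→APL
    synapses, then APL-source noise; (4) subtract APL feedback through
    noisy APL→KC synapses — one shared noise term per KC in the
    single-synapse variant, independent per-synapse noise (which averages
    as sigma/sqrt(count)) in the multi-synapse variant; (5) rectify at 0.

    Per-synapse noise on a KC's ``c`` unit-strength contacts is applied as
    a single draw with sd sigma/sqrt(c), the exact law of the mean of c
    independent draws.
    """
    p = circuit.params
    g = circuit.apl_gain if gain is None else gain
    if g is None:
        raise ValueError("circuit gain not calibrated; run calibrate_apl_gain")
    n_kc = p.n_kc
    counts = circuit.apl_counts.astype(float)

    rates = pn_rates
    if noise.sigma_pn > 0:
        rates = rates * (1 + rng.normal(0, noise.sigma_pn, rates.shape))
    if noise.sigma_pn_kc > 0:
        w = circuit.pn_kc_weights * (
            1 + rng.normal(0, noise.sigma_pn_kc, circuit.pn_kc_weights.shape)
        )
        drive = w @ rates
    else:
        drive = circuit.pn_kc_weights @ rates
    if noise.sigma_kc > 0:
        drive = drive * (1 + rng.normal(0, noise.sigma_kc, n_kc))
    drive = np.clip(drive - p.kc_threshold_t, 0.0, None)

    s_out = counts
    if noise.sigma_kc_apl > 0:
        s_out = s_out * (1 + rng.normal(0, noise.sigma_kc_apl / np.sqrt(counts)))
    apl = float(np.sum(drive * s_out))
    if noise.sigma_apl > 0:
        apl *= 1 + rng.normal(0, noise.sigma_apl)

    s_in = counts
    if noise.sigma_apl_kc > 0:
        if p.wta_variant == "single":
            s_in = s_in * (1 + rng.normal(0, noise.sigma_apl_kc, n_kc))
        else:
            s_in = s_in * (1 + rng.normal(0, noise.sigma_apl_kc / np.sqrt(counts)))
    return np.clip(drive - apl * s_in * g, 0.0, None)


def _noiseless_active_fraction(circuit: Circuit, panel: OdorPanel, gain: float) -> float:
    quiet = NoiseConfig()
    rng = np.random.default_rng(0)  # unused on the noiseless path
    fracs = [
        float((simulate_trial(circuit, r, quiet, rng, gain=gain) > 0).mean())
        for r in panel.pn_rates
    ]
    return float(np.mean(fracs))


def calibrate_apl_gain(
    circuit: Circuit,
    panel: OdorPanel,
    target_active_fraction: float | None = None,
    tol_pp: float = 0.005,
    max_iter: int = 80,
) -> float:
    """Bisect the APL gain so the noiseless active fraction hits the target.

    The active fraction is monotone non-increasing in the gain; the search
    stops when the mean noiseless active fraction over the panel's odors is
    within ``tol_pp`` (0.5 percentage points by default) of the target.
    The calibrated gain is stored on the circuit and returned.
    """
    target = (
        circuit.params.target_active_fraction
        if target_active_fraction is None
        else target_active_fraction
    )
    lo, hi = 0.0, 1.0
    f_lo = _noiseless_active_fraction(circuit, panel, lo)
    if f_lo < target:
        raise ValueError(
            f"target {target:.3f} exceeds the zero-gain active fraction {f_lo:.3f}"
        )
    while _noiseless_active_fraction(circuit, panel, hi) > target and hi < 1e6:
        hi *= 2.0
    if hi >= 1e6:
        raise ValueError("gain search failed to bracket the target")
    gain = hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = _noiseless_active_fraction(circuit, panel, mid)
        if abs(f - target) <= tol_pp:
            gain = mid
            break
        if f > target:
            lo = mid
        else:
            hi = mid
        gain = mid
    circuit.apl_gain = gain
    return gain


def run_experiment(
    circuit: Circuit,
    panel: OdorPanel,
    noise: NoiseConfig,
    n_trials: int,
    seed: int,
) -> np.ndarray:
    """Simulate the full panel; returns activity (kc, odor, trial).

    Fresh noise is drawn on every trial; connectivity and gain are fixed.
    """
    rng = np.random.default_rng(seed)
    activity = np.zeros((circuit.params.n_kc, panel.n_odors, n_trials))
    for o, rates in enumerate(panel.pn_rates):
        for t in range(n_trials):
            activity[:, o, t] = simulate_trial(circuit, rates, noise, rng)
    return activity


def activity_to_mask(activity: np.ndarray) -> SignificanceMask:
    """Wrap model activity for the response-analysis stage.

    A KC counts as responding when its final activity is positive, and the
    activity value doubles as the response size.
    """
    return SignificanceMask(
        responded=activity > 0,
        response_size=activity,
        threshold_sd=1.0,
        baseline_mean=np.zeros(activity.shape),
        baseline_sd=np.zeros(activity.shape),
    )


def evaluate_characteristics(
    activity: np.ndarray, targets: CharacteristicTargets | None = None
) -> dict:
    """Score an activity table against the five stochastic-code statistics.

    Delegates classification and fractions to the response-analysis module.
    A run with no unreliable cells has an undefined ratio and is reported
    as a failure rather than a division error.
    """
    targets = targets or CharacteristicTargets()
    mask = activity_to_mask(activity)
    table = classify_cells(mask)
    fr = population_fractions(table, mask)
    per_trial = fr["per_trial"]
    per_odor = fr["per_odor"]
    rel_pt = per_trial.frac_reliable.mean() * 100
    un_pt = per_trial.frac_unreliable.mean() * 100
    rel_po = per_odor.frac_reliable.mean() * 100
    un_po = per_odor.frac_unreliable.mean() * 100
    ratio = rel_pt / un_pt if un_pt > 0 else float("inf")
    values = np.array([ratio, rel_pt, un_pt, rel_po, un_po])
    tgt = targets.as_array()
    with np.errstate(invalid="ignore"):
        rel_err = np.abs(values / tgt - 1.0)
    finite = np.isfinite(values)
    passed = bool(finite.all() and np.all(rel_err <= targets.rel_tolerance))
    return {
        "ratio_reliable_unreliable_per_trial": float(ratio),
        "reliable_per_trial_pct": float(rel_pt),
        "unreliable_per_trial_pct": float(un_pt),
        "reliable_per_odor_pct": float(rel_po),
        "unreliable_per_odor_pct": float(un_po),
        "max_rel_error": float(rel_err[finite].max()) if finite.all() else float("inf"),
        "passed": passed,
    }


def default_sweep_grid(
    sigma_kc=(0.6, 0.8, 1.0),
    sigma_apl=(0.15, 0.20, 0.25, 0.30),
    gain_targets=(0.06, 0.07, 0.08, 0.09, 0.10, 0.11),
) -> list:
    """Grid over KC-integration noise x APL-source noise x gain target.

    These are the loci the model identifies as jointly producing the
    stochastic code: APL-source noise escapes synaptic averaging, and KC
    noise trades off against it, so the sweep combs their combinations
    with the APL band restricted to the physiologically plausible 15–30%.
    """
    return [
        (NoiseConfig(sigma_kc=k, sigma_apl=a), g)
        for k, a, g in product(sigma_kc, sigma_apl, gain_targets)
    ]


def parameter_sweep(
    params: CircuitParams,
    grid: list,
    n_odors: int = 6,
    n_trials: int = 6,
    replicates: int = 5,
    seed: int = 0,
    targets: CharacteristicTargets | None = None,
) -> pd.DataFrame:
    """Run every (noise, gain-target) configuration with replicate circuits.

    One row per configuration x replicate; each replicate draws a fresh
    circuit and odor panel, calibrates the gain noiselessly, simulates the
    panel and scores the five characteristics.
    """
    targets = targets or CharacteristicTargets()
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(replicates)
    rows = []
    for cfg_idx, (noise, gain_target) in enumerate(grid):
        p = replace(params, target_active_fraction=gain_target)
        for rep, rep_ss in enumerate(rep_seeds):
            build_seed, panel_seed, run_seed = [
                int(s.generate_state(1)[0] % (2**31)) for s in rep_ss.spawn(3)
            ]
            circuit = build_circuit(p, build_seed)
            panel = make_odor_panel(n_odors, p.n_pn_types, panel_seed)
            calibrate_apl_gain(circuit, panel)
            activity = run_experiment(circuit, panel, noise, n_trials, run_seed)
            res = evaluate_characteristics(activity, targets)
            rows.append(
                {
                    "config": cfg_idx,
                    "replicate": rep,
                    "sigma_pn": noise.sigma_pn,
                    "sigma_pn_kc": noise.sigma_pn_kc,
                    "sigma_kc": noise.sigma_kc,
                    "sigma_kc_apl": noise.sigma_kc_apl,
                    "sigma_apl": noise.sigma_apl,
                    "sigma_apl_kc": noise.sigma_apl_kc,
                    "gain_target": gain_target,
                    **res,
                }
            )
    return pd.DataFrame(rows)


def summarize_sweep(
    sweep: pd.DataFrame, targets: CharacteristicTargets | None = None
) -> pd.DataFrame:
    """Per-configuration mean statistics, pass fraction, and overall pass.

    A configuration passes when its replicate-mean statistics all lie
    within the targets' relative tolerance.  Sorted by distance to the
    characteristic set (max relative error of the means).
    """
    targets = targets or CharacteristicTargets()
    stat_cols = [
        "ratio_reliable_unreliable_per_trial",
        "reliable_per_trial_pct",
        "unreliable_per_trial_pct",
        "reliable_per_odor_pct",
        "unreliable_per_odor_pct",
    ]
    meta_cols = [
        "sigma_pn", "sigma_pn_kc", "sigma_kc",
        "sigma_kc_apl", "sigma_apl", "sigma_apl_kc", "gain_target",
    ]
    grouped = sweep.groupby("config")
    out = grouped[stat_cols].mean()
    out[meta_cols] = grouped[meta_cols].first()
    out["pass_fraction"] = grouped["passed"].mean()
    tgt = CharacteristicTargets().as_array() if targets is None else targets.as_array()
    vals = out[stat_cols].to_numpy()
    with np.errstate(invalid="ignore"):
        rel_err = np.abs(vals / tgt - 1.0)
    rel_err[~np.isfinite(vals)] = np.inf
    out["max_rel_error"] = rel_err.max(axis=1)
    out["passed_mean"] = out["max_rel_error"] <= targets.rel_tolerance
    return out.sort_values("max_rel_error").reset_index()


def noise_threshold_for_ratio(
    params: CircuitParams,
    locus: str,
    sigma_grid,
    target_ratio: float = 2.0,
    n_odors: int = 6,
    n_trials: int = 6,
    replicates: int = 5,
    seed: int = 0,
) -> float | None:
    """Smallest sigma at a single noise locus driving the per-trial
    reliable:unreliable ratio down to ``target_ratio``.

    The ratio decreases monotonically (in expectation) with noise; loci
    whose noise escapes synaptic averaging (the WTA loci) need far smaller
    sigma than the feedforward loci.  Returns None when no grid value
    reaches the target.
    """
    field_name = f"sigma_{locus}"
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(replicates)
    for sigma in sorted(sigma_grid):
        noise = NoiseConfig(**{field_name: sigma})
        ratios = []
        for rep_ss in rep_seeds:
            build_seed, panel_seed, run_seed = [
                int(s.generate_state(1)[0] % (2**31)) for s in rep_ss.spawn(3)
            ]
            circuit = build_circuit(params, build_seed)
            panel = make_odor_panel(n_odors, params.n_pn_types, panel_seed)
            calibrate_apl_gain(circuit, panel)
            activity = run_experiment(circuit, panel, noise, n_trials, run_seed)
            res = evaluate_characteristics(activity)
            ratios.append(res["ratio_reliable_unreliable_per_trial"])
        finite = [r for r in ratios if np.isfinite(r)]
        if finite and np.mean(finite) <= target_ratio:
            return float(sigma)
    return None
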