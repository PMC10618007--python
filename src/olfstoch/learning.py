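"""Associative plasticity at KC→MBON synapses and discrimination scoring.

Reward depresses the synapses from odor-active KCs onto the avoidance
MBON; punishment depresses those onto the approach MBON; each depression is
proportional to the cell's response and the learning rate, floored at zero.
A cell's contribution to discriminating a rewarded odor A from a punished
odor B is its response probability to A times its approach−avoid weight
difference; the population discrimination is the sum over cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import RELIABLE, SILENT, UNRELIABLE


@dataclass
class SynapseWeights:
    """Per-KC weights onto the approach and avoid MBONs.

    Weights start equal and can only be depressed, never below zero.
    """

    w_approach: np.ndarray
    w_avoid: np.ndarray
    delta: float = 0.5
    initial_weight: float = 1.0

    def __post_init__(self) -> None:
        self.w_approach = np.asarray(self.w_approach, dtype=float)
        self.w_avoid = np.asarray(self.w_avoid, dtype=float)
        if self.delta <= 0:
            raise ValueError("learning rate delta must be positive")
        if np.any(self.w_approach < 0) or np.any(self.w_avoid < 0):
            raise ValueError("synaptic weights cannot be negative")

    def copy(self) -> "SynapseWeights":
        return SynapseWeights(
            self.w_approach.copy(), self.w_avoid.copy(),
            delta=self.delta, initial_weight=self.initial_weight,
        )


@dataclass
class TrainingConfig:
    """Training regimes: normal (short) vs extended (long) CS-US pairing."""

    n_trials_normal: int = 12
    n_trials_extended: int = 100
    valence_map: dict = field(default_factory=dict)  # odor -> reward|punishment
    simplified_saturation: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.n_trials_normal < self.n_trials_extended:
            raise ValueError("need extended > normal > 0 training trials")
        for v in self.valence_map.values():
            if v not in ("reward", "punishment"):
                raise ValueError(f"unknown valence {v!r}")


@dataclass
class DiscriminationReport:
    """Per-cell and total discrimination contributions for an odor pair."""

    d_x: np.ndarray          # per-KC contribution
    total: float             # sum over cells
    regime: str              # training regime label
    per_class: pd.DataFrame  # signed and absolute sums per reliability class


def init_weights(
    n_cells: int, initial_weight: float = 1.0, delta: float = 0.5
) -> SynapseWeights:
    """Equal initial weights onto both MBONs."""
    w = np.full(n_cells, float(initial_weight))
    return SynapseWeights(w.copy(), w.copy(), delta=delta,
                          initial_weight=initial_weight)


def update_weights(
    weights: SynapseWeights, responses: np.ndarray, valence: str
) -> SynapseWeights:
    """Apply sequential training trials to the weights (returns a copy).

    ``responses`` has shape (n_trials, n_cells); each reward trial
    depresses the avoid weights, each punishment trial the approach
    weights, by delta times the cell's response, floored at zero.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    if np.any(responses < 0):
        raise ValueError("response amplitudes must be non-negative")
    if valence not in ("reward", "punishment"):
        raise ValueError(f"unknown valence {valence!r}")
    out = weights.copy()
    target = out.w_avoid if valence == "reward" else out.w_approach
    for r in responses:
        np.maximum(target - out.delta * r, 0.0, out=target)
    return out


def _per_odor_arrays(table: pd.DataFrame, odor: int):
    sub = table[table.odor == odor].sort_values("cell")
    p = sub.p_response.to_numpy()
    expected = sub.expected_response.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(p > 0, expected / p, 0.0)  # mean size per response
    return p, amp, sub.label.to_numpy()


def train_association(
    table: pd.DataFrame,
    odor_a: int,
    odor_b: int,
    config: TrainingConfig,
    regime: str = "normal",
    seed: int = 0,
    initial_weight: float = 1.0,
    delta: float = 0.5,
) -> SynapseWeights:
    """Train A→reward, B→punishment from a reliability table.

    In the full stochastic mode each training trial resamples every cell's
    response from its reliability probability (amplitude = its mean
    per-response size).  In the simplified-saturation mode the reliable-cell
    synapses are set to zero after normal training and additionally the
    unreliable-cell synapses after extended training, with no sampling.
    """
    if regime not in ("normal", "extended"):
        raise ValueError("regime must be 'normal' or 'extended'")
    n_trials = (
        config.n_trials_normal if regime == "normal" else config.n_trials_extended
    )
    p_a, amp_a, lab_a = _per_odor_arrays(table, odor_a)
    p_b, amp_b, lab_b = _per_odor_arrays(table, odor_b)
    weights = init_weights(len(p_a), initial_weight, delta)

    if config.simplified_saturation:
        saturate_a = lab_a == RELIABLE
        saturate_b = lab_b == RELIABLE
        if regime == "extended":
            saturate_a |= lab_a == UNRELIABLE
            saturate_b |= lab_b == UNRELIABLE
        weights.w_avoid[saturate_a] = 0.0     # A rewarded
        weights.w_approach[saturate_b] = 0.0  # B punished
        return weights

    rng = np.random.default_rng(seed)
    resp_a = (rng.uniform(size=(n_trials, len(p_a))) < p_a) * amp_a
    resp_b = (rng.uniform(size=(n_trials, len(p_b))) < p_b) * amp_b
    weights = update_weights(weights, resp_a, "reward")
    weights = update_weights(weights, resp_b, "punishment")
    return weights


def discrimination_score(
    weights: SynapseWeights,
    table: pd.DataFrame,
    odor_a: int,
    regime: str = "",
) -> DiscriminationReport:
    """Per-cell contributions D_x = p_x(A)·(w_approach − w_avoid) and sums.

    Class-restricted sums are reported both signed and as sums of absolute
    contributions, keyed by the cell's reliability class and level for the
    rewarded odor A.
    """
    p_a, _, lab_a = _per_odor_arrays(table, odor_a)
    d_x = p_a * (weights.w_approach - weights.w_avoid)
    sub = table[table.odor == odor_a].sort_values("cell")
    frame = pd.DataFrame(
        {
            "label": lab_a,
            "n_responses": sub.n_responses.to_numpy(),
            "d": d_x,
            "abs_d": np.abs(d_x),
        }
    )
    per_class = (
        frame.groupby(["label", "n_responses"])[["d", "abs_d"]]
        .sum()
        .reset_index()
        .rename(columns={"d": "signed_sum", "abs_d": "abs_sum"})
    )
    return DiscriminationReport(
        d_x=d_x, total=float(d_x.sum()), regime=regime, per_class=per_class
    )


def class_total(report: DiscriminationReport, label: str, signed: bool = True) -> float:
    """Summed contribution of one reliability class (signed or absolute)."""
    sub = report.per_class[report.per_class.label == label]
    col = "signed_sum" if signed else "abs_sum"
    return float(sub[col].sum())


def contribution_by_reliability(
    report_normal: DiscriminationReport,
    report_extended: DiscriminationReport,
    n_trials: int,
) -> pd.DataFrame:
    """Change in discrimination per reliability level, extended − normal.

    Levels are response counts 1..n_trials for the rewarded odor; each
    level's contribution is the sum of |D_x| over its cells.
    """
    def level_sums(report: DiscriminationReport) -> pd.Series:
        f = report.per_class[report.per_class.label != SILENT]
        return f.groupby("n_responses")["abs_sum"].sum()

    levels = np.arange(1, n_trials + 1)
    normal = level_sums(report_normal).reindex(levels, fill_value=0.0)
    extended = level_sums(report_extended).reindex(levels, fill_value=0.0)
    return pd.DataFrame(
        {
            "reliability_level": levels,
            "normal": normal.to_numpy(),
            "extended": extended.to_numpy(),
            "change": (extended - normal).to_numpy(),
        }
    )
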