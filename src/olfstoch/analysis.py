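"""Response-significance, reliability-class and distribution analyses.

Turns a :class:`~olfstoch.tensor.ResponseTensor` into significance masks,
reliable/unreliable/silent classes, population fractions, overlap and
similarity statistics, and maximum-likelihood Gamma fits — the statistics
that characterise a stochastic population code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tensor import ResponseTensor

DEFAULT_THRESHOLD_SD = 2.33  # one-sided p = 0.01 under a Gaussian baseline

RELIABLE, UNRELIABLE, SILENT = "reliable", "unreliable", "silent"


@dataclass
class SignificanceMask:
    """Per cell-odor-trial response significance.

    ``responded[c, o, t]`` is True when the mean ΔF/F over the response
    window exceeds the baseline mean by ``threshold_sd`` baseline standard
    deviations.  ``response_size`` carries the baseline-subtracted response
    window mean for every trial (significant or not), so downstream stages
    can compute expected responses without re-touching the raw tensor.
    Cells with zero baseline variance are listed in ``excluded_cells`` and
    never counted as responders.
    """

    responded: np.ndarray
    response_size: np.ndarray
    threshold_sd: float
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    excluded_cells: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")
        if self.responded.shape != self.response_size.shape:
            raise ValueError("responded and response_size shapes differ")

    @property
    def n_cells(self) -> int:
        return self.responded.shape[0]

    @property
    def n_odors(self) -> int:
        return self.responded.shape[1]

    @property
    def n_trials(self) -> int:
        return self.responded.shape[2]


@dataclass
class GammaFit:
    """Maximum-likelihood Gamma fit with the location fixed at zero."""

    shape: float
    scale: float
    method: str = "mle"
    goodness: float = float("nan")  # Kolmogorov–Smirnov statistic

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Gamma shape and scale must be positive")


def detect_significant(
    tensor: ResponseTensor,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    baseline_window: np.ndarray | None = None,
    response_window: np.ndarray | None = None,
    pooled_baseline: bool = False,
) -> SignificanceMask:
    """Threshold responses against the pre-stimulus baseline.

    A cell-trial responds when its mean over ``response_window`` exceeds
    ``baseline_mean + threshold_sd * baseline_sd``.  Baseline statistics
    are computed per trial from that trial's pre-onset window by default;
    with ``pooled_baseline`` they are pooled per cell-odor across trials.
    Cells whose baseline variance is exactly zero are flagged and excluded
    from the mask rather than divided through.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if baseline_window is None:
        baseline_window = tensor.baseline_frames()
    if response_window is None:
        response_window = tensor.response_frames()
    baseline_window = np.asarray(baseline_window)
    response_window = np.asarray(response_window)
    if np.intersect1d(baseline_window, response_window).size:
        raise ValueError("baseline and response windows overlap")
    for w, name in ((baseline_window, "baseline"), (response_window, "response")):
        if w.min() < 0 or w.max() >= tensor.n_frames:
            raise ValueError(f"{name} window outside the frame range")

    base = tensor.values[:, :, :, baseline_window]
    resp = tensor.values[:, :, :, response_window].mean(axis=3)
    bmean = base.mean(axis=3)
    bsd = base.std(axis=3, ddof=1)
    if pooled_baseline:
        # pool the pre-onset frames of all trials of a cell-odor
        pooled = base.reshape(base.shape[0], base.shape[1], -1)
        bmean = pooled.mean(axis=2)[:, :, None] * np.ones_like(bmean)
        bsd = pooled.std(axis=2, ddof=1)[:, :, None] * np.ones_like(bsd)

    responded = resp > bmean + threshold_sd * bsd
    zero_var = np.all(bsd == 0, axis=(1, 2))
    excluded = np.flatnonzero(zero_var)
    if excluded.size:
        responded = responded.copy()
        responded[excluded] = False
    return SignificanceMask(
        responded=responded,
        response_size=resp - bmean,
        threshold_sd=threshold_sd,
        baseline_mean=bmean,
        baseline_sd=bsd,
        excluded_cells=excluded,
    )


def classify_cells(mask: SignificanceMask) -> pd.DataFrame:
    """Reliability table: class label and expected response per cell-odor.

    Reliable cells respond in more than half of an odor's trials;
    unreliable cells respond in at least one but at most half; the rest are
    silent.  With an even trial count, exactly-half responders fall in the
    unreliable class.  The expected response is the mean over trials of
    (response indicator x response size).
    """
    if mask.n_trials < 2:
        raise ValueError("classification requires at least 2 trials per odor")
    n_resp = mask.responded.sum(axis=2)
    t = mask.n_trials
    label = np.where(
        n_resp > t / 2, RELIABLE, np.where(n_resp >= 1, UNRELIABLE, SILENT)
    )
    expected = np.where(mask.responded, mask.response_size, 0.0).mean(axis=2)
    cells, odors = np.meshgrid(
        np.arange(mask.n_cells), np.arange(mask.n_odors), indexing="ij"
    )
    return pd.DataFrame(
        {
            "cell": cells.ravel(),
            "odor": odors.ravel(),
            "n_responses": n_resp.ravel(),
            "n_trials": t,
            "p_response": n_resp.ravel() / t,
            "label": label.ravel(),
            "expected_response": expected.ravel(),
        }
    )


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def population_fractions(
    table: pd.DataFrame,
    mask: SignificanceMask,
    denominator: str = "all",
) -> dict:
    """Fractions of reliable and unreliable cells, per trial and per odor.

    Per-trial fraction: class members responding in that trial / denominator.
    Per-odor fraction: class members across all trials / denominator.
    ``denominator`` is ``"all"`` (total imaged cells) or ``"responsive"``
    (cells with at least one significant response to that odor) — it is an
    explicit parameter, never inferred.

    Returns a dict with ``per_trial`` and ``per_odor`` tidy frames plus a
    ``summary`` frame holding mean ± SEM under both reductions (over
    odor-trial pairs / trials, and over odors).
    """
    if denominator not in ("all", "responsive"):
        raise ValueError("denominator must be 'all' or 'responsive'")
    n_cells = mask.n_cells
    lab = table.pivot(index="cell", columns="odor", values="label").to_numpy()
    is_rel = lab == RELIABLE
    is_unrel = lab == UNRELIABLE

    per_trial_rows, per_odor_rows = [], []
    for o in range(mask.n_odors):
        denom = (
            n_cells
            if denominator == "all"
            else max(int((is_rel[:, o] | is_unrel[:, o]).sum()), 1)
        )
        for t in range(mask.n_trials):
            resp = mask.responded[:, o, t]
            per_trial_rows.append(
                {
                    "odor": o,
                    "trial": t,
                    "frac_reliable": (resp & is_rel[:, o]).sum() / denom,
                    "frac_unreliable": (resp & is_unrel[:, o]).sum() / denom,
                }
            )
        per_odor_rows.append(
            {
                "odor": o,
                "frac_reliable": is_rel[:, o].sum() / denom,
                "frac_unreliable": is_unrel[:, o].sum() / denom,
            }
        )
    per_trial = pd.DataFrame(per_trial_rows)
    per_odor = pd.DataFrame(per_odor_rows)

    rows = []
    for cls in ("reliable", "unreliable"):
        col = f"frac_{cls}"
        rows.append(
            {
                "statistic": f"per_trial_{cls}",
                "reduction": "odor_trial_pairs",
                "mean": per_trial[col].mean(),
                "sem": _sem(per_trial[col].to_numpy()),
            }
        )
        odor_means = per_trial.groupby("odor")[col].mean()
        rows.append(
            {
                "statistic": f"per_trial_{cls}",
                "reduction": "odors",
                "mean": odor_means.mean(),
                "sem": _sem(odor_means.to_numpy()),
            }
        )
        rows.append(
            {
                "statistic": f"per_odor_{cls}",
                "reduction": "odors",
                "mean": per_odor[col].mean(),
                "sem": _sem(per_odor[col].to_numpy()),
            }
        )
    return {"per_trial": per_trial, "per_odor": per_odor, "summary": pd.DataFrame(rows)}


def pairwise_overlap(table: pd.DataFrame) -> dict:
    """Overlap — the probability a cell responds to both odors of a pair.

    Per cell and odor pair the overlap is the product of the cell's
    response probabilities; the pair score is the mean over cells
    responsive to at least one odor of the pair.
    """
    p = table.pivot(index="cell", columns="odor", values="p_response").to_numpy()
    per_cell = p[:, :, None] * p[:, None, :]  # (cell, odor_i, odor_j)
    n_odors = p.shape[1]
    rows = []
    for i in range(n_odors):
        for j in range(n_odors):
            if i == j:
                continue
            responsive = (p[:, i] > 0) | (p[:, j] > 0)
            mean = per_cell[responsive, i, j].mean() if responsive.any() else 0.0
            rows.append(
                {
                    "odor_i": i,
                    "odor_j": j,
                    "mean_overlap": mean,
                    "n_responsive": int(responsive.sum()),
                }
            )
    return {"per_cell": per_cell, "per_pair": pd.DataFrame(rows)}


def overlap_score(n_responses_a: int, n_responses_b: int, n_trials: int) -> float:
    """Overlap of one cell from response counts: (k_a/T) * (k_b/T)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return (n_responses_a / n_trials) * (n_responses_b / n_trials)


def fit_gamma(values: np.ndarray) -> GammaFit:
    """Maximum-likelihood Gamma fit (location fixed at 0)."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values for a Gamma fit")
    if np.any(values <= 0):
        raise ValueError("Gamma fit requires strictly positive values")
    if np.allclose(values, values[0]):
        raise ValueError("degenerate (constant) input")
    shape, _, scale = stats.gamma.fit(values, floc=0)
    ks = stats.kstest(values, "gamma", args=(shape, 0, scale)).statistic
    return GammaFit(shape=float(shape), scale=float(scale), goodness=float(ks))


def cumulative_frequency(values: np.ndarray) -> pd.DataFrame:
    """Nonparametric cumulative frequency curve: P(X <= x) at each value."""
    values = np.sort(np.asarray(values, dtype=float))
    uniq, counts = np.unique(values, return_counts=True)
    return pd.DataFrame(
        {"value": uniq, "cumulative_frequency": np.cumsum(counts) / values.size}
    )


def _masked_sizes(mask: SignificanceMask) -> np.ndarray:
    """Response sizes with non-significant trials zeroed."""
    return np.where(mask.responded, mask.response_size, 0.0)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance vector excluded from correlation")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def odor_similarity(
    tensor_or_mask,
    mask: SignificanceMask | None = None,
    similar_cutoff: float = 0.5,
    dissimilar_cutoff: float = 0.15,
) -> pd.DataFrame:
    """Pairwise odor similarity from population response vectors.

    Two measures per unordered pair, both Pearson correlations over cells:

    - ``trial_pair_corr`` — the mean over all cross-odor trial pairs,
      discounting pairs with the same trial index;
    - ``avg_vector_corr`` — the correlation of trial-averaged vectors.

    Pairs with ``avg_vector_corr > similar_cutoff`` are labelled similar,
    ``<= dissimilar_cutoff`` dissimilar, otherwise intermediate.
    """
    m = tensor_or_mask if mask is None else mask
    if isinstance(m, ResponseTensor):
        m = detect_significant(m)
    sizes = _masked_sizes(m)  # (cell, odor, trial)
    n_odors, n_trials = m.n_odors, m.n_trials
    rows = []
    for i in range(n_odors):
        for j in range(i + 1, n_odors):
            cs = []
            for ti in range(n_trials):
                for tj in range(n_trials):
                    if ti == tj:
                        continue
                    c = _safe_corr(sizes[:, i, ti], sizes[:, j, tj])
                    if not np.isnan(c):
                        cs.append(c)
            trial_pair = float(np.mean(cs)) if cs else float("nan")
            avg = _safe_corr(sizes[:, i].mean(axis=1), sizes[:, j].mean(axis=1))
            label = (
                "similar"
                if avg > similar_cutoff
                else "dissimilar" if avg <= dissimilar_cutoff else "intermediate"
            )
            rows.append(
                {
                    "odor_i": i,
                    "odor_j": j,
                    "trial_pair_corr": trial_pair,
                    "avg_vector_corr": avg,
                    "label": label,
                }
            )
    return pd.DataFrame(rows)


def class_restricted_similarity(
    mask: SignificanceMask,
    table: pd.DataFrame,
    reference_class: str = RELIABLE,
) -> pd.DataFrame:
    """Odor-pair correlation using only the reference class of the first odor.

    For ordered pair (A, B) the cells in ``reference_class`` for odor A are
    selected (a cell reliable for A may be anything for B), and the
    correlation of their mean responses to A and to B is emitted — one
    point per ordered pair.  ``reference_class`` may also be
    ``"responsive"`` (reliable or unreliable), which reduces to the
    unrestricted measure.  Pairs whose class is empty for the first odor
    are skipped with a notice column.
    """
    sizes = _masked_sizes(mask).mean(axis=2)  # (cell, odor) trial-averaged
    lab = table.pivot(index="cell", columns="odor", values="label").to_numpy()
    rows = []
    for a in range(mask.n_odors):
        if reference_class == "responsive":
            sel = (lab[:, a] == RELIABLE) | (lab[:, a] == UNRELIABLE)
        else:
            sel = lab[:, a] == reference_class
        for b in range(mask.n_odors):
            if a == b:
                continue
            if sel.sum() < 2:
                rows.append(
                    {"odor_a": a, "odor_b": b, "correlation": float("nan"),
                     "n_cells": int(sel.sum()), "note": "class empty or too small"}
                )
                continue
            c = _safe_corr(sizes[sel, a], sizes[sel, b])
            rows.append(
                {"odor_a": a, "odor_b": b, "correlation": c,
                 "n_cells": int(sel.sum()), "note": ""}
            )
    return pd.DataFrame(rows)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _top_set(expected: np.ndarray, responsive: np.ndarray, lo: float, hi: float):
    """Cells between the lo-th and hi-th top percentile of responsive cells,
    ranked by expected response (hi=25 with lo=0 is the top quartile)."""
    idx = np.flatnonzero(responsive)
    if idx.size == 0:
        raise ValueError("no responsive cells for this odor")
    order = idx[np.argsort(-expected[idx], kind="stable")]
    n = idx.size
    start = int(np.floor(lo / 100 * n))
    stop = max(int(np.ceil(hi / 100 * n)), start + 1)
    return order[start:stop]


def percentile_similarity(
    mask: SignificanceMask,
    table: pd.DataFrame,
    percentiles=(25, 50, 75, 100),
    bands: bool = False,
) -> pd.DataFrame:
    """Cosine similarity of odor pairs restricted to top-percentile cells.

    For each odor the responsive cells are ranked by expected response; for
    a pair and percentile q the cosine of the two odors' trial-averaged
    response vectors is computed over the union of each odor's top-q% set.
    With ``bands`` the four quartile bands (0–25, 25–50, 50–75, 75–100) are
    used instead of nested top sets.
    """
    sizes = _masked_sizes(mask).mean(axis=2)
    exp = table.pivot(index="cell", columns="odor", values="expected_response").to_numpy()
    p = table.pivot(index="cell", columns="odor", values="p_response").to_numpy()
    responsive = p > 0
    windows = (
        [(lo, lo + 25) for lo in (0, 25, 50, 75)]
        if bands
        else [(0, q) for q in percentiles]
    )
    rows = []
    for i in range(mask.n_odors):
        for j in range(i + 1, mask.n_odors):
            for lo, hi in windows:
                cells = np.union1d(
                    _top_set(exp[:, i], responsive[:, i], lo, hi),
                    _top_set(exp[:, j], responsive[:, j], lo, hi),
                )
                rows.append(
                    {
                        "odor_i": i,
                        "odor_j": j,
                        "band_lo": lo,
                        "percentile": hi,
                        "cosine": _cosine(sizes[cells, i], sizes[cells, j]),
                        "n_cells": cells.size,
                    }
                )
    return pd.DataFrame(rows)


def selectivity_bias(
    table: pd.DataFrame,
    odor_pair: tuple[int, int],
    reliability_level: int,
) -> dict:
    """Observed co-response count over the random-membership expectation.

    For reliability level k and odors (A, B): cells at level k for A
    (count n_A) and for B (count n_B) would share n_A*n_B/N members if
    class membership were random over the N cells; the bias is the
    observed shared count divided by that expectation.
    """
    a, b = odor_pair
    n_resp = table.pivot(index="cell", columns="odor", values="n_responses").to_numpy()
    n_cells = n_resp.shape[0]
    at_level_a = n_resp[:, a] == reliability_level
    at_level_b = n_resp[:, b] == reliability_level
    n_a, n_b = int(at_level_a.sum()), int(at_level_b.sum())
    observed = int((at_level_a & at_level_b).sum())
    expected = n_a * n_b / n_cells
    if expected == 0:
        raise ValueError(
            f"zero expectation: no level-{reliability_level} cells for one odor"
        )
    return {
        "observed": observed,
        "expected": expected,
        "ratio": observed / expected,
        "n_a": n_a,
        "n_b": n_b,
        "n_cells": n_cells,
    }


def shuffle_expectation(
    n_cells: int, n_a: int, n_b: int, n_shuffles: int, seed: int
) -> float:
    """Monte-Carlo expectation of the shared count under random membership."""
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_shuffles):
        a = rng.choice(n_cells, size=n_a, replace=False)
        b = rng.choice(n_cells, size=n_b, replace=False)
        total += np.intersect1d(a, b).size
    return total / n_shuffles


def variability_stats(
    mask: SignificanceMask, table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """CV and Fano factor of significant responses per cell-odor.

    CV = sd/mean and FF = var/mean of the significant response sizes, both
    with the n−1 (sample) denominator; requires at least two significant
    responses and a positive mean.  Reliability annotations are merged in
    when a table is supplied.
    """
    rows = []
    for c in range(mask.n_cells):
        for o in range(mask.n_odors):
            sel = mask.responded[c, o]
            if sel.sum() < 2:
                continue
            sizes = mask.response_size[c, o, sel]
            mean = sizes.mean()
            if mean <= 0:
                continue
            sd = sizes.std(ddof=1)
            rows.append(
                {
                    "cell": c,
                    "odor": o,
                    "n_responses": int(sel.sum()),
                    "mean": mean,
                    "cv": sd / mean,
                    "fano": sd**2 / mean,
                }
            )
    df = pd.DataFrame(rows, columns=["cell", "odor", "n_responses", "mean", "cv", "fano"])
    if table is not None and not df.empty:
        df = df.merge(table[["cell", "odor", "label", "p_response"]], on=["cell", "odor"])
    return df


def split_half_frequency(mask: SignificanceMask) -> dict:
    """Second-half response frequency of cells that responded exactly once
    in the first half of trials, with the homogeneous-null prediction
    (one response in n1 trials -> frequency 1/n1)."""
    t = mask.n_trials
    if t < 4:
        raise ValueError("split-half analysis needs at least 4 trials")
    n1 = t // 2
    first = mask.responded[:, :, :n1].sum(axis=2)
    second = mask.responded[:, :, n1:]
    sel = first == 1
    cells, odors = np.nonzero(sel)
    freq = second[cells, odors].mean(axis=1)
    df = pd.DataFrame({"cell": cells, "odor": odors, "second_half_frequency": freq})
    return {"table": df, "null_frequency": 1.0 / n1}


def threshold_sensitivity(
    tensor: ResponseTensor, thresholds, **detect_kwargs
) -> pd.DataFrame:
    """Population fractions and class sizes across significance thresholds."""
    rows = []
    for thr in thresholds:
        if thr <= 0:
            raise ValueError("thresholds must be positive")
        m = detect_significant(tensor, threshold_sd=thr, **detect_kwargs)
        tab = classify_cells(m)
        fr = population_fractions(tab, m)["summary"]
        pick = fr[fr.reduction == "odor_trial_pairs"].set_index("statistic")["mean"]
        per_odor = fr[fr.statistic.str.startswith("per_odor")].set_index("statistic")["mean"]
        rows.append(
            {
                "threshold_sd": thr,
                "n_responsive_cell_trials": int(m.responded.sum()),
                "n_reliable": int((tab.label == RELIABLE).sum()),
                "n_unreliable": int((tab.label == UNRELIABLE).sum()),
                "per_trial_reliable": pick["per_trial_reliable"],
                "per_trial_unreliable": pick["per_trial_unreliable"],
                "per_odor_reliable": per_odor["per_odor_reliable"],
                "per_odor_unreliable": per_odor["per_odor_unreliable"],
            }
        )
    return pd.DataFrame(rows)
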