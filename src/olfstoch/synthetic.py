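"""Seeded synthetic response tensors with the statistical structure of
third-order olfactory population recordings.

The generator emulates the features the downstream analyses assume:
Gaussian pre-stimulus baselines, per cell-odor response probabilities on a
Gamma-distributed reliability continuum, response amplitudes that grow with
reliability, and odor pairs with controllable representational similarity
in which shared cells are drawn preferentially from the high-reliability
tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .tensor import ResponseTensor

# Gamma (shape, scale) laws fitted to the recorded cumulative distributions
# of reliability (response probability), response size (ΔF/F) and odor-pair
# overlap, per species.
PRESET_DISTRIBUTIONS = {
    "fly": {
        "reliability": (0.64, 0.42),
        "response": (0.77, 0.28),
        "overlap": (0.19, 0.60),
    },
    "mouse": {
        "reliability": (0.64, 0.17),
        "response": (0.70, 0.24),
        "overlap": (0.18, 0.35),
    },
}


def preset_distributions(name: str) -> dict:
    """Gamma (shape, scale) parameters for a species preset."""
    try:
        return dict(PRESET_DISTRIBUTIONS[name])
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_DISTRIBUTIONS)}"
        ) from None


def sample_preset(
    name: str, which: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from a preset Gamma law.

    ``which`` is one of ``reliability``, ``response`` or ``overlap``.  Draws
    come from the fitted Gamma itself (no truncation); truncation to [0, 1]
    happens only where a draw is used as a response probability.
    """
    shape, scale = preset_distributions(name)[which]
    return rng.gamma(shape, scale, size=n)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic response generator.

    The fly preset mirrors the main fly recording (124 KCs, 7 odors x 6
    trials, 10 s baseline, responses averaged over 2.5 s post onset); the
    mouse preset mirrors the piriform recording (10 odors x 8 trials,
    0.453 s frames).
    """

    n_cells: int = 124
    n_odors: int = 7
    n_trials: int = 6
    n_baseline_frames: int = 20
    n_response_frames: int = 5
    frame_duration: float = 0.5
    reliability_gamma: tuple = (0.64, 0.42)
    response_gamma: tuple = (0.77, 0.28)
    amplitude_coupling: float = 2.0
    coupling: str = "copula"  # "copula" | "exponential" | "none"
    copula_rho: float = 0.9
    amplitude_base: float = 0.1  # the a of E[amp] = a*exp(b*p), exponential mode
    trial_cv: float = 0.4  # trial-to-trial amplitude jitter (CV)
    baseline_sd: float = 0.02
    fixed_reliability: float | None = None
    pair_similarity: list = field(default_factory=list)
    preset_name: str = "fly"

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_odors", "n_trials", "n_baseline_frames",
                     "n_response_frames"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_trials < 2:
            raise ValueError("n_trials must be at least 2")
        for name in ("reliability_gamma", "response_gamma"):
            shape, scale = getattr(self, name)
            if shape <= 0 or scale <= 0:
                raise ValueError(f"{name} shape and scale must be positive")
        if self.coupling not in ("copula", "exponential", "none"):
            raise ValueError(f"unknown coupling mode {self.coupling!r}")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be non-negative")
        if self.fixed_reliability is not None and not (
            0.0 <= self.fixed_reliability <= 1.0
        ):
            raise ValueError("fixed_reliability must lie in [0, 1]")
        for (i, j, r) in self.pair_similarity:
            if not -1.0 <= r <= 1.0:
                raise ValueError("target correlations must lie in [-1, 1]")


def fly_config(**overrides) -> GeneratorConfig:
    """Fly preset: 7 odors x 6 trials on a 0.5 s frame grid."""
    cfg = GeneratorConfig(
        n_cells=124, n_odors=7, n_trials=6,
        n_baseline_frames=20, n_response_frames=5, frame_duration=0.5,
        reliability_gamma=PRESET_DISTRIBUTIONS["fly"]["reliability"],
        response_gamma=PRESET_DISTRIBUTIONS["fly"]["response"],
        preset_name="fly",
    )
    return replace(cfg, **overrides)


def mouse_config(**overrides) -> GeneratorConfig:
    """Mouse preset: 10 odors x 8 trials on a 0.453 s frame grid."""
    cfg = GeneratorConfig(
        n_cells=285, n_odors=10, n_trials=8,
        n_baseline_frames=22, n_response_frames=10, frame_duration=0.453,
        reliability_gamma=PRESET_DISTRIBUTIONS["mouse"]["reliability"],
        response_gamma=PRESET_DISTRIBUTIONS["mouse"]["response"],
        preset_name="mouse",
    )
    return replace(cfg, **overrides)


def config_from_preset(name: str, **overrides) -> GeneratorConfig:
    if name == "fly":
        return fly_config(**overrides)
    if name == "mouse":
        return mouse_config(**overrides)
    raise ValueError(f"unknown preset {name!r}; choose 'fly' or 'mouse'")


def _truncated_gamma_uniforms(
    shape: float, scale: float, size, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample from Gamma(shape, scale) truncated to [0, 1].

    Implemented by inverse-CDF on [0, F(1)], which is distributionally
    identical to rejection sampling but also yields each draw's quantile
    within the truncated law (used for the amplitude copula).
    """
    f1 = stats.gamma.cdf(1.0, shape, scale=scale)
    u = rng.uniform(0.0, 1.0, size=size)
    p = stats.gamma.ppf(u * f1, shape, scale=scale)
    return np.clip(p, 0.0, 1.0), u


def _latent_fields(
    config: GeneratorConfig, size, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent (reliability p, amplitude A) fields of the given shape.

    Amplitudes follow the configured response Gamma exactly; the coupling
    mode controls how strongly a cell-odor's amplitude rank tracks its
    reliability rank.
    """
    rshape, rscale = config.reliability_gamma
    ashape, ascale = config.response_gamma
    if config.fixed_reliability is not None:
        p = np.full(size, config.fixed_reliability)
        u = np.full(size, 0.5)
    else:
        p, u = _truncated_gamma_uniforms(rshape, rscale, size, rng)
    if config.coupling == "exponential":
        amp = config.amplitude_base * np.exp(config.amplitude_coupling * p)
    elif config.coupling == "none":
        amp = rng.gamma(ashape, ascale, size=size)
    else:  # Gaussian copula: exact Gamma marginal, monotone E[amp | p]
        rho = config.copula_rho
        z_rel = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
        z_amp = rho * z_rel + np.sqrt(1.0 - rho**2) * rng.standard_normal(size)
        amp = stats.gamma.ppf(stats.norm.cdf(z_amp), ashape, scale=ascale)
    return p, amp


def _assemble_tensor(
    config: GeneratorConfig,
    p: np.ndarray,
    amp: np.ndarray,
    rng: np.random.Generator,
) -> ResponseTensor:
    """Turn latent (p, amplitude) fields into a noisy frame-resolved tensor."""
    n_c, n_o = p.shape
    n_t = config.n_trials
    n_frames = config.n_baseline_frames + config.n_response_frames
    responded = rng.uniform(size=(n_c, n_o, n_t)) < p[:, :, None]
    if config.trial_cv > 0:
        k = 1.0 / config.trial_cv**2
        jitter = rng.gamma(k, 1.0 / k, size=(n_c, n_o, n_t))
    else:
        jitter = np.ones((n_c, n_o, n_t))
    trial_amp = np.where(responded, amp[:, :, None] * jitter, 0.0)
    values = rng.normal(0.0, config.baseline_sd, size=(n_c, n_o, n_t, n_frames)) \
        if config.baseline_sd > 0 else np.zeros((n_c, n_o, n_t, n_frames))
    values[:, :, :, config.n_baseline_frames:] += trial_amp[:, :, :, None]
    return ResponseTensor(
        values=values,
        frame_duration=config.frame_duration,
        odor_onset_frame=config.n_baseline_frames,
        labels=[f"odor{i}" for i in range(n_o)],
    )


def generate_responses(config: GeneratorConfig, seed: int) -> ResponseTensor:
    """Generate a seeded response tensor.

    For each (cell, odor) a latent reliability probability is drawn from
    the truncated-to-[0, 1] reliability Gamma; on each trial the cell
    responds with that probability, and responding trials add a post-onset
    amplitude that increases with reliability.  All frames carry Gaussian
    baseline noise.  The same (config, seed) yields a bitwise-identical
    tensor.
    """
    rng = np.random.default_rng(seed)
    p, amp = _latent_fields(config, (config.n_cells, config.n_odors), rng)
    return _assemble_tensor(config, p, amp, rng)


def latent_reliabilities(config: GeneratorConfig, seed: int) -> np.ndarray:
    """The latent reliability field that `generate_responses` would use."""
    rng = np.random.default_rng(seed)
    p, _ = _latent_fields(config, (config.n_cells, config.n_odors), rng)
    return p


def latent_amplitudes(config: GeneratorConfig, seed: int) -> np.ndarray:
    """The latent amplitude field that `generate_responses` would use."""
    rng = np.random.default_rng(seed)
    _, amp = _latent_fields(config, (config.n_cells, config.n_odors), rng)
    return amp


def _expected_corr(p_a, amp_a, p_b, amp_b) -> float:
    ea, eb = p_a * amp_a, p_b * amp_b
    if ea.std() == 0 or eb.std() == 0:
        return 0.0
    return float(np.corrcoef(ea, eb)[0, 1])


def generate_correlated_pair(
    config: GeneratorConfig,
    target_corr: float,
    seed: int,
    corr_tol: float = 0.1,
) -> ResponseTensor:
    """Generate a two-odor tensor with controlled representational similarity.

    The Pearson correlation between the two odors' expected-response
    population vectors (reliability x amplitude) is calibrated to within
    ``corr_tol`` of ``target_corr`` by tuning the fraction of cells whose
    latent fields are shared between the odors.  For similar pairs
    (``target_corr > 0.5``) shared cells are drawn preferentially from the
    high-reliability tail, as observed in recordings.

    Raises
    ------
    ValueError
        If the target correlation cannot be reached with the configured
        number of cells (reported, not silently clipped).
    """
    if not 0.0 <= target_corr <= 1.0:
        raise ValueError("target_corr must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = config.n_cells
    p_a, amp_a = _latent_fields(config, (n,), rng)
    p_ind, amp_ind = _latent_fields(config, (n,), rng)

    # order in which cells become shared as the shared fraction grows:
    # high-reliability first for similar pairs, random otherwise
    if target_corr > 0.5:
        weight = p_a**2 + 1e-9
    else:
        weight = np.ones(n)
    order = rng.permutation(n)
    order = order[np.argsort(-weight[order], kind="stable")]

    def fields_b(f: float):
        n_shared = int(round(f * n))
        shared = order[:n_shared]
        p_b, amp_b = p_ind.copy(), amp_ind.copy()
        p_b[shared] = p_a[shared]
        amp_b[shared] = amp_a[shared]
        return p_b, amp_b

    lo, hi = 0.0, 1.0
    corr_hi = _expected_corr(p_a, amp_a, *fields_b(1.0))
    corr_lo = _expected_corr(p_a, amp_a, *fields_b(0.0))
    if target_corr > corr_hi + corr_tol or target_corr < corr_lo - corr_tol:
        raise ValueError(
            f"target correlation {target_corr} unreachable with {n} cells: "
            f"achievable range [{corr_lo:.3f}, {corr_hi:.3f}]"
        )
    best_f, best_err = 1.0, abs(corr_hi - target_corr)
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        c = _expected_corr(p_a, amp_a, *fields_b(mid))
        if abs(c - target_corr) < best_err:
            best_f, best_err = mid, abs(c - target_corr)
        if c < target_corr:
            lo = mid
        else:
            hi = mid
    p_b, amp_b = fields_b(best_f)
    p = np.stack([p_a, p_b], axis=1)
    amp = np.stack([amp_a, amp_b], axis=1)
    pair_cfg = replace(config, n_odors=2, pair_similarity=[])
    return _assemble_tensor(pair_cfg, p, amp, rng)
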