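"""Within-habitat sample-based rarefaction and extrapolation.

Non-parametric species-area machinery for incidence data: the probability
that a species with incidence frequency ``Qi`` out of ``T`` plots is missed
by a random subsample of ``t`` plots (hypergeometric, extended to real ``t``
through log-gamma), expected richness under rarefaction, the Chao2 estimate
of undetected richness, and richness extrapolation beyond the reference
sample.  Together these define a continuous estimated species-area curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data_io import IncidenceFrequencies

__all__ = [
    "miss_probability",
    "rarefied_richness",
    "chao2_undetected",
    "extrapolated_richness",
    "richness_curve",
    "RichnessCurve",
]


def miss_probability(T, Qi, t):
    """Probability that a species of incidence frequency ``Qi`` in ``T`` plots
    is absent from a random subsample of ``t`` plots (without replacement).

    For integer ``t`` this is ``C(T-Qi, t) / C(T, t)``; real ``t`` in
    ``[0, T]`` is handled by evaluating the binomial ratio with log-gamma,
    which decays continuously to zero as ``t`` approaches ``T - Qi + 1``
    (the gamma-function pole) and is zero beyond, matching the integer
    values ``C(T-Qi, t) = 0`` for ``t > T - Qi``.  Broadcasts over ``Qi``
    and ``t``.
    """
    T = int(T)
    Qi = np.asarray(Qi)
    t = np.asarray(t, dtype=float)
    if np.any(Qi < 0) or np.any(Qi > T):
        raise ValueError(f"Qi must lie in 0..T={T}")
    if np.any(t < 0) or np.any(t > T):
        raise ValueError(f"t must lie in [0, T={T}]")
    Qi = Qi.astype(float)
    free = T - Qi  # plots the species does not occupy
    # the log-gamma form is valid while free - t + 1 > 0; at and beyond the
    # pole the probability is identically zero
    valid = t < free + 1
    log_p = (
        gammaln(free + 1)
        - gammaln(np.where(valid, free - t + 1, 1.0))
        - gammaln(T + 1)
        + gammaln(T - t + 1)
    )
    p = np.where(valid, np.exp(log_p), 0.0)
    # exact at the edges; elsewhere tiny round-off clamped into [0, 1] (tol 1e-12)
    p = np.where((t == 0) | (Qi == 0), 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    if p.ndim == 0:
        return float(p)
    return p


def rarefied_richness(freqs: IncidenceFrequencies, t) -> float:
    """Expected species richness of ``t`` plots subsampled from the reference
    sample (``0 <= t <= T``): sum over species of detection probabilities."""
    t = float(t)
    if t > freqs.T:
        raise ValueError(f"t={t} exceeds T={freqs.T}; use extrapolated_richness")
    q = freqs.frequencies()
    if q.size == 0:
        return 0.0
    return float(np.sum(1.0 - miss_probability(freqs.T, q, t)))


def chao2_undetected(freqs: IncidenceFrequencies) -> float:
    """Chao2 estimate of the number of species present but undetected.

    Uses uniques (Q1) and duplicates (Q2); when Q2 = 0 the bias-corrected
    variant ``(T-1)/T * Q1*(Q1-1)/2`` avoids division by zero.
    """
    T, Q1, Q2 = freqs.T, freqs.Q1, freqs.Q2
    if Q1 == 0:
        return 0.0
    factor = (T - 1) / T
    if Q2 > 0:
        return factor * Q1 * Q1 / (2.0 * Q2)
    return factor * Q1 * (Q1 - 1) / 2.0


def extrapolated_richness(freqs: IncidenceFrequencies, t_star) -> float:
    """Estimated richness of ``T + t_star`` plots (``t_star >= 0`` beyond the
    reference sample), approaching ``S_obs + Q0_hat`` as ``t_star`` grows."""
    t_star = float(t_star)
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    S_obs = freqs.S_obs
    Q0 = chao2_undetected(freqs)
    if Q0 == 0.0:
        return float(S_obs)
    Q1, T = freqs.Q1, freqs.T
    rate = Q1 / (Q1 + T * Q0)
    return float(S_obs + Q0 * (1.0 - (1.0 - rate) ** t_star))


@dataclass(frozen=True)
class RichnessCurve:
    """Estimated species-area curve on a grid of plot counts."""

    t_grid: np.ndarray
    values: np.ndarray
    T_ref: int
    regime: tuple[str, ...]  # per point: interpolated / observed / extrapolated

    def __post_init__(self) -> None:
        if len(self.t_grid) != len(self.values) or len(self.t_grid) != len(self.regime):
            raise ValueError("t_grid, values and regime must have equal length")


def richness_curve(freqs: IncidenceFrequencies, t_max: float, n_points: int) -> RichnessCurve:
    """Evaluate the rarefaction/extrapolation curve on a uniform grid over
    ``[0, t_max]``; the two branches join continuously at ``t = T``."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    T = freqs.T
    t_grid = np.linspace(0.0, float(t_max), n_points)
    values = np.empty_like(t_grid)
    regime = []
    for i, t in enumerate(t_grid):
        if t <= T:
            values[i] = rarefied_richness(freqs, t)
            regime.append("observed" if t == T else "interpolated")
        else:
            values[i] = extrapolated_richness(freqs, t - T)
            regime.append("extrapolated")
    return RichnessCurve(t_grid=t_grid, values=values, T_ref=T, regime=tuple(regime))
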