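"""Discrete distributions of ChIP-seq binding-event counts.

The specific component of TF-DNA binding is modelled by the Kolmogorov-Waring
(K-W) distribution — the stationary law of a linear birth-death process with
spontaneous and preferential binding/dissociation.  Its parameters are

* ``theta`` — ratio of preferential binding to preferential dissociation
  intensity, 0 < theta <= 1,
* ``a`` — spontaneous-over-preferential binding ratio, a > 0,
* ``b`` — spontaneous-over-preferential dissociation ratio, b > 0.

The zero class ``p0 = 1 / 2F1(a, 1; b+1; theta)`` is the fraction of binding
sites that produce no observed fragment — the quantity that turns an observed
site count into a genome-wide total.  The empirical stand-in for the K-W tail
is the (truncated) Generalized Discrete Pareto, ``f(m) ∝ (m + beta)^(-k)``,
and the non-specific background is an exponential decay in peak height.

All probability vectors are materialized to a caller-supplied upper bound;
residual tail mass is reported on the result, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KWParams",
    "GDPParams",
    "TruncationWindow",
    "ExpNoiseParams",
    "PmfVector",
    "kw_p0",
    "kw_pmf",
    "kw_pmf_zero_truncated",
    "kw_pmf_double_truncated",
    "gdp_pmf",
    "kw_pareto_asymptotic_exponent",
    "exp_noise_counts",
]

# theta this close to 1 is treated as the boundary: the Gauss series converges
# arbitrarily slowly there while the closed form is exact.
_THETA_ONE_EPS = 1e-8
_SERIES_RTOL = 1e-14
_SERIES_MAX_TERMS = 10**6


@dataclass(frozen=True)
class KWParams:
    """Kolmogorov-Waring parameters (theta, a, b)."""

    theta: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= 1.0):
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        if self.a <= 0.0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if self.b <= 0.0:
            raise ValueError(f"b must be > 0, got {self.b}")

    @property
    def at_theta_boundary(self) -> bool:
        return 1.0 - self.theta < _THETA_ONE_EPS


@dataclass(frozen=True)
class GDPParams:
    """Generalized Discrete Pareto parameters: skewness k, offset beta."""

    k: float
    beta: float

    def __post_init__(self) -> None:
        if self.k <= 0.0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.beta <= -1.0:
            raise ValueError(f"beta must be > -1, got {self.beta}")


@dataclass(frozen=True)
class TruncationWindow:
    """Integer support window [t_low, J] for truncated distributions."""

    t_low: int
    J: int

    def __post_init__(self) -> None:
        if self.t_low < 0:
            raise ValueError(f"t_low must be >= 0, got {self.t_low}")
        if self.J < self.t_low:
            raise ValueError(f"J ({self.J}) must be >= t_low ({self.t_low})")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.t_low, self.J + 1)


@dataclass(frozen=True)
class ExpNoiseParams:
    """Exponential background: expected counts amplitude * exp(-d*(m-1))."""

    d: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.d <= 0.0:
            raise ValueError(f"d must be > 0, got {self.d}")
        if self.amplitude < 0.0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class PmfVector:
    """A probability mass function on a contiguous integer support.

    ``tail_mass`` is the analytic mass beyond the materialized support (zero
    for finitely supported / renormalized families).
    """

    support: np.ndarray
    probs: np.ndarray
    tail_mass: float = 0.0

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        if support.shape != probs.shape:
            raise ValueError("support and probs must have matching shapes")
        if np.any(probs < -1e-15):
            raise ValueError("negative probability mass")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", np.maximum(probs, 0.0))

    def prob(self, m: int) -> float:
        idx = np.searchsorted(self.support, m)
        if idx >= len(self.support) or self.support[idx] != m:
            return 0.0
        return float(self.probs[idx])

    @property
    def total_mass(self) -> float:
        return float(self.probs.sum()) + self.tail_mass


def _gauss_2f1_a1(a: float, c: float, theta: float) -> float:
    """2F1(a, 1; c; theta) by direct series with term-ratio recursion.

    Terms obey t_{m+1} = t_m * theta * (a+m)/(c+m) and are accumulated in
    vectorized blocks; summation stops when the running term drops below
    _SERIES_RTOL of the partial sum.  If the term cap is reached with the
    terms already in geometric decay, the remaining tail is bounded by the
    geometric sum term * r/(1 - r) and folded in; otherwise the series is
    declared non-convergent.
    """
    block = 8192
    total = 1.0
    term = 1.0
    m0 = 0
    while m0 < _SERIES_MAX_TERMS:
        m = np.arange(m0, m0 + block, dtype=float)
        ratios = theta * (a + m) / (c + m)
        terms = term * np.cumprod(ratios)
        total += terms.sum()
        term = float(terms[-1])
        m0 += block
        if term < _SERIES_RTOL * total:
            return total
    # geometric tail bound: beyond m0 the term ratio is <= r
    r = theta * max(1.0, (a + m0) / (c + m0))
    if r < 1.0:
        tail = term * r / (1.0 - r)
        # the geometric bound overestimates the true tail, so folding it in
        # leaves a relative error below tail/total
        if tail < 1e-6 * total:
            return total + tail
    raise RuntimeError(
        f"2F1 series did not converge in {_SERIES_MAX_TERMS} terms "
        f"(a={a}, c={c}, theta={theta})"
    )


def kw_p0(params: KWParams) -> float:
    """Fraction of undetected events: p0 = 1 / 2F1(a, 1; b+1; theta).

    At the theta -> 1 boundary the Gauss summation theorem gives the closed
    form p0 = (b - a)/b, valid only for b > a (otherwise the series diverges
    and no proper stationary distribution exists).
    """
    a, b, theta = params.a, params.b, params.theta
    if params.at_theta_boundary:
        if b <= a:
            raise ValueError(
                f"divergent K-W series: theta ~ 1 requires b > a (a={a}, b={b})"
            )
        return (b - a) / b
    return 1.0 / _gauss_2f1_a1(a, b + 1.0, theta)


def kw_pmf(params: KWParams, m_max: int) -> PmfVector:
    """K-W pmf on m = 0..m_max via the recursion p_{m+1} = p_m*theta*(a+m)/(b+1+m)."""
    if m_max < 1:
        raise ValueError(f"m_max must be >= 1, got {m_max}")
    p0 = kw_p0(params)
    probs = np.empty(m_max + 1)
    probs[0] = p0
    a, b, theta = params.a, params.b, params.theta
    for m in range(m_max):
        probs[m + 1] = probs[m] * theta * (a + m) / (b + 1.0 + m)
    tail = max(0.0, 1.0 - float(probs.sum()))
    return PmfVector(np.arange(m_max + 1), probs, tail_mass=tail)


def kw_pmf_zero_truncated(params: KWParams, m_max: int) -> PmfVector:
    """Zero-truncated K-W: p_m / (1 - p0) on m >= 1."""
    p0 = kw_p0(params)
    if p0 >= 1.0 - 1e-15:
        raise ValueError("degenerate distribution: all mass at m = 0")
    full = kw_pmf(params, m_max)
    probs = full.probs[1:] / (1.0 - p0)
    tail = max(0.0, 1.0 - float(probs.sum()))
    return PmfVector(full.support[1:], probs, tail_mass=tail)


def kw_pmf_double_truncated(params: KWParams, window: TruncationWindow) -> PmfVector:
    """K-W pmf renormalized to the window [t_low, J] (t_low >= 1).

    Adjacent-probability ratios are those of the untruncated recursion; only
    the normalization changes.
    """
    if window.t_low < 1:
        raise ValueError("double truncation requires t_low >= 1")
    full = kw_pmf(params, window.J)
    lo = window.t_low
    segment = full.probs[lo : window.J + 1]
    mass = segment.sum()
    if mass <= 0.0:
        raise ValueError(f"zero K-W mass on window [{lo}, {window.J}]")
    return PmfVector(window.support, segment / mass)


def gdp_pmf(params: GDPParams, window: TruncationWindow) -> PmfVector:
    """(Double-)truncated Generalized Discrete Pareto on [t_low, J].

    f(m) = (m + beta)^(-k) / zeta(k, beta; t_low, J) with the truncated
    generalized zeta normalization zeta = sum_{i=t_low..J} (i + beta)^(-k).
    """
    if window.t_low < 1:
        raise ValueError("GDP support starts at m >= 1")
    support = window.support
    weights = np.power(support + params.beta, -float(params.k), dtype=float)
    zeta = weights.sum()
    if not np.isfinite(zeta) or zeta <= 0.0:
        raise ValueError("degenerate GDP normalization on the given window")
    return PmfVector(support, weights / zeta)


def kw_pareto_asymptotic_exponent(params: KWParams) -> float:
    """Tail exponent of the theta = 1 (Waring) case: p_m ~ C * m^-(b-a+1).

    For theta < 1 the tail is geometrically damped and carries no pure power
    law, which is an error here.
    """
    if not params.at_theta_boundary:
        raise ValueError("power-law tail exists only at theta = 1")
    if params.b <= params.a:
        raise ValueError("theta = 1 requires b > a")
    return params.b - params.a + 1.0


def exp_noise_counts(
    params: ExpNoiseParams,
    window: TruncationWindow,
    normalized: bool = False,
) -> np.ndarray:
    """Expected noise-locus counts amplitude*exp(-d*(m-1)) on the window.

    With ``normalized=True`` returns a proper pmf over the window instead of
    count units.
    """
    if window.t_low < 1:
        raise ValueError("noise counts are defined for m >= 1")
    support = window.support
    counts = params.amplitude * np.exp(-params.d * (support - 1))
    if normalized:
        total = counts.sum()
        if total <= 0.0:
            raise ValueError("cannot normalize all-zero noise counts")
        return counts / total
    return counts


def log_rising_factorial(z: float, m: np.ndarray | int) -> np.ndarray | float:
    """log of the rising factorial z^[m] = z(z+1)...(z+m-1), in log-space.

    Used by oracles and the simulator; avoids overflow for m beyond ~170.
    """
    from scipy.special import gammaln

    return gammaln(z + np.asarray(m, dtype=float)) - gammaln(z)
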