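"""Birth-death simulation of TF-DNA binding and synthetic library generation.

Per locus, TF occupancy m evolves as a continuous-time Markov chain with
linear intensities: binding at rate ``lam0 + lam1*m`` (spontaneous plus
preferential attachment) and dissociation at rate ``mu0 + mu1*m``.  Its
stationary law is the Kolmogorov-Waring distribution with

    theta = lam1/mu1,   a = lam0/lam1,   b = mu0/mu1.

The module provides the exact stationary mapping, a vectorized Gillespie
sampler, a forward (master-equation) integrator, and a synthetic ChIP-seq
library generator (specific K-W loci + exponential noise loci + binomial
depth thinning) used throughout the test surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .distributions import (
    ExpNoiseParams,
    KWParams,
    PmfVector,
    kw_pmf_zero_truncated,
)
from .histogram import BindingHistogram

__all__ = [
    "BDRates",
    "ForwardSolution",
    "SimulatedLibrary",
    "rates_to_kw",
    "gillespie_steady_state",
    "solve_forward",
    "sample_zero_truncated_kw",
    "sample_noise_heights",
    "synth_library",
]


@dataclass(frozen=True)
class BDRates:
    """Linear birth-death intensities (events per unit time).

    Binding: lam0 (spontaneous) + lam1*m (preferential);
    dissociation: mu0 (spontaneous) + mu1*m (preferential).
    """

    lam0: float
    lam1: float
    mu0: float
    mu1: float

    def __post_init__(self) -> None:
        for name in ("lam0", "lam1", "mu0", "mu1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def birth(self, m) -> np.ndarray:
        return self.lam0 + self.lam1 * np.asarray(m, dtype=float)

    def death(self, m) -> np.ndarray:
        """Dissociation intensity; identically zero at m = 0 (nothing bound)."""
        m = np.asarray(m, dtype=float)
        return np.where(m > 0, self.mu0 + self.mu1 * m, 0.0)


@dataclass
class ForwardSolution:
    """Solution of the forward equations: p_m(t) on a time grid."""

    times: np.ndarray
    pmf: np.ndarray                 # shape (n_times, m_max+1)
    conservation_defect: np.ndarray

    @property
    def terminal(self) -> np.ndarray:
        return self.pmf[-1]


@dataclass
class SimulatedLibrary:
    """A synthetic ChIP-seq-like library with full ground truth."""

    histogram: BindingHistogram
    true_m: np.ndarray              # specific loci true occupancy
    observed_m: np.ndarray          # after depth thinning (0 = unobserved)
    noise_m: np.ndarray             # noise locus heights
    kw: KWParams
    noise: ExpNoiseParams
    n_noise_loci: int
    depth_fraction: float
    seed: int

    @property
    def n_undetected(self) -> int:
        """Specific loci lost to depth thinning (true N0 of the simulation)."""
        return int(np.sum(self.observed_m == 0))


def rates_to_kw(rates: BDRates) -> KWParams:
    """Stationary K-W parameters of the linear birth-death process.

    Detailed balance gives p_{m+1}/p_m = (lam0+lam1*m)/(mu0+mu1*(m+1))
    = theta*(a+m)/(b+1+m) with theta = lam1/mu1, a = lam0/lam1, b = mu0/mu1.
    Requires lam1 <= mu1 (otherwise mass escapes to infinity).
    """
    if rates.lam1 <= 0 or rates.mu1 <= 0:
        raise ValueError("preferential rates lam1, mu1 must be positive")
    if rates.lam1 > rates.mu1:
        raise ValueError(
            "no stationary distribution: preferential binding exceeds "
            f"preferential dissociation (lam1={rates.lam1} > mu1={rates.mu1})")
    return KWParams(
        theta=rates.lam1 / rates.mu1,
        a=rates.lam0 / rates.lam1,
        b=rates.mu0 / rates.mu1,
    )


def stationary_series_converges(rates: BDRates) -> bool:
    """Existence check for the stationary law via the intensity-ratio tail.

    The ratio eta_m = birth(m)/death(m+1) must eventually stay below some
    nu < 1; for linear rates that holds iff lam1 < mu1, or lam1 = mu1 with
    mu0 > lam0 (equivalently theta < 1, or theta = 1 with b > a).
    """
    if rates.lam1 <= 0 or rates.mu1 <= 0:
        return False
    if rates.lam1 < rates.mu1:
        return True
    if rates.lam1 == rates.mu1:
        return rates.mu0 > rates.lam0
    return False


def relaxation_time(rates: BDRates) -> float:
    """Crude relaxation-time scale used to pick burn-in defaults."""
    gap = rates.mu1 - rates.lam1 + rates.mu0 / max(1.0, rates.mu0 + rates.mu1)
    return 1.0 / max(gap, 1e-3)


def gillespie_steady_state(
    rates: BDRates,
    n_loci: int,
    burn_in_time: float | None = None,
    seed: int = 0,
    max_events: int = 10**4,
) -> np.ndarray:
    """Occupancy sample of n_loci independent loci after burn-in.

    All loci start at m = 0 and are advanced with a vectorized Gillespie
    loop (per-iteration exponential waiting times across the whole cohort).
    The empirical distribution converges to ``kw_pmf(rates_to_kw(rates))``.
    """
    if not stationary_series_converges(rates):
        if rates.lam0 == 0 and rates.lam1 == 0:
            return np.zeros(n_loci, dtype=int)   # absorbing at m = 0
        raise ValueError("no stationary distribution for these rates")
    if burn_in_time is None:
        burn_in_time = 20.0 * relaxation_time(rates)
    rng = np.random.default_rng(seed)
    m = np.zeros(n_loci, dtype=np.int64)
    t = np.zeros(n_loci)
    active = np.ones(n_loci, dtype=bool)
    for _ in range(max_events):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        birth = rates.birth(m[idx])
        death = rates.death(m[idx])
        total = birth + death
        stuck = total <= 0
        if np.any(stuck):
            active[idx[stuck]] = False
            idx = idx[~stuck]
            if idx.size == 0:
                break
            birth, death, total = birth[~stuck], death[~stuck], total[~stuck]
        t_next = t[idx] + rng.exponential(1.0 / total)
        # the snapshot at burn_in_time is the state *before* the first jump
        # that crosses it — do not apply that jump
        crossed = t_next >= burn_in_time
        active[idx[crossed]] = False
        jump = ~crossed
        up = rng.random(idx.size) < birth / total
        m[idx[jump]] += np.where(up[jump], 1, -1)
        t[idx] = t_next
    return m


def solve_forward(
    rates: BDRates,
    m_max: int,
    t_end: float,
    init: PmfVector | np.ndarray | None = None,
    n_eval: int = 25,
    boundary_flux_tol: float = 1e-8,
) -> ForwardSolution:
    """Integrate the forward Kolmogorov equations on states m = 0..m_max.

    dp_m/dt = birth(m-1) p_{m-1} + death(m+1) p_{m+1}
              - (birth(m) + death(m)) p_m,
    with a reflecting upper boundary.  Errors out if the terminal mass at the
    boundary exceeds ``boundary_flux_tol`` (choose a larger m_max).
    """
    if init is None:
        p_init = np.zeros(m_max + 1)
        p_init[0] = 1.0
    elif isinstance(init, PmfVector):
        p_init = np.zeros(m_max + 1)
        p_init[init.support] = init.probs
    else:
        p_init = np.asarray(init, dtype=float)
        if len(p_init) != m_max + 1:
            raise ValueError("init length must be m_max + 1")
    if abs(p_init.sum() - 1.0) > 1e-9:
        raise ValueError("initial pmf must be normalized")

    states = np.arange(m_max + 1)
    birth = rates.birth(states)
    death = rates.death(states)
    birth_eff = birth.copy()
    birth_eff[-1] = 0.0           # reflecting top boundary

    def rhs(_t, p):
        flux_up = birth_eff * p                     # m -> m+1
        flux_down = death * p                       # m -> m-1
        dp = -(flux_up + flux_down)
        dp[1:] += flux_up[:-1]
        dp[:-1] += flux_down[1:]
        return dp

    times = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(rhs, (0.0, t_end), p_init, t_eval=times,
                    method="BDF", rtol=1e-10, atol=1e-13)
    if not sol.success:
        raise RuntimeError(f"forward integration failed: {sol.message}")
    pmf = sol.y.T
    defect = np.abs(pmf.sum(axis=1) - 1.0)
    if pmf[-1, -1] > boundary_flux_tol:
        raise ValueError(
            f"probability mass {pmf[-1, -1]:.3g} reached the m_max boundary; "
            "increase m_max")
    return ForwardSolution(times=sol.t, pmf=pmf, conservation_defect=defect)


def sample_zero_truncated_kw(
    kw: KWParams, size: int, rng: np.random.Generator, m_max: int = 200_000
) -> np.ndarray:
    """Inverse-cdf sampling from the zero-truncated K-W distribution."""
    pmf = kw_pmf_zero_truncated(kw, m_max)
    cdf = np.cumsum(pmf.probs)
    cdf /= cdf[-1]                 # residual tail mass folded into the top bin
    u = rng.random(size)
    return pmf.support[np.searchsorted(cdf, u)]


def sample_noise_heights(
    noise: ExpNoiseParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Heights of noise loci: discretized exponential on m >= 1.

    P(m) proportional to exp(-d*(m-1)) is a geometric law with success
    probability 1 - exp(-d).
    """
    return rng.geometric(1.0 - np.exp(-noise.d), size=size)


def synth_library(
    kw: KWParams | BDRates,
    n_specific_loci: int,
    noise: ExpNoiseParams,
    n_noise_loci: int,
    depth_fraction: float = 1.0,
    seed: int = 0,
) -> SimulatedLibrary:
    """Generate a synthetic ChIP-seq-like peak-height histogram.

    Specific loci draw their true occupancy from the zero-truncated K-W law;
    each fragment survives sequencing with probability ``depth_fraction``
    (binomial thinning), so loci thinned to zero become unobserved and count
    toward the simulation's true N0.  Noise loci draw heights from the
    discretized exponential.  The histogram pools both components.
    """
    if isinstance(kw, BDRates):
        kw = rates_to_kw(kw)
    if not (0.0 < depth_fraction <= 1.0):
        raise ValueError("depth_fraction must be in (0, 1]")
    if n_specific_loci < 1 or n_noise_loci < 0:
        raise ValueError("locus counts must be positive")
    rng = np.random.default_rng(seed)
    true_m = sample_zero_truncated_kw(kw, n_specific_loci, rng)
    if depth_fraction < 1.0:
        observed = rng.binomial(true_m, depth_fraction)
    else:
        observed = true_m.copy()
    noise_m = (sample_noise_heights(noise, n_noise_loci, rng)
               if n_noise_loci else np.empty(0, dtype=int))
    heights = np.concatenate([observed[observed > 0], noise_m])
    hist = BindingHistogram.from_heights(heights)
    return SimulatedLibrary(
        histogram=hist, true_m=true_m, observed_m=observed, noise_m=noise_m,
        kw=kw, noise=noise, n_noise_loci=n_noise_loci,
        depth_fraction=depth_fraction, seed=seed,
    )


def noise_loci_for_alpha(
    kw: KWParams,
    n_specific_loci: int,
    noise: ExpNoiseParams,
    alpha: float,
    m_max: int = 200_000,
) -> int:
    """Noise locus count giving an expected specific fragment share alpha.

    The expected specific fragment mass is n_specific * E[m | zero-truncated
    K-W]; the expected noise fragment mass per locus is the geometric mean
    height 1/(1 - exp(-d)).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    pmf = kw_pmf_zero_truncated(kw, m_max)
    mean_specific = float((pmf.support * pmf.probs).sum())
    mean_noise = 1.0 / (1.0 - np.exp(-noise.d))
    m_specific = n_specific_loci * mean_specific
    return int(round(m_specific * (1.0 / alpha - 1.0) / mean_noise))
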