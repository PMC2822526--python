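"""Fitting and back-extrapolation of the binding-event mixture model.

An observed peak-height histogram n(m) is modelled as the superposition of

* an exponential background, ``A * exp(-d*(m-1))``, dominating small m, and
* a specific component following a heavy-tailed law — fitted empirically by
  the truncated Generalized Discrete Pareto and interpreted mechanistically
  by the Kolmogorov-Waring distribution.

The pipeline: fit the noise on the left of the histogram, subtract it, fit
the TGDP to the reliable tail, extrapolate the fitted tail back below the
specificity threshold, choose the smallest threshold t from which the
specific component accounts for the target specificity Sp(t), fit the K-W
law to the noise-subtracted reliable tail (double-truncated likelihood) and
back-extrapolate it over the noise-rich head; a refinement pass then removes
the predicted specific counts from the bins the noise is fitted to and
repeats.  The K-W zero class p0 converts the number of specific loci
seen in the library into a genome-wide total:

    N_tot = Ns / (1 - p0),     Se = (1 - p0) * 100 %.

The estimator :class:`BindingMixtureModel` wraps the same pipeline in
scikit-learn conventions (``fit`` on per-locus peak heights, fitted
attributes with trailing underscores).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .distributions import (
    ExpNoiseParams,
    GDPParams,
    KWParams,
    TruncationWindow,
    gdp_pmf,
    kw_p0,
    kw_pmf_zero_truncated,
)
from .histogram import BindingHistogram

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureConfig",
    "NoiseFit",
    "TGDPFit",
    "KWFit",
    "MixtureResult",
    "PipelineError",
    "fit_noise",
    "fit_tgdp_tail",
    "back_extrapolate",
    "estimate_threshold",
    "subtract_noise",
    "estimate_alpha",
    "fit_kw",
    "totals",
    "analyze_library",
    "BindingMixtureModel",
]

_THETA_CAP = 1.0 - 1e-9


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class MixtureConfig:
    """Free choices of the fitting pipeline.

    Parameters
    ----------
    sp_target : required binding specificity Sp(t) at the threshold.
    noise_fit_range : inclusive m-interval for the exponential noise fit.
    tail_fit_start : initial left edge of the TGDP tail fit; default is the
        first bin after the noise range.  The fit is re-run at the estimated
        threshold until the threshold is stable.
    objective : tail-fit objective — "mle" (truncated multinomial maximum
        likelihood, the default: unbiased on sparse tails where log-space
        least squares must drop zero bins), "wls_log" (weighted least squares
        on log10 counts, weights = counts, matching the log-log presentation
        of such histograms) or "chisq" (Pearson chi-square on counts).
    kw_objective : same choices for the K-W stage.
    n_refine : extra passes re-fitting the noise after removing the
        predicted specific component from the left bins.
    """

    sp_target: float = 0.95
    noise_fit_range: tuple[int, int] = (1, 8)
    tail_fit_start: int | None = None
    objective: str = "mle"
    kw_objective: str = "mle"
    n_refine: int = 2
    max_iter: int = 2000
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.sp_target < 1.0):
            raise ValueError("sp_target must be in (0, 1)")
        lo, hi = self.noise_fit_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad noise_fit_range {self.noise_fit_range}")
        if self.objective not in ("mle", "wls_log", "chisq"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.kw_objective not in ("mle", "wls_log", "chisq"):
            raise ValueError(f"unknown kw_objective {self.kw_objective!r}")


@dataclass
class NoiseFit:
    params: ExpNoiseParams
    se_d: float
    se_amplitude: float
    n_points: int

    def expected(self, m: np.ndarray) -> np.ndarray:
        m = np.asarray(m)
        return self.params.amplitude * np.exp(-self.params.d * (m - 1))


@dataclass
class TGDPFit:
    params: GDPParams
    window: TruncationWindow
    norm: float                      # fitted tail total (count units)
    se_k: float
    se_beta: float
    objective_value: float
    gof_chi2: float
    gof_pvalue: float
    n_points: int


@dataclass
class KWFit:
    params: KWParams
    p0: float
    objective_value: float
    at_boundary: bool                # theta pinned at 1


@dataclass
class MixtureResult:
    """Complete output of the fitting-and-back-extrapolation pipeline."""

    t: int
    sp_at_t: float
    sp_curve: dict[int, float]
    alpha: float
    s_weight: float
    noise: NoiseFit
    gdp: TGDPFit
    kw: KWFit
    p0: float
    Ns: float
    Ns1: float
    Ns2: float
    N1: int
    N2: int
    M1: int
    M2: int
    N0: int
    Ntot: int
    Se: float
    Mhat_s: float
    N: int
    M: int
    J: int
    clipped_bins: int
    warnings: list[str] = field(default_factory=list)
    specific_pred: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "t": self.t,
            "sp_at_t": self.sp_at_t,
            "alpha": self.alpha,
            "s_weight": self.s_weight,
            "p0": self.p0,
            "Se": self.Se,
            "Ns": self.Ns,
            "Ns1": self.Ns1,
            "Ns2": self.Ns2,
            "N0": self.N0,
            "Ntot": self.Ntot,
            "N1": self.N1,
            "N2": self.N2,
            "M1": self.M1,
            "M2": self.M2,
            "Mhat_s": self.Mhat_s,
            "N": self.N,
            "M": self.M,
            "J": self.J,
            "noise": {"d": self.noise.params.d,
                      "amplitude": self.noise.params.amplitude,
                      "se_d": self.noise.se_d,
                      "se_amplitude": self.noise.se_amplitude},
            "gdp": {"k": self.gdp.params.k, "beta": self.gdp.params.beta,
                    "t_low": self.gdp.window.t_low, "J": self.gdp.window.J,
                    "se_k": self.gdp.se_k, "se_beta": self.gdp.se_beta,
                    "gof_pvalue": self.gdp.gof_pvalue},
            "kw": {"theta": self.kw.params.theta, "a": self.kw.params.a,
                   "b": self.kw.params.b, "at_boundary": self.kw.at_boundary},
            "clipped_bins": self.clipped_bins,
            "warnings": list(self.warnings),
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def fit_noise(
    hist: BindingHistogram | np.ndarray, cfg: MixtureConfig
) -> NoiseFit:
    """Exponential fit A*exp(-d*(m-1)) to the noise-dominated left bins.

    Weighted least squares on log counts with weights equal to the counts;
    in log space the model is linear, so the fit is closed-form.  Accepts a
    histogram or a dense count vector over m = 1..J (the refinement pass
    fits counts with the predicted specific component already removed).
    """
    lo, hi = cfg.noise_fit_range
    if isinstance(hist, BindingHistogram):
        m_all, n_all = hist.as_arrays()
    else:
        n_all = np.asarray(hist, dtype=float)
        m_all = np.arange(1, len(n_all) + 1)
    mask = (m_all >= lo) & (m_all <= min(hi, len(m_all))) & (n_all > 0)
    if mask.sum() < 3:
        raise PipelineError("fit_noise",
                            f"need >= 3 positive bins in m = [{lo}, {hi}]")
    m, n = m_all[mask], n_all[mask]
    x = m - 1.0
    y = np.log(n)
    w = n
    # WLS closed form for y = c0 - d*x
    W = w.sum()
    xbar = (w * x).sum() / W
    ybar = (w * y).sum() / W
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    d = -slope
    c0 = ybar - slope * xbar
    amplitude = float(np.exp(c0))
    if d <= 0:
        raise PipelineError("fit_noise",
                            f"noise counts do not decay (d = {d:.4g})")
    resid = y - (c0 + slope * x)
    dof = max(1, len(m) - 2)
    s2 = (w * resid ** 2).sum() / dof
    se_slope = float(np.sqrt(s2 / sxx))
    se_c0 = float(np.sqrt(s2 * (1.0 / W + xbar ** 2 / sxx)))
    return NoiseFit(
        params=ExpNoiseParams(d=float(d), amplitude=amplitude),
        se_d=se_slope,
        se_amplitude=amplitude * se_c0,
        n_points=int(mask.sum()),
    )


def _tail_objective(counts: np.ndarray, model: np.ndarray, kind: str) -> float:
    pos = counts > 0
    if kind == "wls_log":
        r = np.log10(counts[pos]) - np.log10(np.maximum(model[pos], 1e-300))
        return float((counts[pos] * r ** 2).sum())
    # Pearson chi-square
    e = np.maximum(model, 1e-12)
    return float(((counts - e) ** 2 / e).sum())


def fit_tgdp_tail(
    hist_counts: np.ndarray | BindingHistogram,
    window: TruncationWindow,
    cfg: MixtureConfig,
) -> TGDPFit:
    """Fit N2 * f(m; k, beta; t, J) to the tail counts on [t, J].

    ``hist_counts`` is either a histogram or a dense count vector over
    m = 1..J (noise-subtracted counts are the usual input).  The tail total
    N2 anchors the normalization; only the shape (k, beta) is optimized.
    """
    if isinstance(hist_counts, BindingHistogram):
        _, dense = hist_counts.as_arrays()
    else:
        dense = np.asarray(hist_counts, dtype=float)
    J = len(dense)
    if window.J > J:
        raise PipelineError("fit_tgdp_tail",
                            f"window J={window.J} beyond histogram J={J}")
    t = window.t_low
    counts = dense[t - 1: window.J]
    support = window.support
    pos = counts > 0
    if pos.sum() < 4:
        raise PipelineError(
            "fit_tgdp_tail",
            f"degenerate tail: only {int(pos.sum())} positive bins in "
            f"[{t}, {window.J}]")
    if np.ptp(counts[pos]) == 0 and pos.sum() < 5:
        raise PipelineError("fit_tgdp_tail", "degenerate tail: flat counts")
    norm = float(counts.sum())

    use_mle = cfg.objective == "mle"

    def model_counts(k: float, beta: float) -> np.ndarray:
        w = np.power(support + beta, -k)
        return norm * w / w.sum()

    def nll(k: float, beta: float) -> float:
        logw = -k * np.log(support + beta)
        hi = logw.max()
        lse = hi + np.log(np.exp(logw - hi).sum())
        return -float((counts * (logw - lse)).sum())

    def obj(x: np.ndarray) -> float:
        k = np.exp(x[0])
        beta = np.expm1(x[1])          # beta > -1
        if use_mle:
            return nll(k, beta)
        return _tail_objective(counts, model_counts(k, beta), cfg.objective)

    rng = np.random.default_rng(cfg.seed)
    best = None
    starts = [(2.0, 5.0)] + [
        (float(np.exp(rng.uniform(np.log(0.5), np.log(8.0)))),
         float(np.expm1(rng.uniform(0.0, np.log1p(40.0)))))
        for _ in range(cfg.n_restarts - 1)
    ]
    for k0, b0 in starts:
        res = optimize.minimize(
            obj, x0=[np.log(k0), np.log1p(b0)], method="Nelder-Mead",
            options={"maxiter": cfg.max_iter, "xatol": 1e-8, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    k_hat = float(np.exp(best.x[0]))
    beta_hat = float(np.expm1(best.x[1]))
    if use_mle:
        se_k, se_beta = _observed_information_se(nll, k_hat, beta_hat)
    else:
        se_k, se_beta = _tgdp_standard_errors(counts, support, norm,
                                              k_hat, beta_hat)

    expected = model_counts(k_hat, beta_hat)
    chi2, pval = _gof_chi2(counts, expected, n_fitted=2)
    return TGDPFit(
        params=GDPParams(k=k_hat, beta=beta_hat),
        window=window,
        norm=norm,
        se_k=se_k,
        se_beta=se_beta,
        objective_value=float(best.fun),
        gof_chi2=chi2,
        gof_pvalue=pval,
        n_points=int(pos.sum()),
    )


def _observed_information_se(nll, k, beta):
    """Standard errors from the inverse numerical Hessian of the likelihood."""
    p = np.array([k, beta])
    eps = np.maximum(np.abs(p), 1.0) * 1e-4
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            d1 = np.zeros(2); d1[i] = eps[i]
            d2 = np.zeros(2); d2[j] = eps[j]
            H[i, j] = (nll(*(p + d1 + d2)) - nll(*(p + d1 - d2))
                       - nll(*(p - d1 + d2)) + nll(*(p - d1 - d2))
                       ) / (4 * eps[i] * eps[j])
    try:
        cov = np.linalg.inv(H)
        if cov[0, 0] <= 0 or cov[1, 1] <= 0:
            raise np.linalg.LinAlgError
        return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")


def _tgdp_standard_errors(counts, support, norm, k, beta):
    """Gauss-Newton standard errors of (k, beta) from the weighted log fit."""
    pos = counts > 0
    m = support[pos]
    n = counts[pos]
    w = n

    def log_model(params):
        kk, bb = params
        wgt = np.power(support + bb, -kk)
        f = norm * wgt / wgt.sum()
        return np.log10(f[pos])

    p = np.array([k, beta])
    eps = np.maximum(np.abs(p), 1.0) * 1e-6
    jac = np.empty((pos.sum(), 2))
    for j in range(2):
        dp = np.zeros(2)
        dp[j] = eps[j]
        jac[:, j] = (log_model(p + dp) - log_model(p - dp)) / (2 * eps[j])
    resid = np.log10(n) - log_model(p)
    dof = max(1, pos.sum() - 2)
    s2 = (w * resid ** 2).sum() / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ (w[:, None] * jac))
        return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")


def _gof_chi2(observed, expected, n_fitted):
    """Pearson chi-square with low-expectation bins pooled to >= 5."""
    obs_p, exp_p = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= 5.0:
            obs_p.append(o_acc)
            exp_p.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 and exp_p:
        obs_p[-1] += o_acc
        exp_p[-1] += e_acc
    obs_p = np.asarray(obs_p)
    exp_p = np.asarray(exp_p)
    if len(obs_p) <= n_fitted + 1:
        return float("nan"), float("nan")
    exp_p = exp_p * obs_p.sum() / exp_p.sum()
    chi2 = float(((obs_p - exp_p) ** 2 / exp_p).sum())
    dof = len(obs_p) - 1 - n_fitted
    return chi2, float(stats.chi2.sf(chi2, dof))


def back_extrapolate(
    gdp: GDPParams, norm: float, tail_start: int, J: int
) -> np.ndarray:
    """Extend the fitted tail to all m >= 1, keeping the tail normalization.

    Returns predicted specific counts over m = 1..J:
    n_s(m) = norm * f(m; k, beta; 1, J) / sum_{i >= tail_start} f(i; ...).
    """
    full = gdp_pmf(gdp, TruncationWindow(1, J))
    tail_mass = full.probs[tail_start - 1:].sum()
    if tail_mass <= 0:
        raise PipelineError("back_extrapolate", "no GDP mass on the tail window")
    return norm * full.probs / tail_mass


def estimate_threshold(
    noise: NoiseFit,
    specific_counts: np.ndarray,
    sp_target: float,
) -> tuple[int, dict[int, float]]:
    """Smallest integer t from which Sp stays at or above sp_target.

    Sp(t) is the specific share of the predicted tail mass at m >= t:
    Sp(t) = sum_{m>=t} n_s(m) / sum_{m>=t} [n_s(m) + n_noise(m)].
    When noise decays faster than the specific component Sp is
    non-decreasing, and this is the smallest t with Sp(t) >= sp_target;
    requiring the whole remaining curve to clear the target additionally
    guards against spurious dips of an unstable head extrapolation.
    """
    J = len(specific_counts)
    m = np.arange(1, J + 1)
    noise_counts = noise.expected(m)
    s_tail = np.cumsum(specific_counts[::-1])[::-1]
    n_tail = np.cumsum(noise_counts[::-1])[::-1]
    sp = s_tail / (s_tail + n_tail)
    curve = {int(mm): float(ss) for mm, ss in zip(m, sp)}
    sp_floor = np.minimum.accumulate(sp[::-1])[::-1]   # min over t' >= t
    ok = np.nonzero(sp_floor >= sp_target)[0]
    if len(ok) == 0:
        raise PipelineError(
            "estimate_threshold",
            f"sp_target {sp_target} unreachable; max achievable "
            f"Sp = {sp.max():.4f}")
    return int(m[ok[0]]), curve


def subtract_noise(
    hist: BindingHistogram, noise: NoiseFit
) -> tuple[np.ndarray, int]:
    """Noise-subtracted ("restored") specific counts, clipped at zero.

    Returns the dense restored vector over m = 1..J and the number of bins
    clipped to zero.
    """
    m, n = hist.as_arrays()
    restored = n - noise.expected(m)
    clipped = int(np.sum((restored < 0) & (n > 0)))
    if clipped:
        logger.info("subtract_noise: clipped %d bins to zero", clipped)
    return np.maximum(restored, 0.0), clipped


def estimate_alpha(Mhat_s: float, M: float) -> float:
    """Fraction of library fragments attributed to specific loci."""
    if M <= 0:
        raise ValueError("library size M must be positive")
    if not (0.0 <= Mhat_s <= M * (1 + 1e-9)):
        raise ValueError(f"Mhat_s = {Mhat_s} outside [0, M = {M}]")
    return float(Mhat_s / M)


def fit_kw(
    counts: np.ndarray, cfg: MixtureConfig, t_low: int = 1
) -> KWFit:
    """Fit the (possibly doubly) truncated K-W law to specific counts.

    ``counts`` is a dense vector over m = 1..J.  With ``t_low = 1`` the
    zero-truncated pmf is fitted to the whole support; with ``t_low > 1``
    only the reliable tail m >= t_low enters the fit, through the
    double-truncated (window-renormalized) form — the pipeline uses this to
    keep model-generated head values out of the K-W likelihood.

    The default objective is the truncated multinomial likelihood ("mle");
    the weighted log least squares used by the other stages is available via
    ``cfg.objective`` when ``cfg.kw_objective`` is set accordingly.  theta
    is optimized on (0, 1] — the boundary theta = 1 is explored by a
    dedicated profile fit because real libraries sit there.
    """
    counts = np.asarray(counts, dtype=float)
    J = len(counts)
    if not (1 <= t_low <= J):
        raise PipelineError("fit_kw", f"t_low {t_low} outside [1, {J}]")
    window = slice(t_low - 1, J)
    win_counts = counts[window]
    pos_w = win_counts > 0
    if pos_w.sum() < 5:
        raise PipelineError(
            "fit_kw", f"need >= 5 positive bins, got {int(pos_w.sum())}")
    total = win_counts.sum()
    i = np.arange(J)

    use_mle = cfg.kw_objective == "mle"

    def log_rel(theta, a, b):
        # log(p_m / p_0) = sum_{i<m} log(theta*(a+i)/(b+1+i))
        return np.cumsum(np.log(theta) + np.log(a + i) - np.log(b + 1.0 + i))

    def eval_obj(theta, a, b):
        if theta >= 1.0:
            if b <= a:
                return np.inf
            theta = 1.0
        with np.errstate(over="ignore", invalid="ignore"):
            lr = log_rel(theta, a, b)[window]
            hi = lr.max()
            lse = hi + np.log(np.exp(lr - hi).sum())
            if not np.isfinite(lse):
                return np.inf
            if use_mle:
                return -float((win_counts[pos_w] * (lr[pos_w] - lse)).sum())
            modeled = total * np.exp(lr - lse)
            if not np.all(np.isfinite(modeled)):
                return np.inf
            return _tail_objective(win_counts, modeled, cfg.kw_objective)

    rng = np.random.default_rng(cfg.seed + 1)

    def obj_free(x):
        theta = 1.0 / (1.0 + np.exp(-x[0]))
        theta = min(theta, _THETA_CAP)
        return eval_obj(theta, np.exp(x[1]), np.exp(x[2]))

    def obj_boundary(x):
        a = np.exp(x[0])
        return eval_obj(1.0, a, a + np.exp(x[1]))

    best_free = None
    starts = [(0.999, 5.0, 7.0)] + [
        (rng.uniform(0.9, 0.99999),
         np.exp(rng.uniform(np.log(0.5), np.log(30.0))),
         None)
        for _ in range(cfg.n_restarts - 1)
    ]
    for th0, a0, b0 in starts:
        if b0 is None:
            b0 = a0 * rng.uniform(1.05, 2.0)
        x0 = [np.log(th0 / (1 - th0)), np.log(a0), np.log(b0)]
        res = optimize.minimize(
            obj_free, x0=x0, method="Nelder-Mead",
            options={"maxiter": cfg.max_iter, "xatol": 1e-8, "fatol": 1e-12})
        if best_free is None or res.fun < best_free.fun:
            best_free = res

    best_bdry = None
    for a0, delta0 in [(5.0, 2.0), (2.0, 1.0), (13.0, 3.0), (1.0, 0.5)]:
        res = optimize.minimize(
            obj_boundary, x0=[np.log(a0), np.log(delta0)], method="Nelder-Mead",
            options={"maxiter": cfg.max_iter, "xatol": 1e-8, "fatol": 1e-12})
        if best_bdry is None or res.fun < best_bdry.fun:
            best_bdry = res

    if best_bdry.fun <= best_free.fun:
        a = float(np.exp(best_bdry.x[0]))
        b = a + float(np.exp(best_bdry.x[1]))
        params = KWParams(theta=1.0, a=a, b=b)
        fun = float(best_bdry.fun)
        at_boundary = True
    else:
        theta = min(float(1.0 / (1.0 + np.exp(-best_free.x[0]))), _THETA_CAP)
        params = KWParams(theta=theta, a=float(np.exp(best_free.x[1])),
                          b=float(np.exp(best_free.x[2])))
        fun = float(best_free.fun)
        at_boundary = False
    if not np.isfinite(fun):
        raise PipelineError("fit_kw", "optimizer failed to find a finite fit")
    return KWFit(params=params, p0=kw_p0(params), objective_value=fun,
                 at_boundary=at_boundary)


def totals(Ns: float, p0: float) -> tuple[int, int, float]:
    """Genome-wide accounting: (Ntot, N0, Se) from observed specific loci.

    Ntot = round(Ns / (1 - p0)); N0 = round(p0 * Ntot); Se = (1 - p0)*100 %.
    """
    if not (0.0 <= p0 < 1.0):
        raise ValueError(f"p0 must be in [0, 1), got {p0}")
    if Ns < 0:
        raise ValueError("Ns must be >= 0")
    ntot = int(round(Ns / (1.0 - p0)))
    n0 = int(round(p0 * ntot))
    return ntot, n0, (1.0 - p0) * 100.0


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def analyze_library(
    hist: BindingHistogram, cfg: MixtureConfig | None = None
) -> MixtureResult:
    """Run the full fitting-and-back-extrapolation pipeline on a histogram."""
    cfg = cfg or MixtureConfig()
    warnings: list[str] = []
    J = hist.J
    m_axis = np.arange(1, J + 1)
    _, raw = hist.as_arrays()

    # alternate between the noise fit and the specific-component estimate:
    # once a specific prediction exists, it is removed from the counts the
    # noise is fitted to, correcting the contamination of the left bins
    noise_input = raw.copy()
    noise = tgdp = kw = None
    t = None
    clipped = 0
    sp_curve: dict[int, float] = {}
    for _refine in range(cfg.n_refine + 1):
        try:
            noise = fit_noise(noise_input, cfg)
        except PipelineError:
            if _refine == 0:
                raise
            # the specific prediction absorbed the left bins entirely:
            # the library is effectively noise-free
            noise = NoiseFit(ExpNoiseParams(d=noise.params.d, amplitude=0.0),
                             se_d=float("nan"), se_amplitude=float("nan"),
                             n_points=0)
            warnings.append("noise component vanished during refinement")
        restored = np.maximum(raw - noise.expected(m_axis), 0.0)
        clipped = int(np.sum((raw - noise.expected(m_axis) < 0) & (raw > 0)))

        t_fit = cfg.tail_fit_start or min(cfg.noise_fit_range[1] + 1,
                                          max(1, J - 4))
        t = None
        # refit the tail at the estimated threshold until it is stable
        for _ in range(5):
            tgdp = fit_tgdp_tail(restored, TruncationWindow(t_fit, J), cfg)
            head = back_extrapolate(tgdp.params, tgdp.norm, t_fit, J)
            t_new, sp_curve = estimate_threshold(noise, head, cfg.sp_target)
            if t_new == t or t_new <= t_fit:
                t = t_new
                break
            t = t_fit = t_new
        assert t is not None and tgdp is not None

        # K-W fitted on the reliable noise-subtracted tail only
        # (double-truncated likelihood); extrapolated head values stay out
        # of the K-W fit
        kw = fit_kw(restored, cfg, t_low=t)
        norm_t = float(restored[t - 1:].sum())
        zt = kw_pmf_zero_truncated(kw.params, J)
        spec_pred = norm_t * zt.probs / zt.probs[t - 1:].sum()
        noise_input = np.maximum(raw - spec_pred, 0.0)

    if clipped:
        warnings.append(f"noise subtraction clipped {clipped} bins to zero")
    if kw.at_boundary:
        warnings.append("K-W fit at the theta = 1 boundary (Waring case)")
    sp_at_t = sp_curve[t]

    Ns2 = float(spec_pred[t - 1:].sum())
    Ns1 = float(spec_pred[: t - 1].sum())
    Ns = Ns1 + Ns2
    Mhat_s = float((m_axis * spec_pred).sum())
    alpha = estimate_alpha(Mhat_s, hist.M)
    noise_locus_total = float(noise.expected(m_axis).sum())
    s_weight = Ns / (Ns + noise_locus_total)

    N2 = int(raw[t - 1:].sum())
    N1 = int(raw[: t - 1].sum())
    M2 = int((m_axis[t - 1:] * raw[t - 1:]).sum())
    M1 = int((m_axis[: t - 1] * raw[: t - 1]).sum())

    ntot, n0, se = totals(Ns, kw.p0)

    return MixtureResult(
        t=t, sp_at_t=sp_at_t, sp_curve=sp_curve, alpha=alpha,
        s_weight=s_weight, noise=noise, gdp=tgdp, kw=kw, p0=kw.p0,
        Ns=Ns, Ns1=Ns1, Ns2=Ns2, N1=N1, N2=N2, M1=M1, M2=M2,
        N0=n0, Ntot=ntot, Se=se, Mhat_s=Mhat_s,
        N=hist.N, M=hist.M, J=J, clipped_bins=clipped, warnings=warnings,
        specific_pred={int(mm): float(v) for mm, v in zip(m_axis, spec_pred)},
    )


class BindingMixtureModel(BaseEstimator):
    """Mixture model of specific vs background binding, scikit-learn style.

    ``fit`` takes per-locus peak heights (n_loci, 1) — the expanded form of
    the binding-event histogram — decomposes the histogram into an
    exponential background and a heavy-tailed specific component, and
    estimates the specificity threshold and the undetected-site fraction.

    Parameters mirror :class:`MixtureConfig`.  After fitting, ``predict``
    labels loci as specific (peak height >= ``threshold_``).

    Attributes
    ----------
    threshold_ : int
        Specificity threshold t.
    p0_ : float
        Undetected-site fraction from the K-W zero class.
    n_total_ : int
        Predicted genome-wide number of specific binding sites.
    sensitivity_ : float
        Assay sensitivity Se = (1 - p0_) * 100, in percent.
    alpha_ : float
        Specific share of library fragments.
    result_ : MixtureResult
        The full structured pipeline output.
    """

    def __init__(
        self,
        sp_target: float = 0.95,
        noise_fit_range: tuple[int, int] = (1, 8),
        tail_fit_start: int | None = None,
        objective: str = "wls_log",
        kw_objective: str = "mle",
        n_refine: int = 2,
        max_iter: int = 2000,
        n_restarts: int = 10,
        random_state: int = 0,
    ):
        self.sp_target = sp_target
        self.noise_fit_range = noise_fit_range
        self.tail_fit_start = tail_fit_start
        self.objective = objective
        self.kw_objective = kw_objective
        self.n_refine = n_refine
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _config(self) -> MixtureConfig:
        return MixtureConfig(
            sp_target=self.sp_target,
            noise_fit_range=tuple(self.noise_fit_range),
            tail_fit_start=self.tail_fit_start,
            objective=self.objective,
            kw_objective=self.kw_objective,
            n_refine=self.n_refine,
            max_iter=self.max_iter,
            n_restarts=self.n_restarts,
            seed=self.random_state,
        )

    def fit(self, X, y=None, M: int | None = None):
        """Fit on per-locus peak heights X of shape (n_loci, 1) or (n_loci,)."""
        X = check_array(X, ensure_2d=False, dtype=int)
        heights = X.ravel()
        if np.any(heights < 1):
            raise ValueError("peak heights must be >= 1")
        hist = BindingHistogram.from_heights(heights, M=M)
        return self.fit_histogram(hist)

    def fit_histogram(self, hist: BindingHistogram):
        """Fit directly on a :class:`BindingHistogram`."""
        self.result_ = analyze_library(hist, self._config())
        r = self.result_
        self.threshold_ = r.t
        self.p0_ = r.p0
        self.n_total_ = r.Ntot
        self.sensitivity_ = r.Se
        self.alpha_ = r.alpha
        self.kw_params_ = r.kw.params
        self.gdp_params_ = r.gdp.params
        self.noise_params_ = r.noise.params
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Label loci as specific (1, peak height >= threshold_) or noise (0)."""
        check_is_fitted(self, "threshold_")
        X = check_array(X, ensure_2d=False, dtype=int)
        return (X.ravel() >= self.threshold_).astype(int)
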