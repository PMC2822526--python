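"""Monte-Carlo null models: uniform fragment placement and qPCR design.

Two background questions are answered by simulation:

* how many peak clusters of each height arise purely by chance when
  fragments land uniformly on a mappable genome (the random-placement null
  used to judge specificity thresholds), and
* how the choice of loci for a qPCR validation panel (uniform over the
  avidity range vs frequency-weighted over observed loci) biases the
  apparent avidity distribution of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histogram import (
    BindingHistogram,
    Fragment,
    FragmentSet,
    cluster_and_peak,
    histogram_from_clusters,
)

__all__ = [
    "GenomeModel",
    "DesignSample",
    "BackgroundResult",
    "mc_background",
    "qpcr_design_sim",
]


@dataclass(frozen=True)
class GenomeModel:
    """A single linear mappable segment of length g with L-bp fragments."""

    g: int
    L: int
    M_frag: int

    def __post_init__(self) -> None:
        if not (self.g > self.L > 0):
            raise ValueError("need genome size g > fragment length L > 0")
        if self.M_frag < 1:
            raise ValueError("need at least one fragment")


@dataclass
class BackgroundResult:
    """Chance peak-height statistics averaged over replicates."""

    support: np.ndarray          # m = 1..J_max over replicates
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    n_reps: int
    threshold: int | None        # smallest t passing the false-positive rule
    fp_rate: float

    def expected_tail(self, t: int) -> float:
        """Expected chance-cluster count at heights >= t."""
        mask = self.support >= t
        return float(self.mean_counts[mask].sum())


@dataclass
class DesignSample:
    """Replicate statistics of a qPCR panel selection scheme."""

    scheme: str
    support: np.ndarray
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    n_select: int
    n_reps: int


def _place_fragments(gm: GenomeModel, rng: np.random.Generator) -> FragmentSet:
    starts = rng.integers(0, gm.g - gm.L + 1, size=gm.M_frag)
    return FragmentSet(
        [Fragment("null", int(s), int(s) + gm.L) for s in starts]
    )


def mc_background(
    gm: GenomeModel,
    n_reps: int = 10,
    min_overlap: int = 4,
    seed: int = 0,
    observed: BindingHistogram | None = None,
    fp_rate: float = 0.05,
) -> BackgroundResult:
    """Expected histogram of chance peak heights under uniform placement.

    Fragments of length L are dropped uniformly on [0, g-L] (integer bp,
    both ends inclusive), clustered with the same machinery as real data,
    and the per-height cluster counts are averaged over replicates.  When an
    observed histogram is supplied, the reported threshold is the smallest t
    at which the expected chance-cluster tail is below ``fp_rate`` times the
    observed tail (an expected false-discovery bound).
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    per_rep: list[dict[int, int]] = []
    j_max = 0
    for _ in range(n_reps):
        frags = _place_fragments(gm, rng)
        clusters = cluster_and_peak(frags, min_overlap)
        hist = histogram_from_clusters(clusters)
        per_rep.append(hist.counts)
        j_max = max(j_max, hist.J)
    support = np.arange(1, j_max + 1)
    table = np.zeros((n_reps, j_max))
    for i, counts in enumerate(per_rep):
        for m, n in counts.items():
            table[i, m - 1] = n
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(j_max)

    threshold = None
    if observed is not None:
        m_obs, n_obs = observed.as_arrays()
        chance_tail = np.concatenate([
            np.cumsum(mean[::-1])[::-1], np.zeros(max(0, observed.J - j_max))
        ])[: observed.J]
        obs_tail = np.cumsum(n_obs[::-1])[::-1]
        ok = np.nonzero(
            (obs_tail > 0) & (chance_tail <= fp_rate * obs_tail)
        )[0]
        if ok.size:
            threshold = int(m_obs[ok[0]])
    return BackgroundResult(
        support=support, mean_counts=mean, sd_counts=sd,
        n_reps=n_reps, threshold=threshold, fp_rate=fp_rate,
    )


def _even_quota(n_select: int, avail: np.ndarray) -> np.ndarray:
    """Spread n_select picks as evenly as possible over height classes.

    Each class gets floor(n/k) capped by availability; the remainder is
    redistributed round-robin over classes with loci left, so n_select = N
    returns every locus.
    """
    k = len(avail)
    quota = np.minimum(avail, n_select // k)
    left = n_select - quota.sum()
    while left > 0:
        room = np.nonzero(quota < avail)[0]
        if room.size == 0:
            break
        for i in room:
            if left == 0:
                break
            quota[i] += 1
            left -= 1
    return quota


def qpcr_design_sim(
    hist: BindingHistogram,
    n_select: int,
    scheme: str = "frequency-weighted",
    n_reps: int = 224,
    seed: int = 0,
) -> DesignSample:
    """Simulate the composition of a qPCR validation panel.

    ``frequency-weighted``: loci are drawn without replacement uniformly
    from the library, so each height m is represented in proportion to n(m)
    (hypergeometric inclusion).  ``uniform-avidity``: the panel is spread
    evenly across the observed m range regardless of how many loci carry
    each height — the design the panel-size-limited experiment tends to use.
    Returns per-height mean and SD of panel counts over replicates.
    """
    if n_select > hist.N:
        raise ValueError(f"cannot select {n_select} of {hist.N} loci")
    if scheme not in ("frequency-weighted", "uniform-avidity"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    heights = hist.expand()
    support = np.arange(1, hist.J + 1)
    table = np.zeros((n_reps, hist.J))
    if scheme == "frequency-weighted":
        for i in range(n_reps):
            pick = rng.choice(heights, size=n_select, replace=False)
            vals, cnts = np.unique(pick, return_counts=True)
            table[i, vals - 1] = cnts
    else:
        observed_ms = np.unique(heights)
        avail = np.array([hist.counts[int(m)] for m in observed_ms])
        quota = _even_quota(n_select, avail)
        table[:, observed_ms - 1] = quota    # deterministic design
        n_reps = 1
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(hist.J)
    return DesignSample(
        scheme=scheme, support=support, mean_counts=mean, sd_counts=sd,
        n_select=n_select, n_reps=n_reps,
    )
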