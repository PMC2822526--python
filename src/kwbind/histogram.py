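"""Binding-event histograms from mapped-fragment intervals.

The empirical object at the centre of the analysis is the peak-height
histogram n(m): the number of genomic loci whose fragment cluster has a
maximum overlap depth of exactly m extended fragments.  This module builds it
the way the underlying ChIP-seq processing did: extend each uniquely mapped
fragment to a fixed length from its 5' end, single-linkage cluster fragments
overlapping by at least ``min_overlap`` bp, and score each cluster by its
peak height (maximum simultaneous coverage), with the member count kept as a
secondary field.

Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "FragmentSet",
    "Cluster",
    "ClusterSet",
    "BindingHistogram",
    "extend_fragments",
    "cluster_and_peak",
    "histogram_from_clusters",
    "histogram_from_bed",
]


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class FragmentSet:
    """A collection of mapped fragments (order-insensitive)."""

    fragments: list[Fragment]

    def __len__(self) -> int:
        return len(self.fragments)

    @classmethod
    def from_bed(cls, path: str | Path) -> "FragmentSet":
        """Read BED3+strand; BED6 accepted, extra columns ignored."""
        frags = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[5] if len(parts) >= 6 else parts[3] if len(parts) == 4 else "+"
                if strand not in ("+", "-"):
                    strand = "+"
                frags.append(Fragment(chrom, start, end, strand))
        return cls(frags)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t.\t0\t{f.strand}\n")


@dataclass(frozen=True)
class Cluster:
    chrom: str
    start: int
    end: int
    fragment_count: int
    peak_height: int

    def __post_init__(self) -> None:
        if self.peak_height > self.fragment_count:
            raise ValueError("peak_height cannot exceed fragment_count")


@dataclass
class ClusterSet:
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def peak_heights(self) -> np.ndarray:
        return np.array([c.peak_height for c in self.clusters], dtype=int)

    def to_bed(self, path: str | Path) -> None:
        """Write clusters as BED with peak_height in the score column."""
        with open(path, "w") as fh:
            for c in self.clusters:
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t"
                    f"n={c.fragment_count}\t{c.peak_height}\t.\n"
                )


@dataclass
class BindingHistogram:
    """Histogram n(m) of loci by peak height, with library totals.

    Attributes
    ----------
    counts : dict mapping m -> n(m), m >= 1
    M : total fragment count over the counted loci ("DNA sequence mass")
    """

    counts: dict[int, int]
    M: int | None = None

    def __post_init__(self) -> None:
        clean = {int(m): int(n) for m, n in self.counts.items() if n > 0}
        if not clean:
            raise ValueError("empty histogram")
        if any(m < 1 for m in clean):
            raise ValueError("peak heights must be >= 1")
        if any(n < 0 for n in clean.values()):
            raise ValueError("negative locus counts")
        self.counts = dict(sorted(clean.items()))
        if self.M is None:
            # fall back to the mass implied by the histogram itself
            self.M = int(sum(m * n for m, n in self.counts.items()))

    @property
    def N(self) -> int:
        """Total number of loci."""
        return int(sum(self.counts.values()))

    @property
    def J(self) -> int:
        """Maximum observed peak height."""
        return max(self.counts)

    @property
    def fragment_mass(self) -> int:
        """sum_m m*n(m) — fragments accounted for by the histogram."""
        return int(sum(m * n for m, n in self.counts.items()))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (m, n) arrays over m = 1..J, zeros included."""
        m = np.arange(1, self.J + 1)
        n = np.array([self.counts.get(int(i), 0) for i in m], dtype=float)
        return m, n

    def expand(self) -> np.ndarray:
        """Per-locus peak heights (one entry per locus)."""
        return np.repeat(
            list(self.counts.keys()), list(self.counts.values())
        ).astype(int)

    @classmethod
    def from_heights(cls, heights, M: int | None = None) -> "BindingHistogram":
        vals, cnts = np.unique(np.asarray(heights, dtype=int), return_counts=True)
        return cls({int(v): int(c) for v, c in zip(vals, cnts)}, M=M)

    def to_tsv(self, path: str | Path) -> None:
        """Write as 2-column TSV (header "m\\tn") plus a JSON sidecar."""
        path = Path(path)
        pd.DataFrame(
            {"m": list(self.counts), "n": list(self.counts.values())}
        ).to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"M": self.M, "N": self.N, "J": self.J}) + "\n"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BindingHistogram":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        if not {"m", "n"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'm' and 'n'")
        M = None
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            M = json.loads(sidecar.read_text()).get("M")
        return cls(dict(zip(df["m"].astype(int), df["n"].astype(int))), M=M)


def extend_fragments(frags: FragmentSet, length: int = 200) -> FragmentSet:
    """Extend each fragment to ``length`` bp anchored at its 5' end.

    Plus-strand fragments keep their start; minus-strand fragments keep their
    end.  The result is deduplicated (the library is a set of *distinct*
    uniquely mapped fragments).  Unknown strands are treated as '+' with a
    warning.
    """
    if length <= 0:
        raise ValueError("extension length must be positive")
    seen: set[tuple[str, int, int, str]] = set()
    out: list[Fragment] = []
    for f in frags.fragments:
        strand = f.strand
        if strand not in ("+", "-"):
            logger.warning("unknown strand %r at %s:%d; treating as '+'",
                           strand, f.chrom, f.start)
            strand = "+"
        if strand == "+":
            start, end = f.start, f.start + length
        else:
            start, end = max(0, f.end - length), f.end
        key = (f.chrom, start, end, strand)
        if key not in seen:
            seen.add(key)
            out.append(Fragment(f.chrom, start, end, strand))
    return FragmentSet(out)


def cluster_and_peak(frags: FragmentSet, min_overlap: int = 4) -> ClusterSet:
    """Single-linkage clustering of intervals overlapping by >= min_overlap bp.

    A candidate joins a growing cluster when its intersection with at least
    one current member is >= min_overlap.  With intervals sorted by start the
    best member is the one with the largest end, so a sweep with a running
    max-end implements single linkage exactly.  Peak height is the maximum
    simultaneous coverage inside the cluster.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: dict[str, list[Fragment]] = {}
    for f in frags.fragments:
        by_chrom.setdefault(f.chrom, []).append(f)

    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda f: (f.start, f.end))
        group: list[Fragment] = []
        max_end = -1
        for f in members:
            # overlap with the farthest-reaching member
            if group and min(max_end, f.end) - f.start >= min_overlap:
                group.append(f)
                max_end = max(max_end, f.end)
            else:
                if group:
                    clusters.append(_finish_cluster(chrom, group))
                group = [f]
                max_end = f.end
        if group:
            clusters.append(_finish_cluster(chrom, group))
    return ClusterSet(clusters)


def _finish_cluster(chrom: str, group: list[Fragment]) -> Cluster:
    starts = np.array([f.start for f in group])
    ends = np.array([f.end for f in group])
    # coverage sweep: +1 at starts, -1 at ends, max prefix sum in position order
    events = np.concatenate([
        np.stack([starts, np.ones_like(starts)], axis=1),
        np.stack([ends, -np.ones_like(ends)], axis=1),
    ])
    # ends sort before starts at equal position (half-open intervals)
    order = np.lexsort((events[:, 1], events[:, 0]))
    peak = int(np.max(np.cumsum(events[order, 1])))
    return Cluster(chrom, int(starts.min()), int(ends.max()), len(group), peak)


def histogram_from_clusters(clusters: ClusterSet) -> BindingHistogram:
    """n(m) = number of clusters with peak height m; M = total member fragments."""
    if len(clusters) == 0:
        raise ValueError("no clusters")
    M = int(sum(c.fragment_count for c in clusters.clusters))
    return BindingHistogram.from_heights(clusters.peak_heights(), M=M)


def histogram_from_bed(
    path: str | Path, extend: int = 200, min_overlap: int = 4
) -> BindingHistogram:
    """BED fragments -> extend -> cluster -> histogram, in one call."""
    frags = extend_fragments(FragmentSet.from_bed(path), extend)
    return histogram_from_clusters(cluster_and_peak(frags, min_overlap))
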