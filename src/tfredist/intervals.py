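"""Interval geometry: nearest-feature distances, overlap filtering, read
counting in features, ECDF/KS comparison, and strand-separated composite
signal profiles around summits."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import CountMatrix, GeneAnnotation, PeakSet

__all__ = [
    "nearest_distance",
    "filter_peaks_overlapping",
    "count_in_intervals",
    "ecdf_ks",
    "CompositeProfile",
    "composite_profile",
]


def nearest_distance(queries: GeneAnnotation, subjects: PeakSet) -> pd.DataFrame:
    """Distance from each gene TSS to its nearest peak interval.

    Distance is 0 when the TSS lies inside the half-open interval, otherwise
    min(|TSS - start|, |TSS - (end-1)|).  Ties go to the leftmost subject,
    then lexicographic name.  Genes on chromosomes with no subject get
    infinite distance and ``no_subject=True``.
    """
    by_chrom: dict[str, list] = subjects.by_chrom()
    arrays = {}
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.name))
        arrays[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
            [iv.name for iv in ivs],
        )
    rows = []
    for _, g in queries.table.iterrows():
        chrom, tss = g["chrom"], int(g["tss"])
        if chrom not in arrays:
            rows.append((g["gene_id"], None, np.inf, True))
            continue
        starts, ends, names = arrays[chrom]
        # 0 inside; start - tss if left of the peak; tss - (end-1) if right
        dist = np.maximum.reduce([starts - tss, tss - (ends - 1), np.zeros(len(starts), dtype=np.int64)])
        k = int(np.argmin(dist))  # argmin takes the first = leftmost on ties
        rows.append((g["gene_id"], names[k], float(dist[k]), False))
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "distance", "no_subject"])


def filter_peaks_overlapping(a: PeakSet, b: PeakSet) -> PeakSet:
    """Subset of ``a`` overlapping >= 1 bp of some interval in ``b``
    (half-open intersection)."""
    trees: dict[str, IntervalTree] = {}
    for iv in b:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    kept = [
        iv
        for iv in a
        if iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end)
    ]
    return PeakSet(kept, a.genome)


def count_in_intervals(
    read_positions: Mapping[str, Mapping[str, Sequence[int]]],
    features: PeakSet,
    sample_meta: pd.DataFrame | None = None,
) -> CountMatrix | pd.DataFrame:
    """Count read positions inside each half-open feature, per sample.

    ``read_positions`` maps sample id -> chrom -> sorted positions (bp).
    Counting is strand-agnostic.  Returns a CountMatrix when sample metadata
    is supplied, else the raw counts DataFrame.
    """
    samples = list(read_positions)
    mat = np.zeros((len(features), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        per_chrom = {c: np.asarray(p) for c, p in read_positions[s].items()}
        for c, p in per_chrom.items():
            if np.any(np.diff(p) < 0):
                per_chrom[c] = np.sort(p)
        for i, iv in enumerate(features):
            pos = per_chrom.get(iv.chrom)
            if pos is None:
                continue
            mat[i, j] = np.searchsorted(pos, iv.end, side="left") - np.searchsorted(
                pos, iv.start, side="left"
            )
    counts = pd.DataFrame(mat, index=features.names, columns=samples)
    if sample_meta is None:
        return counts
    return CountMatrix(counts, sample_meta)


@dataclass
class KSResult:
    ecdf_a: object
    ecdf_b: object
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    n_excluded: int


def ecdf_ks(
    distances_a: Sequence[float],
    distances_b: Sequence[float],
    method: str = "asymp",
    n_perm: int = 2000,
    seed: int = 0,
) -> KSResult:
    """Two-sample KS comparison of two distance distributions.

    Infinite values (genes with no qualifying peak) are excluded and counted.
    D = sup|F_a - F_b|; p from the asymptotic Kolmogorov distribution with
    effective n = n_a n_b/(n_a + n_b), or from a seeded permutation when
    ``method='permutation'``.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    n_excluded = int((~np.isfinite(a)).sum() + (~np.isfinite(b)).sum())
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs >= 3 finite values")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    D = float(res.statistic)
    if method == "asymp":
        p = float(res.pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            d = stats.ks_2samp(
                pooled[: len(a)], pooled[len(a) :], method="asymp"
            ).statistic
            if d >= D - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
    else:
        raise ValueError(f"unknown method {method!r}")
    ecdf_a = stats.ecdf(a).cdf
    ecdf_b = stats.ecdf(b).cdf
    return KSResult(ecdf_a, ecdf_b, D, p, len(a), len(b), n_excluded)


@dataclass
class CompositeProfile:
    """Mean stranded signal at each offset from anchor summits."""

    offsets: np.ndarray
    plus_signal: np.ndarray
    minus_signal: np.ndarray
    n_anchors: int


def composite_profile(
    signal: Mapping[str, tuple[np.ndarray, np.ndarray]],
    anchors: PeakSet,
    half_width: int,
) -> CompositeProfile:
    """Average per-base (plus, minus) signal in summit-centered windows.

    ``signal`` maps chrom -> (plus array, minus array) of per-base values.
    Anchors whose window would be truncated at a chromosome edge are
    excluded.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    offsets = np.arange(-half_width, half_width + 1)
    plus_acc = np.zeros(len(offsets))
    minus_acc = np.zeros(len(offsets))
    n = 0
    for iv in anchors:
        if iv.chrom not in signal:
            continue
        plus, minus = signal[iv.chrom]
        summit = iv.summit if iv.summit is not None else iv.midpoint
        lo, hi = summit - half_width, summit + half_width + 1
        if lo < 0 or hi > len(plus):
            continue
        plus_acc += np.asarray(plus[lo:hi], dtype=float)
        minus_acc += np.asarray(minus[lo:hi], dtype=float)
        n += 1
    if n == 0:
        raise ValueError("no usable anchors within chromosome bounds")
    return CompositeProfile(offsets, plus_acc / n, minus_acc / n, n)
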