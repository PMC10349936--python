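"""Anchor-TF-dependent redistribution of a second TF's binding.

Groups a TF's per-peak binding fold changes either by proximity to gene
classes (within a bp window of a TSS) or by summit-to-summit distance to the
nearest anchor peak, then tests each group's mean log2 fold change against 0
with a two-sided one-sample t-test.  Stars follow the figure convention:
"***" for p < 1e-3, "N.S." for p > 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneAnnotation, PeakSet

__all__ = [
    "GroupedFoldChanges",
    "fc_by_gene_class",
    "fc_by_distance_to_anchor",
    "rank_sum_compare",
]

DEFAULT_BINS = (0, 10_000, 100_000)


@dataclass
class GroupedFoldChanges:
    group: str
    member_ids: list[str]
    log2fc: np.ndarray
    t: float
    pvalue: float
    warning: str | None = None
    stars: str = field(init=False)

    def __post_init__(self) -> None:
        p = self.pvalue
        if np.isnan(p):
            self.stars = ""
        elif p < 1e-3:
            self.stars = "***"
        elif p > 0.1:
            self.stars = "N.S."
        else:
            self.stars = ""

    @property
    def n(self) -> int:
        return len(self.log2fc)

    @property
    def mean_log2fc(self) -> float:
        return float(np.mean(self.log2fc)) if self.n else np.nan


def _one_sample_t(values: np.ndarray) -> tuple[float, float]:
    """Two-sided one-sample t vs 0; an all-zero group is the exact null
    (t=0, p=1) rather than 0/0."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return np.nan, np.nan
    sd = values.std(ddof=1)
    if sd == 0:
        if values.mean() == 0:
            return 0.0, 1.0
        return np.inf if values.mean() > 0 else -np.inf, 0.0
    res = stats.ttest_1samp(values, 0.0)
    return float(res.statistic), float(res.pvalue)


def fc_by_gene_class(
    er_results: pd.DataFrame,
    er_peaks: PeakSet,
    genes: GeneAnnotation,
    window: int = 100_000,
    exclusive: bool = False,
    class_order: tuple[str, ...] = ("activated", "repressed", "unchanged"),
) -> list[GroupedFoldChanges]:
    """Group TF-peak fold changes by the classes of genes within ``window``
    bp of the peak summit.

    ``er_results`` needs columns feature_id and log2fc; ``genes.table`` needs
    a ``class`` column.  By default a peak near genes of several classes
    joins every such group; ``exclusive`` assigns it only to the class of the
    nearest qualifying TSS.
    """
    if "class" not in genes.table.columns:
        raise ValueError("gene table must carry a 'class' column")
    lfc = er_results.set_index("feature_id")["log2fc"]
    gt = genes.table
    tss_by_chrom = {
        chrom: (grp["tss"].to_numpy(), grp["class"].to_numpy())
        for chrom, grp in gt.groupby("chrom")
    }
    members: dict[str, list[str]] = {c: [] for c in class_order}
    values: dict[str, list[float]] = {c: [] for c in class_order}
    for iv in er_peaks:
        if iv.name not in lfc.index or not np.isfinite(lfc.loc[iv.name]):
            continue
        summit = iv.summit if iv.summit is not None else iv.midpoint
        hit = tss_by_chrom.get(iv.chrom)
        if hit is None:
            continue
        tss, cls = hit
        d = np.abs(tss - summit)
        near = d <= window
        if not near.any():
            continue
        if exclusive:
            chosen = [cls[near][np.argmin(d[near])]]
        else:
            chosen = list(np.unique(cls[near]))
        for c in chosen:
            if c in members:
                members[c].append(iv.name)
                values[c].append(float(lfc.loc[iv.name]))
    out = []
    for c in class_order:
        vals = np.array(values[c])
        if len(vals) == 0:
            out.append(
                GroupedFoldChanges(c, [], vals, np.nan, np.nan, warning="empty group")
            )
            continue
        t, p = _one_sample_t(vals)
        out.append(GroupedFoldChanges(c, members[c], vals, t, p))
    return out


def fc_by_distance_to_anchor(
    er_results: pd.DataFrame,
    er_peaks: PeakSet,
    anchors: PeakSet,
    bins: tuple[float, ...] = DEFAULT_BINS,
) -> tuple[list[GroupedFoldChanges], int]:
    """Group TF-peak fold changes by summit-to-summit distance to the nearest
    anchor peak; last bin is open-ended.  Returns the groups and the number
    of peaks excluded for lacking a same-chromosome anchor.
    """
    bins = tuple(bins)
    if bins[0] != 0 or any(b >= c for b, c in zip(bins, bins[1:])):
        raise ValueError("bins must be strictly increasing with first edge 0")
    anchor_summits = {
        chrom: np.array(
            sorted(iv.summit if iv.summit is not None else iv.midpoint for iv in ivs)
        )
        for chrom, ivs in anchors.by_chrom().items()
    }
    lfc = er_results.set_index("feature_id")["log2fc"]
    edges = list(bins) + [np.inf]
    labels = [
        f"[{int(lo / 1000)}kb,{'inf' if np.isinf(hi) else str(int(hi / 1000)) + 'kb'})"
        for lo, hi in zip(edges, edges[1:])
    ]
    members: list[list[str]] = [[] for _ in labels]
    values: list[list[float]] = [[] for _ in labels]
    excluded = 0
    for iv in er_peaks:
        if iv.name not in lfc.index or not np.isfinite(lfc.loc[iv.name]):
            continue
        summits = anchor_summits.get(iv.chrom)
        if summits is None or len(summits) == 0:
            excluded += 1
            continue
        s = iv.summit if iv.summit is not None else iv.midpoint
        i = np.searchsorted(summits, s)
        cands = summits[max(i - 1, 0) : i + 1]
        d = float(np.min(np.abs(cands - s)))
        b = int(np.searchsorted(edges, d, side="right")) - 1
        b = min(b, len(labels) - 1)
        members[b].append(iv.name)
        values[b].append(float(lfc.loc[iv.name]))
    out = []
    for lab, mem, vals in zip(labels, members, values):
        vals = np.array(vals)
        if len(vals) == 0:
            out.append(
                GroupedFoldChanges(lab, [], vals, np.nan, np.nan, warning="empty group")
            )
            continue
        t, p = _one_sample_t(vals)
        out.append(GroupedFoldChanges(lab, mem, vals, t, p))
    return out, excluded


def rank_sum_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum comparison.

    Exact enumeration when n_a + n_b <= 20 and there are no ties; otherwise
    the normal approximation with midrank tie handling and continuity
    correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("rank-sum comparison requires non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif len(pooled) <= 20:
        # exact with ties via permutation over all group assignments
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        obs = res.statistic
        perm = stats.permutation_test(
            (a, b),
            lambda x, y: stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        return float(obs), float(min(perm.pvalue, 1.0))
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)
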