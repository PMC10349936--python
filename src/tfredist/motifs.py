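"""PWM scanning with exact score-distribution p-values and class-wise motif
prevalence testing around peak summits.

Scores are log2 odds of the pseudocount-smoothed position probabilities
against a 0-order background.  P-values come from an exact dynamic program
over the discretized per-position score distributions (the FIMO approach),
with a default bin width of 1/1000 bit so the discretization error is
explicitly bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io_formats import ALPHABET, MotifModel, PeakSet

__all__ = [
    "MotifHit",
    "PrevalenceResult",
    "log_odds_score",
    "ScoreDistribution",
    "score_pvalue_table",
    "scan_intervals",
    "prevalence_test",
    "prevalence_timecourse",
]

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
NEG_INF = float("-inf")


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N etc.) -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def _score_matrix(motif: MotifModel) -> np.ndarray:
    """(length, 4) log2-odds matrix from the smoothed probabilities."""
    p = motif.smoothed_probs()
    return np.log2(p / motif.background[None, :])


def log_odds_score(motif: MotifModel, window: str) -> float:
    """Score one window of exactly motif length, in bits; windows containing
    non-ACGT letters score -inf (excluded from hits)."""
    if len(window) != len(motif):
        raise ValueError(f"window length {len(window)} != motif length {len(motif)}")
    enc = _encode(window)
    if (enc == 4).any():
        return NEG_INF
    M = _score_matrix(motif)
    return float(M[np.arange(len(motif)), enc].sum())


@dataclass
class ScoreDistribution:
    """Exact null distribution of the PWM score under the 0-order background,
    discretized to fixed-width bins."""

    bin_width: float
    offset: int  # score of bin index i is (i + offset) * bin_width
    pmf: np.ndarray
    sf: np.ndarray = field(init=False)  # P(score >= bin lower edge)

    def __post_init__(self) -> None:
        self.sf = np.cumsum(self.pmf[::-1])[::-1]

    @property
    def min_score(self) -> float:
        return self.offset * self.bin_width

    @property
    def max_score(self) -> float:
        return (self.offset + len(self.pmf) - 1) * self.bin_width

    def pvalue(self, score: float) -> float:
        """P(score_null >= score); conservative to within one bin."""
        if score == NEG_INF:
            return 1.0
        idx = int(np.floor(score / self.bin_width + 1e-9)) - self.offset
        if idx <= 0:
            return 1.0
        if idx >= len(self.pmf):
            return 0.0
        return float(self.sf[idx])

    def score_for_pvalue(self, p: float) -> float:
        """Smallest bin edge s with P(score >= s) <= p (inf if unattainable)."""
        idx = np.searchsorted(-self.sf, -p, side="left")
        if idx >= len(self.pmf):
            return float("inf")
        return (idx + self.offset) * self.bin_width


def score_pvalue_table(motif: MotifModel, granularity: int = 1000) -> ScoreDistribution:
    """Exact DP over positions: convolve the discretized per-position score
    distributions under the background.  ``granularity`` is bins per bit
    (default 1000, i.e. 0.001-bit bins)."""
    if granularity < 100:
        raise ValueError("granularity must be >= 100 bins per bit")
    delta = 1.0 / granularity
    M = _score_matrix(motif)
    bins = np.round(M / delta).astype(np.int64)  # (L, 4) integer bin offsets
    bg = motif.background

    lo = int(bins.min(axis=1).sum())
    hi = int(bins.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # start with position 0
    cur_lo = 0
    cur = np.array([1.0])
    for pos in range(M.shape[0]):
        step_lo = int(bins[pos].min())
        step_hi = int(bins[pos].max())
        step = np.zeros(step_hi - step_lo + 1)
        for letter in range(4):
            step[bins[pos, letter] - step_lo] += bg[letter]
        cur = np.convolve(cur, step)
        cur_lo += step_lo
    pmf[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    total = pmf.sum()
    if abs(total - 1.0) > 1e-9:
        pmf = pmf / total
    return ScoreDistribution(bin_width=delta, offset=lo, pmf=pmf)


def scan_intervals(
    motif: MotifModel,
    sequences: Mapping[str, str],
    regions: PeakSet,
    p_threshold: float = 1e-4,
    granularity: int = 1000,
) -> list[MotifHit]:
    """Scan both strands of each region; at each position keep the better
    strand; report hits with p-value <= threshold in genome-absolute,
    0-based half-open coordinates."""
    L = len(motif)
    dist = score_pvalue_table(motif, granularity)
    M_fwd = _score_matrix(motif)
    M_rev = _score_matrix(motif.reverse_complement())
    enc_cache: dict[str, np.ndarray] = {}
    hits: list[MotifHit] = []
    for iv in regions:
        if iv.chrom not in sequences:
            raise ValueError(f"region {iv.name}: no sequence for {iv.chrom}")
        seq = sequences[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"region {iv.name} [{iv.start},{iv.end}) exceeds {iv.chrom} "
                f"length {len(seq)}"
            )
        if iv.chrom not in enc_cache:
            enc_cache[iv.chrom] = _encode(seq)
        enc = enc_cache[iv.chrom][iv.start : iv.end]
        n_pos = len(enc) - L + 1
        if n_pos <= 0:
            continue
        valid = enc < 4
        enc_safe = np.where(valid, enc, 0)
        fwd = np.zeros(n_pos)
        rev = np.zeros(n_pos)
        ok = np.ones(n_pos, dtype=bool)
        for j in range(L):
            col = enc_safe[j : j + n_pos]
            fwd += M_fwd[j, col]
            rev += M_rev[j, col]
            ok &= valid[j : j + n_pos]
        best = np.maximum(fwd, rev)
        strand = np.where(fwd >= rev, "+", "-")
        for i in np.nonzero(ok)[0]:
            p = dist.pvalue(best[i])
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        chrom=iv.chrom,
                        start=iv.start + int(i),
                        end=iv.start + int(i) + L,
                        strand=str(strand[i]),
                        score=float(best[i]),
                        pvalue=p,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


@dataclass
class PrevalenceResult:
    """Class-wise motif prevalence contingency plus Pearson chi-square."""

    table: pd.DataFrame  # index=class, columns=[n_with_motif, n_total]
    window: int
    chi2: float
    df: int
    pvalue: float
    warning: str | None = None

    @property
    def prevalence(self) -> pd.Series:
        return self.table["n_with_motif"] / self.table["n_total"]


def _peaks_with_motif(
    hits: Sequence[MotifHit], peaks: PeakSet, window: int
) -> set[str]:
    """Peak names with >= 1 hit center within summit +/- window."""
    centers: dict[str, np.ndarray] = {}
    for chrom in {h.chrom for h in hits}:
        centers[chrom] = np.array(sorted(h.center for h in hits if h.chrom == chrom))
    with_motif = set()
    for iv in peaks:
        cs = centers.get(iv.chrom)
        if cs is None or len(cs) == 0:
            continue
        summit = iv.summit if iv.summit is not None else iv.midpoint
        lo = np.searchsorted(cs, summit - window, side="left")
        hi = np.searchsorted(cs, summit + window, side="right")
        if hi > lo:
            with_motif.add(iv.name)
    return with_motif


def prevalence_test(
    hits: Sequence[MotifHit],
    peaks: PeakSet,
    classes: Mapping[str, str],
    window: int = 150,
    class_order: Sequence[str] = ("increased", "unchanged", "decreased"),
) -> PrevalenceResult:
    """Pearson chi-square (no continuity correction) of class x has-motif.

    A peak "has" the motif iff at least one hit center lies within
    summit +/- window (default 150 bp).  ``classes`` maps peak name to class.
    """
    with_motif = _peaks_with_motif(hits, peaks, window)
    counts: dict[str, list[int]] = {}
    for iv in peaks:
        cls = classes.get(iv.name)
        if cls is None:
            continue
        row = counts.setdefault(cls, [0, 0])
        row[1] += 1
        if iv.name in with_motif:
            row[0] += 1
    order = [c for c in class_order if c in counts] + sorted(
        set(counts) - set(class_order)
    )
    table = pd.DataFrame(
        {c: counts[c] for c in order}, index=["n_with_motif", "n_total"]
    ).T
    nonempty = table[table["n_total"] > 0]
    if len(nonempty) < 2:
        raise ValueError("prevalence test needs >= 2 non-empty classes")
    cont = np.column_stack(
        [nonempty["n_with_motif"], nonempty["n_total"] - nonempty["n_with_motif"]]
    )
    warning = None
    if (cont.sum(axis=0) == 0).any():
        # every peak has the motif (or none does): no association measurable
        chi2, df, p = 0.0, len(nonempty) - 1, 1.0
        warning = "degenerate table: a has-motif column is all zero"
    else:
        res = chi2_contingency(cont, correction=False)
        chi2, df, p = float(res.statistic), int(res.dof), float(res.pvalue)
        if (res.expected_freq < 1).any():
            warning = "expected cell count < 1; chi-square approximation unreliable"
    return PrevalenceResult(
        table=table,
        window=window,
        chi2=chi2,
        df=df,
        pvalue=p,
        warning=warning,
    )


def prevalence_timecourse(
    hits: Sequence[MotifHit],
    classifications: Mapping[object, Mapping[str, str]],
    peaks: PeakSet,
    window: int = 150,
    class_order: Sequence[str] = ("increased", "unchanged", "decreased"),
) -> pd.DataFrame:
    """Motif prevalence per (timepoint, class); empty classes give NA.

    ``classifications`` maps timepoint -> {peak name -> class}, each
    classified against the same control condition.
    """
    with_motif = _peaks_with_motif(hits, peaks, window)
    rows = {}
    for tp in sorted(classifications):
        classes = classifications[tp]
        cells = {}
        for cls in class_order:
            members = [n for n, c in classes.items() if c == cls]
            if not members:
                cells[cls] = np.nan
            else:
                cells[cls] = sum(1 for n in members if n in with_motif) / len(members)
        rows[tp] = cells
    return pd.DataFrame.from_dict(rows, orient="index")[list(class_order)]
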