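"""Gene-set machinery: Fisher over-representation, weighted running-sum GSEA
with permutation p-values, cohort z-score ranking, and the two-tailed regulon
differential enrichment score (dES) for per-patient activity classification.

Sign conventions (the error-prone point, pinned here and tested):

* The regulon's **activated** half contains genes UP upon depletion of the
  anchor TF — i.e. the TF's *repressed* targets.  The **repressed** half
  contains genes DOWN upon depletion — the TF's *activated* targets.
* A patient has **high** TF activity iff the depletion-up half is negatively
  enriched (ES < 0, significant) AND the depletion-down half is positively
  enriched (ES > 0, significant) in that patient's cohort-scaled expression
  ranking: an active repressor keeps its repressed targets low and its
  activated targets high.  **low** is the mirror image; everything else is
  **intermediate**.
* dES = ES(activated half) - ES(repressed half); high-activity patients
  therefore sit at the negative end of the dES ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffcount import bh_adjust

__all__ = [
    "GeneSet",
    "Regulon",
    "read_gmt",
    "write_gmt",
    "fisher_ora",
    "gsea_es",
    "gsea_permutation_p",
    "cohort_zscore_rank",
    "patient_activity",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class Regulon:
    """Paired depletion-response halves of a TF's primary target genes."""

    activated: GeneSet  # up upon depletion => TF-repressed targets
    repressed: GeneSet  # down upon depletion => TF-activated targets

    def __post_init__(self) -> None:
        overlap = self.activated.genes & self.repressed.genes
        if overlap:
            raise ValueError(f"regulon halves overlap: {sorted(overlap)[:5]}")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with < 3 fields: {line[:60]!r}")
        sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na"] + sorted(s.genes)) + "\n")


# ---------------------------------------------------------------------------
# Over-representation


def fisher_ora(
    hits: GeneSet,
    universe: Iterable[str],
    sets: Sequence[GeneSet],
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of ``hits`` in each set.

    Each set is first intersected with the universe; the p-value is the
    hypergeometric upper tail of the hits-in-set count; BH across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits.genes <= universe:
        raise ValueError("hits must be a subset of the universe")
    N = len(universe)
    n = len(hits.genes)
    rows = []
    for s in sets:
        members = s.genes & universe
        K = len(members)
        k = len(hits.genes & members)
        p = stats.hypergeom.sf(k - 1, N, K, n) if K else 1.0
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((s.name, k, K, n, N, odds, p))
    df = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "n_hits", "n_universe", "odds_ratio", "pvalue"]
    )
    df["padj"] = bh_adjust(df["pvalue"])
    return df


# ---------------------------------------------------------------------------
# GSEA


def _running_sum(
    is_hit: np.ndarray, weights: np.ndarray, exponent: float
) -> np.ndarray:
    """Classic weighted KS running sum over a ranking.

    Hits step up by |w|^exponent / sum over hits of |w|^exponent; misses step
    down by 1/(N - |S|).  Starts implicitly at 0 and returns to 0.
    """
    N = len(is_hit)
    S = int(is_hit.sum())
    if S == 0 or S == N:
        raise ValueError("gene set must be a proper non-empty subset of the ranking")
    w = np.abs(weights) ** exponent
    hit_mass = w * is_hit
    denom = hit_mass.sum()
    if denom == 0:  # all hit weights zero: fall back to equal steps
        hit_mass = is_hit.astype(float)
        denom = float(S)
    steps = hit_mass / denom - (~is_hit.astype(bool)) / (N - S)
    return np.cumsum(steps)


def gsea_es(
    ranked: Sequence[str],
    weights: Sequence[float],
    gene_set: GeneSet,
    exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score of ``gene_set`` in a ranked, weighted gene list.

    Returns (ES, running sum); ES is the signed maximum deviation of the
    running sum from 0 and lies in [-1, 1].
    """
    ranked = list(ranked)
    weights = np.asarray(weights, dtype=float)
    if len(ranked) != len(weights):
        raise ValueError("ranked ids and weights differ in length")
    is_hit = np.fromiter((g in gene_set.genes for g in ranked), bool, len(ranked))
    rs = _running_sum(is_hit, weights, exponent)
    i = int(np.argmax(np.abs(rs)))
    return float(rs[i]), rs


def _es_from_positions(
    positions: np.ndarray, abs_w_pow: np.ndarray, N: int
) -> np.ndarray:
    """Vectorized ES for many hit-position sets.

    ``positions``: (n_sets, S) sorted 0-based ranks of the hits;
    ``abs_w_pow``: |w|^exponent for the full ranking.  The running-sum
    extremum over a ranking is attained either at a hit or just before one,
    so only 2S candidate values per set need checking.
    """
    n_sets, S = positions.shape
    w = abs_w_pow[positions]  # (n_sets, S)
    denom = w.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    cum_hit = np.cumsum(w, axis=1) / denom
    ranks = positions + 1  # 1-based
    misses_before_incl = ranks - np.arange(1, S + 1)  # misses up to & incl. this hit
    miss_step = 1.0 / (N - S)
    at_hit = cum_hit - misses_before_incl * miss_step
    before_hit = np.concatenate(
        [np.zeros((n_sets, 1)), cum_hit[:, :-1]], axis=1
    ) - misses_before_incl * miss_step
    cand = np.concatenate([at_hit, before_hit], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_sets), idx]


def _random_subsets(
    rng: np.random.Generator, n_sets: int, N: int, S: int
) -> np.ndarray:
    """(n_sets, S) sorted random S-subsets of 0..N-1 (uniform, no replacement)."""
    keys = rng.random((n_sets, N))
    positions = np.argpartition(keys, S, axis=1)[:, :S]
    positions.sort(axis=1)
    return positions


def gsea_permutation_p(
    ranked: Sequence[str],
    weights: Sequence[float],
    gene_set: GeneSet,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Gene-label permutation p-value for the enrichment score.

    Null ES values come from random same-size gene sets on the same ranking;
    p = (1 + #{same-sign null ES with |ES| >= |ES_obs|}) /
        (1 + #{same-sign null ES}).  Returns (ES_obs, p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = list(ranked)
    weights = np.asarray(weights, dtype=float)
    es_obs, _ = gsea_es(ranked, weights, gene_set, exponent)
    N = len(ranked)
    S = len(gene_set.genes & set(ranked))
    rng = np.random.default_rng(seed)
    abs_w_pow = np.abs(weights) ** exponent
    positions = _random_subsets(rng, n_perm, N, S)
    es_null = _es_from_positions(positions, abs_w_pow, N)
    same_sign = es_null * np.sign(es_obs) > 0 if es_obs != 0 else np.ones(n_perm, bool)
    extreme = same_sign & (np.abs(es_null) >= abs(es_obs) - 1e-12)
    p = (1 + int(extreme.sum())) / (1 + int(same_sign.sum()))
    return es_obs, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Cohort activity


def cohort_zscore_rank(
    expression: pd.DataFrame, patient_id: str
) -> tuple[list[str], np.ndarray, int]:
    """Rank genes by a patient's expression scaled against the whole cohort.

    z = (x_patient - mean_cohort)/sd_cohort per gene; genes ordered by z
    descending with gene id as the stable tie-break.  Zero-variance genes
    are dropped; their count is returned.
    """
    if expression.shape[1] < 3:
        raise ValueError("cohort ranking needs >= 3 patients")
    if patient_id not in expression.columns:
        raise ValueError(f"unknown patient {patient_id!r}")
    mean = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    z = (expression.loc[keep, patient_id] - mean[keep]) / sd[keep]
    order = sorted(z.index, key=lambda g: (-z.loc[g], g))
    return order, z.loc[order].to_numpy(), n_dropped


def _patient_es_and_p(
    z_sorted: np.ndarray,
    hit_positions: np.ndarray,
    exponent: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    N = len(z_sorted)
    S = len(hit_positions)
    abs_w_pow = np.abs(z_sorted) ** exponent
    es_obs = float(
        _es_from_positions(hit_positions[None, :], abs_w_pow, N)[0]
    )
    positions = _random_subsets(rng, n_perm, N, S)
    es_null = _es_from_positions(positions, abs_w_pow, N)
    same_sign = es_null * np.sign(es_obs) > 0 if es_obs != 0 else np.ones(n_perm, bool)
    extreme = same_sign & (np.abs(es_null) >= abs(es_obs) - 1e-12)
    p = (1 + int(extreme.sum())) / (1 + int(same_sign.sum()))
    return es_obs, float(min(p, 1.0))


def patient_activity(
    expression: pd.DataFrame,
    regulon: Regulon,
    exponent: float = 1.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Two-tailed regulon activity (dES) and class for every patient.

    For each patient, genes are ranked by cohort z-score; each regulon half
    gets an ES and a gene-label permutation p; dES = ES(activated half) -
    ES(repressed half).  Class (see module docstring): high iff ES_up < 0 and
    ES_down > 0, both p <= alpha; low is the mirror; else intermediate.
    Returned frame is sorted by dES ascending (high activity first).
    """
    genes = set(expression.index)
    up = regulon.activated.genes & genes
    down = regulon.repressed.genes & genes
    if len(up) < min_overlap or len(down) < min_overlap:
        raise ValueError(
            f"regulon overlap with expressed genes too small "
            f"({len(up)} up, {len(down)} down; need >= {min_overlap})"
        )
    rng = np.random.default_rng(seed)
    # cohort scaling computed once; per-patient ranking is an argsort of one column
    mean = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=0)
    keep = sd > 0
    zmat = expression.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    gene_ids = np.array(zmat.index)
    id_order = np.argsort(gene_ids, kind="mergesort")  # tie-break by gene id
    up_mask = np.isin(gene_ids, list(up))
    down_mask = np.isin(gene_ids, list(down))
    rows = []
    for pid in expression.columns:
        z = zmat[pid].to_numpy()
        order = id_order[np.argsort(-z[id_order], kind="mergesort")]
        z_sorted = z[order]
        pos_up = np.nonzero(up_mask[order])[0]
        pos_down = np.nonzero(down_mask[order])[0]
        es_up, p_up = _patient_es_and_p(z_sorted, pos_up, exponent, n_perm, rng)
        es_down, p_down = _patient_es_and_p(z_sorted, pos_down, exponent, n_perm, rng)
        des = es_up - es_down
        if es_up < 0 and p_up <= alpha and es_down > 0 and p_down <= alpha:
            cls = "high"
        elif es_up > 0 and p_up <= alpha and es_down < 0 and p_down <= alpha:
            cls = "low"
        else:
            cls = "intermediate"
        rows.append((pid, es_up, p_up, es_down, p_down, des, cls))
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "es_activated_set",
            "p_activated",
            "es_repressed_set",
            "p_repressed",
            "dES",
            "class",
        ],
    )
    return df.sort_values("dES", kind="mergesort").reset_index(drop=True)
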