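"""Differential testing of count matrices over a depletion time course.

The model is a negative-binomial GLM with log link, variance mu + alpha*mu^2,
per-sample size factors as offsets, and a mean-dispersion trend with shrinkage
toward it.  The approach is DESeq2-inspired but deliberately not DESeq2-
identical: no outlier handling or independent filtering, moment-based (not
Cox-Reid) dispersion estimation, and normal-prior fold-change shrinkage.
Directional calls at an FDR threshold (default 0.1) are the quantity of
interest downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix

__all__ = [
    "DispersionModel",
    "size_factors",
    "estimate_dispersions",
    "wald_test",
    "lrt_timecourse",
    "shrink_lfc",
    "bh_adjust",
    "classify_features",
    "differential_analysis",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "feature_id",
    "base_mean",
    "log2fc",
    "log2fc_se",
    "stat",
    "pvalue",
    "padj",
    "shrunken_log2fc",
    "class",
]

LN2 = np.log(2.0)


@dataclass
class DispersionModel:
    """Per-feature NB dispersions: raw moment estimates, a log-log trend on
    the mean, and trend-shrunk values used by the tests."""

    raw: pd.Series
    trend_coef: tuple[float, float]  # (intercept, slope) of log alpha ~ log mean
    shrunk: pd.Series
    prior_weight: float
    floor: float

    def alpha(self, feature_id: str) -> float:
        return float(self.shrunk.loc[feature_id])


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, s_j is the median over features i (positive in every
    sample) of k_ij / geomean_i; the vector is then rescaled so its geometric
    mean is 1.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; filter low-coverage "
            "features before normalization"
        )
    sub = arr[all_positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=mat.columns, name="size_factor")


def estimate_dispersions(
    counts: CountMatrix,
    factors: pd.Series,
    prior_weight: float | None = None,
    floor: float = 1e-8,
) -> DispersionModel:
    """Moment-based NB dispersions with a mean trend and shrinkage toward it.

    Raw per-feature alpha = max(floor, (var - mean)/mean^2) using replicate
    groups sharing (condition, timepoint); the trend is an OLS fit of
    log(alpha) on log(mean) with a smearing-corrected intercept; the final
    estimate is exp of the prior-weighted average of log raw and log trend.

    ``prior_weight`` is the weight on the trend.  The default (None) sets it
    adaptively from precisions: the sampling variance of a log moment
    dispersion with m residual df is ~trigamma(m/2), and the prior variance
    is the observed residual spread around the trend minus that, floored at
    0.05 — so noisy raw estimates (few replicates) lean on the trend and
    genuinely spread dispersions keep their per-feature signal.
    """
    norm = counts.counts.div(factors, axis=1)
    meta = counts.sample_meta
    groups = meta.groupby(["condition", "timepoint"], sort=True).groups
    rep_groups = {k: list(v) for k, v in groups.items() if len(v) >= 2}
    if not rep_groups:
        raise ValueError("no condition/timepoint group has >= 2 replicates")

    # pooled within-group variance and grand mean on normalized counts
    n_tot = 0
    ss = np.zeros(len(norm))
    for samples in rep_groups.values():
        block = norm[samples].to_numpy()
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        n_tot += len(samples)
    var = ss / max(n_tot - len(rep_groups), 1)
    mean = norm.to_numpy().mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mean) / mean**2
    raw = np.where(np.isfinite(raw), raw, floor)
    raw = np.maximum(raw, floor)
    raw_s = pd.Series(raw, index=norm.index, name="raw_dispersion")

    usable = (mean > 0) & (raw > floor)
    resid_var = None
    if usable.sum() >= 2:
        x = np.log(mean[usable])
        y = np.log(raw[usable])
        slope, intercept = np.polyfit(x, y, 1)
        # retransformation (smearing) correction: the OLS fit estimates
        # E[log alpha]; shift the intercept by half the residual variance so
        # exp(trend) targets E[alpha] instead of the geometric mean
        resid = y - (intercept + slope * x)
        resid_var = float(np.var(resid))
        intercept += 0.5 * resid_var
    else:  # degenerate: flat trend at the raw median
        intercept, slope = float(np.log(max(np.median(raw), floor))), 0.0
    with np.errstate(divide="ignore"):
        log_trend = intercept + slope * np.log(np.maximum(mean, 1e-12))
    trend = np.maximum(np.exp(log_trend), floor)

    if prior_weight is None:
        m = max(n_tot - len(rep_groups), 1)
        sampling_var = float(special.polygamma(1, m / 2.0))
        spread = resid_var if resid_var is not None else sampling_var
        prior_var = max(spread - sampling_var, 0.05)
        w = sampling_var / (sampling_var + prior_var)
    else:
        w = prior_weight
    shrunk = np.exp((1.0 - w) * np.log(raw) + w * np.log(trend))
    shrunk = np.maximum(shrunk, floor)
    return DispersionModel(
        raw=raw_s,
        trend_coef=(float(intercept), float(slope)),
        shrunk=pd.Series(shrunk, index=norm.index, name="dispersion"),
        prior_weight=w,
        floor=floor,
    )


def _fit_nb_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    """Fit one NB GLM by IRLS; returns the statsmodels results or None."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
        if not np.all(np.isfinite(res.params)):
            return None
        return res
    except Exception:
        return None


def wald_test(
    counts: CountMatrix,
    factors: pd.Series,
    dispersions: DispersionModel,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Per-feature NB Wald test of condition a vs b (log2fc = log2(a/b)).

    ``contrast=(a, b)`` compares condition/timepoint label a against b, e.g.
    ("dTAG", "DMSO").  The labels are matched first against the condition
    column, then against the timepoint column (as strings), so a timepoint
    pair like ("30", "0") tests one treated timepoint against the control.
    Features with all-zero counts across the used samples get NA statistics.
    """
    a, b = contrast
    meta = counts.sample_meta
    cond = meta["condition"].astype(str)
    tp = meta["timepoint"].astype(str)
    if str(a) in set(cond) and str(b) in set(cond):
        labels = cond
    elif str(a) in set(tp) and str(b) in set(tp):
        labels = tp
    else:
        raise ValueError(f"contrast {contrast} not found in condition or timepoint labels")
    samples = list(labels.index[labels.isin([str(a), str(b)])])
    if len(samples) < 2:
        raise ValueError("need >= 2 samples across the two contrast levels")
    sub = counts.counts[samples]
    sf = factors.loc[samples].to_numpy(dtype=float)
    is_a = (labels.loc[samples] == str(a)).to_numpy()
    X = np.column_stack([np.ones(len(samples)), is_a.astype(float)])
    offset = np.log(sf)

    rows = []
    for fid, y in zip(sub.index, sub.to_numpy()):
        base_mean = float((y / sf).mean())
        if y.sum() == 0:
            rows.append((fid, base_mean, np.nan, np.nan, np.nan, np.nan))
            continue
        res = _fit_nb_glm(y.astype(float), X, offset, dispersions.alpha(fid))
        if res is None:
            logger.warning("NB GLM did not converge for feature %s", fid)
            rows.append((fid, base_mean, np.nan, np.nan, np.nan, np.nan))
            continue
        lfc = res.params[1] / LN2
        se = res.bse[1] / LN2
        z = lfc / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append((fid, base_mean, lfc, se, z, p))

    df = pd.DataFrame(
        rows, columns=["feature_id", "base_mean", "log2fc", "log2fc_se", "stat", "pvalue"]
    )
    df["padj"] = np.nan
    df["shrunken_log2fc"] = np.nan
    df["class"] = "unchanged"
    return df[RESULT_COLUMNS]


def lrt_timecourse(
    counts: CountMatrix,
    factors: pd.Series,
    dispersions: DispersionModel,
) -> pd.DataFrame:
    """Likelihood-ratio test of any change over the time course.

    Full model: intercept + timepoint factor; reduced: intercept only.  The
    statistic 2*(ll_full - ll_reduced) is referred to chi-square with
    (#timepoints - 1) df.  Because the LRT carries no single effect size, the
    reported log2fc/se are the treated-timepoint coefficient of largest
    magnitude, which gives downstream classification a direction.
    """
    meta = counts.sample_meta
    tps = sorted(meta["timepoint"].unique())
    if len(tps) < 2:
        raise ValueError("time-course LRT needs >= 2 timepoints")
    df_chi2 = len(tps) - 1
    samples = list(meta.index)
    sf = factors.loc[samples].to_numpy(dtype=float)
    offset = np.log(sf)
    tp_arr = meta["timepoint"].to_numpy()
    X_full = np.column_stack(
        [np.ones(len(samples))] + [(tp_arr == t).astype(float) for t in tps[1:]]
    )
    X_red = np.ones((len(samples), 1))
    sub = counts.counts[samples]

    rows = []
    for fid, y in zip(sub.index, sub.to_numpy()):
        base_mean = float((y / sf).mean())
        if y.sum() == 0:
            rows.append((fid, base_mean, np.nan, np.nan, np.nan, np.nan))
            continue
        alpha = dispersions.alpha(fid)
        full = _fit_nb_glm(y.astype(float), X_full, offset, alpha)
        red = _fit_nb_glm(y.astype(float), X_red, offset, alpha)
        if full is None or red is None:
            logger.warning("NB GLM did not converge for feature %s", fid)
            rows.append((fid, base_mean, np.nan, np.nan, np.nan, np.nan))
            continue
        stat = max(2.0 * (full.llf - red.llf), 0.0)
        p = stats.chi2.sf(stat, df_chi2)
        coefs = full.params[1:] / LN2
        ses = full.bse[1:] / LN2
        k = int(np.argmax(np.abs(coefs)))
        rows.append((fid, base_mean, coefs[k], ses[k], stat, p))

    df = pd.DataFrame(
        rows, columns=["feature_id", "base_mean", "log2fc", "log2fc_se", "stat", "pvalue"]
    )
    df["padj"] = np.nan
    df["shrunken_log2fc"] = np.nan
    df["class"] = "unchanged"
    return df[RESULT_COLUMNS]


def shrink_lfc(results: pd.DataFrame) -> pd.DataFrame:
    """Normal-prior shrinkage of log2 fold changes.

    The prior variance tau^2 is moment-matched on the MLE fold changes:
    tau^2 = max(0, var(lfc) - mean(se^2)); each estimate is scaled by
    tau^2 / (tau^2 + se^2).  With tau^2 = 0 every shrunken value is 0.
    """
    out = results.copy()
    ok = out["log2fc"].notna() & out["log2fc_se"].notna()
    if ok.sum() == 0:
        out["shrunken_log2fc"] = np.nan
        return out
    lfc = out.loc[ok, "log2fc"].to_numpy()
    se2 = out.loc[ok, "log2fc_se"].to_numpy() ** 2
    tau2 = max(0.0, float(np.var(lfc)) - float(np.mean(se2)))
    out.loc[ok, "shrunken_log2fc"] = lfc * tau2 / (tau2 + se2) if tau2 > 0 else 0.0
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NA entries are excluded from m
    and returned as NA."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return out
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values outside [0, 1]")
    out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def classify_features(results: pd.DataFrame, fdr: float = 0.1) -> pd.DataFrame:
    """Directional classes at an FDR threshold.

    increased iff padj < fdr and log2fc > 0; decreased iff padj < fdr and
    log2fc < 0; everything else (including NA padj) is unchanged.
    """
    out = results.copy()
    padj = out["padj"]
    lfc = out["log2fc"]
    cls = np.full(len(out), "unchanged", dtype=object)
    sig = padj.notna() & (padj < fdr)
    cls[(sig & (lfc > 0)).to_numpy()] = "increased"
    cls[(sig & (lfc < 0)).to_numpy()] = "decreased"
    out["class"] = cls
    return out


def differential_analysis(
    counts: CountMatrix,
    contrast: tuple[str, str] | None = None,
    fdr: float = 0.1,
    test: str = "wald",
) -> pd.DataFrame:
    """Convenience pipeline: size factors -> dispersions -> test -> BH ->
    shrinkage -> classification.  ``test`` is "wald" (needs ``contrast``) or
    "lrt" (all timepoints)."""
    sf = size_factors(counts)
    disp = estimate_dispersions(counts, sf)
    if test == "wald":
        if contrast is None:
            raise ValueError("wald test requires a contrast")
        res = wald_test(counts, sf, disp, contrast)
    elif test == "lrt":
        res = lrt_timecourse(counts, sf, disp)
    else:
        raise ValueError(f"unknown test {test!r}")
    res["padj"] = bh_adjust(res["pvalue"])
    res = shrink_lfc(res)
    return classify_features(res, fdr=fdr)
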