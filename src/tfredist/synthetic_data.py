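"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate a rapid-depletion study design: a repressive anchor TF
(TRPS1-like) whose acute degradation opens proximal chromatin, a second TF
(ER-like) that redistributes from anchor-distal to anchor-proximal sites,
genes whose response class tracks proximity to opened regions, a patient
cohort whose latent anchor-TF activity drives a regulon and hazard, and
exponential cell growth with a treatment-modified rate.

Every generator is a pure function of its config (including the seed): one
independent RNG stream per generator, derived from the master seed with a
fixed label, so adding a generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet, Regulon
from .io_formats import (
    ALPHABET,
    CountMatrix,
    GeneAnnotation,
    GenomicInterval,
    MotifModel,
    PeakSet,
    SurvivalRecord,
)

__all__ = [
    "SimulationConfig",
    "GeometryConfig",
    "CohortConfig",
    "GrowthConfig",
    "TruthTable",
    "SyntheticLandscape",
    "SyntheticCohort",
    "default_gata_motif",
    "default_er_halfsite_motif",
    "simulate_peak_landscape",
    "simulate_timecourse_counts",
    "simulate_cohort",
    "simulate_growth",
]

# fixed stream labels: adding a generator cannot perturb the others
_STREAMS = {"landscape": 11, "counts": 12, "cohort": 13, "growth": 14}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], extra, seed])


def default_gata_motif(p: float = 0.95) -> MotifModel:
    """Synthetic GATA-family PWM (extended AGATAA core), an in-repo stand-in
    for a database GATA matrix.  Ten informative positions so that strong
    matches clear a FIMO-style 1e-4 p-value threshold."""
    return _consensus_motif("GATA_synthetic", "AAGATAAGAT", p)


def default_er_halfsite_motif(p: float = 0.95) -> MotifModel:
    """Synthetic nuclear-receptor half-site PWM (AGGTCA core with flanks)."""
    return _consensus_motif("ER_halfsite_synthetic", "CAGGTCACAG", p)


def _consensus_motif(name: str, consensus: str, p: float) -> MotifModel:
    q = (1.0 - p) / 3.0
    probs = np.full((len(consensus), 4), q)
    for i, b in enumerate(consensus):
        probs[i, ALPHABET.index(b)] = p
    return MotifModel(name=name, probs=probs)


@dataclass
class GeometryConfig:
    """Distance-effect coupling of the planted landscape (bp units)."""

    peak_spacing: int = 3000
    peak_width: int = 400
    trps1_width: int = 300
    trps1_frac_at_increased: float = 0.9
    trps1_frac_at_other: float = 0.05
    er_n_peaks: int = 300
    er_width: int = 300
    er_frac_proximal: float = 0.5
    er_proximal_offset: int = 800  # max |ER summit - anchor summit| when proximal
    er_distal_gap: int = 200_000  # separation of the distal ER region
    er_lfc_proximal: float = 0.8
    er_lfc_distal: float = -0.8
    er_lfc_sd: float = 0.3
    gene_near_min: int = 500
    gene_near_max: int = 5000
    margin: int = 10_000


@dataclass
class CohortConfig:
    n_patients: int = 200
    n_genes: int = 1000
    regulon_size: int = 100  # genes per regulon half
    beta: float = 2.0  # latent activity -> expression shift (sd units)
    gamma: float = 1.0  # latent activity -> log hazard
    baseline_hazard: float = 0.01  # events per month
    censor_rate: float = 0.005  # per month, independent
    max_followup: float = 360.0  # months, administrative cap


@dataclass
class GrowthConfig:
    days: tuple = (0, 3, 7, 10, 14)
    n_replicates: int = 4
    n0: float = 12_500.0  # cells plated
    rate_control: float = 0.35  # per day (~2-day doubling)
    rate_treated: float = 0.25
    noise_sd: float = 0.1  # lognormal sd of counting noise
    conditions: tuple = ("DMSO", "dTAG")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study-design defaults."""

    seed: int = 0
    n_peaks: int = 2000
    n_genes: int = 600
    timepoints: tuple = (0, 30, 60, 120, 240, 1440)  # minutes; 0 = vehicle
    n_replicates: int = 4
    frac_increased: float = 0.25
    frac_decreased: float = 0.10
    frac_secondary: float = 0.4  # of increased peaks: late-onset, motif-poor
    secondary_onsets: tuple = (240, 1440)
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    dispersion: float = 0.05
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    size_factor_sd: float = 0.2
    motif_enrichment: dict = field(
        default_factory=lambda: {"increased": 0.8, "unchanged": 0.2, "decreased": 0.2}
    )
    er_motif_enrichment: dict = field(
        default_factory=lambda: {"increased": 0.6, "unchanged": 0.2, "decreased": 0.6}
    )
    frac_genes_activated: float = 0.25
    frac_genes_repressed: float = 0.25
    genome_size: int | None = None  # None: sized to fit the requested peaks
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)

    def __post_init__(self) -> None:
        for name in ("frac_increased", "frac_decreased"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_increased + self.frac_decreased > 1:
            raise ValueError("class fractions sum to > 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name in ("n_peaks", "n_genes", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cohort.regulon_size > self.cohort.n_genes // 2:
            raise ValueError("regulon halves must fit in half the cohort genes")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key, sub in (("geometry", GeometryConfig), ("cohort", CohortConfig), ("growth", GrowthConfig)):
            if key in d and isinstance(d[key], Mapping):
                d[key] = sub(**d[key])
        for key in ("timepoints", "secondary_onsets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth of every planted effect, for parameter-recovery tests."""

    features: pd.DataFrame | None = None  # indexed by feature_id
    genes: pd.DataFrame | None = None
    patients: pd.DataFrame | None = None
    timepoints: tuple = ()

    def lfc_at(self, timepoint: int, kind: str | None = None) -> pd.Series:
        col = f"lfc_t{timepoint}"
        df = self.features
        if kind is not None:
            df = df[df["kind"] == kind]
        return df[col]

    @classmethod
    def from_planted_lfc(
        cls,
        feature_ids: Sequence[str],
        timepoints: Sequence[int],
        lfc: np.ndarray,
        baseline_mean: np.ndarray | None = None,
        seed: int = 0,
        baseline_log_mean: float = 5.0,
        baseline_log_sd: float = 1.0,
    ) -> "TruthTable":
        """Build a feature-level truth directly from a planted log2FC matrix
        (features x timepoints); convenient for calibration studies that do
        not need a genomic landscape."""
        lfc = np.asarray(lfc, dtype=float)
        if lfc.shape != (len(feature_ids), len(timepoints)):
            raise ValueError("lfc must be (n_features, n_timepoints)")
        if baseline_mean is None:
            rng = np.random.default_rng([_STREAMS["counts"], 99, seed])
            baseline_mean = np.exp(
                rng.normal(baseline_log_mean, baseline_log_sd, len(feature_ids))
            )
        df = pd.DataFrame(index=pd.Index(feature_ids, name="feature_id"))
        df["kind"] = "feature"
        df["baseline_mean"] = baseline_mean
        maxabs = np.abs(lfc).max(axis=1)
        cls_arr = np.where(
            maxabs == 0,
            "unchanged",
            np.where(lfc[np.arange(len(lfc)), np.abs(lfc).argmax(axis=1)] > 0, "increased", "decreased"),
        )
        df["class"] = cls_arr
        for j, tp in enumerate(timepoints):
            df[f"lfc_t{tp}"] = lfc[:, j]
        return cls(features=df, timepoints=tuple(timepoints))


@dataclass
class SyntheticLandscape:
    atac: PeakSet
    trps1: PeakSet
    er: PeakSet
    sequences: dict
    genes: GeneAnnotation
    truth: TruthTable
    config: SimulationConfig


def _plant(seq_arr: np.ndarray, pos: int, motif: MotifModel, rng: np.random.Generator) -> None:
    """Write one sampled motif instance into the sequence at pos."""
    draws = np.array(
        [rng.choice(4, p=row / row.sum()) for row in motif.probs]
    )
    seq_arr[pos : pos + len(motif)] = draws


def simulate_peak_landscape(config: SimulationConfig) -> SyntheticLandscape:
    """Generate the full synthetic genomic landscape.

    One synthetic chromosome carries an accessibility-peak region (with the
    anchor-TF peaks and anchor-proximal second-TF sites interleaved) and,
    beyond a large gap, a region of anchor-distal second-TF sites.  Motif
    instances are planted around summits with class-dependent probability;
    gene TSSs of the activated class are placed near primary increased peaks.
    """
    geo = config.geometry
    rng = _rng(config.seed, "landscape")
    n = config.n_peaks
    if geo.peak_spacing < geo.peak_width:
        raise ValueError("peak spacing below peak width: peaks exceed genome capacity")

    chrom = "chrS"
    region_a_len = geo.margin + n * geo.peak_spacing + geo.margin
    er_n_distal = geo.er_n_peaks - round(geo.er_n_peaks * geo.er_frac_proximal)
    region_b_start = region_a_len + geo.er_distal_gap
    genome_len = region_b_start + (er_n_distal + 1) * geo.peak_spacing + geo.margin
    if config.genome_size is not None:
        if config.genome_size < genome_len:
            raise ValueError(
                f"requested peaks need {genome_len} bp at minimum spacing but "
                f"genome_size={config.genome_size}"
            )
        genome_len = config.genome_size
    seq_arr = rng.integers(0, 4, genome_len, dtype=np.int8)

    # --- accessibility peaks with classes and kinetic onsets
    n_inc = round(n * config.frac_increased)
    n_dec = round(n * config.frac_decreased)
    classes = np.array(
        ["increased"] * n_inc
        + ["decreased"] * n_dec
        + ["unchanged"] * (n - n_inc - n_dec)
    )
    rng.shuffle(classes)
    jitter = rng.integers(-geo.peak_spacing // 4, geo.peak_spacing // 4 + 1, n)
    summits = geo.margin + np.arange(n) * geo.peak_spacing + geo.peak_spacing // 2 + jitter
    half_w = geo.peak_width // 2

    magnitudes = np.abs(rng.normal(config.lfc_mean, config.lfc_sd, n))
    lfc_full = np.where(
        classes == "increased", magnitudes, np.where(classes == "decreased", -magnitudes, 0.0)
    )
    onsets = np.full(n, config.timepoints[1] if len(config.timepoints) > 1 else 30)
    inc_idx = np.nonzero(classes == "increased")[0]
    secondary = rng.random(len(inc_idx)) < config.frac_secondary
    onsets[inc_idx[secondary]] = rng.choice(config.secondary_onsets, secondary.sum())
    primary = np.ones(n, dtype=bool)
    primary[inc_idx[secondary]] = False

    baselines = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))

    gata = default_gata_motif()
    er_motif = default_er_halfsite_motif()
    planted_gata = np.zeros(n, dtype=bool)
    planted_er = np.zeros(n, dtype=bool)
    atac_ivs = []
    for i in range(n):
        name = f"atac_{i + 1}"
        s = int(summits[i])
        atac_ivs.append(
            GenomicInterval(chrom, s - half_w, s + half_w, name, 0.0, ".", s)
        )
        cls = classes[i]
        p_gata = config.motif_enrichment.get(
            cls if primary[i] else "unchanged", 0.0
        )
        if rng.random() < p_gata:
            off = int(rng.integers(-75, -len(gata)))
            _plant(seq_arr, s + off, gata, rng)
            planted_gata[i] = True
        p_er = config.er_motif_enrichment.get(cls, 0.0)
        if rng.random() < p_er:
            off = int(rng.integers(5, 75 - len(er_motif)))
            _plant(seq_arr, s + off, er_motif, rng)
            planted_er[i] = True

    # --- anchor-TF peaks at (mostly) increased accessibility peaks
    trps1_ivs = []
    trps1_summits = []
    k = 0
    for i in range(n):
        frac = (
            geo.trps1_frac_at_increased
            if classes[i] == "increased" and primary[i]
            else geo.trps1_frac_at_other
        )
        if rng.random() < frac:
            k += 1
            s = int(summits[i] + rng.integers(-50, 51))
            hw = geo.trps1_width // 2
            trps1_ivs.append(
                GenomicInterval(chrom, s - hw, s + hw, f"trps1_{k}", 0.0, ".", s)
            )
            trps1_summits.append(s)
    trps1_summits = np.array(sorted(trps1_summits))

    # --- second-TF peaks: proximal to anchors gain, distal lose
    n_er = geo.er_n_peaks
    n_prox = round(n_er * geo.er_frac_proximal)
    er_rows = []
    er_ivs = []
    hw = geo.er_width // 2
    used = set()
    for j in range(n_prox):
        anchor = int(trps1_summits[rng.integers(0, len(trps1_summits))])
        while True:
            off = int(rng.integers(-geo.er_proximal_offset, geo.er_proximal_offset + 1))
            s = anchor + off
            if s not in used:
                used.add(s)
                break
        lfc = rng.normal(geo.er_lfc_proximal, geo.er_lfc_sd)
        er_ivs.append(GenomicInterval(chrom, s - hw, s + hw, f"er_{j + 1}", 0.0, ".", s))
        er_rows.append((f"er_{j + 1}", "proximal", s, lfc))
    for j in range(n_prox, n_er):
        s = int(
            region_b_start
            + (j - n_prox) * geo.peak_spacing
            + geo.peak_spacing // 2
            + rng.integers(-geo.peak_spacing // 4, geo.peak_spacing // 4 + 1)
        )
        lfc = rng.normal(geo.er_lfc_distal, geo.er_lfc_sd)
        er_ivs.append(GenomicInterval(chrom, s - hw, s + hw, f"er_{j + 1}", 0.0, ".", s))
        er_rows.append((f"er_{j + 1}", "distal", s, lfc))

    # --- genes: activated TSSs near primary increased (anchor-proximal)
    # peaks, repressed TSSs near the distal second-TF sites, unchanged
    # uniform over the accessibility region
    ng = config.n_genes
    n_act = round(ng * config.frac_genes_activated)
    n_rep = round(ng * config.frac_genes_repressed)
    gene_classes = np.array(
        ["activated"] * n_act + ["repressed"] * n_rep + ["unchanged"] * (ng - n_act - n_rep)
    )
    rng.shuffle(gene_classes)
    primary_inc_summits = summits[(classes == "increased") & primary]
    distal_summits = np.array([s for _, grp, s, _ in er_rows if grp == "distal"])
    tss = np.empty(ng, dtype=np.int64)
    for g in range(ng):
        if gene_classes[g] == "activated" and len(primary_inc_summits):
            anchor = int(primary_inc_summits[rng.integers(0, len(primary_inc_summits))])
            d = int(rng.integers(geo.gene_near_min, geo.gene_near_max + 1))
            tss[g] = anchor + d * (1 if rng.random() < 0.5 else -1)
        elif gene_classes[g] == "repressed" and len(distal_summits):
            anchor = int(distal_summits[rng.integers(0, len(distal_summits))])
            d = int(rng.integers(geo.gene_near_min, geo.gene_near_max + 1))
            tss[g] = anchor + d * (1 if rng.random() < 0.5 else -1)
        else:
            tss[g] = int(rng.integers(geo.margin, region_a_len - geo.margin))
    strands = np.where(rng.random(ng) < 0.5, "+", "-")
    genes = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": [f"gene_{g + 1}" for g in range(ng)],
                "chrom": chrom,
                "tss": tss,
                "strand": strands,
                "class": gene_classes,
            }
        )
    )

    # --- truth tables
    tps = config.timepoints
    feat_rows = []
    for i in range(n):
        row = {
            "feature_id": f"atac_{i + 1}",
            "kind": "atac",
            "class": classes[i],
            "chrom": chrom,
            "summit": int(summits[i]),
            "baseline_mean": baselines[i],
            "onset": int(onsets[i]),
            "primary": bool(primary[i]),
            "planted_gata": bool(planted_gata[i]),
            "planted_er_motif": bool(planted_er[i]),
        }
        for tp in tps:
            ramp = 0.0 if tp == 0 else min(1.0, tp / onsets[i])
            row[f"lfc_t{tp}"] = lfc_full[i] * ramp
        feat_rows.append(row)
    er_baselines = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_er)
    )
    for (name, grp, s, lfc), bl in zip(er_rows, er_baselines):
        row = {
            "feature_id": name,
            "kind": "er",
            "class": "increased" if lfc > 0 else "decreased",
            "er_group": grp,
            "chrom": chrom,
            "summit": s,
            "baseline_mean": bl,
            "onset": int(tps[1]) if len(tps) > 1 else 30,
            "primary": True,
            "planted_gata": False,
            "planted_er_motif": False,
        }
        for tp in tps:
            row[f"lfc_t{tp}"] = 0.0 if tp == 0 else lfc
        feat_rows.append(row)
    features = pd.DataFrame(feat_rows).set_index("feature_id")
    truth = TruthTable(
        features=features,
        genes=genes.table.copy(),
        timepoints=tps,
    )
    seq = "".join(ALPHABET[i] for i in seq_arr)
    return SyntheticLandscape(
        atac=PeakSet(atac_ivs, {chrom: genome_len}),
        trps1=PeakSet(trps1_ivs, {chrom: genome_len}),
        er=PeakSet(er_ivs, {chrom: genome_len}),
        sequences={chrom: seq},
        genes=genes,
        truth=truth,
        config=config,
    )


def simulate_timecourse_counts(
    truth: TruthTable,
    config: SimulationConfig,
    kind: str | None = None,
    timepoints: Sequence[int] | None = None,
) -> CountMatrix:
    """NB counts over the depletion time course for the features in a truth
    table.

    counts ~ NB(mean = baseline * size_factor * 2^lfc(t), dispersion alpha)
    with variance mu + alpha mu^2; per-sample size factors are lognormal;
    the t = 0 samples are the vehicle (DMSO) condition.
    """
    feats = truth.features
    if kind is not None and "kind" in feats.columns:
        feats = feats[feats["kind"] == kind]
    tps = tuple(timepoints) if timepoints is not None else tuple(truth.timepoints)
    kind_tag = 0 if kind is None else sum(ord(c) for c in kind) % 1000
    rng = _rng(config.seed, "counts", extra=kind_tag)
    sample_ids, conditions, tp_col, rep_col = [], [], [], []
    for tp in tps:
        cond = "DMSO" if tp == 0 else "dTAG"
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{cond}_t{tp}_r{r}")
            conditions.append(cond)
            tp_col.append(tp)
            rep_col.append(r)
    sf = np.exp(rng.normal(0.0, config.size_factor_sd, len(sample_ids)))
    baseline = feats["baseline_mean"].to_numpy()
    alpha = config.dispersion
    mat = np.empty((len(feats), len(sample_ids)), dtype=np.int64)
    for j, (tp, s) in enumerate(zip(tp_col, sf)):
        lfc = feats[f"lfc_t{tp}"].to_numpy()
        mu = baseline * s * np.power(2.0, lfc)
        if alpha < 1e-8:
            mat[:, j] = rng.poisson(mu)
        else:
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mu)
            mat[:, j] = rng.negative_binomial(n_param, p_param)
    counts = pd.DataFrame(mat, index=feats.index, columns=sample_ids)
    meta = pd.DataFrame(
        {"condition": conditions, "timepoint": tp_col, "replicate": rep_col},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(counts, meta)


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame  # genes x patients
    records: list
    regulon: Regulon
    truth: TruthTable


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Patient cohort with a latent anchor-TF activity driving regulon
    expression and hazard.

    Latent activity a_p ~ N(0, 1).  Genes in the depletion-up regulon half
    (the TF's repressed targets) are shifted by -beta * a_p, the depletion-
    down half by +beta * a_p: an active repressor keeps its repressed targets
    low.  Survival is exponential with hazard h0 * exp(gamma * a_p) under
    independent exponential censoring and an administrative cap.
    """
    cc = config.cohort
    rng = _rng(config.seed, "cohort")
    genes = [f"cg_{i + 1}" for i in range(cc.n_genes)]
    up_half = genes[: cc.regulon_size]
    down_half = genes[cc.regulon_size : 2 * cc.regulon_size]
    patients = [f"P{i + 1:04d}" for i in range(cc.n_patients)]
    activity = rng.normal(0.0, 1.0, cc.n_patients)
    expr = rng.normal(0.0, 1.0, (cc.n_genes, cc.n_patients))
    expr[: cc.regulon_size] -= cc.beta * activity[None, :]
    expr[cc.regulon_size : 2 * cc.regulon_size] += cc.beta * activity[None, :]
    expression = pd.DataFrame(expr, index=genes, columns=patients)

    hazard = cc.baseline_hazard * np.exp(cc.gamma * activity)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = (
        rng.exponential(1.0 / cc.censor_rate, cc.n_patients)
        if cc.censor_rate > 0
        else np.full(cc.n_patients, np.inf)
    )
    t_cens = np.minimum(t_cens, cc.max_followup)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    er_status = np.where(rng.random(cc.n_patients) < 0.7, "positive", "negative")
    records = [
        SurvivalRecord(pid, float(t), int(e), {"er_status": s})
        for pid, t, e, s in zip(patients, time, event, er_status)
    ]
    regulon = Regulon(
        activated=GeneSet("depletion_up", frozenset(up_half)),
        repressed=GeneSet("depletion_down", frozenset(down_half)),
    )
    truth = TruthTable(
        patients=pd.DataFrame(
            {"patient_id": patients, "activity": activity, "time": time, "event": event}
        ).set_index("patient_id")
    )
    return SyntheticCohort(expression, records, regulon, truth)


def simulate_growth(config: SimulationConfig) -> pd.DataFrame:
    """Exponential growth table (day, condition, replicate, count) with a
    condition-specific rate and lognormal counting noise."""
    gc = config.growth
    if len(gc.conditions) < 2:
        raise ValueError("growth simulation needs >= 2 conditions")
    if len(gc.days) < 3:
        raise ValueError("growth simulation needs >= 3 timepoints")
    rng = _rng(config.seed, "growth")
    rates = {gc.conditions[0]: gc.rate_control, gc.conditions[1]: gc.rate_treated}
    for c in gc.conditions[2:]:
        rates[c] = gc.rate_treated
    rows = []
    for cond in gc.conditions:
        for day in gc.days:
            for rep in range(1, gc.n_replicates + 1):
                noise = np.exp(rng.normal(0.0, gc.noise_sd)) if gc.noise_sd > 0 else 1.0
                count = gc.n0 * np.exp(rates[cond] * day) * noise
                rows.append((day, cond, rep, count))
    return pd.DataFrame(rows, columns=["day", "condition", "replicate", "count"])
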