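# tfredist

Downstream statistics for rapid transcription-factor depletion studies.

When a repressive TF (e.g. a GATA-family repressor such as TRPS1 in luminal
breast cancer cells) is acutely degraded with a chemical-genetic degron,
chromatin accessibility, the binding of other TFs (e.g. the estrogen
receptor), and nascent transcription all shift within minutes. `tfredist`
implements the statistical tail of that experimental design for
computational genomicists: everything downstream of read counting, from
differential testing over the depletion time course to patient
stratification by a regulon activity score — plus seeded synthetic-data
generators with planted effects, so every stage is testable end-to-end with
no external data.

## What it computes

**Differential counts** (`tfredist.diffcount`). Counts *K<sub>ij</sub>* in
peaks or genes are modeled as NB(μ<sub>ij</sub>, α<sub>i</sub>) with
Var = μ + αμ², μ<sub>ij</sub> = s<sub>j</sub>q<sub>ij</sub>, and
median-of-ratios size factors s<sub>j</sub>. Per-feature moment dispersions
are shrunk toward a log-log mean trend with precision-based weights; Wald
tests compare two conditions (log₂FC = β/ln 2, z = log₂FC/SE), a
likelihood-ratio test with χ²<sub>T−1</sub> reference detects any change
across T timepoints, p-values are BH-adjusted, and peaks are classified
increased / unchanged / decreased at FDR 0.1. Fold changes are shrunk with
a moment-matched normal prior: β̃ = β·τ²/(τ² + SE²).

**Motifs** (`tfredist.motifs`). PWM scanning in log₂-odds bits against a
0-order background, with exact p-values from a dynamic program over the
discretized per-position score distributions (0.001-bit bins) — the FIMO
approach. Class-wise motif prevalence around peak summits (summit ± 150 bp)
is compared with a Pearson χ² test.

**Geometry** (`tfredist.intervals`, `tfredist.redistribution`). Nearest-peak
distances from gene TSSs, ECDF comparison by two-sample KS; binding fold
changes of a second TF grouped by gene-class windows (TSS ± 100 kb) or by
summit-to-summit distance to the anchor TF, each group tested against zero
with a two-sided one-sample t-test (`***` marks p < 10⁻³).

**Kinetics** (`tfredist.kinetics`). Dynamic features z-scored across
timepoints and clustered hierarchically (1 − Pearson correlation, Ward)
into response groups with median/IQR kinetic traces.

**Regulon activity** (`tfredist.enrichment`). The regulon is split into a
depletion-up half (the TF's repressed targets) and a depletion-down half
(its activated targets). For each patient, genes are ranked by cohort
z-score and each half gets a weighted Kolmogorov–Smirnov enrichment score
(ES) with a gene-label permutation p-value. The differential enrichment
score dES = ES(up half) − ES(down half) ranks patients; a patient is
**high**-activity iff the up half is significantly negatively enriched *and*
the down half significantly positively enriched (an active repressor keeps
its repressed targets low), **low** for the mirror image, else
**intermediate**.

**Survival and growth** (`tfredist.survival_growth`). Kaplan–Meier curves
and an unweighted logrank test across activity classes; exponential growth
fit as ln N = β₀ + β₁·day (+ β₂·treated + β₃·day·treated), with an F-test on
the treatment terms and doubling times ln 2/rate.

## Worked example

Simulate a landscape with planted effects, call differential accessibility
at the earliest treated timepoint, and test GATA-motif prevalence by class:

```python
from tfredist import synthetic_data as syn, diffcount as dc, motifs as mo

cfg = syn.SimulationConfig(seed=42, n_peaks=1000, n_genes=300)
land = syn.simulate_peak_landscape(cfg)
counts = syn.simulate_timecourse_counts(land.truth, cfg, kind="atac",
                                        timepoints=(0, 30))
res = dc.differential_analysis(counts, contrast=("dTAG", "DMSO"), fdr=0.1)
print(res["class"].value_counts().to_string())

hits = mo.scan_intervals(syn.default_gata_motif(), land.sequences, land.atac,
                         p_threshold=1e-4)
prev = mo.prevalence_test(hits, land.atac,
                          dict(zip(res["feature_id"], res["class"])))
print(prev.table.to_string())
print(f"chi2 = {prev.chi2:.1f}, p = {prev.pvalue:.3g}")
```

```
class
unchanged    733
increased    142
decreased    125
           n_with_motif  n_total
increased            95      142
unchanged           162      733
decreased            19      125
chi2 = 130.5, p = 4.65e-29
```

Of 1000 peaks, 142 are called increased and 125 decreased at FDR 0.1
(the generator plants 25% increased — some with late onsets that a
30-minute contrast cannot see — and 10% decreased). The GATA-like motif
sits in 67% of increased peaks versus 22% of unchanged and 15% of
decreased, and the χ² test rejects independence of class and motif content
— the signature of a repressor whose direct targets open upon depletion.

The same objects feed the rest of the pipeline: `intervals.ecdf_ks` for
TSS-proximity CDFs, `redistribution.fc_by_distance_to_anchor` for the
proximal-gain/distal-loss binding pattern, `enrichment.patient_activity`
for dES stratification, and `survival_growth` for logrank and growth-rate
tests. A thin CLI wraps each step (`tfredist simulate|diff|proximity|
kinetics|redistribute|activity|survive|growth`, see `tfredist --help`).

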