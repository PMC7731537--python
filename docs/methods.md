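# Methods

`tcatrace` analyzes in vivo stable isotope-resolved metabolomics (SIRM)
experiments in which ¹³C-glutamine is infused to a plasma plateau and the
labeling of TCA-cycle intermediates is read out by GC-MS selected ion
monitoring (SIM) in sorted bone-marrow cell fractions. This note records the
models, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## First-turn isotopologue model

Glutamine anaplerosis enters the TCA cycle as glutamine → glutamate →
α-ketoglutarate, then proceeds oxidatively through succinate, fumarate,
malate and oxaloacetate, branching to aspartate (transamination) and citrate
(condensation with acetyl-CoA). Carbon fates are encoded as explicit atom
maps with IUPAC numbering; the α-ketoglutarate dehydrogenase step releases
α-KG C1 as CO₂. Succinate and fumarate are symmetric molecules: both
orientations are carried as an equiprobable mixture, which leaves the
nominal mass unchanged but keeps positional queries well-defined downstream.
Acetyl-CoA is treated as unlabeled in the first turn, so citrate inherits
only the four oxaloacetate carbons.

Consequences: a uniformly labeled [U-¹³C₅]glutamine tracer produces m+5
glutamate and α-ketoglutarate and m+4 succinate, fumarate, malate, aspartate
and citrate; a [5-¹³C] tracer produces m+1 throughout, because C5 is the
carbon farthest from the decarboxylated C1.

Assumptions and limits: first turn only, oxidative direction only.
Reductive carboxylation (which would yield m+5 citrate), second-turn
isotopomers, pyruvate-carboxylase input and exchange fluxes are not modeled.
This is deliberate: at plasma enrichments of 3–10% and a 60-minute infusion,
multi-turn species are second-order in the tracer fraction, and the analysis
below only consumes the single-turn shift. The model is not a flux model —
no EMU/cumomer machinery, no rate estimation.

The idealized MID used as the forward model is a two-pool mixture: a
fraction *f* of the metabolite pool exchanged with plasma glutamine (of
which the tracer fraction is the plateau enrichment *e*) and the remainder
unlabeled,

    MID = (1 − f·e)·M0 + (f·e)·M_shift.

*f* is referred to as the anaplerotic fractional contribution. The atom maps
and metabolite definitions ship as a versioned YAML config so the pathway
can be extended without code changes.

## Natural-abundance correction

SIM channels M0..M(n+2) are monitored per fragment, n being the backbone
carbon count; the two extra channels capture the heavy-isotope tails of the
derivatization atoms. The TBDMS/ethoxime derivatives are Si-rich (2–4 Si
atoms), so the natural M1/M2 signals are large — for the 3-TBDMS glutamate
fragment roughly 23% and 11% of the total, respectively — and correcting
them is the difference between a usable and a meaningless enrichment.

Column j of the correction matrix is the theoretical spectrum of a molecule
with exactly j tracer carbons: the convolution of the natural-abundance mass
distributions of all atoms except those j carbons with the binomial
isotopic-purity distribution of the j tracer carbons (default purity 0.99,
configurable), truncated to the monitored channels. Isotope abundances
default to IUPAC representative values and are config-replaceable. Fragment
elemental compositions are user-supplied config; the shipped example catalog
is derived from standard TBDMS/ethoxime chemistry and reproduces the
monitored M0 m/z values of the assay to within ~0.3 u.

The corrected MID solves `A·x ≈ raw` by nonnegativity-constrained least
squares (`scipy.optimize.nnls`), then truncates to M0..Mn and renormalizes.
NNLS was chosen over direct inversion because measured intensities are
noisy and plain inversion produces negative isotopologue fractions; the
solver is exact when the raw vector lies in the forward model's range, so
the correction round-trips any valid MID at zero noise. The correction
accepts raw intensities, not only fractions (scale invariance), and raises
on an all-zero vector or an ill-conditioned matrix (condition number
> 1e8, which signals a malformed composition).

Mole percent enrichment (MPE) is defined as the carbon-weighted average
labeling, `MPE = Σᵢ i·Mᵢ / n`; the simpler "fraction of molecules labeled",
`Σ_{i≥1} Mᵢ`, is exposed separately as `fraction_labeled`. Under the
two-pool model, MPE = f·e·shift/n.

## Enrichment statistics

Each metabolite's MPE is divided by the same subject's plasma glutamine
plateau enrichment (precursor–product normalization), which removes dose
and pharmacokinetic differences between subjects and does not require
isotopic steady state inside the cells. The per-subject CD138+/CD138− ratio
of relative enrichments contrasts the sorted plasma cells with the paired
remaining mononuclear cells; a zero denominator yields a flagged, excluded
record. Ratios are summarized by geometric mean, since ratios compose
multiplicatively.

Group machinery: two-sided paired t tests for the within-subject fraction
contrast (identical vectors are reported as t = 0, p = 1 rather than 0/0);
Mann-Whitney U for concentration comparisons, exact when both arms have ≤ 8
observations and no ties, otherwise the normal approximation with tie
correction; ordinary least squares with Pearson r for concentration
correlations. Enrichment summaries are mean ± SEM, concentrations are
summarized by medians. No multiple-testing correction is applied by default
(per-metabolite p-values are reported as such); Benjamini–Hochberg
adjustment is available behind a flag. Subjects missing one metabolite are
dropped for that metabolite only, never listwise.

## Quantitation

Absolute concentrations come from internal-standard response ratios read
against per-analyte calibration lines (12 calibrators for the GC-MS assay,
10 for LC-MS; the fitter requires ≥ 5). Unweighted OLS is the default with
an optional 1/x weighting; r² < 0.98 triggers a warning. Quantifying inverts
the line; responses above 1.5× the top calibrator are flagged as
extrapolation but not rejected (clinical samples can exceed the calibrated
range), and negative estimates are floored at zero with a warning.
Cross-platform concordance (GC-MS vs LC-MS on matched samples) reuses the
correlation machinery.

## Synthetic cohorts

The generator emulates a three-arm study — volunteers infused with
[5-¹³C]glutamine, MGUS and MM patients with [U-¹³C₅]glutamine — and emits
exactly the tables the pipeline consumes plus a latent-truth table.
Defaults (all config-exposed; effect sizes are modeling choices that mimic
the study's qualitative patterns, **not** measured values):

| parameter | default | rationale |
|---|---|---|
| arm sizes | 7 / 11 / 12 | the study's cohort sizes |
| plateau enrichment | U(0.04, 0.10) volunteers; U(0.03, 0.07) patients | observed plateau ranges |
| CD138− anaplerotic fraction | lognormal, mean 0.20, CV 0.40 | mid-range turnover; CV produces the marked between-subject heterogeneity |
| within-subject σ (log) | 0.20 | fraction-level biological + sorting variability |
| MM CD138+/CD138− effect ratio | 1.5 (all metabolites) | qualitative elevation in malignant plasma cells |
| MGUS effect ratio | 1.0, aspartate 1.3 | aspartate-only elevation pre-malignancy |
| SIM noise | multiplicative CV 0.01 per channel + additive σ 2·10⁻⁴ of total | replicate-injection precision of SIM peak areas (lower end) |
| concentrations | linear in marrow plasma-cell % (glutamate +0.6, aspartate +0.25, glutamine −1.8 µmol/L per %), lognormal noise | tumor-burden-tracking marrow microenvironment |
| cross-platform σ (log) | 0.06 | per-platform measurement error giving r ≳ 0.9 concordance |

Raw intensities are the ideal MIDs pushed through the same
natural-abundance convolution the correction inverts, scaled by a lognormal
total ion intensity, with the noise applied per channel. At zero noise the
full pipeline is therefore the exact inverse of the generator.

On SIM noise: error propagation through the deconvolution shows the
recovered labeled-channel fraction inherits both the additive term and the
multiplicative noise on the *large natural-abundance channels* (≈ 0.23 of
the total for 3-TBDMS fragments), so the error on the recovered anaplerotic
fraction is roughly (σ_add + CV·M_NA)/e. At the defaults and e ≈ 0.05 this
predicts ~5% relative error for the U-¹³C₅ patient arms, which the
validation reproduces (pooled median ≈ 5% over 100 replicates). The same
propagation explains why the [5-¹³C] volunteer tracer is 3–4× less precise:
its single labeled channel (m+1) sits directly under the natural-abundance
M1 envelope. That asymmetry is a real property of the two tracers and
matches the motivation for using the uniformly labeled tracer in the
patient cohorts.

What the synthetic validation does **not** show: real chromatographic
artifacts (co-elution, baseline drift, detector saturation), sorting losses
that differ between tracer and tracee, isotopic non-steady state, or any
quantitative fidelity to the human cohort values. Passing tests demonstrate
that the pipeline's inference is correct when its model assumptions hold,
at realistic noise — not that the human effect sizes are as configured.

## Pipeline and reproducibility

All tables are tidy UTF-8 CSV with a `#` header comment carrying the schema
version. Every stage is runnable standalone from the CLI (`simulate`,
`correct`, `enrich`, `quantify`, `report`) on intermediate CSVs. A run log
records the package version, seed and a SHA-256 digest of the config;
outputs are written with a fixed float format, so identical config + seed
reproduce byte-identical tables. All generator randomness derives from a
single mandatory seed.

Validation problem sizes: the cohort-recovery check uses 100 replicates of
an 11-subject patient arm (the study's MM sample size); the null-calibration
check uses 1000 paired-t replicates at n = 10; correction oracles enumerate
fragments of ≤ 12 atoms exhaustively. The full suite runs in well under a
minute on one CPU.
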