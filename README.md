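# tcatrace

Analysis toolkit for **in vivo ¹³C-glutamine stable isotope-resolved
metabolomics (SIRM)** of TCA-cycle anaplerosis — built for studies that
infuse ¹³C-glutamine to a plasma plateau, sort bone-marrow cells into
CD138+ (clonal plasma cells) and CD138− (remaining mononuclear cells)
fractions, and read out isotopologue labeling of TCA intermediates by
GC-MS selected ion monitoring (SIM).

It is a library first (import `tcatrace`), with a thin composable CLI for
running the stages on CSV tables.

## What it computes

**First-turn isotopologue model.** Explicit atom maps propagate glutamine
carbons through one oxidative TCA turn (glutamine → glutamate → α-KG →
succinate → fumarate → malate → OAA → {aspartate, citrate}), handling the
C1 loss as CO₂ at α-KG dehydrogenase and the symmetry of succinate/
fumarate. [U-¹³C₅]glutamine ⇒ m+5 glutamate/α-KG and m+4 beyond;
[5-¹³C]glutamine ⇒ m+1 throughout.

**Natural-abundance correction.** For each derivatized fragment (TBDMS
chemistry, Si-rich), the correction matrix A has columns equal to the
theoretical spectrum of a molecule with exactly j tracer carbons
(natural-abundance convolution × tracer-purity binomial). Raw SIM channels
M0..M(n+2) are deconvolved by nonnegative least squares, giving corrected
mass isotopomer distributions (MIDs) and mole percent enrichment
MPE = Σᵢ i·Mᵢ/n.

**Enrichment statistics.** Per-subject precursor–product normalization
(MPE ÷ plasma glutamine plateau enrichment), paired CD138+/CD138−
contrasts (paired t), per-subject fractional-enrichment ratios with
geometric-mean summaries, Mann-Whitney U for concentrations, OLS/Pearson
correlations.

**Quantitation.** 12-point internal-standard calibration curves, inversion
to µmol/L with extrapolation flagging, GC-MS vs LC-MS concordance.

**Synthetic cohorts.** A seeded generator emits raw SIM intensity tables,
plasma enrichments, calibration/response tables and a latent-truth table
with the study's group structure, so the whole pipeline is testable
end-to-end without access to human data (see `docs/methods.md` for every
default and its rationale).

## Worked example

```python
from tcatrace import (U13C5_GLUTAMINE, MIDVector, build_correction_matrix,
                      correct_mid, ideal_mid, load_fragment_catalog,
                      mole_percent_enrichment, propagate_first_turn)

propagate_first_turn(U13C5_GLUTAMINE)
# {'glutamate': 5, 'alpha_ketoglutarate': 5, 'succinate': 4, 'fumarate': 4,
#  'malate': 4, 'oxaloacetate': 4, 'aspartate': 4, 'citrate': 4}

frag = load_fragment_catalog()["glutamate"]        # 3-TBDMS fragment, m/z 432.2
A = build_correction_matrix(frag)                  # (8 channels x 6 labels)
truth = ideal_mid(U13C5_GLUTAMINE, "glutamate", 0.30)  # f=0.30 at e=0.05
raw = A.matrix @ truth                             # what the instrument reports
corrected = correct_mid(MIDVector("glutamate", raw), A)
mole_percent_enrichment(corrected)
# 0.015000000000000003
```

The raw vector spreads ~38% of the signal into M1..M7 from natural
²⁹/³⁰Si, ¹³C, ¹⁷/¹⁸O abundance; correction recovers the true MID (M0 =
0.985, M5 = 0.015) to machine precision, and MPE = 0.015·5/5 = 0.015 —
i.e. 30% of the glutamate pool exchanged with plasma glutamine at a 5%
tracer plateau.

Narrative scripts in `examples/` cover each capability; e.g.
`python examples/03_cohort_contrast.py` generates a full synthetic cohort
and prints the per-metabolite paired contrasts — all five TCA metabolites
significantly elevated in MM plasma cells (p = 0.0002–0.004), aspartate
only in MGUS (p = 0.013) — and geometric-mean CD138+/CD138− ratios of 1.46
(MM) vs 1.09 (MGUS), recovering the configured effect structure.

## CLI

```bash
tcatrace simulate --seed 1 --out data/           # synthetic cohort tables
tcatrace correct  --raw data/raw_intensities.csv --out corrected/
tcatrace enrich   --mpe corrected/mpe.csv --plasma data/plasma_enrichment.csv \
                  --metadata data/metadata.csv --out enriched/
tcatrace quantify --calibration data/calibration.csv \
                  --responses data/responses.csv --out quant/
tcatrace report   --config pipeline.yaml         # full end-to-end bundle
```

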