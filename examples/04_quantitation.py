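"""Absolute quantitation from 12-point calibration curves plus the
GC-MS vs LC-MS concordance check.

Uses the synthetic cohort's calibration and response tables, fits one
curve per analyte, quantifies every bone-marrow plasma sample and
correlates the result against the cohort's LC-MS values, then contrasts
MGUS vs MM glutamate with the Mann-Whitney U test.
"""

from tcatrace import CohortConfig, generate_cohort, platform_concordance, unpaired_group_test
from tcatrace.pipeline import quantify_samples

tables = generate_cohort(CohortConfig(seed=1))
concentrations, curves = quantify_samples(tables["calibration"], tables["responses"])

print("calibration curves:")
for _, row in curves.iterrows():
    print(f"  {row['analyte']:<22s} slope={row['slope']:.5f}  r^2={row['r_squared']:.4f}")

lc = tables["concentrations"]
lc = lc[lc["platform"] == "LC-MS"]
for analyte in ("glutamate", "aspartate"):
    res = platform_concordance(concentrations, lc, analyte)
    print(f"\n{analyte}: GC-MS vs LC-MS slope={res.slope:.3f}, r={res.r:.3f} "
          f"(n={res.n})")

conc = concentrations.merge(
    tables["metadata"], left_on="sample_id", right_on="subject_id")
glu = conc[conc["analyte"] == "glutamate"]
mgus = glu.loc[glu["group"] == "MGUS", "concentration"]
mm = glu.loc[glu["group"] == "MM", "concentration"]
res = unpaired_group_test(mgus, mm)
print(f"\nbone-marrow plasma glutamate, MGUS (median {mgus.median():.0f} umol/L)"
      f" vs MM (median {mm.median():.0f} umol/L): Mann-Whitney p={res.pvalue:.4f}")
print("Higher marrow glutamate with higher tumor burden is the configured "
      "concentration structure; the test recovers it from the quantified values.")
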