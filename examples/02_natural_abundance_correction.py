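"""Natural-abundance correction of a simulated glutamate SIM measurement.

Builds the correction matrix for the TBDMS glutamate fragment (three Si
atoms contribute large natural M1/M2 signals), pushes a known labeled
MID through it, and shows the nonnegative-least-squares correction
recovering the truth and the mole percent enrichment.
"""

import numpy as np

from tcatrace import (
    MIDVector,
    U13C5_GLUTAMINE,
    build_correction_matrix,
    correct_mid,
    ideal_mid,
    load_fragment_catalog,
    mole_percent_enrichment,
)

frag = load_fragment_catalog()["glutamate"]
matrix = build_correction_matrix(frag)

# truth: 30% of the glutamate pool turned over from plasma glutamine at
# 5% tracer enrichment -> 1.5% of molecules fully labeled (m+5)
truth = ideal_mid(U13C5_GLUTAMINE, "glutamate", 0.30)
raw = matrix.matrix @ truth  # what the instrument would report

print("raw (uncorrected) channel fractions:")
print("  " + "  ".join(f"M{i}={v:.4f}" for i, v in enumerate(raw)))
corrected = correct_mid(MIDVector("glutamate", raw), matrix)
print("corrected MID:")
print("  " + "  ".join(f"M{i}={v:.4f}" for i, v in enumerate(corrected.values)))
print(f"max deviation from truth: {np.abs(corrected.values - truth).max():.2e}")
print(f"mole percent enrichment:  {mole_percent_enrichment(corrected):.4f}")
print("\nThe raw M1 (~0.23) is entirely 29Si/13C natural abundance;"
      "\nafter correction only the tracer-derived M5 (0.015) remains, and"
      "\nMPE = 0.015 * 5/5 = 0.0150.")
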