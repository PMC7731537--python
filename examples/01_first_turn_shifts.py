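"""Expected first-turn labeling of TCA intermediates for two tracers.

Propagates glutamine carbons through the atom maps of one oxidative TCA
turn. Uniformly labeled glutamine keeps all five carbons through
alpha-ketoglutarate (m+5) and loses one as CO2 at the dehydrogenase step
(m+4 beyond); [5-13C]glutamine keeps its single label throughout (m+1).
"""

from tcatrace import C5_GLUTAMINE, U13C5_GLUTAMINE, TracerSpec, propagate_first_turn

for tracer in (U13C5_GLUTAMINE, C5_GLUTAMINE, TracerSpec("[1-13C]glutamine", frozenset({1}))):
    shifts = propagate_first_turn(tracer)
    print(f"\n{tracer.name}:")
    for met in ("glutamate", "alpha_ketoglutarate", "succinate",
                "fumarate", "malate", "aspartate", "citrate"):
        print(f"  {met:<20s} m+{shifts[met]}")

print("\nThe m+ value is the count of tracer carbons each intermediate "
      "retains; [1-13C] shows the C1 label vanishing as CO2.")
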