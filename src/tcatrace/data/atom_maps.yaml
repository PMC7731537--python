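# Carbon atom maps for the first oxidative turn of the TCA cycle fed by
# glutamine anaplerosis (glutamine -> glutamate -> alpha-ketoglutarate ->
# succinate -> fumarate -> malate -> oxaloacetate -> {aspartate, citrate}).
#
# Conventions:
#   - IUPAC carbon numbering for each acid; glutamine C1 is the alpha-carboxyl
#     carbon, C5 the amide carbon.
#   - alpha-ketoglutarate dehydrogenase releases alpha-KG C1 as CO2.
#   - citrate synthase condenses oxaloacetate with acetyl-CoA; acetyl carbons
#     are treated as unlabeled in the first turn, and occupy citrate positions
#     1-2 here (only the count of tracer carbons matters for nominal mass).
#   - succinate and fumarate are symmetric: both molecular orientations are
#     chemically indistinguishable and are carried as an equiprobable mixture.
#
# `map` entries are substrate_carbon: product_carbon (1-based).
version: 1
metabolites:
  glutamine:            {carbons: 5}
  glutamate:            {carbons: 5}
  alpha_ketoglutarate:  {carbons: 5}
  succinate:            {carbons: 4, symmetric: true}
  fumarate:             {carbons: 4, symmetric: true}
  malate:               {carbons: 4}
  oxaloacetate:         {carbons: 4}
  aspartate:            {carbons: 4}
  citrate:              {carbons: 6}
reactions:
  - name: glutaminase
    substrate: glutamine
    product: glutamate
    map: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}
  - name: glutamate_dehydrogenase
    substrate: glutamate
    product: alpha_ketoglutarate
    map: {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}
  - name: alpha_ketoglutarate_dehydrogenase
    substrate: alpha_ketoglutarate
    product: succinate
    map: {2: 1, 3: 2, 4: 3, 5: 4}
    lost_carbons: [1]
  - name: succinate_dehydrogenase
    substrate: succinate
    product: fumarate
    map: {1: 1, 2: 2, 3: 3, 4: 4}
  - name: fumarase
    substrate: fumarate
    product: malate
    map: {1: 1, 2: 2, 3: 3, 4: 4}
  - name: malate_dehydrogenase
    substrate: malate
    product: oxaloacetate
    map: {1: 1, 2: 2, 3: 3, 4: 4}
  - name: aspartate_transaminase
    substrate: oxaloacetate
    product: aspartate
    map: {1: 1, 2: 2, 3: 3, 4: 4}
  - name: citrate_synthase
    substrate: oxaloacetate
    product: citrate
    map: {1: 3, 2: 4, 3: 5, 4: 6}
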