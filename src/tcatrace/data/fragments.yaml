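# Example catalog of derivatized GC-MS fragments monitored in SIM mode.
#
# Metabolites are derivatized by ethoximation of keto groups followed by
# tert-butyldimethylsilylation (TBDMS); the monitored ion is the [M-57]+
# fragment (loss of the tert-butyl radical). Elemental compositions below are
# derived from that chemistry; the M0 m/z of each fragment is a stored
# instrument constant. Users with different derivatization or fragments
# supply their own catalog in this format.
#
# backbone_carbons counts the metabolite's own carbon skeleton (the carbons
# the tracer can label); `composition` counts every atom in the monitored
# fragment, derivatization atoms included.
version: 1
fragments:
  lactate:
    backbone_carbons: 3
    m0_mz: 261.2
    composition: {C: 11, H: 25, O: 3, Si: 2}
  fumarate:
    backbone_carbons: 4
    m0_mz: 287.1
    composition: {C: 12, H: 23, O: 4, Si: 2}
  succinate:
    backbone_carbons: 4
    m0_mz: 289.1
    composition: {C: 12, H: 25, O: 4, Si: 2}
  alpha_ketoglutarate:
    backbone_carbons: 5
    m0_mz: 360.2
    composition: {C: 15, H: 30, N: 1, O: 5, Si: 2}
  malate:
    backbone_carbons: 4
    m0_mz: 419.3
    composition: {C: 18, H: 39, O: 5, Si: 3}
  aspartate:
    backbone_carbons: 4
    m0_mz: 418.3
    composition: {C: 18, H: 40, N: 1, O: 4, Si: 3}
  glutamate:
    backbone_carbons: 5
    m0_mz: 432.2
    composition: {C: 19, H: 42, N: 1, O: 4, Si: 3}
  glutamine:
    backbone_carbons: 5
    m0_mz: 431.4
    composition: {C: 19, H: 43, N: 2, O: 3, Si: 3}
  two_hydroxyglutarate:
    backbone_carbons: 5
    m0_mz: 433.2
    composition: {C: 19, H: 41, O: 5, Si: 3}
  citrate:
    backbone_carbons: 6
    m0_mz: 591.4
    composition: {C: 26, H: 55, O: 7, Si: 4}
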