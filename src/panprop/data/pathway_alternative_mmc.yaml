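# Alternative methylmalonyl-CoA (mmc) route for syntrophic propionate oxidation,
# as organized in Cloacimonadota genomes: the succinate/fumarate/malate segment of
# the classical route is replaced by reductive carboxylation of succinyl-CoA to
# 2-oxoglutarate (KOR) followed by transamination to oxaloacetate (aspartate
# aminotransferase, aspB).
#
# Transcription conventions (see docs/methods.md):
#   * transformed (primed) standard state, pH 7, 25 degC: protons never appear in
#     stoichiometries; water activity is 1.
#   * reducing equivalents are expressed as H2 (reduced ferredoxin treated at the
#     H2 electrode); KOR consumes and POR regenerates one H2-equivalent pair.
#   * activation is by the kinase / phosphate-propionyltransferase route (steps
#     1/1b); acetate leaves by the reverse route with substrate-level ATP (step 9),
#     so the adenylate pool cycles over the chain.
#   * the transamination step swaps carbon skeletons: aspartate enters and
#     glutamate leaves as a co-substrate couple, so the chain's literal net is
#     propionate + aspartate -> acetate + glutamate (net_reaction below).
#     Once the amino pool is regenerated by cellular nitrogen metabolism, the
#     transformation the route effects is the canonical propionate-oxidation net
#     (reference_net below), which the ledger also evaluates.
pathway_id: alternative_mmc
description: >
  Alternative mmc route (Cloacimonadota-type): kinase/PTA activation, sodium-pumping
  methylmalonyl-CoA decarboxylase run carboxylating, epimerase, mutase, KOR, aspB
  transamination, oxaloacetate decarboxylation, POR, acetate kinase route exit.
steps:
  - step: "1"
    enzyme: "PK (propionate kinase route, activation)"
    stoichiometry: {propionate: -1, ATP: -1, propionyl_phosphate: 1, ADP: 1}
  - step: "1b"
    enzyme: "PTA (phosphate propionyltransferase)"
    stoichiometry: {propionyl_phosphate: -1, CoA: -1, propionyl_CoA: 1, Pi: 1}
  - step: "2"
    enzyme: "MMD (methylmalonyl-CoA decarboxylase, Na+-pumping, carboxylating direction)"
    stoichiometry: {propionyl_CoA: -1, CO2: -1, methylmalonyl_CoA_S: 1}
  - step: "3"
    enzyme: "EPI (methylmalonyl-CoA epimerase)"
    stoichiometry: {methylmalonyl_CoA_S: -1, methylmalonyl_CoA_R: 1}
  - step: "4"
    enzyme: "MUT (methylmalonyl-CoA mutase)"
    stoichiometry: {methylmalonyl_CoA_R: -1, succinyl_CoA: 1}
  - step: "5"
    enzyme: "KOR (2-oxoglutarate:ferredoxin oxidoreductase, reductive carboxylation)"
    stoichiometry: {succinyl_CoA: -1, CO2: -1, H2: -1, oxoglutarate: 1, CoA: 1}
  - step: "6"
    enzyme: "ASPB (aspartate aminotransferase)"
    stoichiometry: {oxoglutarate: -1, aspartate: -1, oxaloacetate: 1, glutamate: 1}
  - step: "7"
    enzyme: "PYC B (oxaloacetate decarboxylation to pyruvate)"
    stoichiometry: {oxaloacetate: -1, pyruvate: 1, CO2: 1}
  - step: "8"
    enzyme: "POR (pyruvate:ferredoxin oxidoreductase)"
    stoichiometry: {pyruvate: -1, CoA: -1, acetyl_CoA: 1, CO2: 1, H2: 1}
  - step: "9"
    enzyme: "PTA/ACK (acetate formation with ATP yield)"
    stoichiometry: {acetyl_CoA: -1, ADP: -1, Pi: -1, acetate: 1, ATP: 1, CoA: 1}
couplings:
  - ["1", "9"]
  - ["2", "7"]
  - ["5", "8"]
net_reaction: {propionate: -1, aspartate: -1, acetate: 1, glutamate: 1}
reference_net: {propionate: -1, water: -2, acetate: 1, CO2: 1, H2: 3}
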