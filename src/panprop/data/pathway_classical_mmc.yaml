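# Classical methylmalonyl-CoA (mmc) pathway for syntrophic propionate oxidation,
# in its standard organization (e.g. Syntrophobacter): CoA-transferase activation,
# methylmalonyl-CoA:pyruvate transcarboxylase, epimerase, mutase, then the
# succinyl-CoA -> succinate -> fumarate -> malate -> oxaloacetate segment that is
# missing from Cloacimonadota genomes (MS1-MS3), closed by POR.
#
# Transcription conventions (see docs/methods.md):
#   * transformed (primed) standard state, pH 7, 25 degC; no explicit protons;
#     reducing equivalents expressed as H2.
#   * succinyl-CoA cleavage (MS1) is written as plain thioester cleavage, without
#     the substrate-level ATP bookkeeping, so the chain's net is the bare catabolic
#     propionate-oxidation reaction that published route totals refer to.
#   * the transcarboxylase couples the carboxyl transfer internally (oxaloacetate
#     -> pyruvate drives propionyl-CoA -> methylmalonyl-CoA), so no free CO2 is
#     consumed at step 2.
pathway_id: classical_mmc
description: >
  Classical mmc pathway: CoA transferase, transcarboxylase, epimerase, mutase,
  succinyl-CoA synthetase segment (MS1), succinate dehydrogenase (MS2), fumarase,
  malate dehydrogenase (MS3), POR.
steps:
  - step: "1"
    enzyme: "CoA transferase (propionate activation / acetate release)"
    stoichiometry: {propionate: -1, acetyl_CoA: -1, propionyl_CoA: 1, acetate: 1}
  - step: "2"
    enzyme: "TC (methylmalonyl-CoA:pyruvate transcarboxylase)"
    stoichiometry: {propionyl_CoA: -1, oxaloacetate: -1, methylmalonyl_CoA_S: 1, pyruvate: 1}
  - step: "3"
    enzyme: "EPI (methylmalonyl-CoA epimerase)"
    stoichiometry: {methylmalonyl_CoA_S: -1, methylmalonyl_CoA_R: 1}
  - step: "4"
    enzyme: "MUT (methylmalonyl-CoA mutase)"
    stoichiometry: {methylmalonyl_CoA_R: -1, succinyl_CoA: 1}
  - step: "MS1"
    enzyme: "SCS (succinyl-CoA synthetase segment; ATP bookkeeping omitted)"
    stoichiometry: {succinyl_CoA: -1, water: -1, succinate: 1, CoA: 1}
  - step: "MS2"
    enzyme: "SDH (succinate dehydrogenase)"
    stoichiometry: {succinate: -1, fumarate: 1, H2: 1}
  - step: "7"
    enzyme: "FUM (fumarase)"
    stoichiometry: {fumarate: -1, water: -1, malate: 1}
  - step: "MS3"
    enzyme: "MDH (malate dehydrogenase)"
    stoichiometry: {malate: -1, oxaloacetate: 1, H2: 1}
  - step: "9"
    enzyme: "POR (pyruvate:ferredoxin oxidoreductase)"
    stoichiometry: {pyruvate: -1, CoA: -1, acetyl_CoA: 1, CO2: 1, H2: 1}
couplings: []
net_reaction: {propionate: -1, water: -2, acetate: 1, CO2: 1, H2: 3}
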