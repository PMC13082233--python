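# panprop

Comparative-genomics and ecology toolkit for testing whether **syntrophic
propionate oxidation (SPO)** is a phylum-wide trait of an uncultured bacterial
phylum (modelled on *Candidatus* Cloacimonadota from anaerobic-digestion
communities). The package implements the full inference chain as reusable,
seed-deterministic components, each exercisable on synthetic inputs with known
ground truth:

1. **Dereplication** (`panprop.derep`) — genome quality filtering
   (completeness > 50%, contamination < 10%), alignment-free ANI from canonical
   k-mer bottom sketches (`ANI = 1 + (1/k)·ln(2j/(1+j))`, `j` the sketch
   Jaccard estimate), and greedy quality-ranked clustering into species-level
   clusters at ANI ≥ 96.5% over ≥ 60% aligned fraction.
2. **Trait profiling** (`panprop.traits`) — genomes × KO matrices, group
   prevalence, habitat enrichment (per-KO linear model on raw counts,
   Benjamini–Hochberg correction; AD-enrichment ⇒ coefficient < 0), and the
   phylum-marker rule: present in ≥ 75% of focal genomes *and* absent in
   ≥ 75% of other genomes (both inclusive).
3. **Pathway thermodynamics** (`panprop.thermo`) — Gibbs free-energy ledgers
   (ΔG°′ = Σ ν·ΔGf°′; ΔG′ = ΔG°′ + RT·ln Q) for the classical
   methylmalonyl-CoA (mmc) route and the alternative route in which
   2-oxoglutarate:ferredoxin oxidoreductase (KOR) and aspartate
   aminotransferase (aspB) replace the missing succinate/fumarate/malate
   segment, with explicit coupled step pairs (1↔9, 2↔7, 5↔8).
4. **Co-occurrence networks** (`panprop.network`) — total-sum-scaled
   abundances, midrank Spearman ρ with seeded permutation p-values, BH-corrected
   edge thresholding, focal-taxon partner ranking, and taxon–covariate
   correlations (e.g. an OTU against propionate concentration).
5. **Synthetic data** (`panprop.synthetic`) — ground-truthed pangenomes
   (planted markers, binomial completeness dropout, contamination), sequence
   pairs at controlled divergence, and compositional abundance series with
   planted monotone associations.
6. **Pipeline** (`panprop.pipeline` / the `panprop` CLI) — end-to-end runs from
   one YAML config, with seeded, byte-reproducible outputs.

## Worked example

Evaluate the two propionate-oxidation routes at standard state and under
syntrophic conditions (low H₂ maintained by a methanogenic partner):

```python
from panprop import thermo

compounds = thermo.load_compound_table()          # Thauer-style dGf°' table
pw = thermo.load_pathway(bundled="alternative_mmc")
led = thermo.pathway_ledger(pw, compounds)
print(round(led.reference_net_dg0, 2))            # 71.67
print({k: round(v, 2) for k, v in led.coupling_dg0.items()})
# {('1', '9'): 8.3, ('2', '7'): -0.1, ('5', '8'): 2.74}

cla = thermo.pathway_ledger(
    thermo.load_pathway(bundled="classical_mmc"), compounds,
    concentrations={"H2": 1e-5, "propionate": 1e-3, "acetate": 1e-3, "CO2": 0.1},
)
print(round(cla.overall_dg0, 2), round(cla.overall_dg_prime, 2))
# 71.67 -19.67
```

The +71.67 kJ/mol standard-state total is the canonical SPO net reaction
(propionate⁻ + 2 H₂O → acetate⁻ + CO₂ + 3 H₂): endergonic on its own, and
exergonic (−19.7 kJ/mol) once a partner keeps H₂ low — the defining
thermodynamics of syntrophy. Of the declared couplings, only the
carboxylation/decarboxylation pair (steps 2↔7, a transcarboxylation with
near-zero net) clears zero at standard state; the activation/deactivation
(1↔9) and KOR/POR (5↔8) pairs need physiological concentrations.

Run the full demo pipeline (simulate → dereplicate → traits → markers →
thermo → network) from the shell:

```bash
panprop run --seed 1 --outdir demo_out
# {"seed": 1, "outdir": "demo_out", "stages_run": ["simulate", "derep",
#  "traits", "markers", "thermo", "network"]}
```

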