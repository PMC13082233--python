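name	dgf0_prime_kJ_mol	source
water	-237.18	Thauer, Jungermann & Decker 1977, Bacteriol Rev 41:100 (Table 6)
H2	0.00	Thauer et al. 1977 (element reference state, gas)
CO2	-394.36	Thauer et al. 1977 (gas)
HCO3	-586.85	Thauer et al. 1977 (aqueous)
ammonium	-79.37	Thauer et al. 1977 (aqueous)
propionate	-361.08	Thauer et al. 1977 (aqueous anion)
acetate	-369.41	Thauer et al. 1977 (aqueous anion)
pyruvate	-474.63	Thauer et al. 1977 (aqueous anion)
succinate	-690.23	Thauer et al. 1977 (aqueous dianion)
fumarate	-604.21	Thauer et al. 1977 (aqueous dianion)
malate	-845.08	Thauer et al. 1977 (aqueous dianion, L-malate)
oxaloacetate	-797.18	Thauer et al. 1977 (aqueous dianion)
oxoglutarate	-793.41	Thauer et al. 1977 (aqueous dianion, 2-oxoglutarate)
aspartate	-700.40	Thauer et al. 1977 (aqueous anion, L-aspartate)
glutamate	-699.60	Thauer et al. 1977 (aqueous anion, L-glutamate)
CoA	0.00	carrier reference (free coenzyme A set to zero; only differences enter reaction sums)
ADP	0.00	carrier reference (set to zero)
Pi	0.00	carrier reference (inorganic phosphate set to zero)
ATP	268.98	derived: ATP + H2O -> ADP + Pi at -31.80 kJ/mol (Thauer et al. 1977) with ADP=Pi=0
acetyl_CoA	-96.53	derived: thioester hydrolysis -35.70 kJ/mol (Thauer et al. 1977) from acetate
propionyl_CoA	-88.30	derived: thioester hydrolysis -35.60 kJ/mol (Thauer-style) from propionate
succinyl_CoA	-418.05	derived: thioester hydrolysis -35.00 kJ/mol (Thauer-style) from succinate
methylmalonyl_CoA_S	-410.95	derived: mutase equilibrium (R)-methylmalonyl-CoA -> succinyl-CoA at -7.10 kJ/mol; epimerase taken as isoenergetic
methylmalonyl_CoA_R	-410.95	derived: mutase equilibrium -7.10 kJ/mol from succinyl-CoA
propionyl_phosphate	-79.90	derived: acyl-phosphate hydrolysis -44.00 kJ/mol (acetyl-phosphate analogue, Thauer et al. 1977) from propionate
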