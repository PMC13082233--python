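# Methods

This note documents the models behind each module, the conventions and
defaults, and the design decisions taken where the underlying methodology is
genuinely open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic pangenomes

`simulate_pangenome` draws a genomes × KO incidence matrix with four planted
gene-family classes: *shared* KOs (present in every genome), *focal core* KOs
(Bernoulli presence at 0.95 in the focal phylum, 0.5 in the background —
ordinary metabolism that is common but not diagnostic), *markers* (present in
an exact configured fraction of focal genomes, default 1.0, and a configured
background fraction, default 0.0), and *accessory* KOs whose per-KO prevalence
is drawn uniformly from [0.1, 0.9] and applied to both groups.

Observation noise follows checkM-style quality semantics: each true gene is
retained independently with probability equal to the genome's completeness
(drawn uniformly from `completeness_range`, default 0.9–1.0), and each absent
KO is added with probability `contamination_rate` (default 0.01) as a
false presence. Contamination is modelled as foreign gene content, not
chimeric sequence — sufficient for every matrix-level analysis downstream.
Default group sizes (60 focal, 40 background) keep prevalence estimates
informative at desk scale while matching the medium-quality-MAG regime the
quality filter targets.

What this generator does **not** emulate: phylogenetic correlation between
genomes (presence/absence draws are independent given the class), annotation
errors that are correlated across KOs, and assembly/binning artifacts. Passing
tests therefore demonstrate correctness of the statistical machinery under the
stated noise model, not robustness to lineage effects in real pangenomes.

Sequence pairs for the ANI estimator use per-site independent substitution with
probability `divergence`, uniform over the three alternative bases
(Jukes–Cantor-like, no indels), which keeps the estimator's expectation
analytic. Abundance series place planted pairs on a shared latent Gaussian
signal: each member's log-abundance is `sign · z + noise`, so the noiseless
association is exactly monotone (Spearman ρ = ±1) and attenuates smoothly with
`noise_sd`. Covariate-linked taxa track an environmental covariate the same
way. All randomness derives from one seed via
`numpy.random.SeedSequence([seed, stream])` with fixed stream tags, so outputs
are bit-identical across runs.

## 2. Dereplication

Quality filtering keeps genomes with completeness **strictly above** 0.50 and
contamination **strictly below** 0.10 ("higher than"/"lower than").

ANI is estimated alignment-free. Canonical (strand-minimum) k-mers (k = 21)
are hashed with a fixed 64-bit mixer (splitmix64), and the Jaccard index `j`
of two k-mer sets is estimated from the bottom-`s` hashes of their union
(default s = 1000). The identity `ANI = 1 + (1/k)·ln(2j/(1+j))` inverts the
Bernoulli k-mer-survival model; its analytic expectation is `1 + ln(1 − d)` at
true divergence `d`, i.e. a small negative bias growing from 0.02 pp at
d = 0.02 to 0.54 pp at d = 0.10 — negligible against the 3.5-pp gap between
the species threshold (96.5%) and typical within/between-species divergences.
Disjoint sketches report ANI 0 with a `below_detection` flag rather than
raising. The gANI "aligned fraction" coverage term is proxied by the
containment of the smaller genome's distinct k-mers in the larger genome's
full k-mer set ((1−d)^k in expectation); a precomputed alignment-based ANI
table can be supplied instead through the TSV input path.

Clustering is greedy and quality-ranked (dRep-style centroid logic collapsed
to a single pass): genomes sorted by `completeness − 5·contamination`
descending (ties lexicographic by id) join the first existing cluster whose
*representative* they match at ANI ≥ 0.965 and aligned fraction ≥ 0.60, else
found a new cluster. The output is always a partition. Note that cluster
count is **not** monotone in the ANI threshold for arbitrary similarity
tables (a stricter threshold can promote a well-connected genome to
representative and absorb several would-be singletons); on well-separated
block-structured tables — the regime dereplication targets — monotonicity
holds and is property-tested there. Representative selection is the same
score argmax with the same tie-break.

## 3. Trait profiling

Long-format annotations pivot into an integer genomes × KO count matrix
(duplicates summed, missing cells zero). Prevalence is the fraction of a
group's genomes with nonzero count, with the group size as denominator —
deliberately **not** completeness-corrected, matching common practice for
medium-quality MAG collections; prevalence estimates are therefore biased low
by roughly the mean incompleteness.

The phylum-marker rule flags KOs with focal prevalence ≥ `p_in` (0.75) and
background prevalence ≤ 1 − `p_out` (0.25), both inclusive ("at least"), with
"absent" meaning zero count. The rule is monotone: tightening either bound
never grows the marker set.

Habitat enrichment regresses the raw per-genome KO count (no normalization or
transformation; a 0/1 incidence mode is available as an option) on a two-level
habitat indicator, second habitat coded 1 — with the default ("AD",
"aquatic") pair, AD-enrichment yields coefficient < 0. The per-KO OLS slope
test is computed in closed form (slope = group-mean difference, pooled
residual variance, t with n−2 df) — algebraically identical to fitting each
univariate linear model — and BH correction is applied once across all tested
KOs. Zero-variance KOs are reported inert (coef 0, p 1). Multi-habitat data
are analysed as independent pairwise contrasts; no other covariates are
modelled.

## 4. Pathway thermodynamics

Reaction energies are signed stoichiometric sums of transformed standard
formation energies (ΔGf°′, pH 7, 25 °C, kJ/mol); concentration corrections add
RT·Σν·ln c with water at unit activity and protons never appearing
(transformed convention). Pathway ledgers report per-step ΔG°′ (and ΔG′ when
concentrations are given), per-coupling nets, and the overall sum, verifying
by Hess's law that the steps cancel to the declared net reaction to 1e−9.
Coupling feasibility is net ΔG ≤ threshold (default 0), with uncoupled
endergonic steps listed.

The bundled compound table anchors small molecules to the classical anaerobic
bioenergetics compilation of Thauer, Jungermann & Decker (1977); CoA-ester,
acyl-phosphate and adenylate entries are back-calculated from standard
hydrolysis free energies (−35 to −36 kJ/mol thioesters, −44 acyl-phosphate,
−31.8 ATP) against those anchors, with CoA/ADP/Pi as zero-point carrier
references (only differences enter reaction sums, and all carriers cycle over
the bundled chains). Every row carries its provenance and the table is
user-replaceable.

Two route transcriptions are shipped as editable YAML. The **classical mmc
chain** (CoA-transferase activation, methylmalonyl-CoA:pyruvate
transcarboxylase, epimerase, mutase, then the succinate–fumarate–malate
segment and POR) is written with succinyl-CoA cleavage bare of its
substrate-level ATP bookkeeping, so the chain cancels exactly to the bare
catabolic SPO net — propionate⁻ + 2 H₂O → acetate⁻ + CO₂(g) + 3 H₂ — which
published route totals refer to; with the bundled table this evaluates to
+71.67 kJ/mol. The **alternative chain** (kinase/phosphotransferase
activation, Na⁺-pumping methylmalonyl-CoA decarboxylase run carboxylating,
epimerase, mutase, KOR reductive carboxylation, aspB transamination,
oxaloacetate decarboxylation, POR, acetate-kinase exit) declares the coupled
pairs 1↔9, 2↔7 and 5↔8. Reducing equivalents are expressed as H₂ (ferredoxin
at the hydrogen electrode); KOR consumes and POR regenerates one pair, so they
cancel over the chain.

A point worth making explicit: the transamination step swaps carbon skeletons,
so aspartate enters and glutamate leaves the alternative chain as a
co-substrate couple. The chain's literal Hess-consistent net is therefore
propionate⁻ + aspartate⁻ → acetate⁻ + glutamate⁻ (−7.5 kJ/mol with this
table) — nearly thermoneutral, because the amino-acid pool absorbs part of the
oxidation, consistent with the proposed link from propionate catabolism to
nitrogen metabolism and poly-γ-glutamate synthesis. The transformation the
route effects once cellular nitrogen metabolism regenerates the amino pool is
the same canonical SPO net as the classical route, which the config declares
as `reference_net` and the ledger evaluates alongside the step sum (+71.67
kJ/mol). Conventional standard-state route totals quoted in the SPO
literature (≈ 72–76 kJ/mol, depending on whether CO₂ is taken as gas or
bicarbonate and on the formation-energy compilation) correspond to this
regenerated net; by Hess's law two routes sharing it must agree, and small
differences between published figures reflect compilation choice, not route
chemistry. Default temperature is 298.15 K; no ionic-strength or
group-contribution corrections are attempted.

## 5. Co-occurrence networks

Counts are total-sum scaled (relative abundance; all-zero samples dropped with
a warning). Spearman ρ uses midranks for ties; the full ρ matrix is Pearson on
standardized rank columns. P-values default to a seeded permutation test
(10 000 permutations) — appropriate for short reactor series — implemented by
permuting every taxon's sample order independently per iteration and computing
all pairwise null correlations by batched matrix products; the t
approximation is available as an option and agrees with the permutation null
within 0.01 for n ≥ 30 on continuous data. Taxa below 20% prevalence and
constant taxa are excluded before testing (warned, never NaN-filled). Edges
require |ρ| ≥ 0.6 and BH q ≤ 0.05 (one BH pass across all tested pairs per
run); these thresholds are explicit logged parameters, not estimates.
Compositionality corrections (e.g. CLR) are deliberately off by default;
Spearman on relative abundances is the convention being mirrored. Partner
ranking sorts a focal taxon's edges by descending ρ (ties by id).

## 6. Pipeline

One flat YAML config with per-stage sections drives
simulate → derep → traits → markers → thermo → network. All domain thresholds
surface as named keys with the defaults above (ani 0.965, coverage 0.60,
completeness 0.50, contamination 0.10, marker 0.75/0.75, q 0.05). Every output
file carries a header echoing the seed and stage parameters; identical
config + seed gives byte-identical outputs. `validate_config` reports
problems by key; CLI exit codes are 0/1/2 (success / user error / stage
failure).

## Problem sizes

Simulation-based checks run at desk scale by design: pangenomes of 100
genomes × ~500 KOs, sketch-ANI genomes of 20 kb (500 kb where estimator
calibration itself is under test), abundance series of 8–50 samples, and
50–200 replicate seeds per calibration claim. These sizes put every planted
effect far above its detection threshold, so recovery rates measure
correctness of the machinery rather than statistical power at scale.

## Known limitations

* Sketch ANI carries the analytic `1 + ln(1−d)` bias (negligible below the
  species threshold) and the k-mer containment coverage proxy is not an
  alignment; precomputed ANI tables are the escape hatch.
* Enrichment models habitat only; no phylogenetic or completeness covariates.
* The thermodynamic ledger is a standard-state bookkeeping device: no
  activity-coefficient, ionic-strength or temperature-dependence corrections,
  and cofactor balancing in the shipped configs is a documented transcription
  of schematic pathway diagrams.
* Permutation p-values for heavily tied (sparse) abundance data are
  approximate in the batched scheme, which permutes columns independently.
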