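# Methods

## Exact-mass arithmetic

Element masses are monoisotopic (CODATA/IUPAC, ≥ 6 decimals), shipped
as a versioned TSV. Ion m/z for singly charged species follows the
usual conventions: deprotonation/protonation add or remove a proton
(1.007276 u); formate adducts add HCOOH and remove a proton; intrinsic
cations (quaternary alkaloids such as berberine, whose printed formula
is the cation's own composition) subtract one electron mass. The
electron correction matters: without it the berberine-type cation
C20H18NO4⁺ computes 1.6 ppm high. m/z values are reported rounded to 4
decimals but always compared with a ppm tolerance, never by string
equality. Charge is fixed at |z| = 1; multiply charged species and
isotope-pattern simulation are out of scope.

Radical (odd-electron) neutral losses — H•, CH3•, OCH3•, COOH• — carry
an electron-parity flag so that fragment compositions stay integral;
loss chains admit at most one radical step, which matches observed
product-ion ladders and prevents combinatorial blow-up. Two printed
loss labels are normalized to their arithmetic meaning: "COOH" from
protonated amino acids is a 46.0055 u CH2O2 (formic acid) loss, and the
aliphatic-acid "H2O+COOH" step is an H2O+CO2 chain.

## Fragmentation rulebase

Class behavior is encoded declaratively (JSON, user-editable): each of
the 25 compound classes has a rule listing diagnostic entries — ordered
neutral-loss chains from the quasi-molecular ion — plus optional
absolute product-ion formulas for retro-Diels–Alder ions (e.g. the
flavonol C7H3O4⁻ ion at 151.0037). Reasoning stays at the formula
level throughout; no bond-level chemistry is simulated, because the
diagnostic arguments that identify these classes are themselves
formula-level arguments.

Scoring: an entry is *applicable* to a precursor when its total loss
formula is elementwise subtractable from the precursor ion formula;
the class score is the weight fraction of applicable entries matched
within the fragment tolerance. Normalizing over applicable (rather
than all) entries keeps aglycones from being penalized for missing
glycoside losses and makes the noiseless simulate→annotate round trip
score exactly 1.0. Weights default to 1.0 and minimum_hits to 1 — the
evidence threshold for a class call is a judgement the source material
never quantifies, so the permissive default is flagged in output
metadata rather than hidden. Free enumeration of loss chains
(`expected_fragments`) is capped at depth 3 by default; two worked
ladders (iridoid aglycone dehydration after decarboxylation, and the
phenylethanoid caffeoyl–Rha–Glc–H2O chain) need depth 4, which callers
request explicitly.

## Annotation and tiering

Candidate search is polarity-aware ([M−H]⁻ and [M+COOH]⁻ in negative
mode; [M+H]⁺, or M⁺ for intrinsic cations, in positive mode) at 5 ppm
precursor tolerance. Each candidate is scored against its own class
rule; results are ranked by (tier, class score, |precursor ppm|, name),
a deterministic ordering that is invariant to peak input order.
Tiers: *identified_with_standard* needs a reference retention time
within ±0.2 min and a class score ≥ 0.1; *tentatively_characterized*
needs a precursor match and ≥ 1 rule hit (peak-free spectra are capped
at this tier and flagged); anything else is *unmatched*. Isomers are
never merged — identical formulas produce identical scores, and only
the retention-time tier separates e.g. cianidanol from epicatechin or
angelicin from psoralen, which is exactly how reference standards
resolve them at the bench. Per-peak explanation assigns each fragment
the minimum-length loss path within tolerance (ties by |ppm|) and
reports the intensity fraction explained.

## Sequential-metabolism fate logic

The seven matrices are ordered by passage: extract → gastric →
intestinal (mesenteric vein) → hepatic (femoral vein after first pass)
→ systemic → urine/feces. Fate labels are a pure function of the
boolean presence row: absence in gastric juice means gastric
degradation; presence in gastric but not intestinal plasma means the
intestinal barrier or intestinal metabolism; presence in intestinal but
not hepatic plasma means hepatic first-pass removal; presence in
hepatic but not systemic plasma means clearance from circulation.
"Absorbed" is the union over the three plasma-derived matrices, because
the complementary surgical sampling routes are alternative windows on
the same absorption event. Presence is boolean at the caller's
detection threshold; intensity-based calling, quantitative
bioavailability and parent→metabolite linkage are deliberately out of
scope — detection tables are what such studies report.

## Synthetic data

*Spectra.* One peak per applicable diagnostic entry (plus the
precursor), each multiplied by (1 + δ), δ ~ N(0, σ·10⁻⁶) with σ = 2 ppm
by default — the scale of the observed-vs-theoretical gaps for
reference standards. Decoy peaks (count ~ Binomial(n_true, f/(1−f)),
f = 0.3 default) are placed uniformly below the precursor but ≥ 20 ppm
from any true peak, so a decoy can never be confused with a diagnostic
ion at the 10 ppm matching tolerance. Intensities are cosmetic
(exponential by default) because annotation is m/z-driven. Retention
times are the library reference values jittered within ±0.05 min.
What this emulates: mass accuracy, decoy contamination, isomer
ambiguity. What it does not: intensity structure, co-elution, in-source
fragmentation, collision-energy dependence — so passing tests speak to
the matching logic, not to chromatographic robustness.

*Presence matrices.* Rows are i.i.d. draws from an explicit probability
vector over the 2⁶ patterns (extract always present), with exact tally
bookkeeping, so `summarize ∘ simulate` is checked for equality, not
estimation.

*Drug–target pairs.* Molecules are chain-grammar SMILES (validated with
rdkit) in which an aromatic thiophene token is planted with probability
√π; proteins are random 60–120-residue sequences (desk-scale choice)
with a 5-residue motif planted with probability √π, and decoys are
rejection-sampled so the motif never occurs by chance. The activity
rule is pharmacophore AND motif; labels are the rule bit XOR
Bernoulli(ε). π is calibrated as (balance − ε)/(1 − 2ε) so the *label*
prevalence equals the requested balance (0.13 by default, the
prevalence regime of public senolytic-activity data). The
Bayes-optimal AUROC against the noisy labels has the closed form
a(1−b) + (ab + (1−a)(1−b))/2 with a = π(1−ε)/p₊, b = πε/(1−p₊),
p₊ = π(1−ε) + (1−π)ε; at ε = 0.05 and balance 0.13 this is ≈ 0.87,
which is why discrimination is assessed against the noise-free rule bit
(recoverable from each record) rather than the noisy labels: the
benchmark measures whether training on corrupted labels still recovers
the planted interaction rule.

## Screening model

Architecture (3-layer GCN drug encoder at node level; 23-symbol
embedding + three 'same'-padded 1-D convolutions for the protein;
bilinear attention over all (atom, subsequence) pairs; bilinear pooling
into a fully connected head) follows the bilinear-attention DTI family.
Dimensions the source design leaves open default to that family's
configuration: D_d = D_p = 128, kernels (3, 6, 9), Adam at 5·10⁻⁴,
batch 64, Θ_d = 290, Θ_p = 1200, 100 epochs — all overridable. The
benchmark protocol runs a reduced configuration (D = 64, 30 epochs,
dataset-tight Θ) with lr = 10⁻³, the larger step compensating the
shortened schedule.

The network runs on a purpose-built reverse-mode autodiff over numpy
(tape-based; broadcast add/mul, batched matmul as single GEMMs, ReLU,
sigmoid, masked softmax, embedding gather, im2col 1-D convolution, and
a softplus-stable BCE-on-logits). Every operator's gradient is checked
against central finite differences in float64. Padded positions
(virtual atom nodes, protein padding) are re-masked after every layer
and excluded from the attention softmax via −10⁹ logits, which makes
the output exactly invariant to the padding budget — verified as a
test invariant. All computation is float32, seed-deterministic on a
single device; cross-hardware bitwise identity is not promised.
Molecules exceeding the node budget are truncated with a warning,
mirroring the protein convention. Splits are random or
label-stratified (default stratified) with largest-remainder rounding;
remainder ties go to later splits, so 80–10–10 of 5,945 gives
4,756/594/595.

Evaluation buys AUROC and AUPRC (average precision) from scikit-learn;
the F1-optimal threshold is selected by enumerating observed score
cut-offs (ties toward the higher threshold) with "positive iff score ≥
threshold". The test suite holds all five metrics to 10⁻⁹ against
brute-force enumeration oracles on small lists.

## Numerical and degenerate-input choices

Empty formulas, unknown elements, non-positive m/z, single-class label
vectors, missing presence values and unparseable SMILES raise
immediately with the offending item named. Empty spectra score 0 with
a warning and are capped at the tentative tier. Loss chains that are
not subtractable are pruned, never errors. Annotation tie-breaks are
lexicographic by compound name after tier, score and |ppm|, so repeated
runs are byte-identical.

## Known limitations

The rulebase encodes the diagnostic chemistry of the worked-example
classes; unusual substituents outside those patterns will lower class
scores rather than be explained. The fate module tracks prototype
compounds only — phase-I/II biotransformation products are not linked
to parents. The screening model is desk-scale: no GPU path, no
adversarial domain adaptation, and dataset-scale results from
proprietary curations (hundreds of identified metabolites, model
metrics near 0.99 on curated bioassay data) are outside what synthetic
benchmarks can or should reproduce.
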