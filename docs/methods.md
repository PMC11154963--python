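# Methods

This note documents the models, defaults and design choices behind
`wwscreen`, and what the synthetic campaigns do and do not establish about
real wastewater data.

## Exact-mass arithmetic

Monoisotopic atomic masses are hard-coded to six decimals from the standard
most-abundant-isotope table (C 12.000000, H 1.007825, N 14.003074,
O 15.994915, S 31.972071, P 30.973762, Cl 34.968853, F 18.998403,
Br 78.918338, Na 22.989770, I 126.904473). Electrospray charging uses the
proton mass 1.007276 Da (metal adducts additionally lose one electron),
not the hydrogen atom mass: `[M+H]+ = M + 1.007276`,
`[M+Na]+ = M + 22.989221`, `[M−H]− = M − 1.007276`. The test suite
cross-checks formula masses against an independent full-precision
implementation; agreement is bounded by the 6-decimal truncation
(≤ 2 × 10⁻⁴ Da for typical drug-sized formulas), well inside the 5 ppm
matching windows used throughout.

Biotransformations are formula deltas with a phase label; conjugation of a
phase-I metabolite yields the combined `I_then_II` phase. A transformation
whose delta would drive an element count negative is rejected.

## Componentization

Grouping within a sample is greedy, seeded by descending intensity with
first-match-wins assignment and a deterministic (m/z, RT) tie-break.
A feature joins the seed's component if it co-elutes (|ΔRT| ≤ 0.1 min) and
its m/z offset matches k·1.00336 (k = 1, 2; the satellite must be weaker
than its precursor in the chain) or a pairwise adduct delta, within 5 ppm.
Cross-sample alignment clusters components in ascending (m/z, RT) order
against running cluster means (5 ppm, 0.5 min) and is invariant to sample
order; gap filling searches the raw feature lists inside the same windows
and flags each cell `measured`, `gap-filled` or `absent`. The 5 ppm window
matches the extraction width used for targeted work; 0.5 min is the
cross-run RT reproducibility assumed for the confirmation comparisons.
The greedy rule is deliberately simple — the goal is a deterministic,
testable stand-in for the preprocessing that commercial software performs,
not a reimplementation of any vendor algorithm; peak quality ratings are
taken from the input feature table (0–10 scale, cutoff 5 by default), not
recomputed.

## Filter cascade

Criteria, in the documented evaluation order: maximum per-sample
monoisotopic intensity > 10⁵ counts (the most permissive reading of an
intensity floor, applied per aligned component); peak rating ≥ 5; an
acquired MS2 spectrum; background (mean blank intensity × 10 ≥ mean sample
intensity — the fold is configurable because "present in background" is
inherently operational); 4 min ≤ RT ≤ 30 min (after the LC dead time,
before the wash-out). Removal is attributed to the first failing
criterion. Because every criterion is evaluated independently of the
others, permuting the order changes only the attribution and never the
retained set; this is asserted over all 120 permutations.

## Modified cosine

Peak weights are √intensity (configurable to raw intensity), each
spectrum's weight vector normalized to unit ℓ₂ norm, so the similarity
lies in [0, 1] and identical spectra score 1. Candidate pairs satisfy
|m/zₐ − m/z_b| ≤ 0.01 Da directly or after subtracting the precursor mass
difference. The assignment of peaks is one-to-one and **exact** (a
rectangular maximum-weight linear-sum assignment) rather than greedy: the
similarity is defined as the maximum achievable sum, and the exact solver
is cheap at MS2 peak counts. A greedy mode (descending pair score) is
provided for comparison and a full-enumeration mode serves as the
independent reference in tests. Network edges require similarity ≥ 0.5
and ≥ 4 matched fragments; each node keeps its top-10 edges (an edge
survives in either endpoint's top-k). These thresholds are configuration,
not measurements — real campaigns tune them per dataset.

## RT model

Ordinary least squares of RT on logD at the chromatographic pH of each
ionization mode (pH 2.7 positive, pH 4.8 negative; separate models).
Because the band is used to judge a single new observation, we compute
**prediction** intervals — t(n−2) quantile times
s·√(1 + 1/n + (x−x̄)²/Sxx) — which are wider than confidence intervals for
the mean and have the advertised coverage for new compounds (verified by
Monte Carlo at n = 369: 95 % ± 2 % over 10,000 held-out draws). A
fixed-half-width band can be configured instead when reproducing published
constant-width bands. Implausibility (outside the 99 % band) only flags a
hit; rejection is a confidence-stage decision. A companion sign check
flags metabolites that are more polar than their parent (lower logD) yet
elute later.

## Confidence

The level scheme is a decision table: a tested reference standard is
decisive (RT and MS2 both matching → level 1; any mismatch → 4 with an
unequivocal formula, else 5); otherwise library MS2 match → 2a, in vitro
S9 match → 2b (m/z ±5 ppm, RT ±0.5 min — an extended window for the
matrix difference between wastewater and liver-S9 extracts — and
modified cosine ≥ 0.8), in silico support → 3, formula → 4, exact mass
→ 5. The harmonized score uses four components in [0, 1]: mass accuracy
max(0, 1 − |ppm|/5), isotope-pattern fit (observed M+1/M ratio against
0.011 × carbon count), best MS2 similarity, and RT plausibility (1 inside
the 95 % band, linear decay to 0 at the 99 % edge). Weights default to
0.25 each and are configuration: the score's structure, not a specific
calibration, is the contract.

## Quantification

Target calibration is weighted least squares with w = 1/x on analyte/ILIS
area ratios; the ILIS assigned to an analyte is the structurally identical
one when present, otherwise the candidate within 5 min of RT whose
relative recovery is closest to 100 % (ties: smaller RT distance).
Concentrations are divided by relative recovery / 100. The calibration
response for an analyte is always formed against the *same* ILIS that
normalizes its sample responses — mixing internal standards between curve
and sample would inject the ratio of their response factors as bias. LOQ
is operational: the lowest calibration level back-calculated within ±30 %.
Negative-mode semiquantification inverts an external (ultrapure-water)
curve after multiplying sample intensities by a per-plant sensitivity
factor, mean ILIS response in standards over mean in that plant's samples.
Positive-mode semiquantification is a pluggable interface (descriptor in,
response factor out) anchored to calibrant targets by a median ratio; the
shipped `LinearSurrogatePredictor` is a lookup table with an optional bias
for testing error propagation, not a trained ionization-efficiency model.

## Ratios and consumption

Expected metabolite/parent ratios are computed on a mass-concentration
basis, Σ f_m·MW_m / (f_p·MW_p) over molar excretion fractions (a molar
basis is available); under the back-cleavage scenario every flagged
phase-II fraction moves from the numerator to the parent fraction, which
strictly lowers the ratio whenever such a fraction is positive. Compounds
with unknown excretion fractions are excluded with a warning rather than
silently defaulted. Consumption back-calculation converts concentration ×
flow to g/day, rescales by MW parent/analyte and the served/reference
population ratio, divides by the molar excretion fraction and annualizes;
uncertainty is the standard deviation over sampling days. Ratio and
consumption analyses use level 1–3 identifications only, so an isobaric
interferent that survives the cascade but fails confirmation cannot
contaminate them.

## Synthetic campaigns

The generator's defaults are the study conditions of the package's own
verification: 3 plants × 5 days + 2 blanks, 50 parents × 3 metabolites,
10 % isobaric decoys, 30 background features. Retention is RT =
3·logD + 5 min with 0.2 min residual scatter inside a 0–34 min run
(parents logD ∈ [1.5, 7.8]; metabolites 0.3–1.5 units more polar).
Per-compound intensities are log-normal with median ≈ 5 × 10⁵ counts
(response factor median 2,500 counts per ng/L, σ 0.7, over concentrations
derived from planted consumption figures, median 75 kg/yr, σ 1.0, plant
flows ≈ 2 × 10⁷ L/day), so roughly a tenth of planted compounds fall under
the 10⁵ intensity filter and the cascade genuinely bites. MS2 spectra are
emitted for ≈ 35 % of planted compounds with probability increasing in
intensity (a logistic around the intensity quantile), emulating the
observation that features without MS2 are the weak ones. Metabolite
spectra reuse 35 % of the parent's fragments directly and 35 % shifted by
the biotransformation mass delta, on a 0.01 Da grid to keep matching
unambiguous at the default tolerance. Decoys sit within ±4 ppm of a
suspect mass with healthy intensity and unrelated MS2 but are displaced
2.5–6 min from the RT the suspect's logD predicts — far outside the 99 %
prediction band, the way a co-isobaric compound of different chemistry
would be. One plant carries a 0.5 multiplicative suppression on analyte
and ILIS responses to exercise the sensitivity factor. Reference standards
exist for 40 % of compounds (their preparation recovery is drawn in
[0.70, 1.00] and corrected via the spike table); half of the unconfirmed
metabolites with MS2 get an S9 detection. ILIS are simulated as fully
recovering, so the sensitivity factor isolates matrix suppression;
semiquantified compounds are simulated without preparation losses, so
semiquantification accuracy reflects suppression correction only.

What passing on these campaigns does **not** show: real chromatographic
peak shapes and coelution, isotope-pattern interference, real MS2 noise
and in-source fragmentation, matrix effects beyond a single multiplicative
factor, suspect lists with the redundancy and error of literature
curation, or any reported field result — the generator recovers planted
truth, it does not reproduce a measured campaign.

## Numerical choices and degenerate inputs

Determinism everywhere: one seed drives the generator; grouping and
alignment break ties lexicographically; reports embed the seed and a
config hash. Empty inputs degrade gracefully (empty spectral file → empty
list with a warning; empty hit list → zero-count report; empty confirmed
set → parent-link fraction undefined/None). Calibration requires ≥ 3
levels and strictly positive concentrations under 1/X; RT fitting requires
n ≥ 3 and non-degenerate logD. mgf stores RT in seconds; reading rounds to
10⁻⁶ min so the minutes→seconds→minutes conversion is exact. Spectral
writers emit shortest-exact decimal representations (padded to ≥ 5
decimals for m/z), which is what makes byte-level round-trips possible.
Table parsing converts numerics with Python's full-precision parser.

## Known limitations

The componentizer assumes singly charged ions and at most M+2 satellites;
no profile-data or vendor-format handling (the pipeline starts at
centroided feature tables); no library search against spectral databases
(library match flags may be supplied as input); the in silico evidence
flag is an input stub, not a fragmenter; the positive-mode
semiquantification accuracy is entirely that of the plugged-in predictor.
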