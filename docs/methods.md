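# Methods

This note records the models, numerical choices and limitations behind the
package, in the order the pipeline runs them.

## Adduct masses and annotation

Monoisotopic masses of the most abundant isotopes (IUPAC atomic-mass
evaluation, ≥ 6 decimals) are summed per formula; negative-mode adduct
deltas *include the electron mass* (0.00054858 Da) carried by the −1 charge
— without it the reference table's calculated m/z values are off in the 4th
decimal. "[M+COOH]⁻" is interpreted as the formate adduct [M+HCOO]⁻
(Δ = +44.997654 + 0.000549 Da). The formula grammar is deliberately small —
element symbol plus optional count, no parentheses, isotopes or charges —
sufficient for natural-product formulas; anything else is a parse error.

ppm error is signed, `(calculated − experimental)/calculated × 10⁶`. For the
packaged reference library this reproduces the transcribed errors of all 37
deprotonated-ion rows to within 0.05 ppm (the residual is printing
precision). The three adduct rows (peaks 35, 38, 39) carry transcribed
errors that do not match this convention under any sign choice; they are
stored verbatim and excluded from the round-trip check. The calculated m/z
of all 40 rows, including those three, reproduces at 4 decimals.

## Common peaks and similarity

Peaks pooled across samples are sorted by retention time and grouped
greedily: a peak joins the open group while its rt is within `rt_tol`
(default 0.5 min) of the group's last member. Groups with two peaks from
one sample are rejected (logged); only groups covering every sample become
common peaks, with the median member rt as consensus. Similarity is the
cosine of common-peak **area vectors** — the downstream models consume the
common-peak table and full chromatographic traces are not available, so the
Pharmacopoeia software's trace-based similarity is treated as a qualitative
regime (values > 0.9), not a reproduction target. The reference fingerprint
is the per-peak **median** across batches.

## PLS-VIP

NIPALS PLS2 on autoscaled blocks (mean 0, unit variance, ddof = 1), inner
loop converging at 1e−10 on the weight vector or 500 iterations, classical
deflation of both blocks per component. ALT and AST are modelled jointly
(PLS2): both endpoints carry information and a single model matches how the
screening is used; a single-column Y works unchanged. The number of
components is chosen by leave-one-out cross-validation maximising Q²,
capped at 5. SSYₐ is the Y sum of squares explained by component a on the
scaled block (tₐ'tₐ·‖cₐ‖²). VIP uses the standard formula with unit-norm
weights; Σ VIP² = p is asserted to 1e−8. Screening keeps VIP strictly
greater than the threshold (default 1.0). Adjusted R² uses
1 − (1 − R²)(n − 1)/(n − p − 1).

## BP-ANN and MIV

A p–3–m network: logistic-sigmoid hidden layer (tanh and linear available),
linear outputs, inputs and outputs min-max scaled to [0, 1], full-batch
gradient descent on the mean squared error, learning rate 0.05, momentum
optional (default off — it keeps the per-epoch loss monotone on smooth
problems), 5000 epochs, weights initialised uniform in [−0.5, 0.5] from a
seeded generator so training is bit-reproducible. MSE and gradient norm are
recorded per epoch. A non-finite loss aborts with the epoch number.

MIV perturbs each input column to (1 ± δ) times its value (δ = 0.10,
configurable) and averages the prediction difference over observations,
summed over outputs. The perturbation and the comparison are applied **in
the scaled spaces** by default. This is a deliberate choice: perturbing raw
inputs by a fixed fraction makes a variable's impact scale with the ratio of
its raw magnitude to its min-max range, so nearly constant matrix peaks
(large areas, tiny ranges) dominate the ranking for reasons unrelated to the
model; in the scaled space all variables are perturbed commensurately.
`scaled_space=False` restores the raw form for comparison.

MIV is signed; the screening ranking is by **signed** MIV descending (ties
toward the lower peak id), with the |MIV| ranking also reported. The signed
default matches how the screening is actually used — the markers of
interest are positive toxicity drivers, and on the printed reference scores
the |MIV| ranking would swap peak 9 (+0.255) for peak 1 (−0.256), which is
not what the published screening kept.

## Clustering

Columns (peak areas + ALT + AST) are z-scored with the sample SD (ddof = 1;
constant columns become zeros with a warning). Distances are euclidean or
correlation (1 − Pearson r); linkage average or complete, computed by
scipy's agglomerative implementation. Leaf order is a deterministic
traversal: at each internal node the child subtree containing the smaller
original index is visited first. The tested artifact is the ordered matrix
and linkage records; image rendering is an optional extra. The default
pipeline metric is correlation — co-variation with the endpoints, not raw
magnitude, is what the heat map is read for.

## Calibration and equivalence

Calibration curves are ordinary least squares; LOD = 3.3σ/S and
LOQ = 10σ/S from the residual SD σ (ddof = 2) and slope S — the conventional
rule, fixed here because reference values are listed without one.
Quantification inverts the line and flags below-LOD/LOQ and out-of-range
results. Marker dose is the literal product content_fraction × extract_dose
(a published dose label that is 5× this product appears to use a different
content normalisation; the literal product is implemented).

The equivalence CI works on natural logs of per-animal enzyme activities:
ratio of geometric means, pooled within-group log SD σ̂w (one-way-ANOVA root
MSE when more than two groups are supplied), t quantile at 0.95 with
n₁+n₂−2 df, and the half-width t·σ̂w·√(½(1/n₁+1/n₂)) — the ½ is implemented
verbatim from the source construction. Note that this halves the variance
relative to the textbook two-sample standard error: the resulting "90%" CI
has measured coverage ≈ 77% (10,000 lognormal replicates), while the
`textbook_se=True` form has coverage 89.8% ≈ 90%. Both forms are exposed;
the verbatim form is the default decision rule, the textbook form backs the
coverage property test. Equivalence requires *strict* containment of the CI
in (0.70, 1.43); ALT and AST are tested separately and no multiplicity
adjustment is applied. Degenerate zero within-group variance collapses the
CI to the point ratio.

## Synthetic study conditions

The default scenario emulates the study regime: 21 batches × 10 common
peaks, planted toxic peaks {9, 10}, 10 animals per group, control baselines
32 (ALT) and 83 (AST) U/L.

Structure of the area matrix: per-peak base levels (the toxic peaks are
minor constituents, ~3.5% of total area) times lognormal factors with three
components —

* a batch-strength factor (σ = 0.12) shared by the matrix peaks: overall
  concentration varies batch to batch, and co-varying matrix peaks are what
  real fingerprints look like;
* small idiosyncratic matrix variation (σ = 0.05), keeping pairwise cosine
  similarity in the 0.94–0.99 band (all > 0.9);
* large, partially shared variation of the two toxic peaks (σ = 0.50,
  correlation 0.5 through a common biosynthetic factor — the two markers
  are pathway-related diterpenoid lactones whose contents track together).

The correlation structure matters statistically, not just cosmetically:
with eight *independent* null peaks at n = 21, correlation noise
(sd ≈ 1/√20) pushes the largest null VIP above 1.0 in roughly half of all
realisations — a consequence of the Σ VIP² = p normalisation that no
parameter tuning removes. With co-varying matrix peaks the nulls share one
correlation draw and the normalisation self-limits them.

Group-mean enzymes are baseline + Σ effectⱼ·areaⱼ over the toxic peaks only
(ALT effects 2400/1850, AST 1200/950 U/L per area unit), placing group-mean
ALT spans around ~3300–17500 U/L across batches, matching the reported
range; per-animal values are lognormal around the group mean with CV 0.30
(mean-preserving parameterisation). Under these fixed conditions, measured
over 100 seeds: VIP > 1.0 selects exactly {9, 10} in 100 seeds, top-2
signed MIV in 99, and permuted toxicity (negative control) recovers the
pair in ≤ 5.

What the generator does **not** emulate: raw chromatographic traces (and
hence trace-based similarity), retention-time drift beyond small jitter,
nonlinear dose–toxicity transduction (metabolic activation), inter-animal
correlation, and measurement censoring. Passing tests therefore demonstrate
that the chemometric machinery recovers planted linear-additive structure
under realistic noise — not that real DBT data would behave as cleanly.

For equal candidate/original groups at n = 10, CV 0.30, the verbatim CI
declares equivalence in ~86% of realisations (analytically
P(|Δ̂| < ln 1.43 − half-width) with Δ̂ ~ N(0, σ²·2/n)); the end-to-end test
asserts a 75% floor that still catches implementation faults.

## Pipeline and selection rule

The final marker set is the intersection of {VIP > threshold} with the
top-k signed-MIV ranks, k being the VIP selection size — the conservative
formalisation of "agreement between the two model-based screens". Cluster
co-membership with the ALT/AST columns is reported as supporting evidence
but does not gate the selection. Reports serialise to JSON, validate
against a packaged structural schema, and carry a config hash, the seed and
the package version so a run can be reproduced exactly.

## Problem sizes used in the checks

The statistical suites run at desk scale by design: property checks on
random 8×4–30×12 problems, linkage against a brute-force oracle at ≤ 8
items, CI coverage at 10,000 two-group replicates, and parameter recovery
over 100 generator seeds (plus 40 permuted-control seeds).
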