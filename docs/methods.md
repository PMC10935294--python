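# Methods

## Scope and model of the problem

pepscreen reproduces, on deterministic inputs, the computational chain used to
nominate ACE-inhibitory peptides from a food protein: rule-based proteolysis of
the protein sequence, z-scale descriptor QSAR prediction of peptide IC₅₀,
intersection with an experimentally observed peptide list, threshold
selection, and enzyme-inhibition analysis of the selected candidates. Wet-lab
steps (ultrafiltration, LC-MS/MS acquisition, peptide synthesis, docking) are
out of scope; their outputs enter as plain tables, and a synthetic-data module
generates every such input with known ground truth.

## Proteolysis

A cleavage rule is a P2/P1/P1′ context predicate on the bond between residues
i and i+1 (1-based; "bond i" follows residue i): P1 must lie in the rule's
P1 class (empty = unrestricted), the P1′ residue must not be in the exclusion
set, and, if a P2 class is given, residue i−1 must belong to it (so such a
rule can never fire at bond 1). Multi-enzyme digestion takes the **union** of
cut sites (simultaneous action, as in BIOPEP's multi-enzyme "Enzyme action");
a sequential mode applies enzymes one at a time for users who prefer staged
hydrolysis. Fragments are the maximal substrings between cuts, carry 1-based
parent coordinates, and always reassemble to the input sequence.

Packaged defaults (conventions, editable in `data/enzymes.yaml` — the exact
specificity differs between BIOPEP releases and the release used upstream of
the packaged fixture is unknown):

| enzyme | P1 | P1′ excluded | P2 required |
|---|---|---|---|
| trypsin | K, R | P | — |
| papain | any | P | A, V, L, I, F, W, Y |
| pepsin (pH 2) | F, L, W, Y | P | — |

Gastrointestinal simulation (`gi_digest`) applies a pepsin stage then a
trypsin stage to a peptide and reports whether it survived intact. Ambiguous
residue codes (B, J, O, U, X, Z) are rejected with the offending position.

Not modelled: cleavage probabilities/efficiencies, missed-cleavage statistics,
pH/temperature dependence, PTMs.

## z-scale encoding

The five z-scales per residue (z1 lipophilicity, z2 steric, z3 charge, z4/z5
electronic) ship as a versioned CSV; encoding concatenates per-residue
5-vectors **position-major** (residue 1's z1..z5, then residue 2's, …), the
standard layout in z-scale QSAR. The layout choice matters only for
interpreting individual coefficients, not predictions. The table
re-serialises byte-identically (all values carry two decimals).

## QSAR (NIPALS PLS)

Per length class n ∈ {3, 6, 7, 8}: X is the m×5n descriptor matrix, y =
log₁₀ IC₅₀ (µM). Base 10 is a stated convention — the transform is monotone,
so threshold screening is base-invariant. Training sets admit only
IC₅₀ < 15 mM (15,000 µM).

Both X and y are autoscaled (mean-centred, unit variance, ddof = 1;
zero-variance columns get scale 1 and are flagged on the model), matching the
default behaviour of the SIMCA line of PLS software. NIPALS then extracts
A = 2 components by default (overridable): w = Xᵀy/‖Xᵀy‖, t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, with deflation X ← X − tpᵀ, y ← y − qt. With a
univariate response the y-side score u of a component is the current y
residual. The regression vector on the scaled data is B = W(PᵀW)⁻¹q,
back-transformed to the original descriptor scale with an explicit intercept,
so a serialized model reproduces predictions bit-for-bit from its JSON.

*Validation.* R² is the training multiple correlation; Q² is leave-one-out
(1 − PRESS/SS_tot). On synthetic data the fitted R² is checked against the
analytic noise ceiling 1 − σ²/Var(y).

*Outlier pruning.* Upstream practice prunes training peptides "by eye" from
t,u-score plots. Operationalized: the inner relation is u ≈ q·t per
component; a sample whose standardized inner-relation residual exceeds
2.5 SD in any component is removed and the model refit, at most 5 rounds,
never below n_components + 2 samples. Threshold and rounds are arguments.

The published per-length R² values of the study the packaged fixture comes
from are not reproducible here — their training compilations and manual
outlier choices are unpublished — so model quality is established by
synthetic parameter recovery instead (coefficient cosine > 0.9, R² at the
noise ceiling, planted gross outliers recovered, PLS = OLS at full rank).

## Screening

Funnel stages: exact-sequence intersection of released fragments with the
observed list (I/L distinct by default because their z-scales differ; an
`il_equivalent` mode exists since MS cannot separate the isobaric pair, but
it is never the default), optional monoisotopic-mass gate (< 3 kDa proxy for
ultrafiltration), length filter to classes with trained models, prediction,
and selection below the IC₅₀ threshold (default 10 µM; counts are also
reported at 100 µM). Reports are sorted ascending by predicted IC₅₀ with
deterministic tie-breaks; TSV + JSON outputs are byte-stable.

The packaged 21-row fixture (`data/predicted_ic50.csv`) pins the funnel: 3
tri-, 5 hexa-, 5 hepta- and 8 octapeptides, 6 candidates < 10 µM and 16
< 100 µM. One candidate appears upstream under two spellings (octapeptide
LYDQHLGK in the prediction table, heptapeptide LYDHLGK as synthesised); the
fixture keeps the prediction-table row and records the variant in an
`alt_spelling` column rather than harmonizing silently.

## Kinetics

*Inhibition rate.* 100·(HAc − HAs)/(HAc − HA_blank), from the hippuric-acid
concentrations of control, sample and enzyme-free blank; undefined (error)
when control equals blank; invariant under common rescaling of all three.

*Dose-response IC₅₀.* Two-parameter log-logistic with the upper asymptote
fixed at 100 %: inhibition = 100/(1 + (IC₅₀/c)^h), fit in log-parameter
space; requires ≥ 4 points bracketing 50 %, and falls back to monotone
log-linear interpolation (recorded in `method`) if the nonlinear fit fails.
The curve form is a stated convention; upstream practice fits an unspecified
"fitting curve".

*Michaelis–Menten.* Per inhibitor level, either the Lineweaver–Burk line
(OLS of 1/v on 1/S; Km = slope/intercept, Vmax = 1/intercept; non-positive
intercept → error, the data are not saturating) or a nonlinear fit of
v = Vmax·S/(Km + S). Both agree to ~1e-8 relative on clean data; standard
errors come from the line covariance (delta method) or the fit covariance.

*Mode classification.* Relative changes of apparent Km and Vmax versus the
uninhibited control, judged at the highest inhibitor level with a 20 %
default "changed" tolerance (an explicit stand-in for reading Lineweaver–Burk
intersection patterns visually): Km↑ with Vmax constant → competitive;
Vmax↓ with Km constant → non-competitive; both ↓ with the Km/Vmax ratio
preserved → uncompetitive (the mechanism sometimes called anticompetitive);
any other joint change → mixed; neither changed → none. Trends must be
monotone in inhibitor concentration, otherwise the call carries a warning.
Classification uses only ratios, so it is invariant to the inhibitor
concentration unit. Ki estimation by global multi-curve fitting is out of
scope.

*Digestion stability.* Welch's unequal-variance t-test on ≥ 3 replicate
IC₅₀s per condition at α = 0.05 (an approximation of the upstream SPSS
letter-annotation procedure, whose exact form is unknown), combined with a
post/pre fold-change bound (default 2): "stable" requires both
non-significance and a bounded fold change. α = 0 can never reject and is
flagged as degenerate.

## Synthetic data

All generators take an explicit seed, use a private `numpy.random.Generator`,
and return their ground truth with the data.

* **Proteins** embed planted peptides between cleavable separator residues
  (default K) in a random background, then *verify* by digestion that every
  planted peptide is released at its recorded coordinates; a planted peptide
  with an internal cleavage site, or whose termini do not cut in context,
  raises an error naming the offending bond. `random_plantable_peptide`
  draws trypsin-compatible peptides (K/R terminus, body free of K/R/P).
* **QSAR sets**: peptides uniform over the 20-letter alphabet;
  log₁₀ IC₅₀ = b₀ + x·β + N(0, σ²), resampled to respect the 15 mM admission
  bound. Defaults (n = 100, hexapeptides, b₀ = 1.7, systematic spread ≈ 0.7
  log units) put IC₅₀s in ~0.5–500 µM, the range typical of ACE-inhibition
  QSAR compilations.
* **Kinetics**: velocities from the closed-form rate law of each mechanism
  (competitive Km(1+I/Ki); non-competitive Vmax/(1+I/Ki); uncompetitive both
  scaled by 1/(1+I/Ki); mixed with interaction factor α) on the substrate
  grid {0.5, 1, 2, 4, 5} mM and inhibitor levels {0, 0.2, 0.5} (mg/mL by
  convention), with multiplicative Gaussian noise. Defaults Km = 1 mM,
  Vmax = 2, Ki = 0.2, α = 2 make every mechanism's apparent-parameter
  signature exceed the 20 % classification tolerance at the top level.
* **Dose-response**: log-logistic points on a two-fold geometric grid
  spanning ⅛×–8× the true IC₅₀, additive noise in percentage points.

What a green synthetic test does **not** establish: the generators draw
residues uniformly and make log-IC₅₀ exactly linear in the descriptors, so
they say nothing about real compositional bias, nonlinearity of true
structure–activity relations, MS identification errors, or the actual
specificity of any commercial enzyme preparation. They establish that the
pipeline's mathematics — cleavage logic, encoding, NIPALS algebra,
cross-validation, curve fitting, mode logic — is correct and deterministic.

## Numerical choices

* NIPALS stops early (remaining components zero) when the X residual carries
  no covariance with y; PᵀW inversion is regularized at machine precision.
* Ties in screening reports break by peptide sequence; report floats print
  with `%.6g` for byte-stable TSVs.
* Dose-response and MM nonlinear fits use `scipy.optimize.curve_fit` with
  data-derived starting values (interpolated IC₅₀; max velocity / median
  substrate).
* Degenerate inputs fail loudly: empty sequences, ambiguous residues,
  constant y, non-bracketing dose-response series, non-saturating kinetics,
  fewer than 3 replicates.

## Known limitations

* Default enzyme specificities are conventions; with the packaged papain rule
  (hydrophobic P2, free P1) some peptides that a different BIOPEP release
  releases intact acquire internal sites. Users matching a specific release
  must edit the rule file.
* The QSAR models are interpolators within a length class; there is no
  applicability-domain analysis beyond length matching.
* Mode classification reports the apparent-parameter pattern only; it does
  not estimate Ki and cannot distinguish partial from full inhibition.
* The stability verdict approximates an unspecified upstream statistical
  procedure with Welch's test plus a fold bound.
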