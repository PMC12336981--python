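# Methods

## Data

The embedded dataset covers 33 dihydropteridone–oxadiazole MCF-7
inhibitors. Activity is pIC50 = 6 − log₁₀(IC50/µM). Two tables coexist
under different numbering systems and are deliberately never joined:

* a 33-compound **descriptor panel** with 17 descriptors, including the
  frontier-orbital energies from which hardness is derived
  (η = (E_LUMO − E_HOMO)/2; the stored values agree with the derived
  half-gap to 1e-4, the rounding of the printed orbital energies);
* a 31-row **modeling table** keyed by its own row order, carrying the six
  model descriptors, observed pIC50, and the source's MLR/MNLR predictions
  (kept as reference values, never recomputed). Two panel compounds were
  excluded from modeling at source; their identities are not recorded, and
  the fixture metadata records the fact rather than a guess.

The split is 25 training / 6 test compounds (modeling-table rows 3, 4, 12,
21, 24, 29 are the held-out set). The source text mentions a 26/7 split;
the enumerated training list, the test-set table, and the reported
statistics (adjusted R² = 0.88 and MSE = 0.020 require n = 25 with
denominator n − p − 1 = 18) all identify 25/6 as the operative split, which
is what the fixtures encode. Fixtures are stored at printed precision, are
never re-derived from one another, and are checksum-verified (sha256
manifest) plus invariant-checked at load time.

## Regression models

**Linear.** `LinearQSAR` solves the least-squares problem via
`numpy.linalg.lstsq` after an explicit rank check. Fit statistics follow
regression-table conventions: MSE = RSS/(n − p − 1), adjusted
R² = 1 − (1 − R²)(n − 1)/(n − p − 1), F = (R²/p)/((1 − R²)/(n − p − 1)).
On the training fixture this yields R² = 0.909, F = 29.98, MSE = 0.0207,
adjusted R² = 0.879, reproducing the reported values at their printed
precision. Per-term contribution scores are standardized coefficients
(coefficient × descriptor standard deviation over the training records):
scale-free, sign-preserving; on the study data they are positive for S,
MP and η and negative for Tor, NRB and repul.

The **published equation** is available as a prediction-ready model and is
a distinct code path from refitting: the published coefficients reproduce
the five designed candidates' printed predictions exactly at two-decimal
rounding, while refits reproduce the training-prediction column to better
than 0.01 activity units.

**Polynomial.** `QuadraticQSAR` appends one squared term per descriptor
(no interactions) and solves OLS on the expanded design. With descriptors
spanning five orders of magnitude (MP² ≈ 10⁶ vs η² ≈ 5·10⁻³) the design's
condition number is ≈ 1.4·10¹⁴; coefficients are therefore ill-determined
individually (a warning is emitted above 10¹⁰) while fitted values remain
stable — the refit reproduces the source's per-compound polynomial
predictions within 0.005. The exact-OLS training R² is 0.9257, matching
the reported 0.93 at printed precision; since OLS is the least-squares
optimum on these terms, no fit on the same design can exceed it, and the
published figure is evidently rounded. The source's polynomial equation is
kept as a reference constant but is too coarsely rounded for quantitative
prediction (its hardness terms are printed to 5 significant figures
against a sensitivity of ~0.07 activity units).

**Neural network.** `ANNQSAR` is a 6-3-1 feed-forward net: sigmoid hidden
layer, identity output, inputs min-max scaled to [0, 1], target unscaled,
trained by full-batch gradient descent with momentum on halved MSE.
Training is a pure function of (data, hyper-parameters, seed) — identical
runs give bit-identical weights. Packaged defaults (learning rate 0.2,
momentum 0.9, 50 000 epochs, seed 20250) reach training R² ≥ 0.99 on the
25-compound fixture. That near-interpolation is a capacity statement — the
network has 25 free parameters for 25 points — not evidence of
predictivity; the architecture ratio ρ = inputs/hidden is recorded as
metadata with its conventional 1–3 validity range and does not constrain
training. Divergence (non-finite loss) raises with the offending epoch.

## Validation

**Leave-one-out.** Each record is dropped in turn and the estimator
(cloned, so any scikit-learn-style regressor works) is refitted on the
remainder. Q² = 1 − PRESS/SS with SS about the mean of the observed
training activities — the standard Q² denominator; the alternative reading
of "the average of observed and predicted" is ambiguous and not used.
MSE_cv = PRESS/n. Training fixture: Q² = 0.831, MSE_cv = 0.0277.

**External validation.** The Golbraikh–Tropsha battery uses the classical
conventions, recorded in every report: k = Σyŷ/Σy², k′ = Σyŷ/Σŷ²,
r₀² = 1 − Σ(ŷ − k·y)²/Σ(ŷ − ȳ̂)², r′₀² = 1 − Σ(y − k′·ŷ)²/Σ(y − ȳ)².
On the six external pairs these give r² = 0.7049, r₀² = 0.6922,
r′₀² = 0.6610, k = 1.0065, k′ = 0.9918, (r² − r₀²)/r² = 0.018,
(r² − r′₀²)/r² = 0.062 — each matching its reported value at printed
precision, which is the justification for the convention choice.
Δr₀² is |r₀² − r′₀²| by definition (0.0312 here); the source's reported
0.0382 is inconsistent with its own tabulated components and is not
reproduced. A reported training-set Q² of 0.618 likewise matches no stated
computation (the text gives 0.83) and is surfaced nowhere as a computed
quantity.

## Applicability domain

Leverage hᵢ = xᵢ(XᵀX)⁻¹xᵢᵀ uses the intercept-augmented design — required
for the hat-trace identity Σhᵢ = p + 1 and for the reported warning
leverage, which counts p + 1 = 7 parameters: h\* = 3(p+1)/n = 21/31 = 0.677.
The domain design for the study reproduction is **all 31 modeling
compounds** (training and test), the only convention consistent with
n = 31 in h\*; under it every modeling compound has h < h\* (max 0.580).
Scored against the training-only design instead, one torsion outlier among
the held-out compounds exceeds h\* (h ≈ 1.48) — both evaluation modes are
supported, and reports state which design defines the domain. Standardized
residuals for Williams plots are residual / RMSE of the training fit, the
usual plotting convention, with boundaries at h\* and ±3. Designed
candidates can be leverage-scored against the modeling domain as an
extension; they score out-of-domain (their stretch energy and hardness sit
at or beyond the modeling ranges), so their predicted activities are
extrapolations.

## Drug-likeness rules

Per-ruleset bounds, with the verdict passing at zero violations except
Lipinski's conventional one-violation allowance:

| rule set | bounds |
|---|---|
| Lipinski | MW ≤ 500 Da, LogP ≤ 5, HBA ≤ 10, HBD ≤ 5 (≤ 1 violation) |
| Veber | rotatable bonds ≤ 10, TPSA ≤ 140 Å² |
| Egan | LogP ≤ 5.88, TPSA ≤ 148.1 Å² |
| Muegge | MW ∈ [200, 600], LogP ∈ [−2, 5], TPSA ≤ 150 Å², RotB ≤ 15, HBA ≤ 10, HBD ≤ 5 |

Two choices are deliberate. Egan's bound is the 99% confidence ellipse of
his passive-absorption model (148.1 Å²) rather than the 95% ellipse
(131.6 Å²): two candidates have TPSA 135.78 Å², and the tighter bound
would contradict their recorded passing verdicts, while both bounds are
published variants of the same filter. Muegge's ring-count and atom-count
predicates require structures, which this dataset does not contain
(structures exist only as images at source); the rule set is evaluated
over the six available properties. Synthetic-accessibility and
AMES-toxicity columns are carried as annotations from external tools,
never computed.

## Synthetic data

The generator emulates the statistical structure the linear model assumes:
descriptors drawn independently and uniformly within per-term ranges
spanning the modeling table (NRB discrete), activity = linear signal +
homoscedastic Gaussian noise, deterministic under its seed. Defaults are
the study-like conditions: 31 compounds, the published coefficients as
ground truth, noise sd 0.13 (the study fit's residual scale; its RMSE is
0.14).

What it does **not** emulate: the real panel's inter-descriptor
correlation and clustering. Independent uniform marginals over the full
ranges carry a signal variance of ≈ 1.26 activity-units², an order of
magnitude above the real panel's ≈ 0.17, so default-configured refits land
near R² ≈ 0.99 rather than the study's 0.91 — the tests check the
generator against the corresponding closed-form variance expectation, not
against the study's R². A Gaussian-copula correlation option exists for
leverage/domain experiments that need collinear panels. Consequences for
interpretation: passing recovery tests demonstrate estimator correctness
(zero-noise recovery is exact to 1e-8; the LOO-vs-training optimism gap
Q̄² < R̄² holds across 100 seeded replicates; coefficient RMSE grows with
noise), not that the pipeline's published performance would be attained on
descriptor panels with a different covariance structure.

## Numerical conventions and limitations

* Comparisons to reported values use the value's printed precision
  (half-ULP of the last printed digit) unless a wider tolerance is stated.
* Least-squares solves use `lstsq`; rank checks precede fitting; the
  leverage module inverts the Gram matrix only after a rank check.
* Perfect fits: F is reported as infinity; standardized residuals are
  refused when the residual scale is numerically zero.
* Descriptor selection is fixed to the six model terms; no subset search,
  no regularized variants, no k-fold/bootstrap/Y-randomization.
* Descriptor computation from structures (molecular mechanics, DFT),
  docking, molecular dynamics and ADMET prediction are outside this
  package's scope; descriptors and external-tool annotations are inputs.
* Problem sizes are the study's own (25/6/31 compounds, 100-replicate
  Monte-Carlo checks), chosen to match the reproduced analyses.
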