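# Methods

`ftirdose` implements a complete in-silico version of an FTIR-based
cytotoxicity dose-prediction study: cultured cells are exposed to a
dilution series of a toxicant (here cisplatin on HepG2 hepatocarcinoma
cells), their mid-infrared absorbance spectra are acquired, difference
spectra against unexposed controls are formed, and a partial
least squares (PLS) regression maps those difference spectra back to the
applied concentration. Because no raw spectra from such studies are
publicly deposited, the package pairs the analysis chain with a
synthetic-data generator whose defaults encode the study conditions, so
every stage is testable end to end.

## The synthetic spectrum model

A cell spectrum on the working grid (1000–3000 cm⁻¹, 1 cm⁻¹ spacing,
2001 points) is a sum of Gaussian vibrational bands

    A(ν; d) = Σ_b a_b(d) · exp(−(ν − c_b(d))² / 2σ²),  σ = 4 cm⁻¹,

whose centres and amplitudes depend on the cisplatin dose d (µg/mL).
Shifting bands move between their unexposed and saturated positions
along a logistic transition

    c_b(d) = c_lo + (c_hi − c_lo) · logistic(s · (d − d_thr)),

with steepness s = 8 (µg/mL)⁻¹ so that a shift is essentially complete
one dose step past its threshold d_thr. The band table encodes the
reported spectroscopy of platinum–biomolecule binding:

| band | centre (cm⁻¹) | behaviour |
|---|---|---|
| guanine | 1725 → 1713 | shifts above ~1.5 µg/mL (Pt–N7 binding) |
| thymine | 1665 → 1657 | shifts above ~1.5 µg/mL (Pt–O2 binding) |
| adenine | 1613 | no shift |
| cytosine | 1499 | no shift |
| amide β-sheet | 1639 → 1624 | shifts above ~2 µg/mL (Pt–protein) |
| phosphate asym/sym | 1228 / 1087 | no shift |
| marker 1648 | 1648 | exposure excess, +0.10 at 0.125 µg/mL |
| marker 1490 | 1490 | exposure deficit, −0.08 at 0.125 µg/mL |
| C–H stretches | 2852 / 2923 / 2958 | no dose dependence |

The two *marker* components model the characteristic difference-spectrum
features: exposed cells carry an absorbance excess at 1648 cm⁻¹ and a
deficit at 1490 cm⁻¹ relative to controls, and both magnitudes decay
linearly with dose to 20 % of their 0.125 µg/mL value at 4 µg/mL. This
gives the difference spectra a positive peak at 1648 and a negative peak
at 1490 whose intensities shrink as concentration rises, and — because
the decay is linear in d — a strong linear component for the regression
to exploit. The 2000–2500 cm⁻¹ region is deliberately left without any
band so that one evaluation window is dose-uninformative by
construction; the C–H stretch bands populate 2500–3000 cm⁻¹ but carry no
dose dependence either.

Replicate-level nuisance terms are a multiplicative scale jitter
(sd 2 %), a random linear baseline (offset sd 0.02 absorbance units,
slope sd 1e-5 per cm⁻¹), and i.i.d. Gaussian noise (sd 0.0035, about
0.5 % of the ~0.71 peak absorbance). These levels make dose recovery
good but not trivial: they are the package's definition of the study
conditions, not tuning knobs. Setting all four to zero yields the
deterministic noise-free spectrum used in worked examples. The default
design is nine concentrations (0, 0.125, 0.25, 0.5, 1, 1.5, 2, 3,
4 µg/mL) × seven replicates.

What the generator does *not* emulate: Mie scattering, water-vapour
lines, detector nonlinearity, batch effects between replicate days, and
any band not in the table. A pass on synthetic data therefore
demonstrates that the analysis chain is correct and sensitive under the
assumed signal/noise structure; it does not certify performance on real
cell spectra, whose nuisance structure is richer.

## Preprocessing

Each spectrum is baseline-corrected by asymmetric least squares (ALS):
the baseline z minimizes Σ w_i (y_i − z_i)² + λ Σ (Δ²z_i)² with
w_i = p above the baseline and 1 − p below, iterated 10 times
(p = 0.01). The banded symmetric system is solved directly, so the
estimate is deterministic. λ defaults to 1e8 on the 2001-point grid:
linear trends (the generator's baseline model) lie in the null space of
the second-difference penalty and are removed exactly for any λ, while a
stiff baseline distorts genuine bands the least — at λ = 1e8 the
corrected noise-free band spectrum deviates from its input by < 0.3 % of
peak height and a second correction pass moves it by < 0.1 %. Smaller λ
(1e5–1e6) tracks curvature under the crowded 1600–1670 cm⁻¹ cluster and
eats 1–2 % of band height; users fitting curved instrumental baselines
can lower λ via `PreprocessParams` or `--lambda`.

After baseline removal each spectrum is min-max normalized to span
exactly [0, 1] over the full working range. Normalization precedes any
windowing, so restricted windows may have maxima below 1 — this mirrors
per-spectrum normalization at acquisition time, before segmentation.

## Biochemical index spectra

A BIS row is one exposed replicate minus the pointwise mean of all
control (0 µg/mL) replicates; controls are consumed as reference only.
Averaging the controls (rather than pairing) is deterministic and uses
all control information. Under the default design this leaves
8 exposed concentrations × 7 replicates = 56 rows — the number the
split protocol assumes.

Peak location runs local-extremum detection with a prominence filter
(negative peaks as maxima of the negated trace), then refines each apex
with a three-point parabolic fit and reports the centre rounded to the
nearest integer cm⁻¹, which is how band positions are conventionally
quoted. On noise-free data this reproduces 1713/1657/1624 at high dose
and the +1648/−1490 BIS extrema exactly.

One subtlety: the 1648 marker peak is detectable as a local maximum only
below ~1.5 µg/mL. Once the thymine and amide shifts engage, the
difference spectrum grows large derivative-shaped lobes (old position
negative, new position positive) that overwhelm the small 1648 feature,
and no distinct local maximum survives there. The monotone decay of the
1648 intensity across the full dose range therefore holds for the BIS
trace value at 1648 cm⁻¹, and for the detected peak height in the
pre-shift regime; the 1490 marker has no interfering shift nearby and
its detected peak shrinks monotonically over all doses.

## PLS1 by NIPALS

The regression is univariate-response partial least squares fit by
NIPALS, written from scratch (`ftirdose.pls`): X and y are centred, and
each component takes w ∝ Xᵀy (unit norm), scores t = Xw, loadings
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, followed by deflation of X and y. The
collapsed regression vector is b = W(PᵀW)⁻¹q, solved by triangular
back-substitution (PᵀW is unit upper triangular in exact arithmetic)
with a conditioning guard at 1e10. For univariate y every step is closed
form — no iterative inner loop, no random initialization — so fits are
deterministic.

Predictors are centred but not autoscaled: the columns are 0–1
normalized absorbances on a common scale, and autoscaling would inflate
noise in low-absorbance regions relative to band heights. An optional
`scale=True` provides the autoscaled variant.

Correctness is pinned by two independent oracles in the test suite: at
full rank the training predictions must equal ordinary least squares
(normal-equations oracle), and on random problems the predictions must
match scikit-learn's `PLSRegression(scale=False)` to 1e-8. scikit-learn
is never used in the pipeline itself.

## Evaluation protocol

The 56 BIS rows are split 20 times into 40 training / 16 testing rows.
Splits are stratified 5/2 within each exposed dose — the only allocation
consistent with 40/16 over eight balanced groups — with an unstratified
option behind a flag. On each training set the number of latent
variables (up to 15, capped by the data) is chosen by 7-fold
cross-validation with dose-balanced folds, minimizing pooled squared
prediction error; ties go to the smaller count. Each fold is fit once at
the maximum count and truncated models supply predictions for all
smaller counts. The selected model is refit on the full training half
and scored with RMSE = √(Σ(w_o − w_p)²/n) and R² = 1 − SS_res/SS_tot on
both halves; R² as squared Pearson correlation is available behind a
flag. Test rows never enter CV or fitting.

The comparison runs over five windows — 1000–3000 cm⁻¹ and its four
quarters. On the default synthetic design the full window recovers dose
with mean test R² ≈ 0.99, the construction-silent 2000–2500 cm⁻¹ window
(and the dose-flat 2500–3000 cm⁻¹ window) sit near zero, and permuting
dose labels collapses the full-window test R² below zero — the
package's permutation control for information leakage.

## Dose–response fitting

Clonogenic mortality is modelled as a two-parameter Hill curve,
mortality% = 100·cʰ/(EC50ʰ + cʰ), with asymptotes fixed at 0 and 100 —
the designed assay reaches both. The fit is least squares on the linear
concentration axis over the non-zero doses (dose 0 is the reference
defining 0 % mortality and is reproduced identically by the model),
multi-started over slopes {0.5, 1, 2, 4} with a deterministic bounded
local optimizer. The EC50 start is the linear interpolation of the 50 %
crossing. A fit whose R² is non-positive (e.g. mortality decreasing in
dose) is flagged `converged=False` rather than returned silently.
Fitting the bundled HepG2 reference table gives LC50 = 0.304 µg/mL
(0.3 at one decimal) with Hill slope ≈ 1.5; the generator's default
ground truth (EC50 0.3, slope 1.6) matches this curve's shape. Simulated
assays draw colony counts as Binomial(n_cells, survival) with the
100-cell-per-well design.

## Numerical and design notes

- Working grid 1000–3000 cm⁻¹ at 1 cm⁻¹: every quoted band centre is
  on-grid, making peak worked-examples exact; the acquisition
  resolution of such instruments (4 cm⁻¹ optical) does not fix the
  digitized spacing, which is a package choice.
- Window intervals are closed on both ends, so adjacent windows
  sharing a boundary (e.g. 2500 cm⁻¹) share one grid point — harmless
  for regression and documented here.
- Seeds: one root seed per run; each stage derives a sub-seed from
  (root, CRC32(stage name)), and the 20 evaluation splits spawn
  children of the stage seed, so results are reproducible and adding a
  stage never shifts earlier streams.
- Degenerate inputs raise typed errors rather than producing silent
  output: constant spectra (normalization), missing controls (BIS),
  constant y or out-of-range component counts (PLS), short dose groups
  (splits), mortality pinned at an asymptote (Hill).
- Problem sizes in the shipped analyses and tests are the study design
  itself (63 spectra, 56 BIS rows, 20 splits, 5 windows); a full
  evaluation runs in seconds on one core.

## Limitations

- Synthetic validation only: no deposited real spectra exist to test
  against, so real-data figures of merit from comparable studies
  (e.g. test R² ≈ 0.97, 7-LV optima) are context, not targets the
  package reproduces.
- The logistic shift model and the linear marker decay are the
  package's formalization of qualitative statements ("shifts appear
  above 1.5 µg/mL", "intensities decreased with concentration"); real
  transitions may be gradual or non-monotone.
- Two-parameter Hill only; confidence intervals and count-likelihood
  (Poisson/binomial) fits are future work.
- PLS1 only (single response); no PLS2, kernel or sparse variants.
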