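# Methods

This note documents the models behind `idpchar`, the conventions and
constants they use, the design choices made where the field offers several,
and what the synthetic-data validation does and does not demonstrate.

## Sequence metrics

**Charge model.** All fraction-based metrics use the pH-7 convention:
K, R count +1; D, E count −1; histidine (side-chain pKa ≈ 6) and the chain
termini are excluded. Fractions are exact count ratios (rational arithmetic
before any rounding), so f₊ + f₋ = FCR holds identically. NCPR is computed
signed (f₊ − f₋); the absolute-value convention some tables use is exposed
as a derived accessor (`ncpr_abs`).

**κ (charge patterning).** For blob size g, each contiguous g-residue
window gets the asymmetry σ = (f₊−f₋)²/(f₊+f₋), zero for chargeless blobs;
δ is the mean squared deviation of window σ from the whole-chain σ. δ_max
comes from the maximally segregated permutation of the same composition —
all positives, then neutrals, then negatives — and its mirror, taking the
larger δ. κ is the mean of δ/δ_max over blob sizes {5, 6}. This δ_max
construction is deterministic and simple; server implementations explore
permutations more exhaustively, so third decimals can differ between tools.
κ is reported as *undefined* (an exception, never a silent 0 or NaN) for
chargeless sequences and when δ_max = 0.

**Phase diagram.** Region 4 (positive polyelectrolyte): f₊ > 0.35 and
f₋ ≤ 0.35; region 5 symmetric; region 3: FCR > 0.35 with both fractions
above 0.35; region 2: 0.25 ≤ FCR ≤ 0.35 (closed interval, so boundary
compositions classify as 2); region 1: FCR < 0.25.

**Hydropathy.** GRAVY is the unweighted mean Kyte–Doolittle value. The
charge–hydropathy plot uses window-5 Kyte–Doolittle values rescaled
linearly to [0, 1] via (h + 4.5)/9, averaged over windows; the mean net
charge is |mean per-residue charge|. The boundary line is
⟨H⟩ = (⟨R⟩ + 1.151)/2.785; a point exactly on the boundary classifies to
the ordered side (deterministic tie-break).

**Isoelectric point.** Henderson–Hasselbalch sum over termini and ionizable
side chains with the Bjellqvist/ProtParam pKa set (N-term 7.5, C-term 3.55;
K 10, R 12, H 5.98; D 4.05, E 4.45, C 9, Y 10). The net-charge curve is
strictly decreasing in pH, so bisection on [0, 14] to a 0.005 half-interval
is exact enough for 2-decimal reporting; tests check agreement with a
0.001-pH exhaustive grid and with an independent ProtParam-style
implementation.

**Masses and digestion.** Average masses come from the standard average
residue-mass table plus one water (via Biopython). The Glu-C digest cleaves
after every D and E (the enzyme's ammonium-bicarbonate specificity),
enumerating peptides up to a missed-cleavage limit with 1-based inclusive
coordinates; the zero-missed peptide masses reconstruct the intact mass
after subtracting (k−1) waters.

**Composition deviation.** (C_PX − C_SPX)/C_SPX per residue against a
frozen snapshot of the Swiss-Prot average composition (early-2021 ProtScale
table, normalized to sum to 1, overridable). A residue absent from the
sequence deviates by exactly −1; the profile is emitted in TOP-IDP
flexibility order (W…P) for plotting.

## Hydrodynamics

Four reference laws (R_S in Å, MM in Da, N residues):

| state | law |
|---|---|
| globular SEC calibrant | log R_S = 0.369·log MM − 0.254 |
| natively folded (compilation) | log R_S = 0.357·log MM − 0.204 |
| urea-unfolded | log R_S = 0.521·log MM − 0.649 |
| IDP | R_S = 2.49·N^0.509 |

**Folded-state reference.** The package provides both folded-state laws and
`profile_protein` defaults to the **calibrant** law for the R_S^NF column
and the compaction index. For the ABA-WDS reference table this is the
convention that reproduces the published values exactly (16.2 Å at
9.2 kDa; CI 0.46/0.59): the compilation law evaluates ≈0.1 Å higher
(16.26 Å, CI 0.47 after rounding). Both laws describe folded globular
proteins and differ within their calibration scatter; the choice is
recorded per profile (`nf_model`) and switchable (`nf_model="uversky"`).

The folded and unfolded laws cross near 520 Da; the profile only annotates
(rather than asserts) the folded < unfolded ordering below 1 kDa.

**SEC calibration** is linear in (elution volume, log₁₀ R_S) — the common
convention when the column's void/total volumes are not modelled — fitted
by least squares on ≥ 3 standards whose radii come from the calibrant law.
Published observed radii are treated as inputs: without the original
column's standards the printed elution volumes cannot be independently
re-converted.

The "close to IDP expectation" annotation (R_S^obs/R_S^IDP within ±15%) is
descriptive only and never tested against.

**Rounding.** Radii are reported to 1 decimal, ratios and CI to 2, matching
the conventional table format; internal values keep full precision.

## Circular dichroism

**MRE.** Θ = 3300·M·ΔA/(l·c·n) with l in cm, c in mg/mL, n residues, M in
Da. The conversion is a documented bijection; round-trips are identity to
1e−12.

**Helix fraction.** f = Θ₂₂₀ / [−39 500·(1 − 2.57/n)], clipped to [0, 1]
with a flag. The reference tends to −39 500 deg·cm²·dmol⁻¹ for long chains
and is −38 277 at n = 83.

**RC/PMG classification.** Rectangular regions on the (Θ₂₀₀, Θ₂₂₂) plane,
mean ± 2 SD of the reference protein sets of the double-wavelength plot:
RC-like Θ₂₀₀ ∈ [−24 500, −13 300], Θ₂₂₂ ∈ [−3 100, −300]; PMG-like
Θ₂₀₀ ∈ [−13 300, −8 100], Θ₂₂₂ ∈ [−6 100, −1 700]. Points outside both
boxes return "folded/other". The constants are arguments, not hard-coded
logic, so other reference sets can be substituted.

**Two-state titration.** f(c) = f_min + (f_max−f_min)·K/(1+K) with
K = exp(−ΔG(c)/RT) and ΔG(c) = m·(C_m − c), making the midpoint and
m-value direct parameters (ΔG₀ = m·C_m). T defaults to 293.15 K.

*Units.* The fit runs on whatever concentration axis the data use —
for TFE conventionally % v/v — and `m_value` is per axis unit. The m-values
conventionally quoted for TFE titrations of disordered domains
(≈0.04–0.05 kcal·mol⁻¹·M⁻¹) are numerically consistent with the %-axis
parameterization: with those magnitudes per percent, the folded fraction
moves from ≈0.1 to ≈0.9 across a 0–50 % titration, which is the observed
sigmoidal behavior; interpreted strictly per mol/L they would produce a
nearly flat curve that could not yield a sigmoidal fit. `idpchar` therefore
reports m per axis unit (matching the literature numbers) and exposes the
strict physical conversion separately (`m_value_molar`, using
1 % v/v TFE = 0.1393 M from density 1.393 g/mL and MW 100.04 g/mol).

*Estimation.* Four free parameters (C_m, m, f_min, f_max) with bounds
C_m within the padded data range, m ∈ (0, 1], baselines in [0, 1].
Initialization: C_m from interpolating the half-range crossing, baselines
from the data extremes, multi-start over m₀ ∈ {0.02, 0.05, 0.12} keeping
the best residual. On sparse designs (a 6-point titration) the plain
least-squares m-estimate is biased high by ≈5% at σ = 0.01 noise — a
generic small-sample property of sigmoid steepness estimates. The estimator
therefore offers a parametric-bootstrap bias correction
(`bias_correction="bootstrap"`): refit B simulated datasets at the fitted
parameters (noise σ known, or estimated from residuals), subtract the
estimated bias, clip to bounds. Monte-Carlo validation (100-curve
ensembles) shows the corrected mean recovers both C_m and m within ±2.5%
at the study conditions; jackknife correction was rejected as unstable at
n = 6. Fits flag midpoints outside the sampled range and inverted
baselines. Recovery is only asserted for adequately sampled transitions
(folded-fraction span ≳ 0.6 across the grid); shallower designs are
flagged as extrapolated rather than held to recovery tolerances.

**Isodichroic point.** Spectra are interpolated onto a common 0.1-nm grid;
the candidate is the wavelength minimizing the across-spectra spread
(max − min). Detection requires the minimal spread to be below 5% of the
family's dynamic range, and fails (returns none, with the reason) for
degenerate families — identical spectra have no unique crossing. Subset
selection lets callers exclude outlier conditions, mirroring the practice
of excluding a spectrum that breaks the two-state family.

**Thermal scans.** Slope of Θ₂₃₀ vs T by least squares; hysteresis is the
mean |heating − cooling| over the shared range divided by the heating
signal range; below 0.05 counts as reversible (an operational threshold).

**Basis unmixing.** Non-negative least squares with the fractions summing
to 1 (weighted augmentation row, then exact renormalization); the basis
condition number is checked first. The bundled basis shapes are *synthetic*
analytic Gaussian mixtures sketching helix / strand / turn / unordered
far-UV bands — stand-ins for empirical deconvolution reference sets, good
for validating the unmixing machinery, not for quantitative secondary
structure of real spectra.

## Assays

Activity = ΔA₃₄₀/min × 8095 (U/L), linear by construction. Residual
activity is relative to the same series' pre-stress baseline, normalized
per replicate and then averaged. Viability = 100 × mean(stressed colonies)
/ mean(control colonies), scale-invariant; fold-changes divide by the
empty-vector reference strain's ratio. The significance test is the classic
pooled-variance Student t (two-sided), with Welch behind a flag; replicate
aggregation defaults to mean ± SD of triplicates.

## Synthetic generators and what passing tests show

Every generator is a pure function of (parameters, seed):

- **Sequences**: exact charge composition (counts must be integral), with
  an optional κ target reached by greedy stochastic swaps (the fully
  segregated arrangement is constructed directly for κ → 1).
- **Titrations**: the two-state model plus Gaussian noise, truncated to
  [0, 1]; replicate k depends only on (seed, k). Defaults mirror the
  ABA-WDS study conditions: 0–50 % TFE in steps of 10, midpoint 27 %,
  m = 0.049 per %, baselines 0.05 → 0.40 (the plateau implied by a ≈35 %
  helix reading at 50 % TFE on an 87%-complete transition), σ = 0.01.
- **CD families**: convex mixtures of two bases shifted to intersect at a
  chosen wavelength — an exact isodichroic construction.
- **SEC standards**: radii from the calibrant law, elution volumes from the
  inverse column line plus volume noise.
- **Protection**: A(t) = A₀·exp(−k·t/factor); the default k makes the
  unprotected residual 11% at 60 min, the canonical unprotected-LDH end
  point.

The generators produce idealized data: Gaussian noise, no baseline drift,
no instrument artefacts (HT voltage saturation, smoothing), no aggregation.
Passing round-trip tests therefore demonstrates the *correctness of the
estimators under their own model assumptions* — that parameters generating
the data are recovered at the stated noise — not the accuracy of any
instrument-facing step on real spectra. Values that only instruments can
supply (measured masses, absolute deconvoluted structure content, measured
residual activities) are treated as inputs or qualitative patterns, never
recomputed.

## Problem sizes and tolerances

The Monte-Carlo suites use 100–200 replicates (recovery means), 200 seeds
(SEC calibration coverage), and 100 random sequences (pI oracle), sizes at
which the standard error of each checked mean is a few tenths of the
allowed tolerance. Self-test recovery bands widen by twice the Monte-Carlo
standard error when reduced replicate counts are requested. Numerical
tolerances: pI bisection 0.005 pH; isodichroic grid 0.1 nm with a ±1 nm
acceptance; unmixing simplex closure 1e−9; MRE round trip 1e−12.

## Known limitations

- κ's δ_max construction is a deterministic approximation; third-decimal
  differences against permutation-search implementations are expected.
- The pI pKa set is one of several in circulation; values shift by ~0.1 pH
  between sets.
- The RC/PMG boxes are rectangular simplifications of empirical scatter.
- SEC calibration ignores column physics (void/total volumes, K_av).
- The two-state m-value's physical molar interpretation for volume-percent
  osmolytes is convention-laden; both conventions are exposed and the
  default matches the literature's numeric usage.
- Basis unmixing with the bundled synthetic shapes is a validation tool,
  not a replacement for empirical reference-set deconvolution.
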