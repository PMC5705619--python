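# Methods

## Scope and data

The package implements a terrestrial radiological assessment for soil:
per-sample ²³⁸U, ²³²Th and ⁴⁰K activity concentrations (Bq/kg, with 1σ
instrument uncertainties) are converted to absorbed dose rate, annual
effective dose, radium equivalent activity, hazard indices, excess
lifetime cancer risk and NORM screening classifications, and activities
are projected in time by the exponential decay law and by a quartic
polynomial approximation of the decay factor.  The bundled reference
dataset is a 26-sample survey of coastal soil along the Tano oil basin
(Ghana); its published per-sample results are also bundled, as printed,
for regression verification.

## Dosimetry

The absorbed dose rate in air 1 m above ground is the standard linear
combination with UNSCEAR conversion coefficients (nGy/h per Bq/kg):
0.462 for ²³⁸U (via its ²²⁶Ra-led gamma emitters), 0.604 for ²³²Th and
0.0417 for ⁴⁰K.  The annual effective dose applies an outdoor occupancy
of 0.20, a 365.25-day year (T = 1753.2 h/y) and a combined conversion
of 0.7×10⁻³ µSv per nGy, so E/D = 1.22724 µSv/y per nGy/h.  All three
constants are configurable through `DoseCoefficients`.

**Uncertainty propagation** defaults to linear absolute summation
(Σ|kᵢ|·σᵢ rather than the quadrature root-sum-square).  The survey's
quoted ± values are only reproduced under this mode — e.g. sample SS1
gives ±3.28 → "3.3" linearly but ±2.12 in quadrature — so linear is the
default and quadrature an explicit option.  Linear summation treats the
three nuclide terms as fully correlated; for survey-style screening it
is the conservative choice.

## Hazard and risk indices

Radium equivalent activity, H_ex and H_in follow the usual definitions
(370, 259 and 4810 Bq/kg of Ra/Th/K produce equal dose).  Two exact
identities, H_ex = Ra_eq/370 and H_in − H_ex = C_U/370, are enforced by
construction and property-tested.  Under the secular-equilibrium
assumption the measured ²³⁸U concentration fills the ²²⁶Ra slot in all
three formulas, matching the source analysis.  ELCR uses a 70-year
duration of life and the ICRP public risk factor 0.05/Sv (both
configurable via `RiskConfig`), giving 3.5×10⁻⁶ per µSv/y of effective
dose.

NORM screening is boundary-inclusive (an activity exactly at the
exemption level is exempt).  The exemption registry is carried verbatim;
its physically impossible "Pb-238" row (no such nuclide) is retained
under the label "Pb-238 (as printed)" but excluded from default
screening rather than silently reassigned to ²¹⁰Pb or ²³⁸U.  The soil
²²⁶Ra screen allows at most 0.185 Bq/g (5 pCi/g) above background.

## Gamma spectrometry

Specific activity per line is A = N·e^(λ_p·T_d)/(p·T_c·η·m).  N is
interpreted as total net counts over the live time (not a rate): that is
the only reading of the formula that yields Bq/kg.  Series activities
average the per-line activities with equal weights, and the quoted
uncertainty is the linear mean of the per-line Poisson uncertainties
(A/√N).  That reported uncertainty deliberately over-covers the mean of
m lines by roughly √m — it describes a typical single line — which the
Monte-Carlo coverage test makes visible (3σ coverage ≈ 100 %).

The line registry is the union list across the survey's two methods
descriptions: 295.2, 351.93, 609.31, 1764.49 keV for the ²³⁸U series;
238.63, 583.19, 911.21, 2614.53 keV for ²³²Th; 1460.83 keV for ⁴⁰K.
Emission probabilities are not part of the survey data; the bundled
values are standard evaluated decay-data constants, expressed per parent
decay (the Tl-208 lines include the 35.9 % branching).  The decay
correction e^(λ_p·T_d) uses the parent's decay constant and is ≈ 1 for
the primordial parents on any laboratory timescale; tests assert that
near-identity.  No efficiency-curve model is fitted: efficiency is
supplied per line as a number, with defaults plausible for a ~30 %
relative-efficiency HPGe and 1 L Marinelli geometry.  Default live time
is 36000 s and sample mass 1 kg, the survey's acquisition settings.

## Decay simulation

Exact decay uses λ = ln2/half-life with the survey's rounded half-lives:
4×10⁹ y (²³⁸U), 1.4×10¹⁰ y (²³²Th), 1.25×10⁹ y (⁴⁰K); these are
overridable.  The quartic approximant interpolates e^(−z) on the
equispaced nodes z ∈ {0, 1, 2, 3, 4} (h = 1) via the forward-difference
table, aₖ = Δᵏy₀/(k!·hᵏ).  This node choice is the one whose expanded
coefficients round to the published quartic
(1, −0.9560, 0.3993, −0.0820, 0.0067) at 4 d.p., which the tests verify.
Numerically the Newton form is evaluated by nested products (preferred)
and the power form by Horner's rule; both agree to < 10⁻⁹ on the span.
The dense-grid maximum deviation from e^(−z) on [0, 4] is 6.2×10⁻³, and
the low-z relative bias is |d + 1|·z ≈ 0.044·z — visible in curve
comparisons but irrelevant at survey horizons where z ≲ 10⁻⁶.
Extrapolation beyond z = 4 is refused by default because the quartic
diverges; `allow_extrapolation=True` overrides (the long-horizon curve
generator uses it deliberately to illustrate the divergence).

Simulation horizons default to 100, 10⁴, 10⁸ and 10⁹ years.  The two
longest are generated as a pair because the source figures for the long
horizon are not distinguishable from their captions; 10⁸/10⁹ y is a
reasonable reading and is documented here as a choice.  Survey-mean
activities are decayed by default; per-sample curves are available by
passing any initial-activity mapping.

## Synthetic data

Activity tables are drawn per nuclide from truncated lognormals —
positive support and right skew are typical of environmental
radiometry; the survey itself fits no distribution, so the family is an
explicit modelling stand-in.  Truncation bounds equal the survey's
observed ranges (U 1.60–21.3, Th 2.78–32.2, K 111–528 Bq/kg), the
log-scale spread is set so the observed range spans about four log-σ
(0.65, 0.61, 0.39), and the location is calibrated in closed form so
the truncated mean equals the observed column mean (8.64, 12.5,
214 Bq/kg).  Relative 1σ uncertainties are uniform on [0.02, 0.25],
covering the bulk of the survey's quoted precisions.  Counting data
invert the quantification formula: expected counts A·p·T_c·η·m·e^(−λT_d)
feed a Poisson draw per line.

What the generator does *not* emulate: spatial correlation between
samples, soil-property covariates, inter-nuclide correlation, detector
backgrounds and peak-fitting error.  Passing recovery tests therefore
demonstrate correctness of the computational chain under idealized
counting statistics, not field performance.

A single integer seed drives named, independently spawnable streams per
stage (`stage_rng`), so the activity and counting stages regenerate
independently and the full pipeline is bit-stable for a fixed seed.

## Verification against the published tables

The published per-sample dose and hazard tables are bundled as printed
strings.  Each recomputed cell must agree within 1 % relative **or**
within one unit in the last printed digit (after rounding the computed
value to the printed precision) — the latter absorbs pure
print-rounding of 2-significant-figure cells.  Nine of 364 cells are
whitelisted as internally inconsistent in the source, each with a note
showing the arithmetic: one contribution percentage contradicted by the
table's own minimum row, one radium-equivalent cell contradicted by its
own row's hazard index, and seven ± cells (all on rows whose potassium
uncertainty carries an anomalous "+ x.x0" print) that follow no
consistent propagation.  All 26 central values of every quantity
reproduce.  The published survey-wide mean Ra_eq (43.4 Bq/kg) exceeds
the mean of its own per-sample column; the recomputed 42.98 is reported
instead and the discrepancy documented here, not reproduced.

## Problem sizes and numerical choices

The fixture pipeline (26 samples) runs in well under a second; the
Monte-Carlo studies use 200 replicates for calibration checks and 1000
for coverage, sizes at which the binomial error on a 99 % coverage
criterion is ≈ 0.3 %.  Interpolant node exactness is asserted at 10⁻¹²,
Newton-vs-power agreement at 10⁻⁹ (the expanded form loses a few digits
to cancellation), and the decay semigroup property at 10⁻¹² relative.
Degenerate inputs fail loudly: empty tables, zero dose (undefined
contribution percentages), non-positive efficiency/mass/live time,
unequal node spacing and out-of-span evaluation all raise with the
offending quantity named.

## Known limitations

Single-exponential decay only — no Bateman chains, progeny in-growth or
disequilibrium; external gamma dose only — no radon inhalation or
ingestion pathways; no spectrum-file parsing, peak fitting, coincidence
summing or self-absorption corrections; and the printed 3-significant-
figure inputs bound any reproduction of the published tables at roughly
the 1 % level, which is why that tolerance is the verification default.
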