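# Methods

This note documents the models implemented in `fishbcf`, the default
parameter values and why they were chosen, the numerical conventions, and
what the synthetic-data generator does and does not emulate.

## In vitro clearance (depletion assay)

Substrate depletion in a hepatocyte suspension is modeled as first order,
C(t) = C₀ e^(−kt).  The fit is unweighted ordinary least squares on
log₁₀ C versus time in hours, k = −ln(10) · slope.  The factor is the exact
ln 10 = 2.302585…, not the commonly printed rounded 2.3 (difference < 0.2 %).
Fitting raw or first-point-normalised concentrations gives the same slope;
normalisation (`normalize_to_first`) is provided for presentation only.
CL_int = k / cell density, with the nominal density 2 × 10⁶ viable cells/mL.

**Linear-window policy.**  Cryopreserved cells can lose activity late in the
4 h incubation, flattening the tail of the log curve.  The default policy
refits without the final point and drops it when its standardized residual
(prediction error over the residual standard error of the remaining-point
fit) exceeds 2.0, at most once (`max_drop = 1` matches the observed practice
of excluding only the 4 h sample); the window never shrinks below 3 points,
and requesting more drops than the floor allows is an error.  An absolute
residual floor of 10⁻⁹ log₁₀ units prevents numerically perfect fits from
triggering the test.  Concentrations at or below a configurable LOQ are
excluded, never substituted, because substitution biases the slope.

**Run-level estimation.**  `estimate_clearance` pools the replicates of a run
into one regression after deciding the window on the replicate-mean curve;
per-replicate fits feed the intra-assay %CV.  Across-run summaries use the
sample (n−1) standard deviation and %CV = 100 · SD/mean.

**Dead-cell QC.**  A run passes when the heat-inactivated control's loss
rate is ≤ 5 % of the live rate (boundary inclusive).  A non-positive live
rate yields an "undefined" QC flag rather than an error, since a no-depletion
run is a scientific result, not a programming fault.

## IVIVE chain

CL_int (mL/h/10⁶ cells) × hepatocellularity (510 × 10⁶ cells/g liver,
an empirical trout value applied to both species) × liver fraction
(0.015 trout, 0.0174 carp, g liver/g fish) × 24 gives CL_in vivo,int in
L/d/kg fish.  The printed "fractional liver weight of 0.015 g/kg" is
interpreted as the unitless fraction g liver per g fish; the scaling chain is
dimensionally consistent only under that reading.

**Binding.**  f_u = f_u,blood / f_u,incubation with the defaults

    P_BW    = 0.16·10^(0.73·logKow) + 0.84          (blood–water partition)
    f_u,bl  = 1 / P_BW
    f_u,inc = 1 / (1 + 125·VR·10^(0.072·logKow² + 0.067·logKow − 1.126))

VR = 0.005 mL cells per mL incubation at 2 × 10⁶ cells/mL.  Alternatively
f_u = 1 ("unity" mode).  Values above 1 are warned about but not clamped, so
configuration errors stay visible.  Note that because the incubation term is
quadratic in log K_OW, f_u has a minimum near log K_OW ≈ 5.3 and rises again
for more hydrophobic chemicals; it is monotone decreasing only below that.

**Blood flow and clearance.**  Cardiac output
Q_C = (0.23·T − 0.78)·(W_g/500)^−0.1 L/h/kg (validated 0–35 °C; the linear
temperature term makes the relation unusable below ≈ 3.4 °C, which is
rejected), hepatic fraction 0.259, Q_H = 0.259 · Q_C · 24 L/d/kg.  The
well-stirred liver model CL_H = Q_H f_u CL_int / (Q_H + f_u CL_int)
interpolates between the binding/enzyme limit (f_u CL_int ≪ Q_H) and the
perfusion limit Q_H.

**Rate constant.**  V_D = lipid_fraction · K_OW / P_BW (L/kg, referenced to
blood) and k_B = CL_H / V_D (1/d).  Carp uses the same binding and blood-flow
algorithms as trout, re-parameterized only through the physiology block; no
carp-specific sub-models are available in the literature the defaults derive
from.

The exact binding QSAR, cardiac-output relation and V_D referencing used in
any particular published application are properties of that application's
model version; here they are one concrete, internally consistent default
suite with every coefficient exposed in `BindingModel` / `FishPhysiology`,
so alternative sub-models can be swapped in as data.  With the defaults, the
four study-case k_B values come out at 0.020–0.044 1/d, within a factor of
2 of reported reference values (0.03–0.08 1/d); the residual offset is
attributable to the binding/blood-flow sub-model ambiguity and is why the
k_B-level comparisons in the acceptance tests use factor-of-2 bounds while
the BCF-level comparisons (where the offset partially cancels) use ±15 %.

## Mass-balance BCF model

One well-mixed compartment exposed via water:
BCF = k₁ / (k₂ + k_E + k_G + k_B).  Default correlations (W in kg, T in °C):

    C_OX = saturation · 468/(31.6 + T)              mg/L
    E_W  = (1.85 + 155/K_OW)⁻¹                      gill uptake efficiency
    G_V  = 1400·W^0.65 / C_OX                       ventilation, L/d
    k₁   = E_W·G_V / W                              L/kg/d
    k₂   = k₁ / K_FW,  K_FW = lipid·K_OW            1/d
    G_D  = 0.022·W^0.85·e^(0.06·T)                  feeding, kg/d
    E_D  = (3×10⁻⁷·K_OW + 2)⁻¹                      diet uptake efficiency
    k_E  = 0.125·E_D·G_D / W                        1/d
    k_G  = c·W^−0.2, c = 5×10⁻⁴ (cold) / 2.51×10⁻³ (warm)

K_FW is lipid-only by default; a non-lipid organic-matter term
(sorptive capacity 0.035 relative to lipid) can be enabled in the suite.
Growth regime follows the species (trout cold, carp warm); a measured growth
rate fitted from fish weights can override the allometric k_G.  One suite
serves both the forward BCF prediction and the in vivo k_B back-calculation
k_B = k_T − (k₂ + k_E + k_G); using a single internally consistent closure
for both directions was preferred over mixing two external model variants,
so round-trip identities hold exactly.  Negative back-calculated k_B is
reported with a "not distinguishable from zero" flag, never truncated.
Multiplicative uncertainty factors give k_B ranges (k_B/UF, k_B·UF).

## TG 305 evaluation

TWA water concentration is the trapezoidal (interval-weighted) mean of the
sampled series, invariant under refinement of a piecewise-linear grid.
BCF_SS = mean of all individual fish concentrations on plateau days / TWA.
Plateau days are user-specified or auto-detected as the longest terminal run
of ≥ 3 uptake sampling days whose day-mean log concentrations show no
significant log-linear trend (α = 0.05).  The depuration fit is OLS on
ln C_f versus days since transfer to clean water (the log-linear form of the
printed exponential), fish treated as independent observations without
pooling; k_T = −slope, C_f,0 = e^intercept.  Non-positive concentrations are
excluded with a warning.  Wet-weight BCFs are reported; lipid normalisation
is deliberately not applied.

## Synthetic data

Noise on every concentration is multiplicative lognormal with mean exactly 1
and a specified CV (σ² = ln(1 + CV²), mean offset −σ²/2) — the standard
model for analytical scatter, and the regime in which log-space OLS is
unbiased, which is why the Monte-Carlo recovery tests can demand median
biases of a few percent.  Depletion scenarios default to the assay design:
8 samples at 5–240 min, triplicates, c₀ = 2 µM, CV 10 % (a BaP-like constant
of 15 % reflects the larger scatter seen without an internal standard), and
a small constant-rate abiotic loss (0.01 1/h, i.e. 2 % of a typical live
rate) in the heat-inactivated control — the constant-rate form of the dead
control is an assumption of convenience.  Study scenarios default to 35 d
uptake (sampling days 0, 7, 14, 21, 28, 31, 35) + 35 d depuration (4, 10,
21, 35), 4 fish/day, water sampled every 7/3 d at CV 20 %, fish noise CV
15 %, exponential weight growth.  Fish follow the one-compartment solution
with constant water concentration; the generator does not emulate
time-varying exposure, multi-compartment kinetics, metabolite formation,
below-LOQ censoring or inter-laboratory effects, so recovery results bound
estimator behaviour under the design's idealised kinetics only.  A master
seed fans out to per-component substreams, so adding replicates or fish does
not perturb existing draws.  The `recovery_report` harness fixes plateau
days to the design's final three uptake sampling days and measures bias
against the noise-free value of the same estimator, so zero-noise biases are
exactly zero by construction.

## Numerical conventions and problem sizes

All rates are reported in 1/d (in vitro fits in 1/h), clearances in L/d/kg,
volumes in L/kg, BCFs in L/kg wet weight.  r² is defined as 0 for a
zero-variance response.  Unit conversions (min→h, g→kg) happen once at the
I/O boundary.  The Monte-Carlo suites use 1000 triplicate depletion runs at
CV 10 % (k ∈ {0.1, 0.5, 1.0} 1/h) and 500 simulated studies at 15 % fish
noise; secondary recovery comparisons use 60–200 seeds, sizes chosen so the
medians under test are stable to well under their tolerance.

## Known limitations

Single-species trout defaults stand behind the carp parameterization except
where carp values exist (liver fraction, temperature, mass, lipid, growth
regime); hepatocellularity in particular varies with nutritional state.
Extrahepatic biotransformation is not modeled, so extrapolated k_B is a
liver-only lower bound relative to whole-body in vivo estimates.  The BCF
model ignores dietary exposure and time-variable temperature.
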