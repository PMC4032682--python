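# Methods

## Hemodynamic quantitation

Each of the three measurement sites of an AV access (arterial anastomosis A,
loop L, venous anastomosis V) contributes one `SiteMeasurement`: peak-systolic
velocity V_p and peak-diastolic velocity V_m in cm/s, heart rate in Hz, and
the site's hydraulic diameter D_H in mm (velocities and diameters cross the
I/O boundary in clinical units and are converted to SI internally). The
hydraulic diameter of a noncircular lumen is D_H = 4A/P with P the wetted
perimeter, reducing to the geometric diameter for a circular duct.

The dimensionless numbers are not printed as closed forms in the source
literature for this pipeline, so the package adopts the canonical pipe-flow
definitions:

- Re = ρ V D_H / μ (inertial / viscous forces),
- α = (D_H/2)·√(ω/ν), ω = 2πf, ν = μ/ρ (pulsatile frequency / viscous
  effects),
- St = f·D_H / V (oscillatory / convective inertia),

with **V = V_p** throughout, because the transition criterion they feed,
Re_peak = 169·α^0.83·St^−0.27, is a *peak-flow* threshold. Using a mean or
time-averaged velocity instead would shrink Re and grow St, changing the
magnitude (not the loop-normalised pattern) of Re_supra = |Re − Re_peak|;
peak-systolic is the only choice consistent with the criterion's derivation.

Blood defaults are whole blood at 40 % hematocrit: ρ = 1055 kg/m³,
μ = 0.01063 N·s/m². The pressure drop ΔP = 4·V_p² (V_p in m/s, ΔP in mmHg)
is the simplified Bernoulli relation of clinical echocardiography and is
reported per site but not used by the classifier.

The feature pattern is Φ = [Ratio_A, Ratio_L, Ratio_V, Res_A, Res_L, Res_V]
with Ratio_s = Re_supra(s)/Re_supra(L). The loop site is the per-unit basis,
so Ratio_L ≡ 1; if Re_supra(L) is zero to a 1e−9 tolerance (the loop sitting
exactly at the transition point) the normalisation is undefined and a
`DegenerateLoopError` is raised rather than returning infinities. The
printed form of the venous ratio in the source material carries an A-site
numerator, which its own worked examples contradict (Ratio_V ≠ Ratio_A for
every tabulated subject); the loop-normalised form is implemented. The
end-diastolic velocity V_ed is carried through I/O but does not enter Φ.

## Color relation analysis classifier

Given a query Φ_r and K labelled training patterns, the classifier computes
Euclidean distances ED(k), gray grades ρ(k) = ξ·e^(−ξ·ED(k)) (ρ ∈ (0, ξ],
strictly decreasing in distance), class-average grades, and an HSV-style
decision transform. The channels are inverted and range-normalised,

    r = (ρ_max − ρ_ave^III)/Δρ,  g = (ρ_max − ρ_ave^I)/Δρ,
    b = (ρ_max − ρ_ave^II)/Δρ,   Δρ = ρ_max − ρ_min,

so exactly one channel is 0 and one is 1. The hue is one 60° hexcone sector
anchored at the branch offset of the class whose mean attains ρ_max; the
channel differences are used directly (they are already Δρ-normalised, so a
second division by Δρ would be redundant). Saturation S = (γ − ρ_min)/γ and
value γ = ρ_max; S is reported as a confidence index but does not enter the
decision. Hue and saturation are invariant under common positive scaling of
the class means; only γ scales.

Two branch conventions are provided:

- `class_centered` (default): Class I → offset 240°, Class II → 120°,
  Class III → mod-360 (red). A query most similar to class c lands within
  ±60° of c's decision angle, consistent with the critical decisions
  H_C = H/360 ∈ {2/3, 1/3, 1}.
- `as_printed`: the literal published branch assignment, which attaches
  120° to Class I and 240° to Class II. It is kept for comparability but is
  mutually inconsistent with the critical decisions (a Class I query then
  always lands nearest H_C = 1/3); only the red branch behaves identically
  under both conventions.

Classification is nearest critical decision under circular distance
d(x, y) = min(|x − y|, 1 − |x − y|) on [0, 1). Degenerate queries (all class
means equal, hue undefined) yield an `unclassifiable` result rather than an
exception so batch runs proceed. If two class means tie for ρ_max with
Δρ > 0, the branch is chosen by the fixed priority III > II > I and the
result is flagged low-confidence. An optional intensity-rescaling step
(min–max mapping of the grades to [0, 1] before class averaging) is
implemented but off by default, preserving the plain class-average
definition.

### Training objective

The mean squared error function MSEF = (1/K)·Σ[T(k) − H_C(k)]² compares each
training pattern's realised decision value with its class target. Two error
modes exist: `wrapped` (default) uses the circular difference — necessary
because Class III's target 1 is the same point as hue 0, so near-perfect
Class III classifications (hue a few degrees above 0°) would otherwise incur
errors near 1 and the 0.05 convergence threshold could never be met — and
`plain` uses the literal difference. Fitness is evaluated **leave-one-out**:
each training pattern is classified against the other K − 1. Resubstitution
would plant a self-match at ED = 0 whose grade ξ dominates every class mean
as ξ grows, making ξ → ∞ a degenerate optimum. An unclassifiable
leave-one-out evaluation is charged the maximum wrapped squared error 0.25.

## TVAC particle swarm

A scalar swarm of G = 20 particles searches ξ ∈ (0, 50] for up to
p_max = 100 iterations. The acceleration coefficients vary linearly with
iteration: cognitive c1 from 2.5 to 0.5, social c2 from 0.5 to 2.5
(exploration → consensus). The inertia weight is not fixed by the TVAC
scheme; the default is the standard linear decay 0.9 → 0.4, configurable to
a constant. Velocities are clamped to 20 % of the bound range and positions
clipped to the bounds; the upper bound 50 exists because grades underflow
for large ξ, flattening the fitness landscape. Personal/global bests update
only on strict improvement, so the best-fitness trace is non-increasing;
iteration stops at the first of MSEF ≤ ε = 0.05 or p = p_max. All
randomness comes from one seeded generator, making runs bit-reproducible.

In practice the leave-one-out fitness surface on default synthetic cohorts
is shallow, with values below 0.05 over a wide ξ range (minimum typically
near ξ ≈ 8–15); the swarm therefore frequently satisfies the convergence
condition already in the initial population. Runs to p_max (small ε) agree
with a 400-point grid scan of the same fitness to 1e−3.

## Synthetic cohort generator

The generator emulates the published group statistics of a 30-patient
cohort: per class (I/II/III, default sizes 12/11/7) and per site, (V_p, V_m)
are drawn from a correlated bivariate normal with the published marginal
means and SDs, resampled until 0 < V_m < V_p. The V_p–V_m correlation (0.7,
configurable) is a modelling assumption — only marginal moments are
published — chosen because independent draws produce implausible V_p/V_m
ratios, which the source treats as a stable trend statistic (> 3.0 in
diseased accesses). The truncation shifts means slightly upward (Class III
loop site: V_p 25.61 → 26.13 cm/s under the truncated law); tests check
moments against the truncated distribution.

Heart rate is uniform on 1.00–1.25 Hz per subject; one baseline hydraulic
diameter per subject is N(5, 0.5) mm truncated above 2 mm. DOS is uniform
inside the subject's class band (defaults U(0.05, 0.30), U(0.30, 0.50),
U(0.50, 0.95)) and the stenosis is localised at the loop segment: the
loop-site measured diameter is D_H·√(1 − DOS) while A and V keep the
baseline, consistent with the collapse of loop-site velocities in severe
disease. V_ed defaults to 0.6·V_m (unused by Φ).

What the generator does **not** emulate: the cross-site, within-subject
correlation structure of real patients (each site's velocities are drawn
independently given the class), measurement noise models, wall motion, or
any coupling between the drawn DOS value and the velocity draw inside a
class. Consequently the synthetic classes overlap more than a real cohort
with coherent per-patient physiology would: the Bayes ceiling of the default
synthetic feature distributions is ≈ 0.89 (cross-validated random forest on
6,000 subjects), and the PSO-tuned CRA reaches a held-out median accuracy of
≈ 0.80 over ten 30-train/10-test splits — while meeting the MSEF ≤ 0.05
training condition in every seed. Passing tests on synthetic data therefore
demonstrate the correctness and convergence of the machinery, not the
clinical accuracy attainable on real, structured examinations. On
well-separated cohorts (velocity SDs scaled to 25 %) the full
simulate → featurize → train → classify pipeline recovers labels with 100 %
median held-out accuracy.

The waveform toolkit synthesizes a two-raised-Gaussian pulse train (systolic
peak at V_p, broader diastolic peak at V_m, floor V_ed) with optional
Gaussian noise — the simplest shape carrying the named landmarks, not an
acoustics simulation. Landmark extraction segments the series by the first
strong autocorrelation peak (lag restricted to heart rates 0.33–4 Hz,
rejected if below 20 % of the zero-lag power) and takes per-cycle medians:
the maximum for V_p, the minimum for V_ed, and the largest local maximum at
least a tenth of a cycle away from the systolic peak for V_m. Clean
round-trips recover all landmarks within 2 %; at noise SD 2 cm/s the
per-cycle extrema acquire noise-extreme bias, so only V_p (within 5 %) and
the heart rate are reliable.

## Numerical and interface choices

- Degenerate denominators and hues raise typed errors
  (`DegenerateLoopError`, `DegenerateHueError`); batch classification maps
  the latter to an unclassifiable flag.
- DOS class bands: DOS < 0.30 → I, 0.30 ≤ DOS ≤ 0.50 → II, > 0.50 → III;
  the band edges (open intervals in the clinical definition) are assigned to
  Class II deterministically.
- CSVs are comma-separated UTF-8 with mandatory headers and '.' decimals;
  outputs carry `#` provenance comments (tool version, seed, config digest —
  no timestamps, so fixed-seed runs are byte-identical). Hue angles print to
  4 decimal places.
- The model file is versioned JSON embedding the training patterns; loading
  validates the schema version and ξ > 0.
- Leave-one-out fitness precomputes the K×K distance matrix once, so each
  swarm evaluation is O(K²) scalar work; a full training run on K = 30
  completes in well under a second.

## Known limitations

- The published per-subject hue angles and the reported optimum
  ξ = 7.9883 depend on the authors' unpublished 30-subject feature matrix;
  they serve only as direction/plausibility references (severe stenosis near
  the red sector, patent access near blue), not numeric targets.
- Whether hydraulic diameter differs per site in real examinations is
  unspecified; the interface allows per-site values, and the generator
  varies only the loop site.
- Saturation is reported but unused in the decision; whether it should gate
  low-confidence calls is an open design question.
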