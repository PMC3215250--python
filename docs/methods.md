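# Methods

## Physical model

Two-site chemical exchange A ⇌ B between a major conformation (population
p_a) and a minor one (p_b = 1 − p_a < 0.5), with total exchange rate
kex = k_ab + k_ba and a chemical shift difference δω (rad/s) between the
states. During a constant-time CPMG element of length T_CPMG, refocusing
pulses applied at frequency ν_CPMG partially quench the exchange
contribution to transverse relaxation, so the effective rate

    R2eff(ν) = (1/T_CPMG) · ln[I(0)/I(ν)]

disperses from R2⁰ + Rex at low ν down to the exchange-free baseline R2⁰
at high ν. Three descriptions are fitted:

* **Model 1, no exchange**: R2eff = R2⁰.
* **Model 2, fast limit (kex ≫ δω)**, Luz-Meiboom:
  R2eff = R2⁰ + (Φ/kex)[1 − (4ν/kex)·tanh(kex/4ν)] with
  Φ = p_a·p_b·δω². In this limit only the composite Φ is observable;
  populations and δω cannot be separated. Rex = Φ/kex.
* **Model 3, slow limit (kex ≪ δω)**, Carver-Richards:
  R2eff = R2⁰ + kex/2 − ν·acosh[D₊cosh(η₊) − D₋cos(η₋)] with
  Ψ = kex² − δω², ξ = −2δω·kex·(p_a − p_b),
  D± = ½[±1 + (Ψ + 2δω²)/√(Ψ² + ξ²)],
  η± = √(±Ψ + √(Ψ² + ξ²)) / (2√2·ν).
  Rex = p_a·p_b·kex / (1 + (kex/δω)²).

δω is stored at a declared reference field and scales linearly with the
spectrometer frequency (Φ therefore quadratically); ν_CPMG is used
exactly as supplied, with no τ_cp reinterpretation.

Numerical safeguards in the slow-limit expression: the acosh argument is
clamped at 1 (logged at debug level) to absorb floating-point undershoot
near the no-exchange limit; for η₊ > 30 the asymptotic form
acosh(D₊cosh η₊ − …) → η₊ + ln D₊ avoids cosh overflow (the D₋ term is
exponentially negligible there); δω = 0 or p_b = 0 return R2⁰ exactly.
The slow-limit curve is *not* globally monotone in ν: when the pulse
rate is below the shift difference (ν < δω/2π) the cos(η₋) term produces
genuine small ripples. Monotone relaxation toward R2⁰ holds on the
refocusing band ν ≥ δω/2π, which is what the property tests assert.

## From intensities to profiles

I(0) is the mean of the reference-spectrum intensities per residue
(multiple references are averaged). Non-positive intensities make a
point missing; negative R2eff values (I(ν) > I(0)) are kept but flagged,
with an option to drop them. The per-residue uncertainty σ_R2eff is the
pooled standard deviation over replicate groups,

    σ² = Σ_j s_j²(n_j − 1) / Σ_j (n_j − 1),

held constant within a residue and per field (two ν values closer than
0.5 Hz form one replicate group). Residues without any replicates fall
back to 2% (configurable) of their median R2eff, with a warning; a
degenerate zero σ is floored at 1e-6 1/s to keep χ² finite.

## Fitting

The target is χ² = Σ_n (R2eff_calc − R2eff_n)²/σ², minimized with
bounded trust-region least squares (scipy `least_squares`, method
`trf`). One joint machinery covers per-residue, global (multi-field),
and cluster (multi-residue) fits through a parameter vector
[one R2⁰ per series, shared kex, shared p_b, one amplitude (Φ or δω)
per residue], with the amplitude evaluated per field through the linear
(δω) or quadratic (Φ) field scaling. Parameter counts: 1 / 3 / 4 for
models 1–3 single-field, plus one R2⁰ per extra field, plus one
amplitude (+ baselines) per extra cluster member.

Starts are a deterministic grid: kex ∈ {100, 500, 1000, 3000, 8000}
1/s, p_b ∈ {0.01, 0.05, 0.1, 0.3}; the amplitude start derives from the
observed low-minus-high-ν R2eff difference (Φ̂ ≈ ΔR·kex, δω̂ =
√(Φ̂/(p_b(1−p_b)))) and R2⁰ starts at the highest-ν R2eff. Bounds:
R2⁰ ∈ (0, 200], kex ∈ (0, 10⁶] 1/s, p_b ∈ [10⁻⁴, 0.5],
δω ∈ [0, 10⁵] rad/s, Φ ∈ [0, 10⁹] (rad/s)². Tolerances 1e-10 on cost,
parameters and gradient, at most 2000 function evaluations per start;
the lowest-χ² start wins, ties broken by grid order. Noiseless
round-trip recovery is exact to well below 0.1% relative for all three
models in all three fit modes.

## Model selection

χ²-form information criteria (appropriate for weighted least squares
with known σ): AIC = χ² + 2k, AICc = χ² + 2k + 2k(k+1)/(n−k−1), lower
wins, ties within 1e-9 go to the simpler model. The F-test alternative
compares along the chain 1 → 2 → winner vs 3 with
F = ((χ²_s − χ²_c)/(k_c − k_s))/(χ²_c/(n − k_c)) and keeps the complex
model iff p < α (default 0.05). Rex is reported for the winning model.

## Monte Carlo uncertainties

Parametric Monte Carlo around the best-fit curve: each of n_sims
(default 500) simulations adds Gaussian noise with SD σ_R2eff to the
fitted curve at every point — jointly across all fields and residues of
a global/cluster fit — and refits starting from the best-fit parameters
(a full multi-start option exists). Errors are the SDs of each
parameter over the converged simulations; non-converged simulations are
dropped, counted, and flagged if they exceed half. Shared parameters of
a cluster get a single error value distributed to all members. Output
is bit-reproducible under a fixed seed. In the small-noise regime the
errors scale linearly with σ; at ≥5% noise the fast-limit amplitude
error distribution becomes heavy-tailed and its SD grows
super-linearly, which is a property of the estimator, not a numerical
artifact.

## Synthetic data generator

The generator emulates a constant-time CPMG measurement series, not the
spectra: it evaluates the exact model equation on a ν grid (default the
14-frequency acquisition list 25, 50, 75, 100, 150, 200, 300, 500, 600,
700, 900, 1000, 1500, 2000 Hz, no replicates) and applies multiplicative
Gaussian noise, R2eff → R2eff·(1 + ε), ε ~ N(0, (p/100)²) truncated at
±3 SD. The attached σ_R2eff is the nominal level (p/100)·mean(R2eff);
noiseless data carries unit weights (σ = 1) so χ² stays defined.
Multi-field simulation scales δω (Φ) by the (squared) field ratio with
independent noise per field; cluster simulation draws independent noise
per residue. Generating parameters are kept alongside the data and can
be written to a JSON sidecar. An intensity writer inverts the R2eff
relation (I(ν) = I(0)·e^(−R2eff·T), T = 0.08 s, I(0) = 10⁶ by default)
so the peak-table readers and the rate-extraction path are exercised
end-to-end; this round trip is exact to 1e-10.

What passing tests on such data do **not** show about real data: no
lineshape/overlap or peak-picking errors, no heteroscedasticity beyond
the single pooled σ, no off-resonance or pulse imperfections, no
deviation from two-site exchange. Reference validation parameter sets
used throughout the tests: fast limit R2⁰ = 15.23 1/s, kex = 3750.3
1/s, Φ = 47457.4 (rad/s)²; slow limit R2⁰ = 15.23 1/s, kex = 306.2 1/s,
p_b = 0.072, δω = 1875.5 rad/s; 4-residue cluster sharing kex = 306.15
1/s, p_b = 0.072 with individual R2⁰ ∈ {12, 15, 18, 21} 1/s and δω ∈
{1200, 1600, 1900, 2300} rad/s.

A known statistical limitation: at 8–10% noise the deterministic χ²
separation between the fast- and slow-limit fits of the slow-exchange
validation set (≈6.5 and ≈4.2) is comparable to the AICc penalty gap
between the two models (4.04 at n = 14), so AICc selection of the
generating slow-limit model degrades to ~70% of seeds there (it is
10/10 at 2% and 5% for both generating models). This is an
identifiability limit of the experiment design, not an optimizer
failure: refits started at the generating parameters reproduce the same
optima. Relatedly, a single-field 14-point profile constrains kex only
weakly (SD ~150 1/s even at 2% noise, with strong kex/p_b correlation)
— the standard remedy, implemented here, is the multi-field global fit.

## Thermodynamics

K = p_b/p_a (minor over major), so ΔG = −RT·ln K > 0 for p_b < 0.5.
Linear van't Hoff regresses ln K on 1/T (slope −ΔH/R, intercept ΔS/R);
the non-linear form adds a constant heat-capacity change, ΔH(T) = ΔH₀ +
ΔCp(T − T₀), ΔS(T) = ΔS₀ + ΔCp·ln(T/T₀), fitted by non-linear least
squares seeded from the linear fit (≥4 temperatures required).
Activation barriers use the Eyring equation with transmission
coefficient 1, ΔG‡ = −RT·ln(k·h/(k_B·T)); forward and backward barriers
from k_ab = p_b·kex and k_ba = p_a·kex satisfy ΔG‡_fwd − ΔG‡_bwd = ΔG
exactly. For fast-limit residues with an independently known δω,
p_b is recovered as the smaller root of p(1−p) = Φ/δω² (no solution if
Φ/δω² > ¼).

## Design choices

* Estimator layer: the fitting core is exposed as scikit-learn-style
  regressors so dispersion fits compose with sklearn tooling; the
  profile-object functions (`fit_residue`, `fit_global`, `fit_cluster`)
  are thin wrappers over the same joint optimizer.
* η± in the slow-limit equation follows the standard Carver-Richards
  form (division by 2√2·ν inside the square-root-free prefactor), and
  ξ is implemented literally as −2δω·kex·(p_a − p_b).
* Global fits keep one R2⁰ per field (a share-R2⁰ switch would further
  constrain the fit but assumes field-independent relaxation, which
  does not hold in general).
* Variance pooling is per field; Monte Carlo perturbs R2eff, not raw
  intensities.
* The p_b upper bound is 0.5 by the minor-state convention; the
  boundary value p(1−p) = ¼ is allowed in the population inversion.

## Problem sizes

The test suite and the acceptance script run on the 14-point default
grid, 10 seeds per stochastic selection condition, 150–500 Monte Carlo
simulations per error estimate, and 4-residue clusters — the sizes at
which the validation experiments above are stable and complete in a few
minutes on one core.
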