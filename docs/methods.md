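# Methods

## Relaxation model

All observables derive from the orientational spectral density J(ω) of
the amide N–H unit vector, the cosine transform of its rank-2 (P2)
autocorrelation function after separation of overall tumbling. The
package assumes a single isotropic tumbling time τc (anisotropic
diffusion tensors are out of scope) and statistical independence of
internal motion and tumbling, so the total correlation function is the
product exp(−t/τc)·C_internal(t). Three parameterisations of J are
implemented: simple Lipari–Szabo (S², τc), extended Lipari–Szabo
(S²_fast, S²_slow, τe, τc), and the multi-Lorentzian form produced by a
multi-exponential fit of a trajectory ACF. They agree in their common
limits (s2_slow = 1, or A0 = 1), which the test suite asserts.

Rate expressions are the standard dipolar + ¹⁵N-CSA combinations of J at
0, ωN, ωH and ωH ± ωN. Two printed-form ambiguities were resolved as
deliberate design choices:

* **η_xy frequency content.** The transverse CSA/DD cross-correlated
  rate is implemented as (1/15)·d·ωN·|ΔσP2|·[4J(0) + 3J(ωN)]. The
  alternative reading with J(ωH − ωN) in place of J(0) predicts a rigid
  η_xy of ≈0.02 s⁻¹ at τc = 14.7 ns — three orders of magnitude below the
  observed ~14 s⁻¹ plateau for rigid residues of a 35 kDa protein — and
  would not share R2's J(0)-dominated (τe, S²) profile. The literal
  variant remains available as `eta_xy_j_zero=False` for transparency.
* **NOE prefactor.** The heteronuclear NOE is
  1 + (γH/γN)(d²/10R1)[6J(ωH+ωN) − J(ωH−ωN)], anchored by the
  extreme-narrowing limit 1 + γH/(2γN) ≈ −3.93, which the acceptance
  suite checks to 0.01.

Signs: γN < 0 is kept where physically meaningful (the NOE is signed and
negative in the narrowing limit); R1, R2 and η_xy are reported as
magnitudes. Units are SI internally; ppm and Å are converted once at the
`InteractionConstants` boundary. The default ¹H frequency is 600.13 MHz
(a nominal "600 MHz" spectrometer); rates are weakly sensitive to the
0.13 MHz difference and the value is configurable.

## Inverse problem: (S², τc) from R1 and η_xy

Under simple Lipari–Szabo, J ∝ S², so the ratio η_xy/R1 is independent of
S² and strictly monotone in τc over 0.5–100 ns at 600 MHz (asserted
numerically on a grid). Each residue's τc is found by bracketed
root-finding (Brent) on log10 τc to 1e-10 relative tolerance; S² then
follows as R1/R1(τc, S²=1). Noise can push S² marginally above 1:
values ≤ 1.05 are accepted with the residue excluded from the rigid set,
larger values raise.

The global τc is the mean over residues with S² above a threshold
(default 0.8) that also pass an error filter. The filter — "small
experimental errors" — is quantified as relative error ≤ 10% on both R1
and η_xy, a configurable choice since no standard number exists. Both the
SD across selected residues and the SEM are reported; the SD is the
honest dispersion of a per-residue quantity, the SEM the precision of the
mean.

## Trajectory pipeline

**Alignment.** Frames are superposed (Kabsch) on the heavy backbone
atoms (N, Cα, C, O) of configured rigid residue ranges, in two passes:
first onto frame 0, then onto the mean structure of that pass. This
removes overall rotation up to one constant global rotation (the common
frame's orientation), to which every downstream quantity — P2 ACFs and
rates — is invariant.

**ACF estimation.** C(t) = ⟨P2(μ(s)·μ(s+t))⟩ over all time origins.
Two algebraically identical estimators exist: a direct lag loop and an
FFT path built on the six-component product-correlation identity
(μ·μ′)² = Σ_k q_k q′_k. They agree to 1e-10 (tested); the FFT path is the
default because it is O(n log n). The lag window defaults to 7×τc; a
warning is raised for segments shorter than 10×τc, below which time
averaging of C(t) is unreliable.

**Multi-exponential fit.** C(t) = A0 + Σ A_j exp(−t/τj) with A ≥ 0 and
ΣA = 1, solved by separable least squares: Nelder–Mead over log τj with
amplitudes obtained at each step by non-negative least squares under the
sum constraint (penalty row). The number of exponentials (0–4) is chosen
by corrected AIC; 500 ns-scale segments rarely support more than four
resolvable time scales. Fits use a logarithmic thinning of the lag grid
(≤256 points) — the information in C(t) is logarithmic in time, so dense
linear sampling adds cost, not content. A time constant longer than 3×
the lag window is not identifiable within the window and is folded into
the plateau; without this rule, model selection can park plateau weight
in a quasi-constant Lorentzian (observed on cone fixtures) and corrupt
the order-parameter estimate, while leaving rates almost unchanged
(τj′ → τc as τj → ∞).

**Back-calculation.** The fit becomes J(ω) by combining each τj with τc
into τj′ = τc τj/(τc + τj), with τc taken from experiment — the
trajectory supplies only internal motion.

**Uncertainties.** Moving-block bootstrap: contiguous frame blocks
(default length = lag window) resampled with replacement to the original
length; ACF → fit → rates repeated per replicate; SD across 100
replicates. Block length and replicate count are package defaults, not
canonical values. Replicate fits reuse the full-data model order and τj
warm starts, keeping replicates comparable and cheap.

## Segment selection and comparison

RMSD plateaus are detected as fixed-length windows (default 500 ns)
whose internal SD is ≤ sd_max (default 0.3 Å) and which contain no
frame-to-frame jump > jump_max (default 1.0 Å), after an equilibration
cutoff (default 700 ns). Plateau selection by eye is common practice;
these thresholds make the choice explicit, and they are echoed into the
output metadata. Ranking among detected plateaus is deliberately left to
the statistical comparison, not the detector.

Per-residue agreement is measured as Δ/σ with σ the experimental error
by default (quadrature combination optional) — the experimental error bar
is the natural yardstick, and back-calculated errors are correlated
across residues through the shared fit. Maximal runs of consecutive
residues exceeding 1σ/2σ/3σ are reported because systematic misfits
appear as contiguous stretches, not isolated points.

Set-level comparison uses the Mann–Whitney U test on the experimental
vs back-calculated rate samples over matched residues (testing Δ-values
against zero is available as an option). The χ² statistic is avoided:
residue-correlated deviations violate its independence assumption even
when residuals are normal. The exact null distribution is used for
min(n, m) ≤ 8 without ties, the normal approximation with tie and
continuity corrections otherwise; the exact path is verified against
brute-force enumeration of all C(n+m, n) assignments in the test suite.
p ≤ 0.05 marks a segment as inconsistent with experiment; no
multiple-testing correction is applied across segments.

## Synthetic data: what it emulates, what it does not

The generator produces unit-vector paths with closed-form ground truth:

* **rigid** — S² = 1;
* **cone** — Brownian wobbling restricted to a spherical cap of
  semi-angle θ0, S² = [cos θ0 (1 + cos θ0)/2]². Implemented as an
  isotropic tangent-arc random walk with Metropolis rejection at the
  boundary: proposals leaving the cap are rejected, so the stationary
  distribution is exactly uniform on the cap and the ACF plateau
  converges to the analytic S² with no boundary-layer bias at any step
  size. Only S² has a closed form; the effective τe is calibrated
  numerically as the area under the plateau-subtracted normalized ACF
  (the plateau is taken from the measured tail, which keeps the finite
  sampling offset out of the area). Default step 4°/frame.
* **jump** — symmetric two-site exchange at angle β,
  S² = (1 + P2(cos β))/2 and τe = −dt/ln(1 − 2p) exactly.

Optional isotropic tumbling composes per-frame rotations with
rotation-vector increments of variance 2·dt/(6τc) per axis, giving
C2(t) = exp(−t/τc). Trajectory files realize the vectors as the amide H
of a synthetic poly-alanine chain (static backbone N/Cα/C/O, so rigid-core
alignment is exact) written as a text multi-model PDB; PDB stores three
decimals, limiting vector round-trip fidelity to ~1e-3 — irrelevant for
ACFs and rates.

What the generator does *not* emulate: force-field physics, correlated
inter-residue motion, anisotropic tumbling, chemical exchange, spectral
noise upstream of peak intensities. Passing tests therefore demonstrate
the correctness of the estimation chain (ACF → fit → J → rates →
statistics), not the realism of any force field.

Noisy relaxation tables are forward-computed from model parameters with
Gaussian noise (default study condition: 3%, the scale of good
relaxation data); intensity series are exponential with Gaussian noise on
the default delay grids (ten R1 delays from 10 to 1444 ms; nine ζ delays
±0.05 s). For the constant-time η_xy experiment the intensity model is
I(ζ) = A·exp(−c·η_xy·ζ) with c = 4 by default; c is exposed as
`ct_exponent_factor` because the modulation convention varies between
implementations of the experiment, and the printed ζ list is wider than
T/4 for T = 60 ms, so ζ/T consistency is only enforced when T is given
explicitly. Reported rate errors are floored at 5% (a conservative
fitting-error convention); the floor interpretation of the "5% cut-off"
is a design choice.

## Problem sizes and determinism

End-to-end trajectory checks use 2×10⁵ frames at 1 ps spacing (200 ns)
for three cone residues, a 5 ns lag window, and 100 bootstrap replicates
— large enough that plateau estimates carry ~0.01–0.02 sampling scatter,
small enough for routine runs on one CPU. Plateau assertions are sized by
that scatter (±0.03 on a fitted plateau; seed-averaged means at 2×SEM).
Every stochastic component takes an explicit seed; identical seeds give
identical outputs, including bootstrap SDs.

## Known limitations

* Single isotropic τc; no anisotropic or local tumbling.
* ¹⁵N backbone amides only; no ¹³C or side-chain relaxation.
* The Mann–Whitney comparison treats residues as exchangeable samples;
  it detects distributional shifts, not residue-by-residue misassignment.
* The empirical prediction of τc from molecular weight and temperature
  is not implemented (no self-contained formula available here).
* NMR-STAR ingestion is a minimal reader for relaxation-style loops
  (tags mapped by name within recognized loop categories), not a general
  STAR parser.
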