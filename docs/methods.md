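# Methods

This note documents the models implemented in `cardioec`, the choices
made where the underlying publications leave latitude, and the known
limitations of each component.

## Myocyte electrophysiology

The electrophysiology core is the Grandi–Pasqualini–Bers (GPB) human
ventricular myocyte model: 38 dynamic states (bulk K⁺ is clamped at
120 mM, the model's convention) spanning membrane gating, four Ca²⁺
compartments (junctional cleft, subsarcolemmal space, bulk cytosol,
SR), Na⁺/Ca²⁺ buffering, RyR release with luminal-Ca regulation, SERCA
uptake and SR leak. The epicardial parameterization of the transient
outward current is used. Equations and constants follow the published
GPB model; all constants live in `cardioec.parameters.GPBParameters`
and every state is registered (name, unit, bounds) in
`cardioec.registry` — no positional indices appear anywhere else.

Two modifications define the variant implemented here:

1. **Late Na⁺ current.** `I_NaL = F_c g_NaL m_L³ h_L (V_m − E_Na,c)`
   in each membrane compartment c ∈ {junctional, subsarcolemmal}, with
   `α_mL = 0.32(V+47.13)/(1−e^{−0.1(V+47.13)})`,
   `β_mL = 0.08 e^{−V/11}`, and steady-state inactivation
   `h_L,∞ = 1/(1+e^{(V+91)/6.1})` with baseline time constant
   τ_hL = 233 ms. The sign convention in h_L,∞ follows the standard
   late-Na formulation; a denominator with a minus sign that sometimes
   appears in print is negative for V > −91 mV and is treated as a
   typographical slip. g_NaL defaults to 0.0065 mS/μF, the canonical
   maximal conductance of this m_L³h_L formulation (the Hund–Rudy /
   Maltsev–Undrovinas lineage from which the gating equations above are
   taken).
2. **Ca transient rescaling.** The junctional↔subsarcolemmal and
   subsarcolemmal↔cytosol Ca diffusion constants are set to
   1.2362·10⁻¹² and 7.4485·10⁻¹² L/ms (1.5× and 2.0× the original GPB
   values). With the original values the healthy CaT peaks at
   0.3–0.4 μM; the modified values bring the peak near 1 μM, the range
   the myofilament model expects. The rescaling lives in the myocyte
   model, not in post-processing of the trace.

**Heart-failure remodelling** enters as 11 non-negative multipliers
(`cardioec.disease.ImpactFactors`) applied multiplicatively to: τ_hL
(f_hl), g_NaL (f_NaL), the I_K1 conductance (f_Ki), the Na/K pump
maximum (f_NaK), background Na and Ca conductances (f_Nabk, f_Cabk),
the NCX maximum (f_ncx), both transient-outward conductances (f_to),
the SR leak rate (f_SRleak), the SERCA maximum (f_SRca) and the
luminal EC50 of RyR release (f_EC50SR). Case A is the unity vector;
Case D is the end-stage set (2, 2, 0.68, 0.5, 0, 1.53, 1.75, 0.4, 5,
0.5, 0.89); cases B/C and any severity s interpolate componentwise,
A + s(D−A), at full precision (printed tables round — or truncate — to
3–4 figures; comparisons against printed values are made at one unit
in the last printed decimal). Severities outside [0, 1] extrapolate
with a warning, clipped at zero.

**Numerics.** Every rate expression of the form x/(1−e^{−kx}) and the
GHK flux factor u/(e^u−1) is evaluated through a series-guarded helper
for |arg| < 10⁻⁴, so removable singularities (e.g. V = −47.13 mV in
α_mL, V = −5 mV in τ_d, V = 0 in the GHK fluxes) produce no NaNs. The
coupled 46-state system (41 electrophysiology + 5 myofilament states)
is integrated with LSODA, rtol 10⁻⁷ / atol 10⁻¹⁰ by default, beat by
beat so the solver never steps across the stimulus discontinuity.
Recorded beats are sampled from dense output at 0.05 ms. Halving the
tolerances moves every biomarker by well under 0.5%, and reruns are
bitwise identical (no hidden randomness anywhere in the package).

## Pacing protocol

The default protocol is a 1000 ms cycle with a 5 ms, 9.5 μA/μF
depolarizing square pulse; 25 pre-pacing beats from the conventional
GPB resting state; the 26th beat is recorded with time zero at
stimulus onset. The published four-case biomarker table this package
reproduces does not state its pacing protocol, and the choice matters
for the failing cases: with several hundred pre-pacing beats the
failing myocyte slowly accumulates Na⁺ (Na_i → ~11 mM), and the
resulting reverse-mode NCX shortens the failing APD back to healthy
durations, contradicting the published panel. The published failing-
case values (long APD, CaT peak ≈ 0.37 μM, depolarized rest) are
characteristic of the pre-accumulation transient, so this package
records an early beat: 25 beats is enough to re-equilibrate the fast
Ca-handling states (the healthy CaT peak is then within ~3% of its
limit-cycle value) while preserving the failing-case AP prolongation.
Both the beat count and the initial state are configurable, and
`paced_to_steady_state` provides explicit convergence-controlled
pacing when the limit cycle itself is wanted.

The effective refractory period is measured from the AP upstroke to a
fixed repolarization fraction; the fraction is the named constant
`biomarkers.ERP_REPOLARIZATION_FRACTION = 0.80`, calibrated once so
the healthy case reproduces the published ERP/APD₉₀ relationship
(ERP/APD₉₀ ≈ 0.965, constant across all four published cases, which is
what a fixed-fraction definition predicts).

## Myofilament model

The NHS model is implemented in its published form: troponin binding
`d[CaTRPN]/dt = k_on[Ca](TRPN_max−[CaTRPN]) − k_off(T)[CaTRPN]` with
tension-dependent unbinding `k_off = k_refoff(1 − T/(γ T_ref))`
(clamped at zero), tropomyosin kinetics in z with the nonlinear
relaxation term and z_max from linearization about z_p = 0.85, length
dependence through β₀, β₁, and three fading-memory crossbridge terms
Q₁–Q₃ driven by the stretch rate. Parameters are the published NHS
constants (k_on = 100 μM⁻¹s⁻¹, k_refoff = 200 s⁻¹, γ = 2,
TRPN_max = 70 μM, Ca50ref = 1.05 μM, T_ref = 56.2 kPa, n = 3, α₀ = 8,
α_r1 = 2, α_r2 = 1.75 s⁻¹, K_z = 0.15, a = 0.35, A = (−29, 138, 129),
α = (30, 130, 625) s⁻¹); none were adjusted to fit the reproduced
tables. Coupling is one-way — the cytosolic CaT drives the
myofilament; troponin-bound Ca is not fed back into the myocyte Ca
balance (the electrophysiology model carries its own troponin buffer).
For production runs the myofilament states are co-integrated with the
myocyte ODEs; `run_isometric` alternatively drives the model from a
sampled CaT with linear interpolation between samples. Under the
default isometric protocol (λ_f = 1, dλ_f/dt = 0) the Q terms receive
no input and remain exactly zero, and tension at the fully relaxed
initial state is exactly 0 kPa.

## Biomarkers

All features are defined on one recorded beat, time origin at stimulus
onset: APD at fraction q runs from the time of maximal dV/dt to the
downstroke crossing of rest + (1−q)·amplitude with sub-sample linear
interpolation; upstroke velocities are maxima of centered differences
on the dense output grid; transient features use the pre-stimulus
(first-sample) value as diastole, time-to-peak from stimulus onset,
rate of development = max dT/dt, and RT50 from the peak to the decay
crossing of diastole + amplitude/2. Extraction is grid-refinement
invariant to <0.1% and raises typed errors on traces without an AP or
without an interior peak.

## Passive and active mechanics

The Holzapfel–Ogden energy uses I₄ᵢ' = max(I₄ᵢ, 1) so fiber and sheet
families bear load only in extension; the isotropic term is normalized
by its reference-state constant a/(2b) so W(I) = 0 (a constant shift,
stress unchanged). The first Piola–Kirchhoff stress is the analytic
gradient of W minus the reference-state correction
a·e^{b(I₁−3)}F^{−T}, which makes P(I) = 0 exactly; it matches a
central-difference gradient of W to <10⁻⁵ relative on random isochoric
deformations (the energy is only C¹ across I₄ = 1, where a
finite-difference oracle loses an order of accuracy — exactly on the
kink the comparison uses the smooth parameter subset). Default
material constants: a = 0.24 kPa, b = 5.08, a_f = 1.46 kPa,
b_f = 4.15, a_s = 0.87 kPa, b_s = 1.6, a_fs = 0.3 kPa, b_fs = 1.3,
T_scale = 3.0. Active stress is the rank-one Cauchy tensor
T_scale·T·f̄⊗f̄.

**Sphere surrogate.** Organ level is represented by a thick-walled
sphere with exactly incompressible radial kinematics
(r³ = R³ + r_i³ − R_i³), fibers along θ̂ and sheets along φ̂ (so both
anisotropic families are tangential and I₈fs = 0), loaded
quasi-statically. Radial equilibrium gives the cavity pressure as the
wall integral of (σ_θθ + σ_φφ − 2σ_rr + T_a)/r, where the constraint
pressure cancels from normal-stress differences and the active tension
T_a = T_scale × (peak isometric myocyte tension) is split equally
between the two tangential directions — the spherical-symmetry
analogue of fiber-direction active stress. EDV is the passive
equilibrium at the end-diastolic pressure (default 8 mmHg); ESV the
equilibrium at the end-systolic pressure (default 150 mmHg) with T_a
held at its peak, mirroring the organ-level protocol of holding peak
CaT and ES pressure until steady state. The actively contracting
sphere can have multiple equilibria; the most-contracted root is
selected deterministically (scan + Brent refinement), which makes ESV
strictly monotone in both tension and afterload. Reference geometry
defaults to an unloaded cavity of radius 2.2 cm with a 1 cm wall —
human-LV scale. The surrogate reproduces pump-function *directions*
(EDV↑ with preload, ESV↓ with contractility, ESV↑ with afterload); it
deliberately makes no claim on organ-level magnitudes, which require
the 3D fluid–structure model, subject geometry and strain-rate-
dependent tension (the full-LV average systolic tension is several
times the isometric single-cell peak).

## Synthetic data and what the tests show

`cardioec.synthetic` generates analytic waveforms — a triangular AP
and Gaussian-bump transients — whose biomarkers have closed forms; the
fixture generator writes them alongside their own ground truth. These
waveforms emulate only the geometric skeleton of a beat (rise, peak,
decay at physiological scales), not AP morphology (notch/dome),
asymmetric CaT decay, or beat-to-beat memory; passing feature tests on
them validates the extraction arithmetic, not the physiology. The
physiological content is tested separately: conservation of total Ca
under a sealed membrane, gate relaxation form, Nernst-crossing of the
late Na current, quiescent fixed points, solver-tolerance and grid
invariances, and the four-case reference panel.

## Known limitations

- The exact parameterization of the source appendices for the variant
  model was not available; the implementation reconstructs it from the
  published GPB, late-Na and NHS formulations plus the stated
  modifications. Healthy-case AP/CaT/tension biomarkers land within a
  few percent of the published panel; systematic residuals of ~5–15%
  remain in the AP upstroke velocity, the failing-case CaT peak, and
  tension kinetics (max dT/dt, failing-case RT50), consistent with
  small undocumented constant differences. These were left as-is
  rather than fitted.
- No tissue-level propagation (contraction is assumed spatially
  homogeneous and simultaneous), no alternative myocyte models, no
  S1–S2 restitution suites, no valve dynamics, and no 3D
  fluid–structure coupling.
- Single precision of the published tables bounds how closely the
  case-definition reproduction can be checked (one unit in the last
  printed decimal).
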