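# cardioec

Multi-scale simulation of cardiac excitation–contraction coupling in
healthy and failing human ventricular myocytes, with a reduced
organ-level pump-function surrogate.

Heart failure remodels the ion channels and Ca²⁺-handling machinery of
the ventricular myocyte — the late Na⁺ current grows, SERCA uptake
falls, SR leak rises, the Na/Ca exchanger is upregulated — which
flattens the intracellular Ca²⁺ transient (CaT), prolongs the action
potential, and weakens active tension. `cardioec` is for computational
physiologists who want to simulate that chain quantitatively, from
ionic currents to myofilament force to ventricular ejection, and to
extract the standard per-beat biomarkers.

## What is in the box

- **`cardioec.gpb`** — the Grandi–Pasqualini–Bers (GPB) human
  ventricular myocyte model (38 ODEs over junctional cleft,
  subsarcolemmal space, bulk cytosol and SR, with explicit buffering),
  extended with a late Na⁺ current
  `I_NaL = F_c · g_NaL · m_L³ h_L (V_m − E_Na,c)` per membrane
  compartment *c*, and with the junctional↔subsarcolemmal↔cytosolic Ca
  diffusion constants adjusted so the healthy CaT peaks near 1 μM
  (J_Ca,juncsl = 1.2362·10⁻¹² L/ms, J_Ca,slmyo = 7.4485·10⁻¹² L/ms).
- **`cardioec.disease`** — the healthy→failing continuum as 11
  multiplicative impact factors (f_hl, f_NaL, f_Ki, f_NaK, f_Nabk,
  f_Cabk, f_ncx, f_to, f_SRleak, f_SRca, f_EC50SR). Named cases A
  (healthy) … D (end-stage failing); B and C are exact componentwise
  interpolants A + s(D−A) at s = 1/3, 2/3, and any severity s ∈ [0,1]
  is accepted.
- **`cardioec.nhs`** — the Niederer–Hunter–Smith (NHS) myofilament
  model: Ca–troponin binding with tension-dependent unbinding,
  tropomyosin kinetics, and fading-memory crossbridge terms, driven
  one-way by the simulated CaT (isometric by default: λ_f = 1,
  dλ_f/dt = 0).
- **`cardioec.biomarkers`** — APD₉₀, resting potential, AP amplitude,
  maximal upstroke velocity, ERP, CaT peak/amplitude/time-to-peak/
  upstroke velocity, peak tension, max dT/dt, RT50.
- **`cardioec.mechanics`** — the Holzapfel–Ogden orthotropic passive
  law W(I₁, I₄f, I₄s, I₈fs) with tension-only fiber/sheet terms, the
  active stress σₐ = T_scale·T·f̄⊗f̄, and a thick-walled
  incompressible-sphere LV surrogate for pump-function trends
  (EDV–preload, ESV–afterload, ESV–contractility).
- **`cardioec.simulation` / `cardioec.io` / `cardioec.cli`** — pacing
  protocols, stiff co-integration of the 46-state coupled system
  (compiled with numba), YAML configs, CSV/JSON artifacts, and the
  `cardioec` command-line tool.

## Worked example

```python
from cardioec import simulate_myocyte, extract_report

for case in ("A", "D"):                 # healthy vs end-stage failing
    report = extract_report(simulate_myocyte(case))
    print(case, report.to_dict())
```

Under the default protocol (1 Hz pacing, 5 ms / 9.5 μA/μF stimulus,
25 pre-pacing beats, one recorded beat) this prints, abbreviated:

```
case A:  apd90_ms 269.2   resting_potential_mV -81.48  cat_peak_uM 0.938
         tension_peak_kPa 9.28   tension_rt50_s 0.161
case D:  apd90_ms 381.5   resting_potential_mV -79.23  cat_peak_uM 0.337
         tension_peak_kPa 3.19   tension_rt50_s 0.295
```

i.e. end-stage remodelling prolongs the action potential by ~110 ms,
cuts the Ca transient to about a third, and cuts peak isometric
tension by two thirds — the cellular signature of systolic failure.

At the organ scale, the sphere surrogate shows why increased
contractility and reduced afterload only partially compensate:

```bash
cardioec lv-surrogate --esp 100,150 --tscale 3.0,6.0 --peak-tension 9.28
```

```
 EDP_mmHg  ESP_mmHg  T_scale    EDV_mL     ESV_mL      SV_mL
      8.0     100.0      3.0 82.625627  23.604368  59.021259
      8.0     100.0      6.0 82.625627  19.319911  63.305716
      8.0     150.0      3.0 82.625627 124.723813 -42.098187
      8.0     150.0      6.0 82.625627  19.910683  62.714943
```

A negative stroke volume means the sphere cannot eject against that
afterload at that contractility (the surrogate is directional, not
quantitative; see `docs/methods.md`).

Other CLI entry points: `cardioec myocyte` (simulate and write a trace
CSV + metadata sidecar), `cardioec biomarkers trace.csv` (JSON report,
or a tidy CSV in batch mode), `cardioec table1` and `cardioec table2`
(regenerate the case-definition and four-case biomarker panels), and
`cardioec fixtures` (synthetic waveforms with analytic ground truth).

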