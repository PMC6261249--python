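# Methods

`cardioem` is a desk-scale coupled electromechanical model of failing human
ventricles used to compare seven conditions: sinus rhythm, left/right bundle
branch block (LBBB/RBBB), each block with cardiac resynchronization therapy
(CRT), and each CRT condition combined with a continuous-flow left
ventricular assist device (LVAD). This note records the model chain, the
parameters that matter, the numerical choices, what the synthetic data do
and do not emulate, and the open design decisions that were settled.

## Model chain

1. **Membrane model.** The ten Tusscher et al. human ventricular myocyte
   model in its 2004 single-cell formulation, with endocardial /
   midmyocardial / epicardial conductance variants (`G_to`, `G_Ks`, and the
   endocardial `s`-gate kinetics). The calcium subsystem is the 2004 one:
   SR leak `V_leak (Ca_sr − Ca_i)`, uptake `Vmax_up / (1 + K_up²/Ca_i²)`,
   and release `(a_rel Ca_sr²/(b_rel² + Ca_sr²) + c_rel)·d·g` with the
   L-type activation gate `d` reused for release and the Ca-dependent
   inactivation gate `g`; cytosolic and SR calcium use the rapid-buffering
   approximation. All constants are exposed in `CellParams` so a different
   parameter set (e.g. the 2006 revision) can be swapped in from
   configuration. One deliberate relaxation: the steady-state expression
   for the `f_Ca` scaling gate, `(α+β+γ+0.23)/1.46`, tops out at 1.047 by
   construction, so state validation bounds `f_Ca` by 1.05 while all true
   probability gates stay in [0, 1].

2. **Tissue activation.** Monodomain reaction–diffusion on an idealized
   biventricular lattice mesh: the full membrane model at every node plus
   axis-wise diffusion with coefficients `D_i = 1/(ρ_i S_i C_m)`. The
   conduction system is a rooted two-branch Purkinje tree; each unblocked
   terminal fires its junction node at `root_time + path_length/CV` with
   zero junction delay. LBBB/RBBB block one branch; the blocked territory
   can still be reached retrogradely through the myocardium, which is what
   produces the prolonged activation. Electrical activation time (EAT) is
   the first upward crossing of −50 mV, linearly interpolated between
   steps.

3. **Myofilament contraction.** A Rice-type approximate cross-bridge model:
   Ca²⁺ binding to low/high-affinity troponin sites, a cooperative
   nonpermissive↔permissive tropomyosin switch, a three-state cross-bridge
   cycle with mean-distortion ODEs, filament-overlap functions, and a
   titin+collagen passive element. Sarcomere length follows
   `mass·SL'' + viscosity·SL' = F_net`, integrated in the equivalent form
   `dSL/dt = (IF + (SL0 − SL)·viscosity)/mass`. ATP consumption rate is
   `E = g_xbT · SOVF_thick` (detachment rate × thick-filament single-overlap
   fraction), reported in s⁻¹ and integrated over the analysis beat.

4. **Ventricular coupling and circulation.** Each ventricle is reduced to
   18 wall segments (3 longitudinal × 6 circumferential); each segment is
   one myofilament unit driven by the steady-state single-cell Ca transient
   delayed by the segment's mean EAT. Cavity pressure is assembled from the
   wall-volume-weighted mean segment tension in tension-scaled elastance
   form, `P = P_pas(V) + E_max·T̄(t)·(V − V_d)`, with an exponential
   end-diastolic P(V) scaled by the same heart-failure stiffening factor as
   the segment passive element. The circulation is a closed eight-compartment
   lumped network (systemic and pulmonary arteries/veins, passive atria,
   diode valves in series with resistances). The LVAD is a constant-flow
   generator from the LV to the systemic artery, continuously active over
   the whole cycle; it enters the mechanics only, the electrical setup of a
   condition is reused for its +LVAD variant.

5. **Timing metrics.** Mechanical activation time (MAT) is the first
   instant a segment's shortening reaches 10% of its eventual maximum
   (linear interpolation); electromechanical delay is EMD = MAT − EAT at
   every site, and averages run over mechanically activated segments of
   both ventricles, with exclusions counted.

## Segment load coupling (the dyssynchrony mechanism)

Two load terms close the loop from the chamber back onto each segment's
afterload:

* a cavity-pressure load, `pressure_coupling · max(P_chamber, 0)`
  (default 5·10⁻⁴ normalized force per mmHg), and
* a force-sharing load, `share_coupling · (T̄_chamber − F_i)` (default 2.0):
  a segment producing less tension than the chamber mean is stretched by
  its neighbours; one producing more unloads into them.

The sharing term carries the dispersion signal: under bundle branch block,
late-activated segments are pre-stretched during early systole and begin
shortening late — the pre-stretch/rebound pattern of dyssynchronous walls —
which prolongs their EMD; resynchronization removes the imbalance. The
pressure term alone cannot do this because it loads every segment with the
same waveform (merely phase-shifted), so compressing the activation spread
re-anchors the EMD–EAT relation without changing its average; the mix is
therefore weighted toward the sharing term. Mechanical unloading by the
LVAD lowers cavity volume and pressure, which shortens EMD and shortens the
aortic-valve opening time.

## Synthetic geometry and conduction tree

No anatomical imaging data ships with the package; geometry is generated,
deterministically per seed:

* **Mesh.** The LV is the wall between two concentric ellipsoids (outer
  semi-axes 2.2 × 2.2 × 3.1 cm, wall 1.0 cm); the RV is a thinner crescent
  (wall 0.9 cm) formed by a second ellipsoid pair shifted along +x; both
  truncated at a basal plane. Nodes sit on a regular lattice (default
  ≈ 6500 nodes, h ≈ 0.21 cm) with small seeded coordinate jitter; cubes of
  interior nodes are split into five tetrahedra for interchange/export.
  Transmural depth is a harmonic (Laplace) field with endocardial surfaces
  at 0 and the epicardium at 1 — continuous across the LV/RV junction —
  and layer thresholds are per-ventricle depth quantiles, so equal-thirds
  layer fractions are node-count fractions. A final pass demotes the rare
  epicardial member of an element that also contains endocardial nodes
  (thin-wall cube diagonals) to mid, enforcing the no-endo–epi-adjacency
  construction rule. Wall regions: septum = LV wall inside the RV outer
  ellipsoid; apex/mid/base by z-bands.
* **Purkinje tree.** His-like root at the basal septal endocardium; each
  bundle descends toward its ventricle's apex and fans out by recursive
  bisection to seeded endocardial target nodes (16 left, 12 right).
  Terminal counts and routing are free parameters of the generator — no
  published geometry constrains them — and edge lengths are straight-line
  chords, so path lengths are approximate.
* **Ca transient fixture.** A smooth single-peak transient
  `(t/tp)² exp(2(1−t/tp))` with exponential decay, peak 1 µM, diastole
  0.1 µM, deactivating by ≈ 250 ms; used for stand-alone myofilament runs
  (the coupled study uses the actual paced-cell transient).

What the synthetic data do **not** emulate: imaged fiber and laminar sheet
architecture (conduction is axis-isotropic after calibration), real RV
crescent cross-section and papillary structure, anatomical Purkinje
branching, and beat-to-beat variability. Passing tests therefore support
the directional, mechanism-level claims (activation orderings, CRT/LVAD
effect directions, conservation and timing identities) — not patient-level
absolute values.

## Numerical choices

* Cell/tissue step: exponential (Rush–Larsen) gate updates with rates
  evaluated at the predicted midpoint voltage, forward concentration
  updates, dt = 0.02 ms. Steps are internally subdivided so no substep
  moves V by more than 0.5 mV, with a Heun correction on the voltage in
  capped substeps; this confines the extra work to the ~1.5 ms upstroke and
  keeps the whole beat within 1 mV of a BDF reference at the production
  step size.
* Tissue diffusion: operator splitting, implicit (backward-Euler) diffusion
  via a cached sparse LU factorization; the operator is assembled from
  lattice edges, symmetric with zero row sums (no-flux boundaries).
* Conduction-velocity calibration: CV(D) is measured on a 1-D cable with
  −50 mV crossings at the 25%/75% probes; the coefficient is bracketed
  (using the CV ∝ √D scaling for the initial search, and treating
  propagation failure as CV = 0) and refined by Brent root finding to the
  60 cm/s target within 2%. The study calibrates on a cable with the
  *mesh's own spacing*, since the discrete CV depends on h.
* Purkinje junction stimuli are suprathreshold current injections
  (−80 pA/pF, 2 ms) into a small ball (radius ≈ 1.3 h, ≥ 0.25 cm) around
  the junction node: single-node injections at this lattice resolution are
  absorbed by the source–sink mismatch and fail to capture.
* Mechanics/circulation: one fused fixed-step loop, dt = 0.1 ms, Heun (RK2)
  updates for the compartment volumes, explicit (previous-step) coupling of
  pressures and shared forces into segment afterloads; 20 s simulated per
  condition, metrics from the final beat. Quadrature for force integrals
  and cycle ATP is trapezoidal on the solver grid.
* Cell pacing protocol: BCL 600 ms, −52 pA/pF for 1 ms (about twice the
  diastolic threshold), 20 beats, at which point successive beats' peak
  Ca_i agree to < 1% (the declared steady-state rule); the slow Na⁺/K⁺
  drift of the reference formulation continues beyond that on the ~100-beat
  scale and is accepted.
* Problem sizes (a package default, configurable): ≈ 6500 tissue nodes,
  400 ms activation window per electrical setup, 36 segments, 20 s of
  coupled mechanics per condition; a full seven-condition study runs in a
  few minutes on one core.

## Parameters, units, defaults

* Membrane model: the published 2004 constants (conductances nS/pF,
  concentrations mM, time ms); `C_m` enters the membrane equation as a
  normalization (currents are per unit capacitance), the total cell
  capacitance 0.185 µF converts currents to concentration fluxes, and the
  per-area capacitance 2 µF/cm² belongs to the diffusion coefficient.
* Myofilament: reference body-temperature rate set (e.g. `fapp` 500 s⁻¹,
  `gxb` 70 s⁻¹, power-stroke 7 nm, cooperativity `nperm` 15). The
  sarcomere-equation constants are not printed anywhere in the mirrored
  study ("described in Fig 1" only), so the mechanical defaults are
  assumed here and exposed: `K_SE` 5 norm/µm, viscosity 25 norm·ms/µm,
  mass 50 norm·ms²/µm — together giving a near-critically-damped series
  assembly with ≈ 5% twitch shortening; `SL0` 2.2 µm; preload equals the
  passive force at `SL0`.
* Heart failure: the passive scaling constant is multiplied by 5 in every
  condition (segments and cavity EDPVR alike) — the study baseline is a
  failing ventricle, including its "normal sinus rhythm" row.
* Circulation and walls: no source values are published (they cite prior
  work), so the defaults were tuned by a coarse manual sweep over LV
  elastance, aortic resistance and blood volume until the failing sinus
  baseline landed near the published normal row (EDV ≈ 88 mL, ESV ≈ 55 mL,
  EF ≈ 38%, CO ≈ 3.4 L/min at BCL 600 ms); resulting defaults include
  `E_max(LV)` 4.6 mmHg/mL, `R_AO` 32 mmHg·ms/mL, systemic resistance
  1700 mmHg·ms/mL, blood volume 4300 mL. Absolute hemodynamic numbers are
  calibration-dependent and treated as qualitative anchors only.
* LVAD: constant 3 L/min, LV → systemic artery, no suction guard beyond
  the negative-volume error. EF is not reported when the device is on (the
  loop is no longer a closed PV cycle); cardiac output then counts forward
  aortic flow plus device flow.

## Design decisions that were genuinely open

* **CRT timing.** Delivering the CRT stimulus at the instant of His
  activation pre-excites the paced region ~60–100 ms ahead of the Purkinje
  terminals on this geometry, *adding* dispersion and inverting the
  expected CRT benefit. The default `crt_delay` is therefore 60 ms —
  comparable to the bundle transit time, so pacing coincides with intrinsic
  endocardial breakthrough — and remains configurable, including 0.
* **Cavity pressure law.** A purely geometric thick-walled-sphere gain
  (∝ ln(1+V_wall/V)) is unstable here: without sarcomere-length feedback
  from the cavity, the gain grows as the cavity empties and ejection runs
  away. The tension-scaled linear elastance is the standard, self-limiting
  reduced form and was adopted instead.
* **RBBB pacing site.** Both printed variants are named options
  (`rv_apex_endo`, default, and `rv_septal_base`).
* **Averages.** MAT/EMD averages cover all mechanically activated segments
  of both ventricles; unactivated segments are excluded and counted.
* **Effect-size conventions.** Reductions use the untreated condition as
  denominator; cardiac-output effects are absolute deltas in L/min;
  percentages round to one decimal. LV-pressure percent claims are not
  reproduced as exact targets (the printed pressures support no single
  denominator convention), and end-systole/end-diastole snapshot times are
  the minimum/maximum LV volume of the analysis beat.

## Known limitations

* The reduced segment model has no kinematic feedback from cavity volume to
  sarcomere length, so Frank–Starling effects enter only through the
  elastance form, and regional strain is a segment property rather than a
  3-D field.
* CRT's hemodynamic benefit in the LBBB condition is directionally
  reproduced (CO, EF, peak pressure, MAT, EMD all improve) but the EMD
  margin is small (~1%), and scenario-average ATP differences are much
  smaller than in the full-resolution study.
* Conduction is isotropic after calibration; no fiber architecture, no
  restitution/arrhythmia behaviour, no atrial contraction, no baroreflex,
  no right-sided assist device, and no long-term remodeling.
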