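# Methods

## Model structure and assumptions

The body is represented by eight compartments: a central plasma pool and
seven tissues — brain, thyroid, bone, GI tract, kidney, uterus and
first-trimester fetus. Each tissue is a well-mixed, constant-volume region
perfused by plasma at flow Q_i (mL/min) and characterised by a
tissue:plasma equilibrium distribution ratio R_i, under the flow-limited
assumption: venous blood leaves tissue *i* already equilibrated with it, at
concentration C_i/R_i. With constant volumes the state is the concentration
vector C (mEq/mL) and the dynamics are linear:

    dC_i/dt = Q_i (C_P − C_i/R_i) / V_i                      (passive tissue)
    dC_G/dt = [Q_G (C_P − C_G/R_G) + G(t)] / V_G             (GI tract)
    dC_K/dt = [Q_K (C_P − C_K/R_K) − kk·C_K/R_K] / V_K       (kidney)
    dC_U/dt = [Q_U (C_P − C_U/R_U) + Q_F (C_F/R_F − C_U/R_U)] / V_U
    dC_F/dt = Q_F (C_U/R_U − C_F/R_F) / V_F
    dC_P/dt = [Σ Q_i C_i/R_i − (Σ Q_i) C_P] / V_P

where the plasma sums run over the six compartments in direct contact with
the circulation (brain, thyroid, bone, GI, kidney, uterus); fetal blood flow
is a sub-loop of the uterine circulation, so the fetus appears nowhere in
the plasma balance. Physiological simplifications baked into the structure:

- **Elimination is renal only** (kk·C_K/R_K). Fecal loss (~1% of clearance)
  is neglected entirely.
- **The fetus has no clearance** — a first-trimester renal system is
  immature — so lithium leaves the fetus only by partitioning back through
  the uterus. This is the mechanism of fetal accumulation and delayed
  washout that motivates the whole exercise.
- **No absorption enters plasma directly**: oral lithium appears in the GI
  compartment via G(t) and reaches plasma by perfusion. The plasma equation
  deliberately carries no G(t) term.
- The model is linear and time-invariant apart from G(t), so trajectories
  superpose and scale with dose — a property the test suite checks to 1e-6
  and the screening logic relies on.

## Dosing input

Each dose of m_D mg of lithium carbonate carries m_D·(8/300) mEq of lithium
(a 300 mg tablet = 8 mEq; 1 mEq = 1 mmol for Li⁺). Controlled-release
tablets are modelled as zero-order input: G(t) = m_D·(8/300)/Δt during the
release window, zero outside; overlapping windows sum. The default window is
Δt = 4 h — the lower end of the 4–12 h time-to-peak range reported for
controlled-release lithium, i.e. the worst case for concentration peaks.
Plasma consequently peaks at the end of the release window (240 min after
dosing). No bioavailability fraction, food effect, or first-order absorption
variant is modelled.

A regimen is a daily (1440 min) cycle of (offset, mass) pairs. Presets cover
every regimen in the screening analysis; n-equal-dose presets are evenly
spaced (12/8/6 h for 2/3/4 doses). The 300/300/500 regimen is encoded at
0/8/16 h even though its narrative is breakfast/lunch/dinner, because
unevenly spaced dosing was explicitly out of scope in the source analysis;
the 1000/300 regimen administers the 1000 mg dose first.

## Parameters

Defaults are packaged in `data/default_physiology.yaml` (all overridable per
run, via file or API):

| parameter | value | unit | note |
|---|---|---|---|
| V_P | 5200 | mL | plasma |
| V_Br, Q_Br, R_Br | 1450, 700, 1.5 | mL, mL/min, – | brain accumulates lithium |
| V_T, Q_T, R_T | 13, 60, 1.5 | | thyroid flow modelled on similar-sized organs |
| V_B, Q_B, R_B | 7273, 272, 1.5 | | V_B = 1000·(8 kg)/(1.1 g/mL), nearest mL |
| V_G, Q_G, R_G | 1650, 1100, 1.0 | | GI tract |
| V_K, Q_K, R_K | 280, 1240, 1.0 | | kidney |
| V_U, Q_U, R_U | 1000, 475, 0.4 | | first-trimester uterus |
| V_F, Q_F, R_F | 150, 300, 0.8 | | fetus; R_F see below |
| kk | 20 | mL/min | renal clearance, low end of 20–40 |
| li_per_mg | 8/300 | mEq/mg | lithium content of Li₂CO₃ |

**The fetal partition ratio R_F is arbitrary.** No measured fetal:plasma
lithium partitioning exists; R_F = 0.8 is a placeholder and an ordinary,
overridable parameter. Fetal concentrations scale linearly with it
(terminal averages exactly; terminal peaks to ~0.3%, because R_F also sets
the fetal time constant V_F·R_F/Q_F), and screening verdicts are invariant
under it since candidate and reference scale together. Absolute fetal
numbers from this model are therefore only meaningful *relative to the
pathological reference computed under the same R_F*.

No gestational-age dependence, allometric scaling, or inter-individual
variability is modelled.

## Units

Physiological volumes and flows are in mL and mL/min, so concentrations are
computed internally in mEq/mL. The clinical literature's printed
concentration magnitudes for these regimens (≈0.4–1.7), however, are only
dimensionally consistent with **mEq/L** given these parameters — at ~36 mEq
of lithium per day in a ~21 L effective distribution volume, mEq/mL
concentrations are O(1e-3). All reported and printed concentrations are
therefore multiplied by 1000 and labelled mEq/L, in every CSV header, JSON
field and log banner. The parameter table is never silently rescaled.

## Numerical choices

- **Integrator**: `scipy.integrate.solve_ivp` with the Radau IIA implicit
  method and the exact (constant) system Jacobian, rtol 1e-8 / atol 1e-12.
  The system is mildly stiff — kidney and thyroid exchange with time
  constants V·R/Q ≈ 0.2–0.3 min against an ~18 h elimination time — which
  leaves explicit methods stability-limited to ~1.4 min steps and, measured
  against the exact matrix-exponential solution, an accumulated start-up
  error floor of ~2e-6 relative that survives tighter tolerances. Radau with
  the analytic Jacobian integrates to ~1e-9 relative and is faster here.
- **Discontinuity handling**: G(t) is piecewise constant; integration is
  restarted at every absorption-window boundary so no discontinuity is
  smoothed. Output lands on a grid of ≤1 min spacing containing every
  boundary.
- **Terminal cycle**: cycles are simulated back to back (each over the
  second cycle of a two-cycle dose expansion, so windows spilling across
  midnight would be handled exactly); convergence requires every
  compartment's cycle peak *and* average to change by <1e-6 relative between
  consecutive cycles, within at most 60 cycles. With a ~12 h plasma
  half-life the cycle map contracts ~4× per day and the default tolerance is
  met in ~12 cycles. Non-convergence is reported as a flag, not an
  exception; screening turns it into an error because a reference from an
  unconverged run would be meaningless.
- **Metrics**: cycle averages by trapezoidal integration on the dense grid;
  peaks as the grid maximum refined by a local quadratic through its
  neighbours. Halving the grid spacing moves peaks by well under 0.1%.
- **Half-life**: time from the plasma maximum (after a single 900 mg dose)
  to the first half-maximum crossing, interpolated linearly on the dense
  grid: 10.73 h with default parameters. The one-pool closed form
  ln2·(V_P + Σ V_i R_i)/CL_eff gives 12.18 h; the simulated value is lower
  because the peak-to-half interval includes the post-absorption
  distribution phase. The slowest system eigenvalue corresponds to a 12.4 h
  terminal half-life.
- **Steady-state oracle**: averaging the ODEs over one terminal cycle gives
  algebraic flow balances used as an independent check on every simulated
  average — avg C_P = (cycle dose/cycle length)/CL_eff with
  CL_eff = kk·Q_K/(Q_K+kk); avg C_i = R_i·avg C_P for brain, thyroid, bone
  and uterus; avg C_F = R_F·avg C_P; avg C_K = R_K·Q_K/(Q_K+kk)·avg C_P;
  and avg C_G = R_G·(avg C_P + dose rate/Q_G) — the GI balance carries the
  absorption inflow, which is easy to overlook.
- **Screening ties**: a candidate within 1e-9 relative of a reference level
  is classified `at_reference` and treated as not acceptable (conservative —
  exact ties have no documented precedent). The pathological regimen
  screened against its own reference is therefore never "acceptable".
  References are recomputed per parameter set, never cached as constants.

## What the reproduction does and does not establish

The published fetal-exposure table for the six documented regimens is
reproduced with peaks matching to <0.1% and averages 2–8% high. The
published averages *cannot* all be exact terminal-cycle values: the three
1200 mg/day regimens (600/600, 400×3, 300×4) must share one terminal average
in a linear system — dose splitting changes peaks, never averages — yet they
were published as 0.886/0.860/0.867. The agreement of the peaks together
with the spread and downward bias of the published averages indicates the
original runs were summarized before full convergence to the periodic steady
state. This package reports true terminal-cycle values (convergence 1e-6,
verified against the closed-form oracle to <1%) and documents a ±10%
comparison band against the published averages.

All regimen classifications reproduce exactly: 700/700 is eliminated on
average only, 1000/300 on peak only, and all five reduced-risk regimens
(300/300, 600/600, 300/300/500, 400/400/400, 300/300/300/300) are
acceptable.

There is no synthetic-data generator: every input is a printed physiological
constant or a dosing schedule, and the model is deterministic end to end. A
green suite therefore establishes internal consistency (conservation,
superposition, flow balances, oracle agreement) and reproduction of the
documented outputs — not clinical validity, which would require fetal
concentration data that does not exist.

## Known limitations

- Flow-limited partitioning with literature R_i values; no
  diffusion-limited variant, no saturable binding or transport.
- First-trimester snapshot: no fetal growth, no parameter trajectories over
  gestation.
- Zero-order absorption with implicit complete bioavailability.
- No maternal efficacy floor: 300/300 is described as a typical lowest
  effective regimen, but no quantitative brain-concentration threshold
  exists, so screening classifies on fetal exposure only and reports
  maternal brain exposure informationally.
- The absolute fetal scale rests on the arbitrary R_F (see above).
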