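# lipbpk

A physiologically based pharmacokinetic (PBPK) simulator of lithium
disposition in a pregnant woman and her first-trimester fetus, with a
screening procedure that classifies oral dosing regimens by the fetal
lithium exposure they produce.

## The problem

Lithium carbonate (Li₂CO₃) remains a first-line treatment for bipolar
disorder, which typically manifests in women before age 30 — squarely within
peak reproductive age. Lithium crosses the placenta freely and is
teratogenic, with fetal exposure most damaging during the first trimester,
yet fetal concentrations cannot be measured and no clinical guidance exists
on a maximum acceptable regimen. What *is* documented is at least one regimen
that caused birth defects: 450 mg in the morning and 900 mg in the evening.

`lipbpk` simulates the fetal lithium concentration profile produced by that
pathological regimen, takes its terminal-cycle fetal **peak** and **average**
as not-to-exceed reference levels, and classifies candidate regimens against
them. A candidate is eliminated if either metric exceeds the reference —
regardless of the (unknowable) absolute fetal partition ratio, because
candidate and reference scale together. This package is a research tool for
pharmacokinetic modelling; it makes no claim of clinical safety.

## The model

Eight well-mixed, constant-volume compartments — plasma, brain, thyroid,
bone, GI tract, kidney, uterus, fetus — under flow-limited (perfusion-limited)
kinetics: blood leaves tissue *i* in equilibrium with it, at concentration
C_i/R_i, where R_i is the tissue:plasma distribution ratio. For a passive
tissue,

    dC_i/dt = Q_i (C_P − C_i/R_i) / V_i

with three structural exceptions:

- **GI tract** adds the oral input G(t): each controlled-release dose of
  m_D mg delivers m_D·(8/300) mEq of lithium at a constant rate over a 4-h
  absorption window (zero-order release, worst case for peaks);
- **kidney** adds elimination −kk·C_K/R_K (renal clearance kk = 20 mL/min;
  urine is effectively the only route out);
- **uterus/fetus**: the fetus exchanges only with the uterus
  (dC_F/dt = Q_F (C_U/R_U − C_F/R_F)/V_F) and has no clearance of its own,
  so fetal lithium can sit at toxic levels even while maternal plasma stays
  therapeutic.

Plasma closes the loop as the flow-weighted sum of all venous returns. The
system is linear; doses enter only through G(t). Repeated daily dosing drives
it to a periodic steady state (the *terminal profile*), detected by running
cycle after cycle until every compartment's peak and average change by less
than 1e-6 between cycles. A closed-form flow-balance oracle (e.g.
avg C_P = dose rate / CL_eff with CL_eff = kk·Q_K/(Q_K+kk) ≈ 19.68 mL/min,
and avg C_F = R_F · avg C_P) cross-checks every simulated terminal average.

Internally everything is computed in {mEq, mL, min}; reported concentrations
are in **mEq/L** (see `docs/methods.md` for the unit-labelling pitfall this
avoids).

## Worked example

Recompute the fetal-exposure table for the six documented regimens
(`average_rel_dev` / `peak_rel_dev` are relative deviations from the
published values):

```text
$ lipbpk table2
        regimen  fetal_average_mEq_L  published_average  average_rel_dev  fetal_peak_mEq_L  published_peak  peak_rel_dev  converged
        450/900               1.0161              0.965           0.0530            1.4340           1.434       -0.0000       True
    300/300/500               0.8280              0.796           0.0401            1.0210           1.021        0.0000       True
        300/300               0.4516              0.419           0.0778            0.5702           0.570        0.0004       True
300/300/300/300               0.9032              0.867           0.0418            0.9600           0.960        0.0000       True
    400/400/400               0.9032              0.860           0.0503            1.0185           1.019       -0.0005       True
        600/600               0.9032              0.886           0.0194            1.1404           1.141       -0.0005       True
```

Peaks reproduce to <0.1%. The simulated averages sit 2–8% above the published
ones and are *identical* for the three 1200 mg/day regimens — which is what a
linear system at exact periodic steady state must produce (the published
averages were evidently taken before full convergence; see
`docs/methods.md`).

Screen candidate regimens against the pathological reference:

```text
$ lipbpk compare --regimens "700/700,1000/300,400/400/400,300/300/300/300"
reference (450/900): fetal average 1.016, peak 1.434 mEq/L
        regimen  fetal_average_mEq_L  fetal_peak_mEq_L     classification  average_margin_mEq_L  peak_margin_mEq_L  brain_average_mEq_L
    400/400/400               0.9032            1.0185         acceptable                0.1129             0.4154               1.6935
300/300/300/300               0.9032            0.9600         acceptable                0.1129             0.4739               1.6935
        700/700               1.0538            1.3305 eliminated_average               -0.0376             0.1035               1.9758
       1000/300               0.9785            1.4703    eliminated_peak                0.0376            -0.0364               1.8347
```

700/700 spreads the day's 1400 mg enough to stay under the reference peak but
its larger daily dose pushes the average over; 1000/300 does the opposite.
Both are eliminated. Splitting 1200 mg/day into three or four doses keeps
both metrics below the reference — the maximum reduced-risk regimens. The
`brain_average` column is informational (maternal therapeutic exposure);
there is no quantitative efficacy floor to classify on.

Other subcommands: `simulate` (trajectory CSV, e.g.
`lipbpk simulate --regimen single-900 --hours 48`), `summarize`
(terminal-cycle JSON), `screen` (one regimen), `validate-params`. Everything
is deterministic — there is no randomness anywhere in the model.

As a library:

```python
import lipbpk as L

params = L.default_params()
summary = L.find_terminal_cycle(params, L.PRESETS["900/900"])
print(summary.compartments["fetus"])   # peak 1.711, average 1.355 mEq/L
print(L.estimate_half_life(params))    # 10.73 h (plasma peak -> half-peak)
```

## Acceptance script

`scripts/acceptance.py` recomputes the headline quantities from scratch —
terminal-cycle fetal averages and maxima for the documented regimens, plus
the single-dose plasma half-life — by running the simulator exactly as above,
and writes them to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(The seed is accepted for interface parity; the model has no stochastic
component.)
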