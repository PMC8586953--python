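# clrccc

Simulation of **closed-loop recycling dual-mode counter-current
chromatography (CLR DM CCC)** separations with finite sample-loading
durations — a process-design tool for preparative and industrial-scale
liquid–liquid chromatography.

Counter-current chromatography separates solutes between two immiscible
liquid phases held in a column of `N` theoretical plates. CLR DM CCC runs in
two stages:

1. **Closed-loop recycling (stage 1).** The sample is loaded continuously
   over a dimensionless time `t_s`, then the column outlet is routed back to
   the inlet so the weakly retained compounds (small partition coefficient
   `K_D = y/x`) pass the column repeatedly — each passage multiplies the
   effective plate count — until the loop is opened and their fractions are
   collected with the mobile x-phase.
2. **Dual-mode inversion (stage 2).** At time `t_x` the phases are inverted:
   the formerly stationary y-phase becomes mobile and elutes the strongly
   retained compounds (large `K_D`) backwards out of the opposite column
   end, quickly and in concentrated bands.

## Model

Each solute moves with the velocity factor

```
a = 1 / (1 − S_f + S_f·K_D)
```

(`S_f` = fractional y-phase volume). A band in recycling cycle `n` at cell
`k` is, to the plate-model approximation, a unit-area Gaussian in
dimensionless time `t = τ·F_x/V_c` with

```
mean      m(n,k) = [ (n−1) + k/N + a·b·(n−1) + a·t_s/2 ] / a
variance  v(n,k) = [ (N(n−1)+k)/N² + (a·t_s)²/12 + (n−1)·a²b²/N_ec ] / a²
```

where the recycling line (relative volume `b = V_ec/V_c`, `N_ec` mixing
cells) adds a delay `b` and a variance `a²b²/N_ec` per completed loop
passage (`b = 0` is the ideal short-line model), and the rectangular loading
pulse adds exactly `t_s²/12` of variance. Stage 2 maps the column state
`s_k = X_n(k, t_x)` through the exact propagator of the reversed cascade,

```
Y(t,1) = K_D · Σ_k  λ^(k−1) e^(−λ) / (k−1)! · s_k ,    λ = K_D·a·N·t ,
```

on the y-phase time basis. Every closed form is validated against an
independent numerical oracle that integrates the cascade ODEs by
matrix-exponential stepping.

## Worked example

The four-compound scenario (`K_D` = 0.4, 0.7, 6, 8; `N` = 300,
`N_ec` = 200, `b` = 0.05, `t_s` = 0.2, loop events at t = 2.0–3.1,
`t_x` = 6):

```sh
clrccc scenario --preset fig4a --out fig4a_demo
```

prints

```
total recovered mass: 4.0554 of 4 compound(s)
outputs written to fig4a_demo
```

with warnings flagging that `t_s` = 0.2 exceeds 20% of the residence time of
the two fast compounds and that compound 2's cycle-2 tail (4.8% of its mass)
leaks into the first collection window. The summary reports, per compound,
the stage-1 collected area, the column mass at the switch and the stage-2
area: compounds 1–2 leave in stage 1 (collected 0.9995 and 1.048 — the
excess is the leaked tail), compounds 3–4 are still entirely in the column
at `t_x` (mass 0.99998 and 1.00000) and elute in stage 2 (areas 0.9990 and
1.0000). The two stage-2 bands peak at `Y` = 7.61 and 9.58 — about 4.0 and
6.4 times higher than the same compounds' conventional single-pass elution
peaks — with resolution 1.18. Fraction purities: F1 94.0% (compound 1), F2
98.5% (compound 2).

The same run from Python:

```python
from clrccc import scheduler

result = scheduler.run_separation(scheduler.preset("fig4a"))
print(result.summary["compounds"]["compound4"])
# {'stage1_collected': 8.7e-09, 'stage2_area': 0.99999,
#  'column_mass_at_tx': 0.99999, 'total_recovered': 0.99999}
```

`clrccc validate` compares the closed forms against the ODE cascade oracle
and prints the error report (peak-time, area, sup-norm discrepancies and
the oracle's mass drift).

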