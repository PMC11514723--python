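# lipasym

Analysis tools for lipid-hydrolysis kinetics of the outer membrane
phospholipase A (OmpLA) in **asymmetric lipid bilayers**, and for the
two-state allosteric model that couples its activation to **differential
membrane curvature stress**.

OmpLA hydrolyzes phospholipids as a calcium-stabilized dimer. When the two
leaflets of a vesicle carry different lipid mixtures, the mismatch in
monolayer curvature frustration (the "differential curvature stress")
changes the mechanical work of reaching the active conformation, and hence
the hydrolysis rate. Ions add a second, indirect lever: Ca²⁺ and Na⁺ make
the anionic lipid POPG more inverted-conical (its intrinsic curvature c₀
drops from slightly positive to negative), which reshapes the stress
balance between leaflets. This package implements the complete quantitative
chain from raw mole-fraction time courses to the allosteric free-energy
analysis:

1. **Composition** — leaflet-resolved bookkeeping of symmetric and
   asymmetric vesicles (equal lipid counts per leaflet; outer-leaflet
   exchange under the no-flip assumption).
2. **Curvature** — tables of intrinsic curvature c₀(lipid, ion,
   concentration) with piecewise-linear interpolation (no extrapolation),
   and mole-fraction-weighted leaflet averages of c₀ and of the monolayer
   bending rigidity κ_m.
3. **Kinetics** — first-order rate fitting. With Δx_PE(t) =
   (x_PE(t) − x_PE^∞)/(x_PE⁰ − x_PE^∞), the linearized rate law
   `ln Δx_PE = −k_PE t` is fitted by ordinary least squares over the
   largest initial window that is still linear (prefix R² ≥ 0.98), so
   late-time deviations (flip-flop, bulk compositional change) do not bias
   the rate. Rates are normalized to a reference lipid concentration and
   protein copy number, and compared through the ratio
   **r = k^asym / k^sym**.
4. **Allosteric model** — each leaflet's activation work is the shape-change
   slope times the monolayer torque, W = s·κ_m·c₀ (in k_BT); the
   differential work is ΔW = ΔW^sym − ΔW^asym, and the activity ratio of a
   two-state (inactive/active) enzyme is

   r(ΔG°, ΔW) = (1 + e^g) / (1 + e^(g+w)),  g = ΔG°/k_BT, w = ΔW/k_BT,

   with ΔG° the activation free energy in symmetric bilayers — the single
   adjustable parameter. The form forces r = 1 at ΔW = 0 and r > 1 only
   for ΔW < 0 with ΔG° ≳ −1 k_BT, so observed r > 1 with positive ΔW is
   flagged **non-conforming** and the signed ΔG° shift needed to rescue the
   model (e.g. additional anionic-lipid/protein electrostatics) is
   reported.
5. **Synthetic data** — a seeded generator for closure-constrained
   densitometry time courses, saturating c₀(salt) curves, and whole study
   designs with a ground-truth ledger, so every stage is testable without
   any experimental download.

## Worked example

A PE/PG vesicle pair (inner leaflet pure POPG; outer leaflet 74 % POPE /
26 % POPG) under 20 mM Ca²⁺, with the asymmetric vesicles hydrolyzing
faster than the symmetric ones:

```python
from lipasym import (
    TABLE_BILAYERS, ScenarioSpec, simulate_timecourse, fit_rate, rate_ratio,
    differential_work, conformance, synthetic_curvature_table, symmetrize,
)

table = synthetic_curvature_table()
asym = TABLE_BILAYERS["PE/PG"]          # inner: PG_0.5; outer: PE_0.37, PG_0.13

spec_a = ScenarioSpec(bilayer=asym, ion="Ca", concentration_mM=20.0,
                      k_true=0.012, noise_sigma=0.01, seed=11)
spec_s = ScenarioSpec(bilayer=symmetrize(asym), ion="Ca", concentration_mM=20.0,
                      k_true=0.010, noise_sigma=0.01, seed=12)
fit_a = fit_rate(simulate_timecourse(spec_a), x_inf=spec_a.x_inf)
fit_s = fit_rate(simulate_timecourse(spec_s), x_inf=spec_s.x_inf)
r, r_err = rate_ratio(fit_a, fit_s)

work = differential_work(asym, table=table, ion="Ca", concentration_mM=20.0)
report = conformance(r, work.delta_W, dG0_band_kBT=(-9.0, -3.0))
```

Output:

```
k_asym = 0.01195 /s   (window (0, 12), R^2 = 0.9996)
k_sym  = 0.01002 /s
r = k_asym / k_sym = 1.192 +/- 0.012
DeltaW = 0.370 kBT
attainable r for DeltaG0 in [-9, -3] kBT: (0.9792, 0.9999)
conforming: False
required DeltaG0 shift: None kBT
```

Reading: the windowed log-linear fits recover both rates to ~1 %
(R² = 0.9996 over all 12 points — no late-time deviation here), giving
r = 1.19: the asymmetric vesicles are 19 % more active. But the mechanical
model computes ΔW = +0.37 k_BT for this composition and ion condition —
activation costs *less* work in the asymmetric bilayer's stress field —
so every ΔG° yields r < 1 (attainable interval entirely below 1). The
observation is non-conforming, and because r > 1 with ΔW > 0 no additive
ΔG° shift can rescue it (`required_shift_kBT = None`): something beyond
curvature mechanics, e.g. direct POPG–protein electrostatics, must
contribute.

## Command line

```sh
lipasym simulate --seed 1 --out study/        # synthetic study + truth ledger
lipasym run study/run.yaml                     # full pipeline -> report.json/tsv
lipasym fit-rates study/timecourses/PE-PG_Ca_asym.csv --x-inf 0.05
lipasym model --r-obs 1.5 --delta-w 0.37
lipasym report study/report/report.json
```

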