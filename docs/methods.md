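# Methods

This note documents the models, estimators and numerical conventions the
package implements, the choices made where the design was genuinely open,
and what the synthetic data do and do not emulate.

## Composition bookkeeping

A bilayer is stored as two maps of lipid → fraction of *total* bilayer
lipid. The package enforces the equal-leaflet-size convention — each
leaflet holds exactly 0.5 of the lipid (validated to 1e−6; a violation
names the offending leaflet). Asymmetric vesicles produced by outer-leaflet
exchange are book-kept under the no-flip assumption: the inner leaflet
retains its pre-exchange composition. Overall compositions are reported in
mole percent (100 × the sum of a lipid's two leaflet fractions), kept at
full double precision internally; rounding to integer percent is a
display-layer concern.

One of the four bundled reference systems (PE/PC_2) has a printed overall
ratio (47 : 53) that disagrees with the ratio implied by its leaflet
fractions (54 : 46). The package stores both and
`check_printed_ratio` emits a `CompositionInconsistencyWarning` when they
disagree by more than 1 mole percent — neither number is silently
"corrected", since the provenance of the discrepancy is unknown.

## Curvature and rigidity tables

Intrinsic curvature c₀ (Å⁻¹) is tabulated per (lipid, ion) against salt
concentration (mM) and interpolated piecewise-linearly; queries outside the
tabulated range raise ("extrapolation refused") rather than clamp, because
c₀(salt) saturates in a lipid-specific way that a clamp would misstate. A
zero-concentration query always resolves to the zero-salt entry. No
functional form is fitted to the tables: measured points are authoritative,
and the synthetic generator provides a saturating curve where measurements
are absent.

Leaflet averages of c₀ and of the monolayer bending rigidity κ_m use
mole-fraction-weighted linear mixing — the standard first-order treatment
for lipid mixtures; the averaged value is always a convex combination of
the per-lipid values.

Defaults: temperature fixed at 35 °C (308.15 K; tables are single-
temperature), POPE c₀ = −0.032 Å⁻¹ treated as salt-independent (divalent
ions barely affect PE), POPC c₀ = −0.011 Å⁻¹ salt-independent (zwitterionic,
weak ion binding), κ_m = 10 k_BT for every lipid unless overridden. POPG's
strong c₀(salt) dependence ships no numeric default: values come from user
CSVs or from the synthetic generator. These defaults are configurable
through the CSV interfaces (`lipid, ion, concentration_mM, c0_invA
[, sigma_invA]` and `lipid, kappa_kBT`).

## Rate fitting

For a POPE mole-fraction series x(t), the normalized decay is
Δx = (x − x_∞)/(x₀ − x_∞), and first-order hydrolysis makes
ln Δx = −k t linear. Estimator conventions:

- **x₀** defaults to the first observed point; **x_∞** defaults to the
  mean of the final 3 points, and both accept overrides. The trailing-mean
  plateau estimator is *biased high by ≈ e^(−k·T_end) of the amplitude*
  when the experiment is stopped before the plateau is closely approached
  (at a 3/k horizon, ≈ 5 % of the amplitude); when the end-state
  composition is known — complete hydrolysis of the accessible pool, or
  the generator's ground truth — the override should be used. The
  package's recovery statistics use the known end-state plateau for this
  reason.
- **OLS with a free intercept**: a mis-specified x₀ then biases the
  intercept, never the slope; k is read from the slope only, its standard
  error from the usual OLS slope variance.
- **Points with Δx ≤ 0** (at or below the plateau) are excluded before the
  log transform, not clipped.
- **Initial-window rule**: starting from all valid points, trailing points
  are trimmed one at a time until the prefix fit reaches R² ≥ 0.98 (with at
  least 4 points); the window always starts at the first point. This
  formalizes the practice of fitting only the initial kinetics before
  flip-flop and bulk compositional change distort the rate law. The
  threshold is configurable. If no qualifying prefix exists the fit fails
  loudly ("no linear initial regime").
- A perfectly flat response (zero decay) is reported as k = 0 with a
  `zero_decay` flag; a positive fitted slope is reported as a negative k
  with a `negative_rate` flag rather than rejected, so basal near-zero
  activity samples survive a batch analysis.

Normalization is ratio-to-reference:
k_norm = k · (c_ref/c) · (N_ref/N) for lipid concentration c and protein
copy number N, keeping s⁻¹ units. The asymmetry statistic is
r = k^asym/k^sym with first-order (delta-method) error propagation; it is
undefined (error) when k^sym ≤ 0.

## Allosteric model

The enzyme is modeled as a two-state (inactive/active) system. Activating
the dimer changes its cross-sectional area profile; linearized in depth,
the change in each leaflet is a slope s (Å) along the leaflet's
outward-pointing normal from the bilayer midplane. Because the first
moment of a relaxed monolayer's lateral pressure profile equals its torque
κ_m·c₀, and the bilayer is tensionless (the depth-independent area change
does no work), each leaflet contributes W = s·κ_m·c₀ (k_BT) to the
activation work. ΔW = W^sym − W^asym compares a bilayer with its
symmetrized counterpart (same overall composition, equal leaflets); it is
exactly zero for symmetric input.

The activity ratio is the ratio of active-state occupancies,

    r(g, w) = (1 + e^g) / (1 + e^(g + w)),   g = ΔG°/k_BT, w = ΔW/k_BT,

evaluated in log space (`logaddexp`), so arbitrarily large |g|, |w| cannot
overflow intermediates; ratios whose true value exceeds float64 range
correctly return inf. Properties that the tests pin down analytically:
r(g, 0) = 1; sign(r − 1) = −sign(w); r → 1 as g → −∞ (a maximally stable
active dimer cannot be modulated); r → e^(−w) as g → +∞; and
sup_w r = 1 + e^g, which is why observed ratios appreciably above 1
require ΔG° around −1 k_BT or higher — a free energy of activation at
thermal-energy scale, i.e. a barely-stable active dimer.

**Inversion.** r is strictly monotone in g for w ≠ 0, so
`fit_dG0` solves r(g, w) = r_obs by Brent bisection on g ∈ [−30, 30] k_BT
(tolerance 1e−8 k_BT). Observations outside the open attainable interval
(between 1 and e^(−w)) raise a `NonConformingError` carrying the interval;
w = 0 raises `UnidentifiableError` (every g gives r = 1).

**Conformance.** Given a plausibility band for ΔG° (default [−9, −3] k_BT),
`conformance` reports the attainable r interval over the band, whether the
observation falls inside, and the smallest signed additive shift of ΔG°
that would make it attainable (None when no shift can — e.g. r > 1 with
w > 0, which no ΔG° reaches). Shifts are reported signed rather than
assuming a direction, since an electrostatic contribution could in
principle act either way.

**Shape default.** The activation shape change defaults to an hourglass:
s_inner = −5 Å, s_outer = +5 Å. The magnitude puts |ΔW| for the studied
mixtures in the few-k_BT range; the sign convention is chosen so that ΔW
of the charged asymmetric systems is positive and *decreases* upon Ca²⁺ or
Na⁺ addition without crossing zero — the behavior expected when ions make
POPG more inverted-conical and partially equalize the leaflets' stress.
Both slopes are configuration parameters; the closed form of r is isolated
in a single function so a refined variant can be swapped in without
touching the property tests that constrain it.

## Synthetic data

The generator emulates the statistical structure the estimators assume:

- **Time courses**: exponential POPE decay x_inf + (x₀ − x_inf)e^(−kt)
  sampled at 12 evenly spaced points over 3/k (minute-scale sampling in
  experimental terms), with defaults x₀ = 0.35, x_inf = 0.05. An optional
  piecewise slowdown multiplies the rate by a residual factor after an
  onset time — a phenomenological stand-in for late-time flip-flop and
  compositional change, sufficient to exercise window selection but not a
  mechanistic model of either. Non-POPE lipid classes keep their initial
  proportions and a pooled `product` class (lyso-lipid + fatty acid)
  absorbs the hydrolyzed fraction, so rows close to 1 exactly before
  noise.
- **Noise**: multiplicative closure noise — every class is scaled by
  1 + N(0, σ) and each row renormalized to sum to 1. Densitometric
  band-quantification error scales with band intensity, which makes the
  relative (multiplicative) model the appropriate one; σ defaults to 0.01
  (1 % CV, a clean but realistic plate). An additive model was considered
  and rejected: it floods the small-Δx tail of the log-linear fit and is
  not how integrated band intensities err.
- **c₀(salt) curves**: saturating form
  c₀(c) = c₀_sat + (c₀_zero − c₀_sat)/(1 + c/c_half), monotone from the
  water value toward saturation — the shape of binding-driven headgroup
  shrinkage. The bundled synthetic POPG parameters (c₀: +0.010 → −0.030
  Å⁻¹; c_half = 5 mM for Ca²⁺, 50 mM for Na⁺) encode the tenfold higher
  Ca²⁺ avidity, so 20 mM Ca²⁺ and 200 mM Na⁺ land on comparable c₀ —
  consistent with the experimental observation that those two conditions
  produce similar enzyme activities.
- **Study bundles** (`scenario_study`): the four reference lipid systems ×
  {basal, 200 mM Na⁺, 20 mM Ca²⁺} × {asym, sym}, with each pair's true
  rate ratio derived from the allosteric model at a configurable g_true
  (default −1 k_BT, inside the identifiable regime) and k^sym = 0.004 s⁻¹
  basal / 0.010 s⁻¹ with ions — the experimentally observed rate scale.
  Leaflet-swapped variants of the charged systems are included so the
  bundle contains ΔW < 0 conditions, and one injected pair carries r > 1
  despite ΔW > 0, which any faithful analysis must flag non-conforming.
  All truths are recorded in a ledger frame; generation is a pure function
  of (spec, seed).

What the generator does **not** emulate: vesicle-size heterogeneity,
enzyme orientation populations, autocorrelated densitometry error,
mechanistic flip-flop, lyso-lipid/fatty-acid kinetics, and SAXS-level c₀
measurement. Passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to every
real-data pathology.

## Problem sizes and reproducibility

The recovery statistics use 200 replicates (12-point series, rates
log-spaced over [1e−3, 1e−1] s⁻¹) and a ~19-pair study bundle — sizes at
which the quantities of interest (median/95th-percentile relative error,
maximum ΔG° recovery error) are stable across seeds to well within their
acceptance margins. All randomness flows from a single integer seed
through `numpy.random.default_rng`; pipeline reports serialize floats at 9
significant digits with sorted keys, so identical configurations reproduce
byte-identical JSON.

## Known limitations

- The two-state ratio form is the minimal closed form satisfying all the
  qualitative constraints of the underlying allosteric picture; refined
  treatments (explicit pressure-profile integrals, area-profile data from
  the dimer structure) would change ΔW quantitatively.
- Linear mixing of c₀ and κ_m ignores non-ideal lipid mixing and
  ion-mediated lipid clustering.
- ΔW is linear in the shape slopes, which are order-of-magnitude defaults,
  not structure-derived quantities; conclusions should rest on signs and
  trends of ΔW, not its absolute magnitude.
- The window rule guards against *late-time* deviations only; an initial
  lag phase would require trimming from the front, which the estimator
  does not attempt.
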