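"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Emulates the three experimental data streams: (i) densitometry time courses
of lipid-class mole fractions during hydrolysis — exponential POPE decay
toward a plateau with compositional closure, multiplicative Gaussian class
noise, and an optional late-time kinetic slowdown; (ii) saturating c0-versus-salt
curves for ion-sensitive lipids; (iii) whole study designs pairing symmetric
and asymmetric vesicles across ion conditions, with hydrolysis rates derived
from the allosteric model so end-to-end recovery of DeltaG0 is testable.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allosteric import DEFAULT_SHAPE, ShapeChange, activity_ratio, differential_work
from .composition import (
    BilayerComposition,
    TABLE_BILAYERS,
    overall_composition,
    symmetrize,
)
from .curvature import (
    DEFAULT_KAPPA_KBT,
    NO_ION,
    POPE_C0_WATER,
    CurvaturePoint,
    CurvatureTable,
)
from .kinetics import HydrolysisTimeCourse, TARGET_LIPID

__all__ = [
    "ScenarioSpec",
    "Slowdown",
    "StudyCondition",
    "StudyPair",
    "StudyBundle",
    "simulate_timecourse",
    "simulate_c0_curve",
    "synthetic_curvature_table",
    "scenario_study",
    "DEFAULT_NOISE_SIGMA",
]

#: Relative densitometry noise on class mole fractions (declared default;
#: the real magnitude is instrument-dependent, typically a few percent CV).
DEFAULT_NOISE_SIGMA = 0.01
DEFAULT_N_TIMEPOINTS = 12
DEFAULT_HORIZON = 3.0  # multiples of 1/k_true
_FLAT_DURATION_S = 3600.0  # sampling span when k_true = 0


@dataclass(frozen=True)
class Slowdown:
    """Piecewise rate change emulating late-time deviations.

    After ``onset`` (in multiples of 1/k_true) the decay continues from the
    reached value with the rate multiplied by ``residual_factor``.  This is
    a phenomenological stand-in for compositional change and flip-flop, not
    a mechanistic model: only its effect on window selection matters.
    """

    onset: float = 1.5
    residual_factor: float = 0.1

    def __post_init__(self) -> None:
        if self.onset <= 0 or not (0 <= self.residual_factor <= 1):
            raise ValueError("need onset > 0 and residual factor in [0, 1]")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated hydrolysis experiment."""

    bilayer: BilayerComposition
    ion: str = NO_ION
    concentration_mM: float = 0.0
    k_true: float = 0.01  # 1/s
    x0: float = 0.35
    x_inf: float = 0.05
    n_timepoints: int = DEFAULT_N_TIMEPOINTS
    horizon: float = DEFAULT_HORIZON  # in units of 1/k_true
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    slowdown: Slowdown | None = None
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_inf < self.x0 <= 1.0):
            raise ValueError("need 0 <= x_inf < x0 <= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_timepoints < 4:
            raise ValueError("need at least 4 time points")
        if self.k_true < 0:
            raise ValueError("k_true must be >= 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


def _pe_trajectory(spec: ScenarioSpec, times: np.ndarray) -> np.ndarray:
    amp = spec.x0 - spec.x_inf
    if spec.k_true == 0.0:
        return np.full_like(times, spec.x0)
    x = spec.x_inf + amp * np.exp(-spec.k_true * times)
    if spec.slowdown is not None:
        t_on = spec.slowdown.onset / spec.k_true
        x_on = spec.x_inf + amp * np.exp(-spec.k_true * t_on)
        late = times > t_on
        k_late = spec.k_true * spec.slowdown.residual_factor
        x[late] = spec.x_inf + (x_on - spec.x_inf) * np.exp(
            -k_late * (times[late] - t_on)
        )
    return x


def simulate_timecourse(spec: ScenarioSpec) -> HydrolysisTimeCourse:
    """Generate one closure-constrained mole-fraction time course.

    POPE decays exponentially from x0 toward x_inf (piecewise-slowed after
    the optional onset); the non-POPE lipid classes hold their initial
    proportions of the remaining 1 - x0, and a ``product`` class (lyso-lipid
    plus fatty acid, pooled) absorbs the hydrolyzed fraction.  Multiplicative
    closure noise emulates densitometry error: every class is scaled by
    1 + N(0, noise_sigma) — band-quantification error is proportional to
    band intensity — and each row is renormalized to closure.
    """
    if spec.k_true > 0:
        duration = spec.horizon / spec.k_true
    else:
        duration = _FLAT_DURATION_S
    times = np.linspace(0.0, duration, spec.n_timepoints)
    x_pe = _pe_trajectory(spec, times)

    overall = overall_composition(spec.bilayer)
    others = {l: p for l, p in overall.items() if l != TARGET_LIPID}
    other_total = sum(others.values())
    columns: dict[str, np.ndarray] = {TARGET_LIPID: x_pe}
    for lipid, percent in others.items():
        weight = percent / other_total if other_total > 0 else 0.0
        columns[lipid] = np.full_like(times, weight * (1.0 - spec.x0))
    # pre-noise closure: PE + others + product = 1 exactly
    columns["product"] = 1.0 - x_pe - sum(
        (columns[l] for l in others), np.zeros_like(times)
    )

    frame = pd.DataFrame(columns)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        noisy = frame.to_numpy() * (
            1.0 + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        )
        noisy = np.clip(noisy, 0.0, None)
        noisy /= noisy.sum(axis=1, keepdims=True)
        frame = pd.DataFrame(noisy, columns=frame.columns)
    return HydrolysisTimeCourse(
        times_s=times,
        fractions=frame,
        label=spec.label or spec.bilayer.label,
        ion=spec.ion,
        concentration_mM=spec.concentration_mM,
    )


def simulate_c0_curve(
    lipid: str,
    ion: str,
    c0_zero_invA: float,
    c0_sat_invA: float,
    half_conc_mM: float,
    concentrations_mM: Sequence[float],
    noise_invA: float = 0.0,
    seed: int = 0,
) -> list[CurvaturePoint]:
    """Saturating c0(salt) curve: c0_sat + (c0_zero - c0_sat)/(1 + c/c_half).

    Monotone from the zero-salt value toward saturation, reaching the
    midpoint at ``half_conc_mM`` — the shape of ion-binding-driven headgroup
    shrinkage.  Optional Gaussian noise emulates measurement scatter.
    """
    if half_conc_mM <= 0:
        raise ValueError("half_conc_mM must be positive")
    rng = np.random.default_rng(seed)
    points = []
    for c in concentrations_mM:
        c0 = c0_sat_invA + (c0_zero_invA - c0_sat_invA) / (1.0 + c / half_conc_mM)
        if noise_invA > 0:
            c0 += rng.normal(0.0, noise_invA)
        points.append(
            CurvaturePoint(
                lipid=lipid,
                ion=ion,
                concentration_mM=float(c),
                c0_invA=float(c0),
                sigma_invA=noise_invA if noise_invA > 0 else None,
            )
        )
    return points


#: POPG c0 parameters for the synthetic salt curves: slightly positive in
#: water, saturating to inverted-cone values; Ca2+ binds ~10x more avidly
#: than Na+ so 20 mM Ca2+ and 200 mM Na+ land on comparable c0.
_POPG_C0_ZERO = 0.010
_POPG_C0_SAT = -0.030
_POPG_HALF_CA_MM = 5.0
_POPG_HALF_NA_MM = 50.0


def synthetic_curvature_table(
    noise_invA: float = 0.0,
    seed: int = 0,
    max_concentration_mM: float = 1000.0,
) -> CurvatureTable:
    """A full curvature table for the study lipids.

    POPE and POPC are salt-independent (c0 = -0.032 and -0.011 1/A); POPG
    follows saturating synthetic curves for Na+ and Ca2+.  kappa_m defaults
    to 10 kBT for every lipid.
    """
    grid = [0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0]
    grid = [c for c in grid if c <= max_concentration_mM]
    points: list[CurvaturePoint] = []
    for lipid, c0 in (("POPE", POPE_C0_WATER), ("POPC", -0.011)):
        points.append(CurvaturePoint(lipid, NO_ION, 0.0, c0))
        for ion in ("Na", "Ca"):
            points.append(CurvaturePoint(lipid, ion, 0.0, c0))
            points.append(CurvaturePoint(lipid, ion, max_concentration_mM, c0))
    points.append(CurvaturePoint("POPG", NO_ION, 0.0, _POPG_C0_ZERO))
    for ion, half in (("Na", _POPG_HALF_NA_MM), ("Ca", _POPG_HALF_CA_MM)):
        points.extend(
            simulate_c0_curve(
                "POPG", ion, _POPG_C0_ZERO, _POPG_C0_SAT, half, grid,
                noise_invA=noise_invA, seed=seed,
            )
        )
    return CurvatureTable(points=points, kappa_default_kBT=DEFAULT_KAPPA_KBT)


@dataclass(frozen=True)
class StudyCondition:
    name: str
    ion: str
    concentration_mM: float


#: Basal buffer plus the two ion challenges used throughout the study.
STUDY_CONDITIONS = (
    StudyCondition("basal", NO_ION, 0.0),
    StudyCondition("Na", "Na", 200.0),
    StudyCondition("Ca", "Ca", 20.0),
)


@dataclass(frozen=True)
class StudyPair:
    """Ground truth for one asymmetric/symmetric pair under one condition."""

    system: str
    condition: StudyCondition
    asym: ScenarioSpec
    sym: ScenarioSpec
    g_true: float | None  # DeltaG0/kBT used to derive r_true; None if injected
    w_true: float  # DeltaW/kBT from the allosteric model
    r_true: float
    injected_nonconforming: bool = False

    @property
    def label(self) -> str:
        return f"{self.system}|{self.condition.name}"


@dataclass(frozen=True)
class StudyBundle:
    """A full synthetic study: scenarios plus their ground-truth ledger."""

    pairs: tuple[StudyPair, ...]
    curvature_table: CurvatureTable
    shape: ShapeChange
    seed: int

    def ledger(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "system": p.system,
                    "condition": p.condition.name,
                    "ion": p.condition.ion,
                    "concentration_mM": p.condition.concentration_mM,
                    "g_true_kBT": p.g_true,
                    "w_true_kBT": p.w_true,
                    "r_true": p.r_true,
                    "k_true_asym": p.asym.k_true,
                    "k_true_sym": p.sym.k_true,
                    "injected_nonconforming": p.injected_nonconforming,
                }
                for p in self.pairs
            ]
        )


def _flip(b: BilayerComposition) -> BilayerComposition:
    return BilayerComposition(
        inner=dict(b.outer), outer=dict(b.inner), label=f"{b.label}-flip"
    )


def scenario_study(
    seed: int = 0,
    g_true: float = -1.0,
    k_sym_s: float = 0.004,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    shape: ShapeChange = DEFAULT_SHAPE,
    include_flipped: bool = True,
    include_injected: bool = True,
) -> StudyBundle:
    """Build the full synthetic study design with a ground-truth ledger.

    For each Table-style lipid system and ion condition, DeltaW is computed
    from the allosteric model on the synthetic curvature table, the true
    ratio r_true = r(g_true, w_true) follows, and the pair's hydrolysis
    rates are k_sym and r_true * k_sym.  Leaflet-swapped ("-flip") variants
    reverse the sign of DeltaW, providing w < 0 conditions where DeltaG0 is
    identifiable from r > 1.  One injected pair carries r > 1 despite w > 0
    and must be flagged non-conforming by any faithful analysis.
    """
    table = synthetic_curvature_table()
    rng = np.random.default_rng(seed)
    systems = dict(TABLE_BILAYERS)
    if include_flipped:
        for name in ("PE/PG", "PE/PC/PG"):
            flipped = _flip(TABLE_BILAYERS[name])
            systems[flipped.label] = flipped

    pairs: list[StudyPair] = []
    for name, bilayer in systems.items():
        for cond in STUDY_CONDITIONS:
            w = differential_work(
                bilayer, shape, table, cond.ion, cond.concentration_mM
            ).delta_W
            r_true = activity_ratio(g_true, w)
            k_sym = k_sym_s * (2.5 if cond.name != "basal" else 1.0)
            k_asym = r_true * k_sym
            sub_asym, sub_sym = (int(x) for x in rng.integers(0, 2**31 - 1, 2))
            mk = lambda b, k, s, tag: ScenarioSpec(
                bilayer=b,
                ion=cond.ion,
                concentration_mM=cond.concentration_mM,
                k_true=k,
                noise_sigma=noise_sigma,
                seed=s,
                label=f"{name}|{cond.name}|{tag}",
            )
            pairs.append(
                StudyPair(
                    system=name,
                    condition=cond,
                    asym=mk(bilayer, k_asym, sub_asym, "asym"),
                    sym=mk(symmetrize(bilayer), k_sym, sub_sym, "sym"),
                    g_true=g_true,
                    w_true=w,
                    r_true=r_true,
                )
            )

    if include_injected:
        bilayer = TABLE_BILAYERS["PE/PG"]
        cond = StudyCondition("Ca-injected", "Ca", 20.0)
        w = differential_work(bilayer, shape, table, "Ca", 20.0).delta_W
        r_inj = 1.5  # above 1 while w > 0: unreachable by the model
        k_sym = k_sym_s * 2.5
        sub_asym, sub_sym = (int(x) for x in rng.integers(0, 2**31 - 1, 2))
        pairs.append(
            StudyPair(
                system="PE/PG",
                condition=cond,
                asym=ScenarioSpec(
                    bilayer=bilayer,
                    ion="Ca",
                    concentration_mM=20.0,
                    k_true=r_inj * k_sym,
                    noise_sigma=noise_sigma,
                    seed=sub_asym,
                    label=f"PE/PG|{cond.name}|asym",
                ),
                sym=ScenarioSpec(
                    bilayer=symmetrize(bilayer),
                    ion="Ca",
                    concentration_mM=20.0,
                    k_true=k_sym,
                    noise_sigma=noise_sigma,
                    seed=sub_sym,
                    label=f"PE/PG|{cond.name}|sym",
                ),
                g_true=None,
                w_true=w,
                r_true=r_inj,
                injected_nonconforming=True,
            )
        )

    return StudyBundle(
        pairs=tuple(pairs), curvature_table=table, shape=shape, seed=seed
    )
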