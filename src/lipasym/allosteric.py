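"""Two-state allosteric model of enzyme activation against curvature stress.

The dimeric enzyme must deform the surrounding bilayer to reach its active
cross-section.  The mechanical work per leaflet is the first moment of the
lateral pressure profile weighted by the activation area change; with the
area change linearized in depth (slope s, in Angstrom) and zero net tension,
each leaflet contributes

    W = s * kappa_m * c0          [kBT]

since the first moment of a relaxed monolayer's stress profile equals its
torque kappa_m * c0.  The differential activation work between symmetric and
asymmetric bilayers of the same overall composition is
DeltaW = W_sym - W_asym.

Activation is modeled as a two-state (inactive/active) equilibrium with free
energy DeltaG0 in the symmetric bilayer, shifted by the extra mechanical
work in the asymmetric one.  The activity ratio is the ratio of active-state
occupancies,

    r = (1 + e^g) / (1 + e^(g + w)),   g = DeltaG0/kBT,  w = DeltaW/kBT,

which satisfies r = 1 at w = 0, r > 1 iff w < 0, r -> 1 as g -> -inf (a
deeply stable active dimer cannot be modulated further) and r -> e^(-w) as
g -> +inf.  Hence r significantly above 1 requires w < 0 together with
g around -1 kBT or higher — a key diagnostic: observed r > 1 with deeply
negative DeltaG0 does not conform to this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .composition import BilayerComposition, symmetrize
from .curvature import TEMPERATURE_K, CurvatureTable, leaflet_c0, leaflet_kappa

__all__ = [
    "ShapeChange",
    "WorkResult",
    "ModelParams",
    "ConformanceReport",
    "NonConformingError",
    "UnidentifiableError",
    "DEFAULT_SHAPE",
    "DEFAULT_DG0_BAND",
    "leaflet_work",
    "differential_work",
    "activity_ratio",
    "fit_dG0",
    "conformance",
]

#: DeltaG0 band consistent with the conforming samples, in kBT.
DEFAULT_DG0_BAND = (-9.0, -3.0)
_FIT_BOUNDS = (-30.0, 30.0)
_WIDE_BOUNDS = (-745.0, 745.0)  # beyond this exp() over/underflows anyway


class NonConformingError(ValueError):
    """The observed ratio is outside the interval the model can produce."""

    def __init__(self, message: str, attainable: tuple[float, float]):
        super().__init__(message)
        self.attainable = attainable


class UnidentifiableError(ValueError):
    """w = 0 forces r = 1 for every DeltaG0; the fit is degenerate."""


@dataclass(frozen=True)
class ShapeChange:
    """Linearized activation cross-section change of the protein.

    ``slope_inner`` / ``slope_outer`` are d(DeltaA)/dz (in Angstrom) across
    the inner- and outer-leaflet regions, with each leaflet's z axis along
    its own outward normal from the bilayer midplane.  ``dA0_A2`` is the
    depth-independent area change; under the tensionless convention it does
    no work and is retained for completeness only.

    The default is an hourglass-like change (opposite slopes in the two
    leaflets) of magnitude 5 A, which puts |DeltaW| for the studied mixtures
    in the few-kBT range.
    """

    slope_inner_A: float = -5.0
    slope_outer_A: float = 5.0
    dA0_A2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("slope_inner_A", "slope_outer_A", "dA0_A2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


DEFAULT_SHAPE = ShapeChange()


@dataclass(frozen=True)
class WorkResult:
    """Activation work in symmetric and asymmetric bilayers, in kBT."""

    W_sym: float
    W_asym: float

    @property
    def delta_W(self) -> float:
        return self.W_sym - self.W_asym


@dataclass(frozen=True)
class ModelParams:
    """Model parameters: DeltaG0 and an optional electrostatic shift, in kBT.

    The shift enters additively on DeltaG0 and is reported signed; it
    represents e.g. anionic-lipid/protein interactions not captured by the
    mechanical term.
    """

    dG0_kBT: float
    electrostatic_shift_kBT: float = 0.0
    temperature_K: float = TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def g(self) -> float:
        return self.dG0_kBT + self.electrostatic_shift_kBT


def leaflet_work(slope_A: float, kappa_m_kBT: float, c0_invA: float) -> float:
    """Activation work of one leaflet: W = s * kappa_m * c0, in kBT.

    A cylindrical shape change (s = 0) does no curvature work; the sign of W
    follows the signs of the slope and of the leaflet's average c0.
    """
    return slope_A * kappa_m_kBT * c0_invA


def differential_work(
    asym: BilayerComposition,
    shape: ShapeChange = DEFAULT_SHAPE,
    table: CurvatureTable | None = None,
    ion: str = "none",
    concentration_mM: float = 0.0,
) -> WorkResult:
    """DeltaW between the symmetric and asymmetric form of a bilayer.

    W_asym sums the per-leaflet works on the asymmetric bilayer; W_sym does
    the same on its symmetrized counterpart (identical overall composition,
    equal leaflets).  A symmetric input therefore returns DeltaW = 0 exactly.
    """
    if table is None:
        from .curvature import default_table

        table = default_table()

    def _work(b: BilayerComposition) -> float:
        return leaflet_work(
            shape.slope_inner_A,
            leaflet_kappa(b, "inner", table),
            leaflet_c0(b, "inner", table, ion, concentration_mM),
        ) + leaflet_work(
            shape.slope_outer_A,
            leaflet_kappa(b, "outer", table),
            leaflet_c0(b, "outer", table, ion, concentration_mM),
        )

    return WorkResult(W_sym=_work(symmetrize(asym)), W_asym=_work(asym))


def activity_ratio(params: ModelParams | float, delta_W_kBT: float) -> float:
    """Model activity ratio r(g, w) = (1 + e^g) / (1 + e^(g + w)).

    ``params`` may be a ModelParams (g = dG0 + shift) or a bare g in kBT.
    Evaluated in log space so arbitrarily large |g| and |w| are safe.
    """
    g = params.g if isinstance(params, ModelParams) else float(params)
    w = float(delta_W_kBT)
    if not (np.isfinite(g) and np.isfinite(w)):
        raise ValueError("g and w must be finite")
    # log r = log(1+e^g) - log(1+e^(g+w)), stable via logaddexp
    log_r = np.logaddexp(0.0, g) - np.logaddexp(0.0, g + w)
    return float(np.exp(log_r))


def _attainable_interval(w: float, g_lo: float, g_hi: float) -> tuple[float, float]:
    lo, hi = sorted((activity_ratio(g_lo, w), activity_ratio(g_hi, w)))
    return lo, hi


def fit_dG0(
    r_obs: float,
    delta_W_kBT: float,
    bounds: tuple[float, float] = _FIT_BOUNDS,
    tol_kBT: float = 1e-8,
) -> float:
    """Invert r(g, w) for g = DeltaG0/kBT at fixed w, by bisection.

    r is strictly monotone in g for w != 0, so the solution is unique when
    it exists.  ``r_obs`` outside the interval attainable on ``bounds``
    raises :class:`NonConformingError` carrying that interval; w = 0 raises
    :class:`UnidentifiableError` since every g then gives r = 1.
    """
    if r_obs <= 0:
        raise ValueError("observed ratio must be positive")
    w = float(delta_W_kBT)
    if w == 0.0:
        raise UnidentifiableError(
            "degenerate: DeltaW = 0 forces r = 1 for every DeltaG0 "
            "(unidentifiable)"
        )
    g_lo, g_hi = bounds
    lo, hi = _attainable_interval(w, g_lo, g_hi)
    if not (lo < r_obs < hi):
        raise NonConformingError(
            f"non-conforming: r = {r_obs:g} lies outside the attainable "
            f"interval ({lo:.6g}, {hi:.6g}) for DeltaW = {w:g} kBT on "
            f"DeltaG0 in [{g_lo:g}, {g_hi:g}] kBT",
            attainable=(lo, hi),
        )
    log_r = float(np.log(r_obs))
    sol = optimize.brentq(
        lambda g: (np.logaddexp(0.0, g) - np.logaddexp(0.0, g + w)) - log_r,
        g_lo,
        g_hi,
        xtol=tol_kBT,
    )
    return float(sol)


@dataclass(frozen=True)
class ConformanceReport:
    """Whether an observed ratio is reachable with DeltaG0 inside a band.

    ``required_shift_kBT`` is the smallest signed additive shift of DeltaG0
    that brings the observation inside the band's reach (0 when conforming,
    None when no shift can: e.g. r > 1 with DeltaW > 0).
    """

    r_obs: float
    delta_W_kBT: float
    dG0_band_kBT: tuple[float, float]
    attainable: tuple[float, float]
    conforming: bool
    required_shift_kBT: float | None
    dG0_fit_kBT: float | None = None


def conformance(
    r_obs: float,
    delta_W_kBT: float,
    dG0_band_kBT: tuple[float, float] = DEFAULT_DG0_BAND,
    rel_tol: float = 1e-9,
) -> ConformanceReport:
    """Classify an observed ratio against the model over a DeltaG0 band.

    Always returns a report.  With w = 0 the model pins r to 1 and only
    r_obs = 1 conforms (no shift can change that).  Otherwise r is monotone
    in g, so the band's reach is the interval between its endpoint ratios,
    and the required shift follows from inverting r at the nearer endpoint.
    """
    g_lo, g_hi = dG0_band_kBT
    if g_lo > g_hi:
        raise ValueError("empty DeltaG0 band")
    w = float(delta_W_kBT)
    if w == 0.0:
        ok = bool(np.isclose(r_obs, 1.0, rtol=rel_tol))
        return ConformanceReport(
            r_obs=r_obs,
            delta_W_kBT=w,
            dG0_band_kBT=(g_lo, g_hi),
            attainable=(1.0, 1.0),
            conforming=ok,
            required_shift_kBT=0.0 if ok else None,
            dG0_fit_kBT=None,
        )
    lo, hi = _attainable_interval(w, g_lo, g_hi)
    if lo * (1 - rel_tol) <= r_obs <= hi * (1 + rel_tol):
        fit = fit_dG0(r_obs, w, bounds=(g_lo - 1e-9, g_hi + 1e-9))
        return ConformanceReport(
            r_obs=r_obs,
            delta_W_kBT=w,
            dG0_band_kBT=(g_lo, g_hi),
            attainable=(lo, hi),
            conforming=True,
            required_shift_kBT=0.0,
            dG0_fit_kBT=fit,
        )
    # outside the band's reach: solve on the widest numerically sane range
    try:
        g_star = fit_dG0(r_obs, w, bounds=_WIDE_BOUNDS)
    except NonConformingError:
        return ConformanceReport(
            r_obs=r_obs,
            delta_W_kBT=w,
            dG0_band_kBT=(g_lo, g_hi),
            attainable=(lo, hi),
            conforming=False,
            required_shift_kBT=None,
            dG0_fit_kBT=None,
        )
    # the smallest |shift| moves the nearer band endpoint onto g_star
    shift = g_star - g_hi if g_star > g_hi else g_star - g_lo
    return ConformanceReport(
        r_obs=r_obs,
        delta_W_kBT=w,
        dG0_band_kBT=(g_lo, g_hi),
        attainable=(lo, hi),
        conforming=False,
        required_shift_kBT=float(shift),
        dG0_fit_kBT=None,
    )
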