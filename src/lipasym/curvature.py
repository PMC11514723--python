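"""Intrinsic lipid curvature and bending-rigidity data.

Intrinsic (spontaneous) curvature c0 quantifies the preferred curvature of a
lipid monolayer set by the effective molecular shape; negative values mean an
inverted-cone shape (small headgroup, e.g. POPE).  Ions screen or bridge
anionic headgroups and thereby shift c0, so the table stores c0 per
(lipid, ion) as a function of salt concentration and interpolates linearly
between measured points.  Leaflet-average elastic parameters use
mole-fraction-weighted linear mixing, the standard first-order treatment for
lipid mixtures.

All quantities refer to 35 degC (308.15 K); only this temperature is
supported.  c0 is in inverse Angstrom, the monolayer bending rigidity
kappa_m in units of kBT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .composition import BilayerComposition, leaflet_mole_fractions

__all__ = [
    "CurvaturePoint",
    "CurvatureTable",
    "CurvatureError",
    "c0_of_lipid",
    "leaflet_c0",
    "leaflet_kappa",
    "read_curvature_table",
    "read_kappa_table",
    "default_table",
    "TEMPERATURE_K",
    "POPE_C0_WATER",
]

TEMPERATURE_K = 308.15
#: Measured intrinsic curvature of POPE in water at 35 degC.
POPE_C0_WATER = -0.032  # 1/A

NO_ION = "none"
DEFAULT_KAPPA_KBT = 10.0


class CurvatureError(ValueError):
    """Raised on missing entries or refused extrapolation."""


@dataclass(frozen=True)
class CurvaturePoint:
    """One tabulated c0 measurement for (lipid, ion) at a salt concentration."""

    lipid: str
    ion: str  # "none" | "Na" | "Ca" (free-form for other salts)
    concentration_mM: float
    c0_invA: float
    sigma_invA: float | None = None

    def __post_init__(self) -> None:
        if self.concentration_mM < 0:
            raise CurvatureError("concentration must be >= 0 mM")
        if self.sigma_invA is not None and self.sigma_invA < 0:
            raise CurvatureError("sigma must be >= 0")


@dataclass
class CurvatureTable:
    """Tabulated c0 per (lipid, ion) plus per-lipid monolayer rigidities.

    ``kappa_kBT`` maps lipid -> kappa_m; lipids absent from the map fall back
    to ``kappa_default_kBT`` unless that is None, in which case the lookup
    raises.
    """

    points: list[CurvaturePoint] = field(default_factory=list)
    kappa_kBT: dict[str, float] = field(default_factory=dict)
    kappa_default_kBT: float | None = DEFAULT_KAPPA_KBT
    temperature_K: float = TEMPERATURE_K

    def __post_init__(self) -> None:
        self._groups: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[tuple[str, str], list[CurvaturePoint]] = {}
        for p in self.points:
            grouped.setdefault((p.lipid, p.ion), []).append(p)
        for key, pts in grouped.items():
            conc = np.array([p.concentration_mM for p in pts], dtype=float)
            if np.any(np.diff(conc) <= 0):
                raise CurvatureError(
                    f"concentrations for {key} must be strictly increasing"
                )
            c0 = np.array([p.c0_invA for p in pts], dtype=float)
            self._groups[key] = (conc, c0)
        for lipid in {p.lipid for p in self.points}:
            zero = self._groups.get((lipid, NO_ION))
            if zero is None or zero[0][0] != 0.0:
                raise CurvatureError(
                    f"{lipid}: a zero-salt (ion='none', 0 mM) entry is required"
                )

    @property
    def lipids(self) -> set[str]:
        return {p.lipid for p in self.points}

    def kappa_of(self, lipid: str) -> float:
        if lipid in self.kappa_kBT:
            return self.kappa_kBT[lipid]
        if self.kappa_default_kBT is not None:
            return self.kappa_default_kBT
        raise CurvatureError(f"no bending rigidity entry for {lipid}")


def c0_of_lipid(
    table: CurvatureTable, lipid: str, ion: str = NO_ION, concentration_mM: float = 0.0
) -> float:
    """c0 of one lipid at the given ion condition, by linear interpolation.

    Exact at tabulated concentrations.  Queries above the tabulated range are
    refused (no silent clamping).  ``concentration_mM == 0`` always resolves
    to the zero-salt value, regardless of the nominal ion species.
    """
    if lipid not in table.lipids:
        raise CurvatureError(f"unknown lipid {lipid!r} in curvature table")
    if concentration_mM == 0.0:
        conc, c0 = table._groups[(lipid, NO_ION)]
        return float(c0[0])
    key = (lipid, ion)
    if key not in table._groups:
        raise CurvatureError(f"no c0 data for lipid {lipid!r} with ion {ion!r}")
    conc, c0 = table._groups[key]
    if concentration_mM > conc[-1] or concentration_mM < conc[0]:
        raise CurvatureError(
            f"extrapolation refused: {lipid}/{ion} tabulated on "
            f"[{conc[0]:g}, {conc[-1]:g}] mM, queried at {concentration_mM:g} mM"
        )
    return float(np.interp(concentration_mM, conc, c0))


def leaflet_c0(
    b: BilayerComposition,
    leaflet: Literal["inner", "outer"],
    table: CurvatureTable,
    ion: str = NO_ION,
    concentration_mM: float = 0.0,
) -> float:
    """Mole-fraction-weighted average c0 of one leaflet."""
    fractions = leaflet_mole_fractions(b, leaflet)
    missing = sorted(set(fractions) - table.lipids)
    if missing:
        raise CurvatureError(
            f"no curvature entry for leaflet lipid(s): {', '.join(missing)}"
        )
    return sum(
        x * c0_of_lipid(table, lipid, ion, concentration_mM)
        for lipid, x in fractions.items()
    )


def leaflet_kappa(
    b: BilayerComposition,
    leaflet: Literal["inner", "outer"],
    table: CurvatureTable,
) -> float:
    """Mole-fraction-weighted average monolayer bending rigidity, in kBT."""
    fractions = leaflet_mole_fractions(b, leaflet)
    return sum(x * table.kappa_of(lipid) for lipid, x in fractions.items())


def read_curvature_table(
    curvature_csv: str,
    kappa_csv: str | None = None,
    kappa_default_kBT: float | None = DEFAULT_KAPPA_KBT,
) -> CurvatureTable:
    """Load a curvature table from CSV.

    ``curvature_csv`` columns: lipid, ion, concentration_mM, c0_invA and an
    optional sigma_invA.  ``kappa_csv`` columns: lipid, kappa_kBT.
    """
    df = pd.read_csv(curvature_csv)
    required = {"lipid", "ion", "concentration_mM", "c0_invA"}
    if not required.issubset(df.columns):
        raise CurvatureError(
            f"curvature CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    has_sigma = "sigma_invA" in df.columns
    df = df.sort_values(["lipid", "ion", "concentration_mM"], kind="stable")
    points = [
        CurvaturePoint(
            lipid=str(row.lipid),
            ion=str(row.ion),
            concentration_mM=float(row.concentration_mM),
            c0_invA=float(row.c0_invA),
            sigma_invA=float(row.sigma_invA)
            if has_sigma and pd.notna(row.sigma_invA)
            else None,
        )
        for row in df.itertuples()
    ]
    kappa: dict[str, float] = {}
    if kappa_csv is not None:
        kdf = pd.read_csv(kappa_csv)
        kappa = dict(zip(kdf["lipid"].astype(str), kdf["kappa_kBT"].astype(float)))
    return CurvatureTable(
        points=points, kappa_kBT=kappa, kappa_default_kBT=kappa_default_kBT
    )


def write_curvature_table(table: CurvatureTable, curvature_csv: str) -> None:
    pd.DataFrame(
        [
            {
                "lipid": p.lipid,
                "ion": p.ion,
                "concentration_mM": p.concentration_mM,
                "c0_invA": p.c0_invA,
                "sigma_invA": p.sigma_invA,
            }
            for p in table.points
        ]
    ).to_csv(curvature_csv, index=False)


def default_table(max_concentration_mM: float = 1000.0) -> CurvatureTable:
    """The shipped salt-independent baseline table.

    POPE keeps c0 = -0.032 1/A under Ca2+ and Na+ (ions barely affect it) and
    POPC is treated as salt-independent with c0 = -0.011 1/A.  POPG, whose c0
    depends strongly on salt, carries no shipped salt curve: supply measured
    values via CSV or generate a saturating synthetic curve.  All lipids use
    kappa_m = 10 kBT unless overridden.
    """
    points: list[CurvaturePoint] = []
    for lipid, c0 in (("POPE", POPE_C0_WATER), ("POPC", -0.011)):
        points.append(CurvaturePoint(lipid, NO_ION, 0.0, c0))
        for ion in ("Na", "Ca"):
            points.append(CurvaturePoint(lipid, ion, 0.0, c0))
            points.append(CurvaturePoint(lipid, ion, max_concentration_mM, c0))
    return CurvatureTable(points=points)
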