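"""Leaflet-resolved lipid compositions of symmetric and asymmetric vesicles.

A bilayer is described by two mole-fraction maps, one per leaflet, where each
entry is the fraction of the *total* bilayer lipid contributed by that species
in that leaflet.  Under the equal-leaflet-size convention each leaflet holds
exactly half of the lipid, so each map sums to 0.5.  Asymmetric vesicles made
by outer-leaflet exchange are book-kept under the no-flip assumption: the
inner leaflet keeps its original composition while the outer leaflet is
replaced wholesale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

__all__ = [
    "LipidSpecies",
    "BilayerComposition",
    "CompositionError",
    "CompositionInconsistencyWarning",
    "make_bilayer",
    "overall_composition",
    "symmetrize",
    "leaflet_mole_fractions",
    "check_printed_ratio",
    "STANDARD_LIPIDS",
    "TABLE_BILAYERS",
    "PRINTED_OVERALL_RATIOS",
]

LEAFLET_SUM = 0.5
_LEAFLET_TOL = 1e-6


class CompositionError(ValueError):
    """Raised when a bilayer composition violates its invariants."""


class CompositionInconsistencyWarning(UserWarning):
    """A stored printed overall ratio disagrees with the leaflet-derived one."""


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid class identified by name, with its headgroup charge.

    The systems studied here are built from POPE and POPC (zwitterionic,
    charge 0) and the anionic POPG (charge -1).
    """

    name: str
    headgroup_charge: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise CompositionError("lipid species needs a non-empty name")
        if self.headgroup_charge not in (0, -1):
            raise CompositionError(
                f"headgroup charge must be 0 or -1, got {self.headgroup_charge}"
            )


#: The phospholipids of the study; hydrocarbon chains are PO (sn-1 palmitoyl,
#: sn-2 oleoyl) throughout, so species differ only in headgroup.
STANDARD_LIPIDS: dict[str, LipidSpecies] = {
    "POPE": LipidSpecies("POPE", 0),
    "POPC": LipidSpecies("POPC", 0),
    "POPG": LipidSpecies("POPG", -1),
}


@dataclass(frozen=True)
class BilayerComposition:
    """Inner/outer leaflet maps of lipid -> fraction of total bilayer lipid."""

    inner: Mapping[str, float]
    outer: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "inner", dict(self.inner))
        object.__setattr__(self, "outer", dict(self.outer))
        for leaflet_name, leaflet in (("inner", self.inner), ("outer", self.outer)):
            for lipid, frac in leaflet.items():
                if frac < 0:
                    raise CompositionError(
                        f"negative fraction for {lipid} in {leaflet_name} leaflet"
                    )
            total = sum(leaflet.values())
            if abs(total - LEAFLET_SUM) > _LEAFLET_TOL:
                raise CompositionError(
                    f"{leaflet_name} leaflet fractions sum to {total:.6g}, "
                    f"expected {LEAFLET_SUM} (equal-leaflet-size convention)"
                )

    @property
    def lipids(self) -> list[str]:
        """All species present, inner leaflet first, stable order."""
        seen = dict.fromkeys(self.inner)
        seen.update(dict.fromkeys(self.outer))
        return list(seen)

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        return set(self.inner) == set(self.outer) and all(
            abs(self.inner[l] - self.outer[l]) <= tol for l in self.inner
        )


def make_bilayer(
    inner: Mapping[str, float], outer: Mapping[str, float], label: str = ""
) -> BilayerComposition:
    """Validate and build a bilayer from per-leaflet total-lipid fractions."""
    return BilayerComposition(inner=inner, outer=outer, label=label)


def overall_composition(b: BilayerComposition) -> dict[str, float]:
    """Overall mole percent per lipid: 100 * (inner + outer fraction)."""
    return {
        lipid: 100.0 * (b.inner.get(lipid, 0.0) + b.outer.get(lipid, 0.0))
        for lipid in b.lipids
    }


def symmetrize(b: BilayerComposition) -> BilayerComposition:
    """The symmetric bilayer with the same overall composition.

    Models reconstitution into vesicles of the same lipid mixture: each
    species' overall fraction is split equally between the leaflets.
    Idempotent, and preserves :func:`overall_composition` exactly.
    """
    half = {
        lipid: (b.inner.get(lipid, 0.0) + b.outer.get(lipid, 0.0)) / 2.0
        for lipid in b.lipids
    }
    label = b.label if b.is_symmetric() else (f"{b.label}-sym" if b.label else "sym")
    return BilayerComposition(inner=half, outer=dict(half), label=label)


def leaflet_mole_fractions(
    b: BilayerComposition, leaflet: Literal["inner", "outer"]
) -> dict[str, float]:
    """Within-leaflet mole fractions (renormalized to sum to 1)."""
    if leaflet not in ("inner", "outer"):
        raise CompositionError(f"leaflet must be 'inner' or 'outer', got {leaflet!r}")
    m = b.inner if leaflet == "inner" else b.outer
    total = sum(m.values())
    if total <= 0:
        raise CompositionError(f"{leaflet} leaflet is empty")
    return {lipid: frac / total for lipid, frac in m.items()}


def check_printed_ratio(
    b: BilayerComposition,
    printed_percent: Mapping[str, float],
    tol_percent: float = 1.0,
) -> bool:
    """Compare leaflet-derived overall percentages against a printed ratio.

    Returns True when they agree within ``tol_percent`` mole percent for each
    lipid.  On disagreement a :class:`CompositionInconsistencyWarning` is
    emitted and False returned; neither value is corrected.
    """
    derived = overall_composition(b)
    bad = {
        lipid: (printed_percent.get(lipid, 0.0), derived.get(lipid, 0.0))
        for lipid in set(derived) | set(printed_percent)
        if abs(printed_percent.get(lipid, 0.0) - derived.get(lipid, 0.0)) > tol_percent
    }
    if bad:
        detail = "; ".join(
            f"{lipid}: printed {p:g}% vs leaflet-derived {d:g}%"
            for lipid, (p, d) in sorted(bad.items())
        )
        warnings.warn(
            f"{b.label or 'bilayer'}: printed overall ratio disagrees with "
            f"leaflet fractions ({detail})",
            CompositionInconsistencyWarning,
            stacklevel=2,
        )
        return False
    return True


# The four studied systems. Subscripted fractions are of the total bilayer
# lipid; inner leaflets keep their pre-exchange composition (no flip-flop).
TABLE_BILAYERS: dict[str, BilayerComposition] = {
    "PE/PC_1": make_bilayer(
        {"POPC": 0.5}, {"POPE": 0.34, "POPC": 0.16}, label="PE/PC_1"
    ),
    "PE/PC_2": make_bilayer(
        {"POPE": 0.19, "POPC": 0.31}, {"POPE": 0.35, "POPC": 0.15}, label="PE/PC_2"
    ),
    "PE/PC/PG": make_bilayer(
        {"POPC": 0.25, "POPG": 0.25},
        {"POPE": 0.25, "POPC": 0.12, "POPG": 0.13},
        label="PE/PC/PG",
    ),
    "PE/PG": make_bilayer({"POPG": 0.5}, {"POPE": 0.37, "POPG": 0.13}, label="PE/PG"),
}

#: Printed overall molar ratios (mole percent). PE/PC_2's printed 47:53
#: disagrees with its leaflet fractions (54:46); both are preserved and
#: check_printed_ratio warns about the discrepancy.
PRINTED_OVERALL_RATIOS: dict[str, dict[str, float]] = {
    "PE/PC_1": {"POPE": 34.0, "POPC": 66.0},
    "PE/PC_2": {"POPE": 47.0, "POPC": 53.0},
    "PE/PC/PG": {"POPE": 25.0, "POPC": 37.0, "POPG": 38.0},
    "PE/PG": {"POPE": 37.0, "POPG": 63.0},
}
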