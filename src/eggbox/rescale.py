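"""Rescaling atomic percents to the alginate C12 block.

The repeating unit for a cross-linked alginate dimer is the C12 block: two
uronic-acid residues, backbone C12H14O12.  Writing a gel's formula per C12
block makes elemental compositions from different samples directly
comparable and turns the measured metal content into X, the average number
of divalent cations per block.  The transformation is pure ratio arithmetic:
every atomic percent in a sample's row is multiplied by 12 / K_C, where K_C
is the sample's carbon at%.  Hydrogen, invisible to EDX, is imputed as 14
per block (the alginate stoichiometry).

The occupancy X classifies the junction-zone architecture of the gel:

* ``dimer_vdw`` (X <= 0.5): cations bind only within isolated dimers, which
  then stack through van der Waals contacts and hydrogen bonds;
* ``electrostatic_intermediate`` (0.5 < X < 1): chains and dimers accrete
  onto growing sheets through cation-carboxylate electrostatics, leaving
  some cells empty;
* ``complete_sheet`` (X = 1): every egg-box cell of the flat sheet holds a
  cation (typical of transition metals).

X above 1 is not a junction-zone state at all — it signals salt associates
physically adsorbed on the sheets, to be separated out by
:mod:`eggbox.decompose` before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .composition import CompositionError, ElementalComposition, round_half_up

__all__ = [
    "C12Composition",
    "JunctionZoneType",
    "JUNCTION_ZONE_TYPES",
    "OCCUPANCY_TOL",
    "DIVALENT_CATIONS",
    "rescale_to_c12",
    "classify_junction_zone",
    "format_c12_formula",
]

#: Divalent metals used as gelling agents; first one found in a composition
#: is taken as the sample's cross-linking cation.
DIVALENT_CATIONS = ("Ba", "Sr", "Ca", "Zn", "Cu", "Ni", "Mn", "Mg", "Cd", "Pb", "Co", "Fe")

#: Default tolerance on occupancy: X within 0.05 of 1 counts as a completely
#: filled sheet (measured 0.99 is "almost equal to one").
OCCUPANCY_TOL = 0.05

_HYDROGEN_PER_BLOCK = 14.0

#: Canonical element order for rendered formulas.
_FORMULA_ORDER = ("C", "H", "O", "Na")


@dataclass(frozen=True)
class C12Composition:
    """Element coefficients per C12 block (carbon pinned to 12).

    ``k_c`` is the raw carbon at% the scaling used; ``cation`` is the
    detected divalent metal, if any.
    """

    sample_id: str
    coefficients: Mapping[str, float]
    k_c: float
    hydrogen_imputed: bool = True
    cation: str | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        object.__setattr__(self, "metadata", dict(self.metadata))
        c = self.coefficients.get("C")
        if c is None or abs(c - 12.0) > 1e-9:
            raise CompositionError(
                f"sample {self.sample_id!r}: carbon coefficient must be 12, "
                f"got {c}"
            )
        if self.hydrogen_imputed:
            h = self.coefficients.get("H")
            if h != _HYDROGEN_PER_BLOCK:
                raise CompositionError(
                    f"sample {self.sample_id!r}: imputed hydrogen must be "
                    f"{_HYDROGEN_PER_BLOCK}, got {h}"
                )

    def coefficient(self, element: str, default: float = 0.0) -> float:
        return self.coefficients.get(element, default)

    @property
    def occupancy(self) -> float:
        """Raw cations per C12 block (may exceed 1 before decomposition)."""
        if self.cation is None:
            return 0.0
        return self.coefficients.get(self.cation, 0.0)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {
            el: round_half_up(v, ndigits) for el, v in self.coefficients.items()
        }

    def formula(self, ndigits: int = 2) -> str:
        return format_c12_formula(self, ndigits=ndigits)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "coefficients": dict(self.coefficients),
            "k_c": self.k_c,
            "hydrogen_imputed": self.hydrogen_imputed,
            "cation": self.cation,
            "metadata": dict(self.metadata),
        }


@dataclass(frozen=True)
class JunctionZoneType:
    """One of the three sheet architectures, with its occupancy interval."""

    label: str
    occupancy_range: tuple[float, float]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.occupancy_range
        return f"{self.label} ({lo:g} < X <= {hi:g})"


JUNCTION_ZONE_TYPES: dict[str, JunctionZoneType] = {
    "dimer_vdw": JunctionZoneType("dimer_vdw", (0.0, 0.5)),
    "electrostatic_intermediate": JunctionZoneType(
        "electrostatic_intermediate", (0.5, 1.0)
    ),
    "complete_sheet": JunctionZoneType("complete_sheet", (1.0, 1.0)),
}


def _entries_of(comp) -> tuple[str, Mapping[str, float], Mapping]:
    if isinstance(comp, C12Composition):
        return comp.sample_id, comp.coefficients, comp.metadata
    if isinstance(comp, ElementalComposition):
        return comp.sample_id, comp.entries, comp.metadata
    raise TypeError(f"cannot rescale {type(comp).__name__}")


def rescale_to_c12(comp, impute_hydrogen: bool = True) -> C12Composition:
    """Scale a composition so carbon equals 12 atoms, preserving all ratios.

    Accepts either a raw :class:`ElementalComposition` (at%) or an existing
    :class:`C12Composition` (the operation is idempotent).  Hydrogen, absent
    from EDX tables, is imputed as 14 per block unless ``impute_hydrogen``
    is false or the input already carries an H entry.
    """
    sample_id, entries, metadata = _entries_of(comp)
    k_c = entries.get("C")
    if k_c is None or not k_c > 0:
        raise CompositionError(
            f"sample {sample_id!r}: carbon absent or non-positive; cannot "
            "anchor the C12 rescaling"
        )
    factor = 12.0 / k_c
    coeff = {el: v * factor for el, v in entries.items()}
    coeff["C"] = 12.0  # pin exactly; factor arithmetic is within 1 ulp anyway
    imputed = False
    if impute_hydrogen and "H" not in coeff:
        coeff["H"] = _HYDROGEN_PER_BLOCK
        imputed = True
    elif isinstance(comp, C12Composition):
        imputed = comp.hydrogen_imputed
    cation = next((m for m in DIVALENT_CATIONS if m in coeff), None)
    if isinstance(comp, C12Composition):
        k_c = comp.k_c  # keep the original at% anchor through re-application
    return C12Composition(
        sample_id=sample_id,
        coefficients=coeff,
        k_c=k_c,
        hydrogen_imputed=imputed,
        cation=cation,
        metadata=metadata,
    )


def classify_junction_zone(
    x: float, tol: float = OCCUPANCY_TOL
) -> JunctionZoneType:
    """Map an occupancy X (cations per C12 block) to its junction-zone type.

    Raises for X beyond 1 + ``tol``: such compositions still contain
    physically adsorbed associates and must be decomposed first, since a
    flat egg-box sheet cannot hold more than one cation per block.
    """
    if x < 0:
        raise ValueError(f"occupancy must be >= 0, got {x}")
    if x > 1.0 + tol:
        raise ValueError(
            f"occupancy {x:.3g} exceeds the egg-box maximum of 1 per C12 "
            "block; separate adsorbed associates (run decomposition) first"
        )
    if abs(x - 1.0) <= tol:
        return JUNCTION_ZONE_TYPES["complete_sheet"]
    if x <= 0.5:
        return JUNCTION_ZONE_TYPES["dimer_vdw"]
    return JUNCTION_ZONE_TYPES["electrostatic_intermediate"]


def _format_coeff(v: float, ndigits: int) -> str:
    r = round_half_up(v, ndigits)
    if r == int(r):
        return "" if int(r) == 1 else str(int(r))
    return f"{r:.{ndigits}f}".rstrip("0")


def format_c12_formula(comp: C12Composition, ndigits: int = 2) -> str:
    """Render ``C12H14O10.75Na0.03Ba0.64``-style formula text.

    Elements appear as C, H, O, Na, then the divalent cation, then any
    remaining elements alphabetically; coefficients are rounded half-up to
    ``ndigits`` with trailing zeros (and unit coefficients) omitted.
    """
    order = [el for el in _FORMULA_ORDER if el in comp.coefficients]
    if comp.cation and comp.cation in comp.coefficients:
        order.append(comp.cation)
    order += sorted(el for el in comp.coefficients if el not in order)
    parts = []
    for el in order:
        v = comp.coefficients[el]
        if round_half_up(v, ndigits) == 0:
            continue
        parts.append(el + _format_coeff(v, ndigits))
    return "".join(parts)
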