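"""Separating structural cations from adsorbed associates and complexes.

A C12-block formula of an ionotropic gel frequently carries more divalent
metal than the egg-box maximum of one cation per block.  The excess is not
structural: neutral salt units (SrCl2, MnCl2, NiSO4*4H2O, ...) physically
adsorb onto the flat junction-zone sheets, and some transition metals sit
in the cells not as bare ions but as hydrated cation-anion complexes
(CuSO4*8H2O).  This module splits the measured metal coefficient into

* ``structural_x``   — bare cations cross-linking chains inside cells,
* ``in_cell_complex_fraction`` — cells occupied by a hydrated complex,
* ``associates``     — adsorbed salt units per C12 block (at most one per
  sheet face, so at most 2, barring chain-break surface growth),

with exact metal conservation, an anion balance, and an oxygen budget that
yields the residual alginate oxygen and, where the budget demands it, the
hydration water per unit.

Four policies cover the observed regimes; ``auto`` picks one from the
composition itself:

``anion_driven``
    Every anion belongs to an adsorbed associate: associates = anion/nu and
    the rest of the metal is structural (Sr, Ca, Zn chlorides/sulfate).
``full_occupancy``
    All cells are filled (X = 1) and the remaining metal is adsorbed;
    any anion imbalance is reported as a residual (Mn, with degraded,
    oxygen-poor chains).
``complex_in_cell``
    Metal is an integer per block within tolerance: adsorbed associates
    (capped at 2, one per face) absorb the integer excess over one per
    block and the remaining anion sits in cells as hydrated complexes
    (Cu, Ni).
``auto``
    Decision tree: no anion -> pure structural; severe oxygen deficit
    (alginate O < 8) -> full_occupancy; near-integer metal >= 1 ->
    complex_in_cell; otherwise anion_driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .composition import round_half_up
from .rescale import (
    OCCUPANCY_TOL,
    C12Composition,
    JunctionZoneType,
    classify_junction_zone,
)

__all__ = [
    "SaltSpec",
    "SALT_REGISTRY",
    "DecompositionResult",
    "DecompositionError",
    "decompose",
    "infer_hydration",
    "render_formula",
    "compare_occupancy",
    "ADSORBED_ASSOCIATE_CAP",
    "ALGINATE_OXYGEN_REFERENCE",
    "OXYGEN_DEFICIT_THRESHOLD",
]

POLICIES = ("anion_driven", "full_occupancy", "complex_in_cell", "auto")

#: One associate per sheet face: adsorption happens on both sides of a flat
#: junction zone, so the geometric cap is 2 per C12 block.
ADSORBED_ASSOCIATE_CAP = 2.0

#: Alginate oxygen per C12 block used as the anchor when hydration water
#: must be inferred from an oxygen surplus.  The backbone carries 12; EDX
#: systematically reads light elements low, and measured gels cluster
#: around 11.
ALGINATE_OXYGEN_REFERENCE = 11.0

#: Alginate oxygen below this per C12 block signals chain degradation
#: (dehydrogenation/decarboxylation) rather than a valid anion-driven split.
OXYGEN_DEFICIT_THRESHOLD = 8.0


class DecompositionError(ValueError):
    """Composition and salt stoichiometry cannot be reconciled."""


@dataclass(frozen=True)
class SaltSpec:
    """Stoichiometry of the gelation salt.

    ``nu`` is the number of anion units per divalent-cation formula unit
    (2 for chlorides, 1 for sulfates); ``anion_oxygens`` the oxygens one
    anion unit contributes to the measured O; ``default_hydration`` the
    crystallisation waters per salt unit.
    """

    cation: str
    anion: str
    nu: int
    anion_oxygens: int = 0
    default_hydration: int = 0

    def __post_init__(self) -> None:
        if self.nu not in (1, 2):
            raise ValueError(f"nu must be 1 or 2, got {self.nu}")
        if self.anion_oxygens < 0 or self.default_hydration < 0:
            raise ValueError("anion_oxygens and default_hydration must be >= 0")

    @property
    def anion_element(self) -> str:
        """Element whose C12 coefficient counts the anion (Cl itself, or S
        for sulfate — sulfate oxygen is folded into the O total)."""
        return "S" if self.anion == "SO4" else self.anion

    @property
    def formula(self) -> str:
        sub = str(self.nu) if self.nu > 1 else ""
        base = f"{self.cation}{self.anion}{sub}"
        if self.default_hydration:
            base += f"·{self.default_hydration}H2O"
        return base

    def anhydrous_formula(self) -> str:
        sub = str(self.nu) if self.nu > 1 else ""
        return f"{self.cation}{self.anion}{sub}"


#: Salts used for ionotropic gelation in the study conditions this package
#: models.  Nickel sulfate is registered as the tetrahydrate.
SALT_REGISTRY: dict[str, SaltSpec] = {
    "BaCl2": SaltSpec("Ba", "Cl", nu=2),
    "SrCl2": SaltSpec("Sr", "Cl", nu=2),
    "CaCl2": SaltSpec("Ca", "Cl", nu=2),
    "MnCl2": SaltSpec("Mn", "Cl", nu=2),
    "ZnSO4": SaltSpec("Zn", "SO4", nu=1, anion_oxygens=4),
    "CuSO4": SaltSpec("Cu", "SO4", nu=1, anion_oxygens=4),
    "NiSO4": SaltSpec("Ni", "SO4", nu=1, anion_oxygens=4, default_hydration=4),
}

#: Cation -> registry key, for auto-selecting the salt from a composition.
SALT_BY_CATION = {spec.cation: key for key, spec in SALT_REGISTRY.items()}


def get_salt(name: str) -> SaltSpec:
    """Look up a salt by formula (``"SrCl2"``) or cation (``"Sr"``)."""
    if name in SALT_REGISTRY:
        return SALT_REGISTRY[name]
    if name in SALT_BY_CATION:
        return SALT_REGISTRY[SALT_BY_CATION[name]]
    raise KeyError(
        f"unknown salt {name!r}; registered: {sorted(SALT_REGISTRY)}"
    )


@dataclass(frozen=True)
class DecompositionResult:
    """Decomposed metal inventory of one gel, per C12 block.

    ``structural_x`` counts bare cross-linking cations;
    ``in_cell_complex_fraction`` counts cells occupied by a hydrated
    complex (each holding one cation); their sum is the cell occupancy X
    that classifies the junction zone.  ``associates`` counts adsorbed salt
    units.  ``residual`` records any per-element imbalance left after the
    split rather than absorbing it silently.
    """

    sample_id: str
    cation: str
    salt: SaltSpec
    structural_x: float
    associates: float
    in_cell_complex_fraction: float = 0.0
    water_per_associate: float = 0.0
    water_per_complex: float = 0.0
    alginate_oxygen: float = 0.0
    sodium: float = 0.0
    residual: Mapping[str, float] = field(default_factory=dict)
    policy_used: str = "anion_driven"
    flags: tuple[str, ...] = ()
    zone_type: JunctionZoneType | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residual", dict(self.residual))
        if self.structural_x < 0 or self.associates < 0:
            raise DecompositionError(
                f"sample {self.sample_id!r}: negative structural_x or "
                "associates"
            )

    @property
    def occupancy(self) -> float:
        """Cells occupied per C12 block (bare ions plus complexes)."""
        return self.structural_x + self.in_cell_complex_fraction

    @property
    def total_metal(self) -> float:
        """Metal accounted for: must equal the measured coefficient."""
        return self.structural_x + self.in_cell_complex_fraction + self.associates

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "cation": self.cation,
            "salt": self.salt.formula,
            "structural_x": self.structural_x,
            "associates": self.associates,
            "in_cell_complex_fraction": self.in_cell_complex_fraction,
            "occupancy": self.occupancy,
            "water_per_associate": self.water_per_associate,
            "water_per_complex": self.water_per_complex,
            "alginate_oxygen": self.alginate_oxygen,
            "sodium": self.sodium,
            "residual": dict(self.residual),
            "policy_used": self.policy_used,
            "flags": list(self.flags),
            "zone_type": self.zone_type.label if self.zone_type else None,
            "formula": render_formula(self),
        }


def _snap(x: float, tol: float) -> float:
    """Round to the nearest integer when within ``tol`` of one."""
    r = round(x)
    return float(r) if abs(x - r) <= tol else x


def _choose_policy(
    metal: float, anion_units: float, oxygen: float, salt: SaltSpec, tol: float
) -> str:
    if anion_units <= tol / 10:
        return "anion_driven"  # degenerates to pure structural
    alginate_o = oxygen - salt.anion_oxygens * anion_units
    if alginate_o < OXYGEN_DEFICIT_THRESHOLD and metal > 1:
        return "full_occupancy"
    if metal >= 1 - tol and abs(metal - round(metal)) <= tol:
        return "complex_in_cell"
    if 0 < metal - anion_units / salt.nu <= 1 + tol:
        return "anion_driven"
    raise DecompositionError(
        f"auto policy: no rule matches metal={metal:.3g}, "
        f"anion/nu={anion_units / salt.nu:.3g}, O={oxygen:.3g}"
    )


def decompose(
    comp: C12Composition,
    salt: SaltSpec | str,
    policy: str = "auto",
    tol: float = OCCUPANCY_TOL,
    hydrated_in_cell: bool = False,
) -> DecompositionResult:
    """Split a gel's metal content into structural, complexed and adsorbed.

    ``hydrated_in_cell`` switches the in-cell complexes from anhydrous salt
    units to hydrated ones carrying the salt's default water (the two
    composition options for nickel; the hydration state of in-cell
    complexes is not experimentally settled).

    Metal conservation — structural + complexes + associates = measured
    metal — holds exactly (pre-rounding) for every policy.
    """
    if isinstance(salt, str):
        salt = get_salt(salt)
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    coeff = comp.coefficients
    if salt.cation not in coeff:
        raise DecompositionError(
            f"sample {comp.sample_id!r} lacks the salt cation {salt.cation}"
        )
    metal = coeff[salt.cation]
    anion_units = coeff.get(salt.anion_element, 0.0)
    oxygen = coeff.get("O", 0.0)
    sodium = coeff.get("Na", 0.0)
    flags: list[str] = []
    residual: dict[str, float] = {}

    if policy == "auto":
        policy = _choose_policy(metal, anion_units, oxygen, salt, tol)
        flags.append(f"auto->{policy}")

    complexes = 0.0
    water_assoc = 0.0
    water_complex = 0.0

    if policy == "anion_driven":
        associates = anion_units / salt.nu
        structural = metal - associates
        if structural < -tol:
            raise DecompositionError(
                f"sample {comp.sample_id!r}: anion ({anion_units:.3g}) exceeds "
                "metal stoichiometry; anion_driven split impossible"
            )
        structural = max(structural, 0.0)
        water_assoc = float(salt.default_hydration) if associates else 0.0
    elif policy == "full_occupancy":
        structural = 1.0
        associates = metal - 1.0
        if associates < -tol:
            raise DecompositionError(
                f"sample {comp.sample_id!r}: metal {metal:.3g} below full "
                "occupancy; full_occupancy policy inapplicable"
            )
        associates = max(associates, 0.0)
        anion_balance = anion_units - salt.nu * associates
        if abs(anion_balance) > tol:
            residual[salt.anion_element] = anion_balance
        water_assoc = float(salt.default_hydration) if associates else 0.0
    elif policy == "complex_in_cell":
        excess = max(metal - 1.0, 0.0)
        associates = min(_snap(excess, tol), ADSORBED_ASSOCIATE_CAP)
        complexes = anion_units / salt.nu - associates
        if complexes < -tol:
            raise DecompositionError(
                f"sample {comp.sample_id!r}: adsorbed associates already "
                "exceed the anion inventory"
            )
        complexes = max(complexes, 0.0)
        structural = metal - associates - complexes
        if structural < -tol:
            raise DecompositionError(
                f"sample {comp.sample_id!r}: anion exceeds metal stoichiometry"
            )
        structural = max(structural, 0.0)
        water_assoc = float(salt.default_hydration) if associates else 0.0
        water_complex = float(salt.default_hydration) if hydrated_in_cell else 0.0
    else:  # pragma: no cover - POLICIES guard above
        raise AssertionError(policy)

    if associates > ADSORBED_ASSOCIATE_CAP + tol / 10:
        flags.append("associates_exceed_face_cap")

    # Oxygen budget: anions and crystallisation water first, alginate keeps
    # the remainder; a surplus beyond the backbone's 12 means hydrated
    # in-cell complexes whose water must be inferred.
    alginate_o = (
        oxygen
        - salt.anion_oxygens * anion_units
        - water_assoc * associates
        - water_complex * complexes
    )
    if alginate_o > 12.0 + tol and complexes > tol:
        units = _snap(complexes, tol)
        inferred = (alginate_o - ALGINATE_OXYGEN_REFERENCE) / units
        water_complex = max(0.0, round(inferred))
        alginate_o -= water_complex * units
        flags.append("in_cell_water_inferred")
    if alginate_o < OXYGEN_DEFICIT_THRESHOLD:
        flags.append("oxygen_deficit_degradation")
    if alginate_o < 0:
        residual["O"] = alginate_o
        alginate_o = 0.0

    x = structural + complexes
    zone = classify_junction_zone(min(x, 1.0 + tol), tol=tol) if x <= 1 + tol else None
    if zone is None:
        flags.append("occupancy_above_unity_unresolved")

    return DecompositionResult(
        sample_id=comp.sample_id,
        cation=salt.cation,
        salt=salt,
        structural_x=structural,
        associates=associates,
        in_cell_complex_fraction=complexes,
        water_per_associate=water_assoc,
        water_per_complex=water_complex,
        alginate_oxygen=alginate_o,
        sodium=sodium,
        residual=residual,
        policy_used=policy,
        flags=tuple(flags),
        zone_type=zone,
    )


def infer_hydration(
    comp: C12Composition,
    result: DecompositionResult,
    alginate_oxygen_reference: float = ALGINATE_OXYGEN_REFERENCE,
    tol: float = OCCUPANCY_TOL,
) -> float:
    """Waters per salt unit implied by the sample's oxygen surplus.

    water = (measured O - alginate O - anion O per unit * units) / units,
    rounded to the nearest integer, where units = associates + in-cell
    complexes (snapped to an integer count when within ``tol`` of one).
    A negative budget clamps to 0: oxygen below the alginate reference
    indicates chain degradation, not negative hydration.
    """
    units = result.associates + result.in_cell_complex_fraction
    units = _snap(units, tol)
    oxygen = comp.coefficients.get("O", 0.0)
    surplus = oxygen - alginate_oxygen_reference
    if units <= 0:
        if surplus > tol:
            import warnings

            warnings.warn(
                f"sample {comp.sample_id!r}: {surplus:.2f} O per block "
                "unassigned (no associates or complexes)",
                stacklevel=2,
            )
        return 0.0
    water = (surplus - result.salt.anion_oxygens * units) / units
    water = round(water)
    if water < 0:
        return 0.0
    return float(water)


def _fmt(v: float, ndigits: int = 2) -> str:
    r = round_half_up(v, ndigits)
    if r == int(r):
        return str(int(r))
    return f"{r:.{ndigits}f}".rstrip("0")


def _unit_formula(salt: SaltSpec, water: float) -> str:
    base = salt.anhydrous_formula()
    if water >= 1:
        base += f"·{_fmt(water)}H2O"
    return base


def _backbone(result: DecompositionResult, me_coeff: float | None) -> str:
    parts = ["C12", "H14", "O" + _fmt(result.alginate_oxygen)]
    if round_half_up(result.sodium) > 0:
        parts.append("Na" + _fmt(result.sodium))
    if me_coeff is not None and round_half_up(me_coeff) > 0:
        c = _fmt(me_coeff)
        parts.append(result.cation + ("" if c == "1" else c))
    return "".join(parts)


def render_formula(result: DecompositionResult, ndigits: int = 2) -> str:
    """Render the decomposition as a chemical formula string.

    Plain gels print as ``(C12H14O10.75Na0.03Ba0.64)n``; gels with adsorbed
    associates append ``+ 1.15·SrCl2``; gels with in-cell complexes print
    the cell mixture, e.g. ``{0.72·C12H14O11.67Ni +
    0.27·C12H14O11.67·(NiSO4) + 2·(NiSO4·4H2O)}n``.  Coefficients are
    half-up-rounded to ``ndigits``, zero terms and unit coefficients
    omitted; the rendering is deterministic.
    """
    cpx = result.in_cell_complex_fraction
    if round_half_up(cpx, ndigits) > 0:
        terms = []
        plain = result.structural_x
        if round_half_up(plain, ndigits) > 0:
            terms.append(f"{_fmt(plain)}·{_backbone(result, 1.0)}")
        cell_unit = _unit_formula(result.salt, result.water_per_complex)
        terms.append(f"{_fmt(cpx)}·{_backbone(result, None)}·({cell_unit})")
        if round_half_up(result.associates, ndigits) > 0:
            ads = _unit_formula(result.salt, result.water_per_associate)
            terms.append(f"{_fmt(result.associates)}·({ads})")
        return "{" + " + ".join(terms) + "}n"
    body = _backbone(result, result.structural_x)
    if round_half_up(result.associates, ndigits) > 0:
        ads = _unit_formula(result.salt, result.water_per_associate)
        body += f" + {_fmt(result.associates)}·{ads}"
    return f"({body})n"


@dataclass(frozen=True)
class OccupancyComparison:
    """Experimental cell occupancy against the combinatorial prediction."""

    sample_id: str
    x_experimental: float
    x_theoretical: float
    difference: float
    preference_set: "object"
    complex_fraction_experimental: float | None = None
    complex_fraction_theoretical: float | None = None

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "x_experimental": self.x_experimental,
            "x_theoretical": self.x_theoretical,
            "difference": self.difference,
            "preference_classes": sorted(self.preference_set.classes),
        }
        if self.complex_fraction_experimental is not None:
            d["complex_fraction_experimental"] = self.complex_fraction_experimental
            d["complex_fraction_theoretical"] = self.complex_fraction_theoretical
        return d


def compare_occupancy(result: DecompositionResult, ratio, prefs) -> OccupancyComparison:
    """Compare measured occupancy X with the preference-set prediction X_T.

    For ``complex_in_cell`` results the in-cell complex fraction is also
    compared against the GG-containing-cell probability (the large cavities
    complexes require), using the Ca preference set.
    """
    from .combinatorics import PREFERENCE_SETS, PreferenceSet, occupancy

    if isinstance(prefs, str):
        prefs = PREFERENCE_SETS[prefs]
    elif not isinstance(prefs, PreferenceSet):
        prefs = PreferenceSet(result.cation, frozenset(prefs))
    x_t = float(occupancy(ratio, prefs))
    x_exp = result.occupancy
    cf_exp = cf_t = None
    if result.policy_used == "complex_in_cell" and result.in_cell_complex_fraction > 0:
        cf_exp = result.in_cell_complex_fraction
        cf_t = float(occupancy(ratio, PREFERENCE_SETS["Ca"]))
    return OccupancyComparison(
        sample_id=result.sample_id,
        x_experimental=x_exp,
        x_theoretical=x_t,
        difference=abs(x_exp - x_t),
        preference_set=prefs,
        complex_fraction_experimental=cf_exp,
        complex_fraction_theoretical=cf_t,
    )
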