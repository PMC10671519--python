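"""Egg-box cell combinatorics for arbitrary monomer ratio mu = M/G.

Alginate is an irregular copolymer of mannuronate (M) and guluronate (G)
residues.  Under the egg-box model, divalent cations cross-link two chains;
the binding cavity ("cell") is formed by four residues — one two-residue
block from each chain.  Treating residues as i.i.d. draws with

    P(M) = mu / (1 + mu),      P(G) = 1 / (1 + mu),

the four ordered blocks have probabilities GG = 1/(1+mu)^2,
GM = MG = mu/(1+mu)^2, MM = mu^2/(1+mu)^2, and the 16 ordered block pairs
collapse into seven cell classes under the cell symmetries (swapping the
two chains, and reading the cell from the other end, which reverses both
blocks at once).  GM-GM and MG-MG fold together but remain distinct from
GM-MG/MG-GM: the former oppose parallel residue patterns, the latter
antiparallel ones.  Class probabilities are multiplicity * mu^degree /
(1+mu)^4 with multiplicities (1, 4, 2, 2, 2, 4, 1).

The theoretical occupancy X_T of a cation is the summed probability of the
cell classes it is able to bind (its "preference set", assembled from
structural literature).  For the alginate studied here (mu = 1.56) the
registry ships the sets used for Ba/Zn, Sr, and Ca/Ni-complexes, plus the
GG-GG-only set governing the dimer-nucleating zipper cells.

The i.i.d. residue model is the one under which the block and cell tables
are exact; real alginates carry block correlations, which the Monte Carlo
simulator in :mod:`eggbox.synth` can emulate via a first-order chain.

Arithmetic is exact (:class:`fractions.Fraction`) whenever mu is supplied
as a rational, so normalisation identities hold with no floating error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Union

__all__ = [
    "MonomerRatio",
    "BlockDistribution",
    "CellClass",
    "CELL_CLASSES",
    "CELL_CLASS_LABELS",
    "BLOCKS",
    "PreferenceSet",
    "PREFERENCE_SETS",
    "block_probabilities",
    "cell_probabilities",
    "occupancy",
    "enumerate_cells_oracle",
    "classify_cell",
    "rationalize_mu",
]

Number = Union[float, Fraction]

BLOCKS = ("GG", "GM", "MG", "MM")


@dataclass(frozen=True)
class MonomerRatio:
    """The ratio mu = M/G characterising an alginate sample.

    When ``exact`` is given (or constructed via :meth:`from_fraction` /
    :meth:`from_string`), all probabilities downstream are exact rationals.
    """

    mu: float
    exact: Fraction | None = None

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.exact is not None:
            if self.exact <= 0:
                raise ValueError(f"exact mu must be > 0, got {self.exact}")
            if abs(float(self.exact) - self.mu) > 1e-12 * max(1.0, self.mu):
                raise ValueError(
                    f"exact ratio {self.exact} disagrees with mu={self.mu}"
                )

    @classmethod
    def from_float(cls, mu: float) -> "MonomerRatio":
        return cls(float(mu))

    @classmethod
    def from_fraction(cls, frac) -> "MonomerRatio":
        frac = Fraction(frac)
        return cls(float(frac), frac)

    @classmethod
    def from_string(cls, text: str) -> "MonomerRatio":
        """Parse ``"1.56"`` (exact: 39/25) or ``"3/2"``."""
        return cls.from_fraction(Fraction(text.strip()))

    @property
    def value(self) -> Number:
        return self.exact if self.exact is not None else self.mu

    @property
    def p_m(self) -> Number:
        """Probability that a residue is mannuronate, mu/(1+mu)."""
        v = self.value
        return v / (1 + v)

    @property
    def p_g(self) -> Number:
        """Probability that a residue is guluronate, 1/(1+mu)."""
        v = self.value
        return 1 / (1 + v)


def _as_ratio(ratio) -> MonomerRatio:
    if isinstance(ratio, MonomerRatio):
        return ratio
    if isinstance(ratio, Fraction):
        return MonomerRatio.from_fraction(ratio)
    return MonomerRatio.from_float(ratio)


@dataclass(frozen=True)
class BlockDistribution:
    """Probabilities of the four ordered two-residue blocks."""

    probabilities: Mapping[str, Number]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probabilities", dict(self.probabilities))

    def __getitem__(self, block: str) -> Number:
        return self.probabilities[block]


@dataclass(frozen=True)
class CellClass:
    """A symmetry class of four-residue egg-box cells.

    ``multiplicity`` counts the ordered (block-from-chain-1,
    block-from-chain-2) configurations in the class; ``mu_degree`` is the
    total number of M residues, i.e. the power of mu in the numerator of
    the class probability multiplicity * mu^degree / (1+mu)^4.
    """

    label: str
    multiplicity: int
    mu_degree: int
    members: tuple[tuple[str, str], ...] = field(repr=False)

    def probability(self, ratio) -> Number:
        mu = _as_ratio(ratio).value
        return self.multiplicity * mu**self.mu_degree / (1 + mu) ** 4


def _cell_orbit(b1: str, b2: str) -> frozenset[tuple[str, str]]:
    rev = (b1[::-1], b2[::-1])  # read the cell from the other end
    return frozenset({(b1, b2), (b2, b1), rev, (rev[1], rev[0])})


def _build_classes() -> tuple[CellClass, ...]:
    seen: dict[frozenset, list[tuple[str, str]]] = {}
    for b1, b2 in itertools.product(BLOCKS, repeat=2):
        orbit = _cell_orbit(b1, b2)
        seen.setdefault(orbit, []).append((b1, b2))
    classes = []
    for orbit, members in seen.items():
        reps = sorted({m for pair in orbit for m in [pair]})
        label = "/".join(
            sorted({f"{a}-{b}" for a, b in orbit})
        )
        degree = sum(m.count("M") for m in reps[0])
        classes.append(
            CellClass(label, len(members), degree, tuple(sorted(members)))
        )
    # stable presentation order: by mu degree, then GG-led before mixed
    classes.sort(key=lambda c: (c.mu_degree, c.label))
    return tuple(classes)


def _canonical_label(raw: str) -> str:
    """Normalise labels built by :func:`_build_classes` to the field's names."""
    alias = {
        "GG-GG": "GG-GG",
        "GG-GM/GG-MG/GM-GG/MG-GG": "GG-GM/GG-MG",
        "GG-MM/MM-GG": "GG-MM",
        "GM-GM/MG-MG": "GM-GM",
        "GM-MG/MG-GM": "GM-MG",
        "GM-MM/MG-MM/MM-GM/MM-MG": "MM-GM/MM-MG",
        "MM-MM": "MM-MM",
    }
    return alias[raw]


CELL_CLASSES: tuple[CellClass, ...] = tuple(
    CellClass(_canonical_label(c.label), c.multiplicity, c.mu_degree, c.members)
    for c in _build_classes()
)

CELL_CLASS_LABELS: tuple[str, ...] = tuple(c.label for c in CELL_CLASSES)

_CLASS_BY_LABEL = {c.label: c for c in CELL_CLASSES}
_CLASS_OF_PAIR = {
    pair: c.label for c in CELL_CLASSES for pair in c.members
}

#: Accepted spellings for user-supplied class labels (en-dash or hyphen,
#: either ordered member of an aggregated class).
_LABEL_ALIASES: dict[str, str] = {}
for _c in CELL_CLASSES:
    _LABEL_ALIASES[_c.label] = _c.label
    for _a, _b in _c.members:
        _LABEL_ALIASES[f"{_a}-{_b}"] = _c.label


def resolve_class_label(label: str) -> str:
    key = label.strip().replace("–", "-").replace("—", "-")
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise KeyError(
            f"unknown cell-class label {label!r}; expected one of "
            f"{CELL_CLASS_LABELS}"
        ) from None


def classify_cell(block1: str, block2: str) -> str:
    """Return the class label of the ordered block pair forming a cell."""
    try:
        return _CLASS_OF_PAIR[(block1, block2)]
    except KeyError:
        raise ValueError(f"invalid blocks ({block1!r}, {block2!r})") from None


@dataclass(frozen=True)
class PreferenceSet:
    """Cell classes a given cation can occupy, per structural literature.

    ``tentative`` marks sets the literature does not fix unequivocally.
    """

    cation: str
    classes: frozenset[str]
    literature_note: str = ""
    tentative: bool = False

    def __post_init__(self) -> None:
        resolved = frozenset(resolve_class_label(c) for c in self.classes)
        if not resolved:
            pass  # empty set allowed: occupancy 0
        object.__setattr__(self, "classes", resolved)


#: Registered preference sets.  Ba and Zn share the GG/MM-block set; Sr adds
#: GG-GM cells (tentative: conflicting literature); Ca — and the in-cell
#: hydrated complexes of Ni — bind only cells containing a GG block; the
#: GG-GG-only set gives the probability of the zipper-nucleating cells.
PREFERENCE_SETS: dict[str, PreferenceSet] = {
    "Ba": PreferenceSet(
        "Ba",
        frozenset({"GG-GG", "GG-MM", "MM-GM/MM-MG", "MM-MM"}),
        "binds cells containing GG and MM blocks; GM-MM inclusion tentative",
        tentative=True,
    ),
    "Zn": PreferenceSet(
        "Zn",
        frozenset({"GG-GG", "GG-MM", "MM-GM/MM-MG", "MM-MM"}),
        "largest transition-metal radius; behaves like the alkaline-earth set",
        tentative=True,
    ),
    "Sr": PreferenceSet(
        "Sr",
        frozenset({"GG-GG", "GG-GM/GG-MG", "GG-MM", "MM-GM/MM-MG"}),
        "prefers GG and GM blocks; literature contradictory",
        tentative=True,
    ),
    "Ca": PreferenceSet(
        "Ca",
        frozenset({"GG-GG", "GG-GM/GG-MG", "GG-MM"}),
        "coordinates only cells containing GG blocks (largest cavities)",
    ),
    "Ni": PreferenceSet(
        "Ni",
        frozenset({"GG-GG", "GG-GM/GG-MG", "GG-MM"}),
        "in-cell hydrated complexes occupy the large GG-containing cavities",
    ),
    "GG_only": PreferenceSet(
        "GG_only",
        frozenset({"GG-GG"}),
        "pure-guluronate cells that nucleate chain zipping into dimers",
    ),
}


def block_probabilities(ratio) -> BlockDistribution:
    """Probabilities of GG, GM, MG, MM blocks on a single chain."""
    r = _as_ratio(ratio)
    pg, pm = r.p_g, r.p_m
    return BlockDistribution(
        {"GG": pg * pg, "GM": pg * pm, "MG": pm * pg, "MM": pm * pm}
    )


def cell_probabilities(ratio) -> dict[str, Number]:
    """Probabilities of the seven cell classes (sums to 1 for any mu)."""
    r = _as_ratio(ratio)
    return {c.label: c.probability(r) for c in CELL_CLASSES}


def occupancy(ratio, prefs: Union[PreferenceSet, Iterable[str]]) -> Number:
    """Theoretical occupancy X_T: summed probability of the preferred classes.

    Monotone under set inclusion; equals 1 for the full seven-class set and
    0 for the empty set.
    """
    if isinstance(prefs, PreferenceSet):
        labels = prefs.classes
    elif isinstance(prefs, str):
        labels = {resolve_class_label(prefs)}
    else:
        labels = {resolve_class_label(c) for c in prefs}
    probs = cell_probabilities(ratio)
    return sum((probs[c] for c in labels), start=Fraction(0) if all(
        isinstance(v, Fraction) for v in probs.values()
    ) else 0.0)


def enumerate_cells_oracle(ratio) -> dict[str, Number]:
    """Brute-force check of :func:`cell_probabilities`.

    Enumerates all 2^4 ordered four-residue configurations (two residues
    per chain, i.i.d. with P(M) = mu/(1+mu)), groups them into cells by the
    symmetry rule, and sums configuration probabilities.  Agrees exactly
    with the closed forms in rational mode.
    """
    r = _as_ratio(ratio)
    p = {"G": r.p_g, "M": r.p_m}
    zero: Number = Fraction(0) if r.exact is not None else 0.0
    totals = {label: zero for label in CELL_CLASS_LABELS}
    for m1, m2, m3, m4 in itertools.product("GM", repeat=4):
        block1, block2 = m1 + m2, m3 + m4
        weight = p[m1] * p[m2] * p[m3] * p[m4]
        totals[classify_cell(block1, block2)] += weight
    return totals


def rationalize_mu(mu: float, max_denominator: int) -> Fraction:
    """Best rational approximation of mu with bounded denominator.

    Continued-fraction convergent, e.g. 1.56 -> 3/2 at ``max_denominator=2``
    and 39/25 at 25.
    """
    if not mu > 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    if max_denominator < 1:
        raise ValueError(f"max_denominator must be >= 1, got {max_denominator}")
    return Fraction(mu).limit_denominator(max_denominator)
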