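"""Per-sample elemental compositions in atomic percent.

Energy-dispersive X-ray spectroscopy (EDX) reports, for a selected zone of a
dried hydrogel microsphere, the relative number of atoms of each detected
element as atomic percent.  This module holds the container for one such
measurement, CSV/JSON round-tripping in a long (sample_id, element,
atomic_percent) and a wide (one column per element) dialect, and the
trace-element filter applied before any stoichiometric rescaling.

EDX is blind to hydrogen, and sputter-coating plus instrument background
contribute sub-0.1 at% traces (Al, Si) that carry no chemical information
about the gel; those are discarded, never renormalised — all downstream
arithmetic works on element ratios, for which renormalisation is a no-op.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("eggbox")

__all__ = [
    "ElementalComposition",
    "CompositionError",
    "ELEMENT_SYMBOLS",
    "DEFAULT_TRACE_CUTOFF",
    "read_composition_table",
    "write_composition_table",
    "discard_traces",
    "round_half_up",
]

#: IUPAC element symbols, H through Og.
ELEMENT_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

#: Smallest cutoff (raw at%) that separates instrument traces (Al, Si and
#: residual Cl after washing) from chemically meaningful residuals such as Na.
DEFAULT_TRACE_CUTOFF = 0.10

#: Tolerated range for the at% total of a raw table (traces already dropped
#: by the instrument software, plus rounding, move the sum off 100).
_SUM_RANGE = (95.0, 105.0)


class CompositionError(ValueError):
    """Invalid elemental-composition data (bad symbol, value, or schema)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed chemical formulas are."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ElementalComposition:
    """One sample's EDX result: element symbol -> atomic percent.

    Parameters
    ----------
    sample_id
        Label of the hydrogel sample (e.g. ``"Ba-alg"``).
    entries
        Mapping of IUPAC element symbol to atomic percent, each > 0.
    metadata
        Free-form sample annotations; conventionally ``r_ion_nm`` (ionic
        radius of the gelling cation), washing protocol, instrument, and —
        after :func:`discard_traces` — the ``discarded`` record.
    """

    sample_id: str
    entries: Mapping[str, float]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise CompositionError("sample_id must be non-empty")
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "metadata", dict(self.metadata))
        for el, pct in self.entries.items():
            if el not in ELEMENT_SYMBOLS:
                raise CompositionError(
                    f"sample {self.sample_id!r}: {el!r} is not an element symbol"
                )
            if not pct > 0:
                raise CompositionError(
                    f"sample {self.sample_id!r}, element {el}: atomic percent "
                    f"must be > 0, got {pct}"
                )
        total = sum(self.entries.values())
        lo, hi = _SUM_RANGE
        if self.entries and not lo <= total <= hi:
            raise CompositionError(
                f"sample {self.sample_id!r}: atomic percents sum to "
                f"{total:.2f}, outside [{lo}, {hi}]"
            )

    @property
    def total(self) -> float:
        return sum(self.entries.values())

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "entries": dict(self.entries),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ElementalComposition":
        return cls(d["sample_id"], d["entries"], d.get("metadata", {}))

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "ElementalComposition":
        return cls.from_dict(json.loads(s))


_LONG_COLUMNS = ["sample_id", "element", "atomic_percent"]


def _parse_long(df: pd.DataFrame, path) -> list[ElementalComposition]:
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise CompositionError(f"{path}: missing column(s) {missing}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        dup = grp["element"][grp["element"].duplicated()]
        if not dup.empty:
            lines = [str(i + 2) for i in dup.index]  # +2: header + 0-base
            raise CompositionError(
                f"{path}: duplicate element(s) {sorted(set(dup))} for sample "
                f"{sid!r} (line {', '.join(lines)})"
            )
        entries = {}
        for idx, row in grp.iterrows():
            try:
                pct = float(row["atomic_percent"])
            except (TypeError, ValueError):
                raise CompositionError(
                    f"{path} line {idx + 2}: unparseable atomic_percent "
                    f"{row['atomic_percent']!r}"
                ) from None
            if not pct > 0:
                raise CompositionError(
                    f"{path} line {idx + 2}: sample {sid!r}, element "
                    f"{row['element']!r}: atomic percent must be > 0, got {pct}"
                )
            entries[str(row["element"])] = pct
        out.append(ElementalComposition(str(sid), entries))
    return out


def _parse_wide(df: pd.DataFrame, path) -> list[ElementalComposition]:
    if "sample_id" not in df.columns:
        raise CompositionError(f"{path}: missing column(s) ['sample_id']")
    out = []
    element_cols = [c for c in df.columns if c != "sample_id"]
    bad = [c for c in element_cols if c not in ELEMENT_SYMBOLS]
    if bad:
        raise CompositionError(f"{path}: non-element column(s) {bad}")
    for idx, row in df.iterrows():
        entries = {
            el: float(row[el]) for el in element_cols if pd.notna(row[el])
        }
        for el, pct in entries.items():
            if not pct > 0:
                raise CompositionError(
                    f"{path} line {idx + 2}: sample {row['sample_id']!r}, "
                    f"element {el}: atomic percent must be > 0, got {pct}"
                )
        out.append(ElementalComposition(str(row["sample_id"]), entries))
    return out


def read_composition_table(path, dialect: str = "long") -> list[ElementalComposition]:
    """Read a CSV of elemental compositions.

    ``dialect="long"`` expects columns ``sample_id, element, atomic_percent``;
    ``"wide"`` expects ``sample_id`` plus one column per element (blank cells
    mean the element was not detected); ``"auto"`` sniffs the header.  An
    empty file yields an empty list with a logged warning.
    """
    if dialect not in ("long", "wide", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty composition table", path)
        warnings.warn(f"{path}: empty composition table", stacklevel=2)
        return []
    if df.empty and len(df.columns) <= 1:
        logger.warning("%s: empty composition table", path)
        return []
    if dialect == "auto":
        dialect = "long" if set(_LONG_COLUMNS) <= set(df.columns) else "wide"
    if dialect == "long":
        return _parse_long(df, path)
    return _parse_wide(df, path)


def write_composition_table(
    comps: Iterable[ElementalComposition], path, dialect: str = "long"
) -> None:
    """Write compositions as CSV in the long (canonical) or wide dialect."""
    comps = list(comps)
    if dialect == "long":
        rows = [
            (c.sample_id, el, pct)
            for c in comps
            for el, pct in c.entries.items()
        ]
        pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)
    elif dialect == "wide":
        records = [{"sample_id": c.sample_id, **c.entries} for c in comps]
        pd.DataFrame(records).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def discard_traces(
    comp: ElementalComposition, cutoff: float = DEFAULT_TRACE_CUTOFF
) -> ElementalComposition:
    """Drop elements below ``cutoff`` raw at%; retained values are untouched.

    The removal list is recorded under ``metadata["discarded"]``.  No
    renormalisation is performed: the subsequent C12 rescaling consumes
    ratios only.  Removing carbon — the scaling anchor for every later
    step — is an error.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be >= 0, got {cutoff}")
    kept = {el: v for el, v in comp.entries.items() if v >= cutoff}
    dropped = {el: v for el, v in comp.entries.items() if v < cutoff}
    if "C" not in kept:
        raise CompositionError(
            f"sample {comp.sample_id!r}: no carbon above cutoff {cutoff}; "
            "carbon is the C12 scaling anchor"
        )
    meta = dict(comp.metadata)
    if dropped:
        prior = dict(meta.get("discarded", {}))
        prior.update(dropped)
        meta["discarded"] = prior
    return replace(comp, entries=kept, metadata=meta)
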