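"""Bundled reference dataset: the divalent-metal alginate gel study.

Eight freeze-dried alginate hydrogel microsphere samples (sodium alginate,
mu = M/G = 1.56, gelled in 1 M divalent-metal salt), characterised by EDX
atomic-percent analysis.  The raw at% rows, the gelation salt of each
sample, and the published C12-block coefficients and decomposition
formulas are stored here so the whole pipeline can be re-run and diffed
against its expected output without any external files.

Samples are ordered by decreasing cation ionic radius.  ``Sr-alg-washed``
is the strontium gel after 6 h of additional washing, which strips the
physically adsorbed SrCl2 associates and leaves the structural cations
only — the experimental control for the associate-separation step.
"""

from __future__ import annotations

from fractions import Fraction

from .composition import ElementalComposition

__all__ = [
    "STUDY_MU",
    "STUDY_MU_EXACT",
    "reference_compositions",
    "REFERENCE_ATOMIC_PERCENT",
    "REFERENCE_SALTS",
    "REFERENCE_C12",
    "REFERENCE_FORMULAS",
    "REFERENCE_PREFERENCE_SET",
    "REFERENCE_BLOCK_TABLE",
    "REFERENCE_CELL_TABLE",
    "REFERENCE_OCCUPANCY",
]

#: Monomer ratio of the studied sodium alginate.
STUDY_MU = 1.56
STUDY_MU_EXACT = Fraction(39, 25)

#: Raw EDX atomic percent per sample (element -> at%), with the cation
#: ionic radius in nm.  Dashes in the published table are absent keys.
REFERENCE_ATOMIC_PERCENT: dict[str, dict] = {
    "Ba-alg": {
        "r_ion_nm": 0.135,
        "entries": {"Ba": 2.74, "C": 51.16, "O": 45.81, "Na": 0.14,
                    "Cl": 0.05, "Al": 0.06, "Si": 0.04},
    },
    "Sr-alg": {
        "r_ion_nm": 0.113,
        "entries": {"Sr": 6.47, "C": 43.18, "O": 41.73, "Na": 0.36,
                    "Cl": 8.27},
    },
    "Sr-alg-washed": {
        "r_ion_nm": 0.113,
        "washing": "additional 6 h",
        "entries": {"Sr": 2.71, "C": 50.04, "O": 47.25},
    },
    "Ca-alg": {
        "r_ion_nm": 0.099,
        "entries": {"Ca": 6.48, "C": 43.30, "O": 38.51, "Na": 0.49,
                    "Cl": 11.15, "Al": 0.04, "Si": 0.03},
    },
    "Zn-alg": {
        "r_ion_nm": 0.074,
        "entries": {"Zn": 5.02, "C": 40.68, "O": 51.33, "S": 2.87,
                    "Al": 0.05, "Si": 0.05},
    },
    "Cu-alg": {
        "r_ion_nm": 0.073,
        "entries": {"Cu": 2.68, "C": 32.40, "O": 62.23, "S": 2.60,
                    "Al": 0.05, "Si": 0.04},
    },
    "Ni-alg": {
        "r_ion_nm": 0.069,
        "entries": {"Ni": 6.49, "C": 26.07, "O": 62.45, "S": 4.94,
                    "Al": 0.03, "Si": 0.02},
    },
    "Mn-alg": {
        "r_ion_nm": 0.067,
        "entries": {"Mn": 11.8, "C": 45.80, "O": 24.99, "Na": 0.12,
                    "Cl": 17.2, "Al": 0.05, "Si": 0.04},
    },
}

#: Gelation salt per sample.
REFERENCE_SALTS: dict[str, str] = {
    "Ba-alg": "BaCl2",
    "Sr-alg": "SrCl2",
    "Sr-alg-washed": "SrCl2",
    "Ca-alg": "CaCl2",
    "Zn-alg": "ZnSO4",
    "Cu-alg": "CuSO4",
    "Ni-alg": "NiSO4",
    "Mn-alg": "MnCl2",
}

#: Published C12-block coefficients (after trace discarding, display
#: rounding half-up to 2 decimals).
REFERENCE_C12: dict[str, dict[str, float]] = {
    "Ba-alg": {"C": 12, "O": 10.75, "Na": 0.03, "Ba": 0.64},
    "Sr-alg": {"C": 12, "O": 11.60, "Na": 0.10, "Sr": 1.80, "Cl": 2.30},
    "Sr-alg-washed": {"C": 12, "O": 11.33, "Sr": 0.65},
    "Ca-alg": {"C": 12, "O": 10.67, "Na": 0.14, "Ca": 1.80, "Cl": 3.09},
    "Zn-alg": {"C": 12, "O": 15.14, "Zn": 1.48, "S": 0.85},
    "Cu-alg": {"C": 12, "O": 23.05, "Cu": 0.99, "S": 0.96},
    "Ni-alg": {"C": 12, "O": 28.75, "Ni": 2.99, "S": 2.27},
    "Mn-alg": {"C": 12, "O": 6.55, "Na": 0.03, "Mn": 3.09, "Cl": 4.51},
}

#: Published decomposition results: key coefficients per sample.
REFERENCE_FORMULAS: dict[str, dict[str, float]] = {
    "Ba-alg": {"structural_x": 0.64, "associates": 0.0},
    "Sr-alg": {"structural_x": 0.65, "associates": 1.15},
    "Sr-alg-washed": {"structural_x": 0.65, "associates": 0.0},
    "Ca-alg": {"structural_x": 0.26, "associates": 1.545},
    "Zn-alg": {"structural_x": 0.63, "associates": 0.85},
    "Cu-alg": {"occupancy": 0.99, "water_per_complex": 8},
    "Ni-alg": {
        "structural_x": 0.72,  # 0.73 in rounded bookkeeping; 2.99 - 2 - 0.27
        "associates": 2.0,
        "in_cell_complex_fraction": 0.27,
        "occupancy": 0.99,
    },
    "Mn-alg": {"structural_x": 1.0, "associates": 2.09},
}

#: Preference set (registry key) whose X_T each sample's X is compared to.
#: Cu and Mn fill every cell, so their prediction is the full set (X_T = 1).
REFERENCE_PREFERENCE_SET: dict[str, str | None] = {
    "Ba-alg": "Ba",
    "Sr-alg": "Sr",
    "Sr-alg-washed": "Sr",
    "Ca-alg": "Ca",
    "Zn-alg": "Zn",
    "Cu-alg": None,
    "Ni-alg": "Ni",
    "Mn-alg": None,
}

#: Published block probabilities at mu = 1.56 (3 d.p.) and 1.5 (2 d.p.).
REFERENCE_BLOCK_TABLE = {
    1.56: {"GG": 0.153, "GM": 0.238, "MG": 0.238, "MM": 0.371},
    1.5: {"GG": 0.16, "GM": 0.24, "MG": 0.24, "MM": 0.36},
}

#: Published cell-class probabilities (4 d.p.) at both ratios.
REFERENCE_CELL_TABLE = {
    1.56: {
        "GG-GG": 0.0233,
        "GG-GM/GG-MG": 0.1453,
        "GG-MM": 0.1133,
        "GM-GM": 0.1133,
        "GM-MG": 0.1133,
        "MM-GM/MM-MG": 0.3536,
        "MM-MM": 0.1379,
    },
    1.5: {
        "GG-GG": 0.0256,
        "GG-GM/GG-MG": 0.1536,
        "GG-MM": 0.1152,
        "GM-GM": 0.1152,
        "GM-MG": 0.1152,
        "MM-GM/MM-MG": 0.3456,
        "MM-MM": 0.1296,
    },
}

#: Published theoretical occupancies at mu = 1.56 per preference set
#: (2 d.p.; GG_only printed as 2.3%).
REFERENCE_OCCUPANCY = {
    "Ba": 0.63,
    "Sr": 0.64,
    "Ca": 0.28,
    "Zn": 0.63,
    "Ni": 0.28,
    "GG_only": 0.023,
}


def reference_compositions() -> list[ElementalComposition]:
    """The eight study samples as validated compositions (raw, traces in)."""
    out = []
    for sid, rec in REFERENCE_ATOMIC_PERCENT.items():
        meta = {k: v for k, v in rec.items() if k != "entries"}
        meta["salt"] = REFERENCE_SALTS[sid]
        out.append(ElementalComposition(sid, rec["entries"], meta))
    return out
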