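"""Builder for the bundled synthetic transformation reference list.

The bundled list (``data/transformations_synthetic_1255.csv``) is a
synthetic stand-in for the supplementary reference lists used in
mass-difference transformation analysis of natural organic matter. It is
generated deterministically from named biochemical moieties (amino acid
residues, sugar residues, small organic losses, S- and P-moieties) and
their pairwise combinations ("net" transformations such as a combined
condensation and decarboxylation), truncated to exactly 1255 entries.

Masses are neutral monoisotopic masses computed from the element masses
in :mod:`riverchem.formulas`, with one deliberate exception: the
phosphate (HPO3) entry carries the conventional reported value
79.9662 Da rather than the recomputed monoisotopic 79.96633 Da, so the
list reproduces the worked-example anchors (alanine 71.0371, phosphate
79.9662) used to sanity-check transformation matching.
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from pathlib import Path

import pandas as pd

from .formulas import MolecularFormula

TARGET_SIZE = 1255

#: (name, composition) of the base biochemical moieties. Amino acids are
#: residues (amino acid minus water), sugars are glycosyl residues unless
#: named as the free compound.
BASE_MOIETIES: list[tuple[str, str]] = [
    ("hydrogenation", "H2"),
    ("water", "H2O"),
    ("methylene", "CH2"),
    ("oxygenation", "O"),
    ("carbonyl", "CO"),
    ("carbon dioxide", "CO2"),
    ("formaldehyde", "CH2O"),
    ("methanol", "CH4O"),
    ("acetyl", "C2H2O"),
    ("ethylene", "C2H4"),
    ("acetic acid", "C2H4O2"),
    ("glyoxal", "C2H2O2"),
    ("sulfur", "S"),
    ("hydrogen sulfide", "H2S"),
    ("sulfonation", "SO3"),
    ("phosphate", "HO3P"),
    ("glycerophosphate", "C3H9O6P"),
    ("phosphoethanolamine", "C2H8NO4P"),
    ("ammonia", "NH3"),
    ("imine", "NH"),
    ("urea", "CH4N2O"),
    ("glycine", "C2H3NO"),
    ("alanine", "C3H5NO"),
    ("serine", "C3H5NO2"),
    ("proline", "C5H7NO"),
    ("valine", "C5H9NO"),
    ("threonine", "C4H7NO2"),
    ("cysteine", "C3H5NOS"),
    ("leucine", "C6H11NO"),
    ("asparagine", "C4H6N2O2"),
    ("aspartate", "C4H5NO3"),
    ("glutamine", "C5H8N2O2"),
    ("lysine", "C6H12N2O"),
    ("glutamate", "C5H7NO3"),
    ("methionine", "C5H9NOS"),
    ("histidine", "C6H7N3O"),
    ("phenylalanine", "C9H9NO"),
    ("arginine", "C6H12N4O"),
    ("tyrosine", "C9H9NO2"),
    ("tryptophan", "C11H10N2O"),
    ("taurine", "C2H7NO3S"),
    ("acetone", "C3H6O"),
    ("propylene", "C3H6"),
    ("pyruvate", "C3H4O3"),
    ("lactate", "C3H6O3"),
    ("glycerol", "C3H8O3"),
    ("oxalate", "C2H2O4"),
    ("succinate", "C4H6O4"),
    ("fumarate", "C4H4O4"),
    ("malate", "C4H6O5"),
    ("citrate", "C6H8O7"),
    ("pentose", "C5H8O4"),
    ("deoxyhexose", "C6H10O4"),
    ("hexose", "C6H10O5"),
    ("glucose", "C6H12O6"),
    ("glucuronate", "C6H8O6"),
    ("benzoic acid", "C7H6O2"),
]

#: Verbatim mass overrides (Da) for entries whose conventional reported
#: value differs slightly from the recomputed monoisotopic mass.
MASS_OVERRIDES = {"phosphate": 79.9662}


def _base_entries() -> list[tuple[str, MolecularFormula, float]]:
    entries = []
    for name, comp in BASE_MOIETIES:
        formula = MolecularFormula.from_string(comp)
        mass = MASS_OVERRIDES.get(name, formula.mass)
        entries.append((name, formula, mass))
    return entries


def build_reference_list(target_size: int = TARGET_SIZE) -> pd.DataFrame:
    """Deterministically build the synthetic reference list.

    Singles come first (base-list order); pairwise combinations (with
    repetition, so e.g. a double methylation appears) follow in diagonal
    order by index sum, truncated to ``target_size`` rows.
    """
    base = _base_entries()
    rows = [(name, mass, formula.to_string()) for name, formula, mass in base]
    pairs = sorted(combinations_with_replacement(range(len(base)), 2),
                   key=lambda ij: (ij[0] + ij[1], ij[0]))
    for i, j in pairs:
        if len(rows) >= target_size:
            break
        name_i, f_i, m_i = base[i]
        name_j, f_j, m_j = base[j]
        rows.append((f"{name_i}+{name_j}", m_i + m_j, (f_i + f_j).to_string()))
    if len(rows) < target_size:
        raise ValueError(f"only {len(rows)} entries available; need {target_size}")
    out = pd.DataFrame(rows[:target_size], columns=["Name", "Mass", "Composition"])
    if out["Name"].duplicated().any():
        raise ValueError("duplicate names in generated reference list")
    return out


def write_reference_list(path: str | Path, target_size: int = TARGET_SIZE) -> None:
    """Write the synthetic list in the dialect :func:`riverchem.io.read_transformation_list` reads."""
    out = build_reference_list(target_size).copy()
    out["Mass"] = out["Mass"].map(lambda m: f"{m:.6f}")
    out.to_csv(path, index=False)
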