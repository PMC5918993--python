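"""Element lookup tables: atomic masses and van der Waals radii.

Radii follow the Bondi compilation (heavy-atom values), which is the
conventional choice for accessible-surface and gap-volume work; both tables
can be overridden per call site with ``masses=`` / ``radii=`` mappings keyed
by element symbol, with a secondary fallback keyed by atom name.
"""

from __future__ import annotations

from .errors import LookupError_

# Atomic masses in Da (unified atomic mass units).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "ZN": 65.38,
    "SE": 78.971,
}

# Bondi van der Waals radii in Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "MN": 2.05,
    "FE": 2.05,
    "ZN": 1.39,
    "SE": 1.90,
}


def _lookup(table: dict[str, float], element: str, atom_name: str,
            kind: str) -> float:
    """Look up by element symbol, falling back to the atom name's leading
    alphabetic characters (handles files with blank element columns)."""
    key = element.strip().upper()
    if key in table:
        return table[key]
    # fallback: derive from atom name, e.g. "CA" -> "C" for carbon names
    name = "".join(ch for ch in atom_name if ch.isalpha()).upper()
    for candidate in (name, name[:2], name[:1]):
        if candidate in table:
            return table[candidate]
    raise LookupError_(
        f"no {kind} for element {element!r} (atom name {atom_name!r}); "
        f"provide an override table"
    )


def mass_of(element: str, atom_name: str = "",
            overrides: dict[str, float] | None = None) -> float:
    table = dict(ATOMIC_MASSES)
    if overrides:
        table.update({k.upper(): v for k, v in overrides.items()})
    return _lookup(table, element, atom_name, "mass")


def radius_of(element: str, atom_name: str = "",
              overrides: dict[str, float] | None = None) -> float:
    table = dict(VDW_RADII)
    if overrides:
        table.update({k.upper(): v for k, v in overrides.items()})
    return _lookup(table, element, atom_name, "van der Waals radius")
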