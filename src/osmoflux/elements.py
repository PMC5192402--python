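"""Standard atomic weights and element inference for structure records."""

from __future__ import annotations

import warnings

#: Standard atomic weights, Da (IUPAC 2021 abridged values).
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "FE": 55.845,
    "ZN": 65.38,
    "SE": 78.971,
    "BR": 79.904,
    "I": 126.904,
}

#: Elements excluded from "heavy atom" selections.
HYDROGEN_LIKE = frozenset({"H", "D"})


def mass_of(element: str) -> float:
    """Atomic weight (Da) for an element symbol (case-insensitive)."""
    sym = element.strip().upper()
    try:
        return ATOMIC_WEIGHTS[sym]
    except KeyError:
        raise KeyError(f"unknown element symbol: {element!r}") from None


def is_heavy(element: str) -> bool:
    """True for any non-hydrogen (and non-deuterium) element."""
    return element.strip().upper() not in HYDROGEN_LIKE


def element_from_atom_name(atom_name: str) -> str:
    """Fall back to the first alphabetic character of a PDB atom name.

    This is a documented pitfall: a calcium ion named ``CA`` is
    indistinguishable from a C-alpha by name alone, so the fallback always
    warns and guesses the single-letter (organic) element.
    """
    letters = [c for c in atom_name.strip() if c.isalpha()]
    if not letters:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    guess = letters[0].upper()
    warnings.warn(
        f"element column empty; inferred {guess!r} from atom name "
        f"{atom_name!r} (CA could be calcium or C-alpha)",
        stacklevel=2,
    )
    return guess
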