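"""Derived transport summary table and size-vs-permeability comparison.

Recomputes, from the packaged membrane/compound constants, the derived
columns of the published transport-parameter overview: the predicted mass
flux at a 1 mg/L feed-side gradient and the rejection implied by each
compound's permeability under the reference water flux — rounded at the
precision the table prints (flux to the nearest integer µg·m⁻²·h⁻¹,
rejection to one decimal percent, ties away from zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import transport
from .io import load_registry, load_registry_raw
from .models import ConfigurationError, InputError
from .units import round_half_away

__all__ = [
    "Table1Row",
    "build_table1",
    "table1_dataframe",
    "check_table1",
    "summarize_size_vs_permeability",
]

#: Reference feed-side concentration difference for the flux column, mg/L.
REFERENCE_DELTA_C_MG_L = 1.0


@dataclass
class Table1Row:
    """One compound's measured constants and derived transport columns."""

    compound: str
    compound_class: str
    permeability: float
    molar_mass: float
    rg: float | None
    flux_ug_m2_h: float
    rejection_pct: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.flux_ug_m2_h) and np.isfinite(self.rejection_pct)):
            raise ValueError("flux and rejection must be finite")
        if self.rejection_pct > 100:
            raise ValueError("rejection cannot exceed 100%")


def build_table1(
    registry_path=None,
    delta_C_mg_L: float = REFERENCE_DELTA_C_MG_L,
) -> list[Table1Row]:
    """Compute the derived flux and rejection columns for every compound in
    the registry.

    flux = (P/l)·ΔC at ΔC = 1 mg/L, nearest integer µg·m⁻²·h⁻¹;
    rejection = (1 − P/(t·J_w))·100 at the registry water flux, one
    decimal.  Raises ConfigurationError naming the compound/field if a
    constant is missing.
    """
    membrane, compounds = load_registry(registry_path)
    raw = load_registry_raw(registry_path)
    classes = {e["name"]: e.get("class", "") for e in raw["compounds"]}
    if membrane.water_flux is None:
        raise ConfigurationError("registry membrane lacks water_flux_L_m2_h")
    rows = []
    for name, comp in compounds.items():
        if comp.permeability is None:
            raise ConfigurationError(
                f"compound {name!r} lacks permeability_m2_s in the registry"
            )
        flux = transport.predicted_flux(comp, membrane, delta_C_mg_L)
        rej = transport.rejection_from_permeability(comp, membrane)
        rows.append(
            Table1Row(
                compound=name,
                compound_class=classes.get(name, ""),
                permeability=comp.permeability,
                molar_mass=comp.molar_mass,
                rg=comp.radius_of_gyration,
                flux_ug_m2_h=round_half_away(flux, 0),
                rejection_pct=round_half_away(rej, 1),
            )
        )
    return rows


def table1_dataframe(rows: list[Table1Row] | None = None) -> pd.DataFrame:
    """The summary table as a DataFrame (one row per compound)."""
    if rows is None:
        rows = build_table1()
    return pd.DataFrame(
        {
            "compound": [r.compound for r in rows],
            "class": [r.compound_class for r in rows],
            "permeability_m2_s": [r.permeability for r in rows],
            "molar_mass_g_mol": [r.molar_mass for r in rows],
            "rg_A": [r.rg for r in rows],
            "flux_ug_m2_h": [r.flux_ug_m2_h for r in rows],
            "rejection_pct": [r.rejection_pct for r in rows],
        }
    )


def check_table1(registry_path=None) -> pd.DataFrame:
    """Compare the recomputed flux/rejection columns with the reference
    values stored alongside the constants.

    Returns a DataFrame with computed, reference and deviation columns;
    the reference columns are NaN when the registry carries none.
    """
    rows = build_table1(registry_path)
    raw = load_registry_raw(registry_path)
    ref_flux = {e["name"]: e.get("reported_flux_ug_m2_h") for e in raw["compounds"]}
    ref_rej = {e["name"]: e.get("reported_rejection_pct") for e in raw["compounds"]}
    df = table1_dataframe(rows)
    df["reference_flux_ug_m2_h"] = [ref_flux.get(c) for c in df["compound"]]
    df["reference_rejection_pct"] = [ref_rej.get(c) for c in df["compound"]]
    df["flux_deviation"] = df["flux_ug_m2_h"] - df["reference_flux_ug_m2_h"]
    df["rejection_deviation"] = df["rejection_pct"] - df["reference_rejection_pct"]
    return df


def summarize_size_vs_permeability(
    rows: list[Table1Row], x: str = "molar_mass"
) -> dict:
    """Pair a size descriptor with the permeability and rank-correlate.

    Parameters
    ----------
    rows : list of Table1Row
    x : {"molar_mass", "rg"}
        Which size descriptor to use on the x axis.

    Returns
    -------
    dict with keys ``pairs`` (DataFrame of compound, x, permeability),
    ``spearman_rho`` (float or None when undefined) and ``x`` (the
    descriptor name).  A constant descriptor makes the rank correlation
    undefined; that is flagged with a warning and ``spearman_rho=None``
    rather than silently returning NaN.
    """
    if x not in ("molar_mass", "rg"):
        raise InputError(f"x must be 'molar_mass' or 'rg', got {x!r}")
    usable = [r for r in rows if getattr(r, x) is not None]
    if len(usable) < 2:
        raise InputError(
            f"need >= 2 rows with {x} present, got {len(usable)}"
        )
    xs = np.array([getattr(r, x) for r in usable], dtype=float)
    ys = np.array([r.permeability for r in usable], dtype=float)
    pairs = pd.DataFrame(
        {"compound": [r.compound for r in usable], x: xs, "permeability": ys}
    )
    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        warnings.warn(
            "rank correlation undefined: a variable is constant over rows",
            stacklevel=2,
        )
        rho = None
    else:
        rho = float(stats.spearmanr(xs, ys).statistic)
    return {"x": x, "pairs": pairs, "spearman_rho": rho}
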