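"""Readers and writers for assay tables, constant registries and ensembles.

Assay CSV columns (header row, UTF-8): compound, feed_conc_initial_mg_L,
feed_conc_final_mg_L (optional), permeate_conc_mg_L, permeate_volume_mL,
duration_h, area_cm2, group (optional).  Values are converted to SI on load.

Structure formats: multi-model PDB (MODEL/ENDMDL delimited, via biotite)
and a minimal multi-frame XYZ (count line, comment line, then
``element x y z`` records, frames concatenated).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .elements import element_from_atom_name
from .models import AssayMeasurement, Compound, InputError, MembraneSpec
from .conformation import ConformerEnsemble
from .units import CM2_TO_M2, ML_TO_M3, S_PER_H, UM_TO_M

REQUIRED_ASSAY_COLUMNS = (
    "compound",
    "feed_conc_initial_mg_L",
    "permeate_conc_mg_L",
    "permeate_volume_mL",
    "duration_h",
    "area_cm2",
)


def read_assay_csv(
    path: str | Path, compounds: dict[str, Compound]
) -> list[AssayMeasurement]:
    """Load a diffusion-assay table, resolving compound names against a
    registry mapping name → Compound."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing assay columns {missing}")
    out = []
    for _, row in df.iterrows():
        name = str(row["compound"])
        if name not in compounds:
            raise InputError(f"{path}: unknown compound {name!r}")
        final = row.get("feed_conc_final_mg_L")
        group = row.get("group")
        out.append(
            AssayMeasurement(
                compound=compounds[name],
                feed_conc_initial=float(row["feed_conc_initial_mg_L"]),
                feed_conc_final=None if pd.isna(final) else float(final),
                permeate_conc=float(row["permeate_conc_mg_L"]),
                permeate_volume=float(row["permeate_volume_mL"]) * ML_TO_M3,
                duration=float(row["duration_h"]) * S_PER_H,
                area=float(row["area_cm2"]) * CM2_TO_M2,
                group=None if group is None or pd.isna(group) else str(group),
            )
        )
    return out


def write_assay_csv(path: str | Path, measurements: list[AssayMeasurement]) -> None:
    """Write measurements back to the assay CSV layout (non-SI columns)."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "compound": m.compound.name,
                "feed_conc_initial_mg_L": m.feed_conc_initial,
                "feed_conc_final_mg_L": m.feed_conc_final,
                "permeate_conc_mg_L": m.permeate_conc,
                "permeate_volume_mL": m.permeate_volume / ML_TO_M3,
                "duration_h": m.duration / S_PER_H,
                "area_cm2": m.area / CM2_TO_M2,
                "group": m.group if m.group is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Constant registry (membrane + compound table)

def load_registry(path: str | Path | None = None) -> tuple[MembraneSpec, dict[str, Compound]]:
    """Load membrane constants and the compound table from a JSON registry.

    With no path, the packaged registry of published membrane/compound
    constants is used (thickness 112 µm, area 0.785 cm², water flux
    9.71 L·m⁻²·h⁻¹ and the five reference compounds).
    """
    if path is None:
        text = (
            resources.files("osmoflux.data")
            .joinpath("table1_registry.json")
            .read_text()
        )
        raw = json.loads(text)
    else:
        raw = json.loads(Path(path).read_text())
    mem = raw["membrane"]
    membrane = MembraneSpec(
        thickness=mem["thickness_um"] * UM_TO_M,
        area=mem["area_cm2"] * CM2_TO_M2,
        water_flux=mem.get("water_flux_L_m2_h"),
        water_permeability_Lp=mem.get("water_permeability_L_m2_h_bar"),
        salt_permeability_B=mem.get("salt_permeability_L_m2_h"),
    )
    compounds: dict[str, Compound] = {}
    for entry in raw["compounds"]:
        c = Compound(
            name=entry["name"],
            molar_mass=entry["molar_mass_g_mol"],
            permeability=entry.get("permeability_m2_s"),
            permeability_ci95=entry.get("permeability_ci95_m2_s"),
            radius_of_gyration=entry.get("radius_of_gyration_A"),
            rg_sd=entry.get("rg_sd_A"),
        )
        compounds[c.name] = c
    return membrane, compounds


def load_registry_raw(path: str | Path | None = None) -> dict:
    """The registry JSON as a dict (includes compound class and any
    published reference columns used for cross-checking)."""
    if path is None:
        return json.loads(
            resources.files("osmoflux.data")
            .joinpath("table1_registry.json")
            .read_text()
        )
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Conformer ensembles

def read_pdb_ensemble(path: str | Path, label: str | None = None) -> ConformerEnsemble:
    """Read a multi-model PDB file into a ConformerEnsemble.

    Elements come from the PDB element column; empty element fields fall
    back (with a warning) to the first letter of the atom name.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    elements = []
    for el, name in zip(stack.element, stack.atom_name):
        el = str(el).strip()
        elements.append(el.upper() if el else element_from_atom_name(str(name)))
    return ConformerEnsemble(
        coords=np.asarray(stack.coord, dtype=float),
        elements=np.array(elements),
        label=label if label is not None else Path(path).stem,
    )


def write_pdb_ensemble(path: str | Path, ens: ConformerEnsemble) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL delimited)."""
    n_frames, n_atoms = ens.n_frames, ens.n_atoms
    atoms = struc.AtomArrayStack(n_frames, n_atoms)
    atoms.coord = np.asarray(ens.coords, dtype=np.float32)
    atoms.element = np.array([e.upper() for e in ens.elements])
    atoms.atom_name = np.array(
        [f"{e.capitalize()}{i + 1}" for i, e in enumerate(ens.elements)]
    )
    atoms.res_name = np.full(n_atoms, "UNK")
    atoms.res_id = np.ones(n_atoms, dtype=int)
    atoms.chain_id = np.full(n_atoms, "A")
    atoms.hetero = np.full(n_atoms, True)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_xyz_ensemble(path: str | Path, label: str | None = None) -> ConformerEnsemble:
    """Read a concatenated multi-frame XYZ file."""
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise InputError(f"{path}: bad XYZ count line {i + 1}: {lines[i]!r}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise InputError(f"{path}: truncated XYZ frame at line {i + 1}")
        frame_el, coords = [], np.empty((n, 3))
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise InputError(f"{path}: bad XYZ atom line: {ln!r}")
            frame_el.append(parts[0].upper())
            coords[j] = [float(p) for p in parts[1:4]]
        if elements is None:
            elements = frame_el
        elif frame_el != elements:
            raise InputError(f"{path}: element order differs between XYZ frames")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise InputError(f"{path}: no XYZ frames found")
    return ConformerEnsemble(
        coords=np.stack(frames),
        elements=np.array(elements),
        label=label if label is not None else Path(path).stem,
    )


def write_xyz_ensemble(path: str | Path, ens: ConformerEnsemble) -> None:
    """Write an ensemble as a concatenated multi-frame XYZ file."""
    out = []
    for f in range(ens.n_frames):
        out.append(str(ens.n_atoms))
        out.append(f"{ens.label or 'frame'} {f}")
        for el, (x, y, z) in zip(ens.elements, ens.coords[f]):
            out.append(f"{el.capitalize()} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(out) + "\n")
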