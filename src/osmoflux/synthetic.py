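"""Synthetic inputs for the whole pipeline, at desk scale.

Two generators:

* a diffusion-cell assay simulator with a known ground-truth permeability —
  the forward model is the same flux law the fitting inverts, plus
  multiplicative (lognormal) measurement noise on the permeate
  concentration, mimicking proportional HPLC quantification error;
* coarse-grained chain conformer generators (straight rod, freely-jointed,
  fixed-bond-angle) whose radius-of-gyration statistics are analytically
  checkable in limiting geometries.  The chains are point-mass geometry
  fixtures, not physical peptide models.

All randomness flows from the explicit seed in each config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conformation import ConformerEnsemble
from .models import AssayMeasurement, Compound, InputError, MembraneSpec
from .units import ML_TO_M3, S_PER_H

__all__ = [
    "AssaySimConfig",
    "AssaySimResult",
    "ChainSimConfig",
    "simulate_assay",
    "simulate_chain",
    "write_fixtures",
]

#: Default feed levels of the diffusion assay, mg/L.
DEFAULT_FEED_LEVELS = (1.0, 5.0, 10.0)


@dataclass
class AssaySimConfig:
    """Configuration of one simulated diffusion-cell campaign.

    Defaults reproduce the bench protocol: feed levels 1/5/10 mg/L in
    triplicate, a 5 h run, a 0.5 mL static permeate chamber over a
    0.785 cm² membrane coupon, and a 100 mL recirculated feed.
    """

    true_permeability: float
    membrane: MembraneSpec
    compound: Compound = field(
        default_factory=lambda: Compound(name="peptide", molar_mass=692.0)
    )
    feed_levels: tuple[float, ...] = DEFAULT_FEED_LEVELS
    replicates: int = 3
    duration: float = 5 * S_PER_H
    permeate_volume: float = 0.5 * ML_TO_M3
    feed_volume: float = 100 * ML_TO_M3
    noise_cv: float = 0.0
    noise_model: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_permeability < 0:
            raise InputError("true_permeability must be >= 0")
        if self.noise_cv < 0:
            raise InputError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise InputError(
                f"noise_model must be 'lognormal' or 'gaussian', "
                f"got {self.noise_model!r}"
            )


@dataclass
class AssaySimResult:
    """Simulated measurements plus the saved ground truth."""

    measurements: list[AssayMeasurement]
    config: AssaySimConfig
    true_permeate_conc: list[float]

    @property
    def true_permeability(self) -> float:
        return self.config.true_permeability


def _noiseless_permeate_conc(cfg: AssaySimConfig, feed_mg_L: float) -> float:
    """Permeate concentration (mg/L) accumulated over the run at a given
    feed level, from the flux law J = (P/l)·ΔC.

    Mass flux in g·m⁻²·s⁻¹ times area and duration gives collected grams;
    dividing by the chamber volume gives g/m³ = mg/L.  Feed depletion is
    ignored (well under 1% of the feed amount transfers).
    """
    j_mass = cfg.true_permeability / cfg.membrane.thickness * feed_mg_L
    mass_g = j_mass * cfg.membrane.area * cfg.duration
    return mass_g / cfg.permeate_volume


def simulate_assay(cfg: AssaySimConfig) -> AssaySimResult:
    """Simulate a diffusion-assay campaign with known permeability.

    For each feed level and replicate, the true permeate concentration
    follows the flux law; measurement noise is applied multiplicatively
    (lognormal, unit mean, coefficient of variation ``noise_cv``) or
    additively (gaussian with sd = cv × truth) depending on
    ``noise_model``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    measurements, truths = [], []
    if cfg.noise_model == "lognormal" and cfg.noise_cv > 0:
        sigma2 = np.log1p(cfg.noise_cv**2)
        sigma = np.sqrt(sigma2)
    for level in cfg.feed_levels:
        c_true = _noiseless_permeate_conc(cfg, level)
        for _ in range(cfg.replicates):
            c_obs = c_true
            if cfg.noise_cv > 0:
                if cfg.noise_model == "lognormal":
                    # unit-mean lognormal multiplier
                    c_obs = c_true * rng.lognormal(-sigma2 / 2, sigma)
                else:
                    c_obs = max(
                        c_true + rng.normal(0.0, cfg.noise_cv * c_true), 0.0
                    )
            measurements.append(
                AssayMeasurement(
                    compound=cfg.compound,
                    feed_conc_initial=level,
                    permeate_conc=c_obs,
                    permeate_volume=cfg.permeate_volume,
                    duration=cfg.duration,
                    area=cfg.membrane.area,
                )
            )
            truths.append(c_true)
    return AssaySimResult(
        measurements=measurements, config=cfg, true_permeate_conc=truths
    )


@dataclass
class ChainSimConfig:
    """Configuration of a coarse-grained chain conformer generator."""

    n_beads: int
    bond_length: float = 1.5
    model: str = "freely_jointed"
    bead_masses: tuple[float, ...] | None = None
    bond_angle_deg: float = 109.47
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise InputError("n_beads must be >= 1")
        if self.bond_length <= 0:
            raise InputError("bond_length must be > 0")
        if self.model not in ("freely_jointed", "fixed_angle", "straight"):
            raise InputError(f"unknown chain model {self.model!r}")
        if self.bead_masses is not None and len(self.bead_masses) != self.n_beads:
            raise InputError("bead_masses length must equal n_beads")


def simulate_chain(cfg: ChainSimConfig) -> ConformerEnsemble:
    """Generate independent chain conformers.

    * ``straight``: collinear beads along x (deterministic); the discrete
      rod with N equal masses at spacing b has Rg = b·sqrt((N²−1)/12).
    * ``freely_jointed``: successive bonds are i.i.d. uniform unit vectors.
    * ``fixed_angle``: fixed bond angle, uniform torsions.

    Beads are emitted as carbon atoms unless ``bead_masses`` overrides the
    per-bead masses.
    """
    rng = np.random.default_rng(cfg.seed)
    n, b = cfg.n_beads, cfg.bond_length
    coords = np.zeros((cfg.n_frames, n, 3))
    if cfg.model == "straight":
        coords[:, :, 0] = np.arange(n) * b
    elif cfg.model == "freely_jointed":
        for f in range(cfg.n_frames):
            bonds = _uniform_unit_vectors(rng, n - 1) * b
            coords[f, 1:] = np.cumsum(bonds, axis=0)
    else:  # fixed_angle
        theta = np.deg2rad(cfg.bond_angle_deg)
        for f in range(cfg.n_frames):
            coords[f] = _fixed_angle_chain(rng, n, b, theta)
    elements = np.array(["C"] * n)
    masses = (
        np.asarray(cfg.bead_masses, dtype=float)
        if cfg.bead_masses is not None
        else None
    )
    return ConformerEnsemble(
        coords=coords,
        elements=elements,
        masses=masses,
        label=f"{cfg.model}_chain_{n}",
    )


def _uniform_unit_vectors(rng: np.random.Generator, k: int) -> np.ndarray:
    """k i.i.d. directions uniform on the unit sphere."""
    if k == 0:
        return np.zeros((0, 3))
    v = rng.normal(size=(k, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _fixed_angle_chain(
    rng: np.random.Generator, n: int, b: float, theta: float
) -> np.ndarray:
    """Chain with fixed bond angle theta (between successive bonds'
    supplement convention: angle between bond vectors is pi - theta for a
    tetrahedral chain; here theta is the geometric angle between successive
    bond directions) and uniform torsions."""
    coords = np.zeros((n, 3))
    if n == 1:
        return coords
    prev = np.array([1.0, 0.0, 0.0])
    coords[1] = coords[0] + b * prev
    for i in range(2, n):
        # orthonormal frame around the previous bond direction
        ref = np.array([0.0, 0.0, 1.0])
        if abs(prev @ ref) > 0.99:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(prev, ref)
        u /= np.linalg.norm(u)
        v = np.cross(prev, u)
        phi = rng.uniform(0.0, 2 * np.pi)
        new = (
            np.cos(theta) * prev
            + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v)
        )
        coords[i] = coords[i - 1] + b * new
        prev = new
    return coords


def write_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Emit a self-consistent desk-scale fixture set.

    Writes an assay CSV simulated at the published peptide permeability,
    the membrane/compound constant registry, and two small chain conformer
    ensembles (one straight rod, one freely-jointed) as multi-model PDB.
    Byte-stable for a fixed seed.
    """
    from . import io as ofio  # local import to avoid a cycle at import time
    from importlib import resources

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {outdir}: {exc}") from exc

    membrane, compounds = ofio.load_registry()
    peptide = compounds["GGG SGA GKT"]
    cfg = AssaySimConfig(
        true_permeability=peptide.permeability,
        membrane=membrane,
        compound=peptide,
        noise_cv=0.05,
        seed=seed,
    )
    sim = simulate_assay(cfg)
    paths = {
        "assay_csv": outdir / "assay.csv",
        "registry_json": outdir / "registry.json",
        "rod_pdb": outdir / "rod_chain.pdb",
        "fjc_pdb": outdir / "fjc_chain.pdb",
    }
    ofio.write_assay_csv(paths["assay_csv"], sim.measurements)
    registry_text = (
        resources.files("osmoflux.data").joinpath("table1_registry.json").read_text()
    )
    paths["registry_json"].write_text(registry_text)
    rod = simulate_chain(
        ChainSimConfig(n_beads=8, bond_length=1.5, model="straight", n_frames=3)
    )
    fjc = simulate_chain(
        ChainSimConfig(
            n_beads=8, bond_length=1.5, model="freely_jointed", n_frames=20,
            seed=seed,
        )
    )
    ofio.write_pdb_ensemble(paths["rod_pdb"], rod)
    ofio.write_pdb_ensemble(paths["fjc_pdb"], fjc)
    return paths
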