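"""Domain types for the diffusion-cell transport analysis.

The dataclasses here are deliberately plain: they validate their physical
invariants on construction and otherwise behave as records.  All fields are
SI unless the name says otherwise (concentrations are mg/L == g/m³).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """A required constant (membrane or compound property) is missing."""


class InputError(ValueError):
    """A measurement or argument violates a physical precondition."""


class EnsembleError(ValueError):
    """A conformer ensemble violates structural integrity (frame shape,
    atom ordering, NaN coordinates)."""


@dataclass
class Compound:
    """A solute: a peptide or small organic molecule crossing the membrane.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"AGKT"``.
    molar_mass : float
        Molar mass in g/mol; must be positive.
    permeability : float, optional
        Solution-diffusion permeability coefficient P in m²/s.
    permeability_ci95 : float, optional
        Half-width of the 95% confidence interval on P, m²/s.
    radius_of_gyration : float, optional
        Ensemble-mean radius of gyration in Å.
    rg_sd : float, optional
        Standard deviation of the per-frame radius of gyration, Å.
    """

    name: str
    molar_mass: float
    permeability: float | None = None
    permeability_ci95: float | None = None
    radius_of_gyration: float | None = None
    rg_sd: float | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise InputError(
                f"Compound {self.name!r}: molar_mass must be > 0, "
                f"got {self.molar_mass}"
            )
        if self.permeability is not None and self.permeability < 0:
            raise InputError(
                f"Compound {self.name!r}: permeability must be >= 0, "
                f"got {self.permeability}"
            )


@dataclass
class MembraneSpec:
    """Membrane constants for one flat-sheet coupon.

    thickness and area are required (m and m²); the transport coefficients
    are optional because not every operation needs all of them.

    Notes
    -----
    The dense-layer thickness plays the same role in the flux law
    (J = P/l · ΔC) and in the rejection formula R = (1 − P/(t·Jw))·100;
    both use this single ``thickness`` field.
    """

    thickness: float
    area: float
    water_flux: float | None = None  # L·m⁻²·h⁻¹
    water_permeability_Lp: float | None = None  # L·m⁻²·h⁻¹·bar⁻¹
    salt_permeability_B: float | None = None  # L·m⁻²·h⁻¹

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InputError(f"thickness must be > 0 m, got {self.thickness}")
        if self.area <= 0:
            raise InputError(f"area must be > 0 m², got {self.area}")


@dataclass
class AssayMeasurement:
    """One diffusion-cell run: a feed reservoir recirculated against a small
    static permeate chamber for a fixed duration, after which the permeate
    concentration is measured.

    Concentrations are mg/L; permeate_volume is m³; duration is s; area m².
    ``feed_conc_final`` defaults to the initial feed concentration (the
    permeate chamber is ~0.5 mL against a ~100 mL feed, so depletion is
    negligible).
    """

    compound: Compound
    feed_conc_initial: float
    permeate_conc: float
    permeate_volume: float
    duration: float
    area: float
    feed_conc_final: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.feed_conc_final is None:
            self.feed_conc_final = self.feed_conc_initial
        for label, value in (
            ("feed_conc_initial", self.feed_conc_initial),
            ("feed_conc_final", self.feed_conc_final),
            ("permeate_conc", self.permeate_conc),
        ):
            if value < 0:
                raise InputError(f"{label} must be >= 0 mg/L, got {value}")
        if self.duration <= 0:
            raise InputError(f"duration must be > 0 s, got {self.duration}")
        if self.permeate_volume <= 0:
            raise InputError(
                f"permeate_volume must be > 0 m³, got {self.permeate_volume}"
            )
        if self.area <= 0:
            raise InputError(f"area must be > 0 m², got {self.area}")

    @property
    def mean_feed_conc(self) -> float:
        """Time-averaged feed concentration (c₀ + c_end)/2, mg/L."""
        return 0.5 * (self.feed_conc_initial + self.feed_conc_final)


@dataclass
class FluxPoint:
    """One point of the flux-vs-gradient line: molar concentration
    difference across the membrane (mol/m³) and molar solute flux
    (mol·m⁻²·s⁻¹)."""

    delta_C: float
    solute_flux: float

    def __post_init__(self) -> None:
        if self.delta_C < 0:
            raise InputError(f"delta_C must be >= 0 mol/m³, got {self.delta_C}")
        if not (math.isfinite(self.delta_C) and math.isfinite(self.solute_flux)):
            raise InputError("FluxPoint values must be finite")


@dataclass
class PermeabilityFit:
    """Result of the flux-vs-ΔC regression.

    slope is P/l in m/s; permeability = slope × membrane thickness, m²/s;
    the confidence bounds are on the permeability.
    """

    slope: float
    permeability: float
    ci95_low: float
    ci95_high: float
    r_squared: float
    n_points: int
    through_origin: bool
    n_groups: int | None = None

    def __post_init__(self) -> None:
        if not (self.ci95_low <= self.permeability <= self.ci95_high):
            raise ValueError(
                "confidence interval must bracket the permeability: "
                f"[{self.ci95_low}, {self.ci95_high}] vs {self.permeability}"
            )
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass
class RgResult:
    """Per-frame radii of gyration of a conformer ensemble with their mean
    and sample standard deviation (Å)."""

    per_frame_rg: list[float]
    mean: float
    sd: float
    heavy_only: bool

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.per_frame_rg):
            raise ValueError("radii of gyration must be non-negative")
        if self.per_frame_rg and not (
            min(self.per_frame_rg) - 1e-12
            <= self.mean
            <= max(self.per_frame_rg) + 1e-12
        ):
            raise ValueError("mean Rg outside the per-frame range")


@dataclass
class ClusterResult:
    """Flat clustering of ensemble frames.

    assignments maps frame index → cluster id (1-based, scipy convention);
    representatives maps cluster id → medoid frame index.
    """

    assignments: dict[int, int]
    linkage: str
    cutoff: float
    representatives: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))
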