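"""Solution-diffusion transport model for a dense forward-osmosis membrane.

The model treats the selective layer as a solid barrier: solutes sorb into
it, diffuse across, and desorb, so at steady state the solute flux is

    J_p = (P / l) · ΔC

with P [m²/s] the permeability coefficient, l [m] the layer thickness and
ΔC [mol/m³] the concentration difference across the membrane.  P factors as
P = D·S into a diffusion and a (dimensionless) sorption coefficient.  The
permeability is determined experimentally as the slope of J_p vs ΔC in a
diffusion cell with the osmotic gradient removed, and the rejection a
compound would see under operating water flux J_w follows from

    R = (1 − P / (t · J_w)) · 100 %

which assumes the trans-membrane concentration difference is well
approximated by the feed concentration (valid for R > 95%).
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import (
    AssayMeasurement,
    Compound,
    ConfigurationError,
    FluxPoint,
    InputError,
    MembraneSpec,
    PermeabilityFit,
)
from .units import (
    mass_flux_to_ug_m2_h,
    mg_per_L_to_mol_per_m3,
    water_flux_to_m_per_s,
)

__all__ = [
    "water_flux",
    "salt_flux",
    "observed_rejection",
    "solute_flux_from_assay",
    "PermeabilityRegressor",
    "fit_permeability",
    "predicted_flux",
    "rejection_from_permeability",
    "decompose_permeability",
]


def water_flux(membrane: MembraneSpec, delta_pi: float) -> float:
    """Osmotically driven water flux J_w = L_p · Δπ, in L·m⁻²·h⁻¹.

    Parameters
    ----------
    membrane : MembraneSpec
        Must carry ``water_permeability_Lp`` (L·m⁻²·h⁻¹·bar⁻¹).
    delta_pi : float
        Osmotic pressure difference between draw and feed, bar (≥ 0).
    """
    if membrane.water_permeability_Lp is None:
        raise ConfigurationError(
            "MembraneSpec.water_permeability_Lp is required for water_flux"
        )
    if delta_pi < 0:
        raise InputError(f"delta_pi must be >= 0 bar, got {delta_pi}")
    return membrane.water_permeability_Lp * delta_pi


def salt_flux(membrane: MembraneSpec, delta_C_salt: float) -> float:
    """Reverse salt flux J_s = −B · ΔC, in g·m⁻²·h⁻¹.

    The negative sign encodes the draw→feed direction of salt leakage.
    """
    if membrane.salt_permeability_B is None:
        raise ConfigurationError(
            "MembraneSpec.salt_permeability_B is required for salt_flux"
        )
    return -membrane.salt_permeability_B * delta_C_salt


def observed_rejection(m: AssayMeasurement) -> float:
    """Observed rejection R = (1 − c_p / c̄_f) · 100 %.

    c̄_f is the feed concentration averaged over the run, (c₀ + c_end)/2.
    A permeate concentration above the mean feed yields a negative
    rejection; that is physically a contaminated or mislabelled sample, so
    it is reported with a warning rather than clipped or raised.
    """
    cf = m.mean_feed_conc
    if cf <= 0:
        raise InputError(
            "observed_rejection undefined: mean feed concentration is zero"
        )
    r = (1.0 - m.permeate_conc / cf) * 100.0
    if r < 0:
        warnings.warn(
            f"negative rejection ({r:.2f}%): permeate concentration "
            f"{m.permeate_conc} mg/L exceeds mean feed {cf} mg/L",
            stacklevel=2,
        )
    return r


def solute_flux_from_assay(
    m: AssayMeasurement, strict_gradient: bool = False
) -> FluxPoint:
    """Convert one diffusion-cell measurement to a (ΔC, J_p) point.

    The permeate chamber accumulates solute for the whole run, so the molar
    flux is the collected amount divided by area and time:

        J_p = (c_p · V_permeate / M_w) / (A · Δt)   [mol·m⁻²·s⁻¹]

    ΔC defaults to the mean feed concentration in mol/m³: the permeate
    stays below a few percent of the feed, so the feed side dominates the
    gradient.  With ``strict_gradient=True`` the permeate concentration is
    subtracted.
    """
    mw = m.compound.molar_mass
    # c_p [g/m³] × V [m³] = g collected; / M_w [g/mol] = mol
    amount_mol = (m.permeate_conc * m.permeate_volume) / mw
    flux = amount_mol / (m.area * m.duration)
    delta_c = mg_per_L_to_mol_per_m3(m.mean_feed_conc, mw)
    if strict_gradient:
        delta_c -= mg_per_L_to_mol_per_m3(m.permeate_conc, mw)
        delta_c = max(delta_c, 0.0)
    return FluxPoint(delta_C=delta_c, solute_flux=flux)


class PermeabilityRegressor(RegressorMixin, BaseEstimator):
    """Least-squares estimator of the solute permeability coefficient.

    Fits solute flux [mol·m⁻²·s⁻¹] against trans-membrane concentration
    difference [mol/m³].  The slope is P/l [m/s]; multiplying by the
    membrane thickness gives the permeability P [m²/s] with a Student-t
    95% confidence interval from the slope's standard error.

    Parameters
    ----------
    thickness : float
        Dense-layer thickness l in m.
    through_origin : bool, default True
        The flux law forces J_p = 0 at ΔC = 0, so the default regression
        has no intercept.  Set False for a free-intercept diagnostic fit.
    aggregate_levels : bool, default False
        Average replicate fluxes at identical ΔC before fitting
        (mean-per-level mode).
    variance : {"proportional", "constant"}, default "proportional"
        Error model of the flux points.  HPLC quantification error is
        proportional to concentration, so the flux variance scales with
        the signal; "proportional" therefore fits weighted least squares
        with weights 1/ΔC² (for a through-origin fit this is the mean of
        the per-point flux/ΔC ratios).  "constant" is plain OLS for
        homoscedastic diagnostics.

    Attributes
    ----------
    slope_ : float
        Fitted P/l in m/s.
    permeability_ : float
        P = slope × thickness, m²/s.
    ci95_ : tuple of float
        95% confidence bounds on the permeability.
    r_squared_ : float
        Coefficient of determination (uncentered when through_origin).
    intercept_ : float
        Fitted intercept (0 when through_origin).
    n_points_ : int
        Number of points used in the fit.

    Examples
    --------
    >>> import numpy as np
    >>> reg = PermeabilityRegressor(thickness=112e-6)
    >>> dC = np.array([1.0, 5.0, 10.0])
    >>> flux = 1e-12 / 112e-6 * dC
    >>> float(reg.fit(dC[:, None], flux).permeability_)
    1e-12
    """

    def __init__(
        self,
        thickness: float = 112e-6,
        through_origin: bool = True,
        aggregate_levels: bool = False,
        variance: str = "proportional",
    ):
        self.thickness = thickness
        self.through_origin = through_origin
        self.aggregate_levels = aggregate_levels
        self.variance = variance

    def fit(self, X, y, groups: Sequence | None = None):
        """Fit the flux line.

        Parameters
        ----------
        X : array-like of shape (n, 1) or (n,)
            Concentration differences, mol/m³.
        y : array-like of shape (n,)
            Solute fluxes, mol·m⁻²·s⁻¹.
        groups : sequence, optional
            Membrane-coupon labels.  When given, a slope is fitted per
            coupon and the confidence interval is computed across coupon
            permeabilities, reflecting membrane heterogeneity rather than
            within-coupon scatter.
        """
        if self.thickness <= 0:
            raise ConfigurationError(
                f"thickness must be > 0 m, got {self.thickness}"
            )
        if self.variance not in ("proportional", "constant"):
            raise ConfigurationError(
                f"variance must be 'proportional' or 'constant', "
                f"got {self.variance!r}"
            )
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise InputError("X must have a single ΔC column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise InputError("X and y must have matching lengths")
        if groups is not None:
            groups = np.asarray(groups)
            if groups.shape[0] != X.shape[0]:
                raise InputError("groups must match X in length")

        if self.aggregate_levels:
            if groups is not None:
                raise InputError(
                    "aggregate_levels and groups cannot be combined"
                )
            levels = np.unique(X)
            y = np.array([y[X == lv].mean() for lv in levels])
            X = levels

        n_distinct = np.unique(X).size
        needed = 1 if self.through_origin else 2
        if n_distinct < needed:
            raise InputError(
                f"need >= {needed} distinct ΔC values "
                f"({'through-origin' if self.through_origin else 'free-intercept'} fit), "
                f"got {n_distinct}"
            )

        slope, intercept, se, rsq, dof = self._ols(X, y)
        self.slope_ = slope
        self.intercept_ = intercept
        self.r_squared_ = rsq
        self.n_points_ = int(X.size)
        self.permeability_ = slope * self.thickness
        self.n_groups_ = None

        if groups is not None and np.unique(groups).size >= 2:
            # CI over per-coupon permeabilities (membrane heterogeneity)
            per_group_p = []
            for g in np.unique(groups):
                gs, *_ = self._ols(X[groups == g], y[groups == g])
                per_group_p.append(gs * self.thickness)
            per_group_p = np.asarray(per_group_p)
            k = per_group_p.size
            self.n_groups_ = int(k)
            centre = per_group_p.mean()
            half = stats.t.ppf(0.975, k - 1) * per_group_p.std(ddof=1) / np.sqrt(k)
            self.permeability_ = float(centre)
            self.ci95_ = (float(centre - half), float(centre + half))
        else:
            if dof > 0 and np.isfinite(se):
                half = stats.t.ppf(0.975, dof) * se * self.thickness
            else:
                half = np.inf  # saturated fit: no residual information
            self.ci95_ = (
                float(self.permeability_ - half),
                float(self.permeability_ + half),
            )
        return self

    def _ols(self, x: np.ndarray, y: np.ndarray):
        if self.through_origin:
            design = x[:, None]
        else:
            design = sm.add_constant(x)
        if self.variance == "proportional":
            if np.any(x <= 0):
                raise InputError(
                    "proportional variance weighting needs all ΔC > 0; "
                    "use variance='constant' for data with zero gradients"
                )
            model = sm.WLS(y, design, weights=1.0 / x**2)
        else:
            model = sm.OLS(y, design)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = model.fit()
            slope = float(res.params[-1])
            intercept = 0.0 if self.through_origin else float(res.params[0])
            se = float(res.bse[-1])
            rsq = float(res.rsquared)
        if not np.isfinite(rsq):
            # saturated fit (zero residual dof): judge by the residual itself
            fitted = design @ res.params
            rsq = 1.0 if np.allclose(fitted, y, rtol=1e-12, atol=0.0) else 0.0
        return slope, intercept, se, np.clip(rsq, 0.0, 1.0), int(res.df_resid)

    def predict(self, X):
        """Predicted molar flux at the given ΔC values."""
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.slope_ * X + self.intercept_

    def to_fit(self) -> PermeabilityFit:
        """Package the fitted attributes as a PermeabilityFit record."""
        check_is_fitted(self, "slope_")
        return PermeabilityFit(
            slope=float(self.slope_),
            permeability=float(self.permeability_),
            ci95_low=self.ci95_[0],
            ci95_high=self.ci95_[1],
            r_squared=float(self.r_squared_),
            n_points=self.n_points_,
            through_origin=self.through_origin,
            n_groups=self.n_groups_,
        )


def fit_permeability(
    points: Sequence[FluxPoint],
    membrane: MembraneSpec,
    through_origin: bool = True,
    aggregate_levels: bool = False,
    variance: str = "proportional",
    groups: Sequence | None = None,
) -> PermeabilityFit:
    """Determine the permeability coefficient from flux-vs-ΔC points.

    Thin wrapper around :class:`PermeabilityRegressor`; see its docstring
    for the statistical details.
    """
    if not points:
        raise InputError("no flux points supplied")
    x = np.array([p.delta_C for p in points])
    y = np.array([p.solute_flux for p in points])
    reg = PermeabilityRegressor(
        thickness=membrane.thickness,
        through_origin=through_origin,
        aggregate_levels=aggregate_levels,
        variance=variance,
    )
    reg.fit(x[:, None], y, groups=groups)
    return reg.to_fit()


def predicted_flux(
    compound: Compound, membrane: MembraneSpec, delta_C_mass: float
) -> float:
    """Predicted mass flux (P/l)·ΔC at a mass concentration difference.

    delta_C_mass is in mg/L (= g/m³), so the result (µg·m⁻²·h⁻¹) does not
    depend on the molar mass: the conversion into and out of molar units
    cancels.
    """
    if compound.permeability is None:
        raise ConfigurationError(
            f"Compound {compound.name!r} has no permeability set"
        )
    j_g_m2_s = compound.permeability / membrane.thickness * delta_C_mass
    return mass_flux_to_ug_m2_h(j_g_m2_s)


def rejection_from_permeability(
    compound: Compound, membrane: MembraneSpec
) -> float:
    """Rejection predicted from the permeability, R = (1 − P/(t·J_w))·100 %.

    J_w is the operating water flux (MembraneSpec.water_flux, L·m⁻²·h⁻¹),
    converted internally to m/s.  The formula assumes the concentration
    difference across the membrane equals the feed concentration, a good
    approximation when rejection is high (> 95%).
    """
    if compound.permeability is None:
        raise ConfigurationError(
            f"Compound {compound.name!r} has no permeability set"
        )
    if membrane.water_flux is None:
        raise ConfigurationError(
            "MembraneSpec.water_flux is required for rejection_from_permeability"
        )
    jw = water_flux_to_m_per_s(membrane.water_flux)
    if jw <= 0:
        raise InputError(
            "rejection from permeability requires a positive water flux: "
            "the formula normalises solute transport by convective water "
            "transport and is undefined at J_w = 0"
        )
    return (1.0 - compound.permeability / (membrane.thickness * jw)) * 100.0


def decompose_permeability(P: float, D: float) -> float:
    """Sorption coefficient S = P / D from the factorisation P = D·S.

    D is the diffusion coefficient of the solute inside the membrane
    matrix (m²/s); S is dimensionless.
    """
    if D <= 0:
        raise InputError(f"diffusion coefficient must be > 0, got {D}")
    if P < 0:
        raise InputError(f"permeability must be >= 0, got {P}")
    return P / D
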