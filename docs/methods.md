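# Methods

## Transport model and its assumptions

The package models solute passage through a dense selective layer with the
solution-diffusion picture: solutes partition into the polymer, diffuse
down their concentration gradient, and desorb. The working equations are
the linear flux law `J_p = (P/l)·ΔC`, the factorisation `P = D·S`, the
concentration-based rejection `R = (1 − c_p/c̄_f)·100` with
`c̄_f = (c₀ + c_end)/2`, and the permeability-based rejection
`R = (1 − P/(t·J_w))·100`. Assumptions worth keeping in mind:

- **Steady state.** The diffusion-cell assay yields a time-averaged flux
  over the run; it is treated as the steady-state flux. The bench protocol
  pre-saturates the cell (5 h or overnight) precisely so that start-up
  adsorption to walls and membrane is spent before the measured window.
- **One thickness.** The flux law's `l` and the rejection formula's `t`
  are the same physical quantity, the dense-layer thickness; the package
  keeps a single `MembraneSpec.thickness`.
- **Feed-side-dominated gradient.** In the assay the permeate stays a few
  percent of the feed at most, so `ΔC` defaults to the mean feed
  concentration in molar units; a `strict_gradient` flag subtracts the
  permeate term for users who want it.
- **High-rejection approximation.** The permeability-based rejection
  assumes the trans-membrane concentration difference equals the feed
  concentration, good for R > 95%; it is *not* a replacement for the
  concentration-based rejection at low-rejection conditions.
- **No concentration polarisation, no pore flow.** Hydrodynamic
  sieve models and boundary-layer corrections are out of scope by design;
  the dense layer under study transports by diffusion.

Mass-flux predictions use mass concentration (mg/L = g/m³) so the molar
mass cancels: `predicted_flux` returns `(P/l)·ΔC` in µg·m⁻²·h⁻¹ regardless
of `M_w`. Water flux converts as 1 L·m⁻²·h⁻¹ = 10⁻³/3600 m·s⁻¹.

## Permeability regression and its error model

`PermeabilityRegressor` fits molar flux against molar concentration
difference. Defaults, and why:

- **Through the origin** (`through_origin=True`): the flux law forces
  `J_p = 0` at `ΔC = 0`. A free-intercept mode exists as a diagnostic for
  offsets (carry-over contamination, baseline drift).
- **Proportional variance** (`variance="proportional"`): HPLC
  quantification error scales with concentration, so flux noise scales
  with the signal. The fit is therefore weighted least squares with
  weights `1/ΔC²` — for a through-origin fit this is exactly the mean of
  the per-point `J_p/ΔC` ratios — and the 95% confidence interval is
  Student-t on the weighted slope. A homoscedastic OLS mode
  (`variance="constant"`) is kept for diagnostics; its slope is nearly
  identical but its interval is anti-conservative under proportional
  noise (simulated coverage ≈ 78% instead of ≈ 96% at 5% CV).
- **Per-replicate points** by default; `aggregate_levels=True` averages
  replicates per concentration level first (both give the same slope for
  balanced designs; the per-replicate fit keeps the replicate scatter in
  the interval).
- **Coupon grouping**: permeability varies between pieces cut from one
  membrane sheet. When measurements carry a `group` label, a slope is
  fitted per coupon and the interval is the t-interval across coupon
  permeabilities — a between-coupon heterogeneity measure, not a
  within-fit residual one.
- **Degenerate fits**: a single through-origin point determines the slope
  but carries no residual information; the interval is reported as
  infinite rather than invented. Identical `ΔC` values without the origin
  constraint raise a rank-deficiency error.

R² is the standard (uncentered, for through-origin) coefficient of
determination of the weighted fit, clipped to [0, 1].

## Rejection conventions

Observed rejections can come out negative when the permeate concentration
exceeds the mean feed — physically a contaminated sample. These are
reported with a warning, not clipped or raised, so QC sees them.
Printed-table rounding uses round-half-away-from-zero: flux to the nearest
integer µg·m⁻²·h⁻¹, rejection to one decimal percent.

## Radius of gyration and clustering

`Rg` and the centre of mass are mass-weighted over the *selected* atoms;
the default selection is heavy atoms (element ≠ H/D), and the total mass
`M` is taken over the same selection. Atomic masses come from a packaged
standard-atomic-weight table; elements are read from the PDB element
column, falling back to the first letter of the atom name with a warning
(the classic pitfall: an ion named `CA` is indistinguishable from a
C-alpha by name alone). Frames containing NaN coordinates are rejected
outright rather than silently skipped.

Pairwise frame distance is plain (unweighted) coordinate RMSD after
optimal superposition (Kabsch, via `scipy.spatial.transform`); the
residual is recomputed explicitly after rotation because the solver's
aggregate residual loses ~√ε precision for near-identical frames.
Clustering is scipy agglomerative linkage (default `average`) on the
condensed RMSD matrix, cut at a distance threshold (default 2 Å); each
cluster is represented by its medoid, the frame minimising summed
within-cluster RMSD. Linkage, cutoff and the hydrogen toggle are exposed
on the CLI. Ensemble Rg statistics default to all frames; a
`--representatives-only` mode averages over cluster medoids instead.

## Synthetic data: what it emulates and what it does not

`simulate_assay` emulates the bench diffusion assay: feed levels 1, 5 and
10 mg/L in triplicate, a 5 h run, a 0.5 mL static permeate chamber over a
0.785 cm² coupon, and a 100 mL recirculated feed. The forward model is the
same flux law the fit inverts — the permeate concentration accumulates as
`(P/l)·ΔC·A·Δt/V` — with feed depletion ignored (the transferred amount is
well under 1% of the dissolved feed mass, consistent with the trace-level
regime the assay operates in; note the permeate *concentration* can still
reach a few percent of the feed concentration because the chamber is 200×
smaller than the feed). Noise is multiplicative lognormal with unit mean
and a chosen coefficient of variation, matching proportional HPLC error;
an additive-Gaussian mode exists for robustness checks. All randomness
flows from the config seed.

What passing these simulations shows: the unit-conversion chain, the
estimator and its interval are self-consistent under the stated error
model. What it does not show: real assays add membrane heterogeneity,
adsorption transients, temperature drift and HPLC calibration bias that
the generator does not model — recovered-parameter accuracy on real data
will be worse than the simulated figures.

`simulate_chain` produces point-mass bead chains (straight rod,
freely-jointed, fixed-bond-angle with uniform torsions). It is a geometry
fixture with analytically checkable limits — the straight rod obeys
`Rg = b·√((N²−1)/12)`, the freely-jointed chain sits at the ideal-chain
`Nb²/6` scale — not a physical peptide model: no excluded volume, side
chains, solvent or force field. Published peptide Rg values from long
explicit-solvent MD are therefore *inputs* (registry constants), never
regenerated here.

## Problem sizes and numerical choices

The test-suite simulations are desk-scale by design: coverage checks use
200 simulated campaigns of 9 measurements; oracle-equivalence checks use
~100 random frames of up to 15 atoms; chain self-consistency compares a
400-frame run against a 4000-frame run of 50 beads. Oracles are
independent of the paths they check: closed-form normal equations and the
pairwise double-loop Rg form, a rotation-grid + simplex search for minimum
RMSD, and connected components of the thresholded distance matrix for
clustering. Tolerances follow the quantity: machine-precision identities
at 1e-9–1e-12 relative, statistical comparisons at 5%, PDB round trips at
the format's three-decimal coordinate precision.

## Known limitations

- Rejection from permeability is undefined at zero water flux and
  unreliable below ~95% rejection (the approximation it rests on fails).
- The proportional-variance weighting requires strictly positive `ΔC`;
  zero-gradient control points need `variance="constant"`.
- The PDB writer emits minimal HETATM records (no occupancy/B-factor
  semantics, no connectivity); the XYZ reader requires a consistent
  element order across frames.
- The compound registry treats molar masses at the precision of its
  source table; mass-flux and rejection predictions do not depend on them,
  but molar flux conversions do.
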