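# osmoflux

Quantitative analysis of trace-solute transport across dense forward-osmosis
(FO) membranes, with companion tools for characterising the conformational
size of the flexible solutes that cross them.

FO membranes with a dense thin-film-composite selective layer reject small
organics almost — but not completely. Peptides and pesticides sorb into the
polyamide layer, diffuse across it and desorb on the far side, so a
downstream-processing or draw-solute application needs to know each
compound's *permeability coefficient* and the rejection it implies. This
package is for membrane scientists and bioprocess engineers who run
diffusion-cell assays on such membranes and want a reproducible route from
raw permeate concentrations to permeability, flux and rejection numbers —
and, because flexible peptides have no single geometric size, from MD-style
conformer ensembles to radius-of-gyration statistics.

## The model

Transport through the dense layer follows the solution-diffusion picture.
With `P` [m² s⁻¹] the solute permeability, `l` [m] the layer thickness and
`ΔC` [mol m⁻³] the concentration difference across the membrane,

```
J_p = (P / l) · ΔC,          P = D · S
```

where `D` is the in-membrane diffusion coefficient and `S` the
dimensionless sorption coefficient. `P` is measured in a diffusion cell
with the osmotic gradient removed: the permeate chamber concentration after
time `Δt` gives the molar flux `J_p = c_p·V/(M_w·A·Δt)`, and `P/l` is the
slope of `J_p` against `ΔC` (weighted least squares with a Student-t
confidence interval; the flux law forces the line through the origin).
Under an operating water flux `J_w` [m s⁻¹] the implied rejection is

```
R = (1 − P / (t · J_w)) · 100 %
```

valid when rejection is high so the trans-membrane gradient is close to the
feed concentration. For the conformational-size side, each conformer's
mass-weighted radius of gyration is

```
Rg² = (1/M) Σᵢ mᵢ ‖Rᵢ − R_CM‖²,    R_CM = (1/M) Σᵢ mᵢ Rᵢ
```

over heavy atoms, with agglomerative clustering of frames on pairwise
optimal-superposition RMSD to pick representative conformations.

A synthetic module generates every input at desk scale: diffusion assays
with a known ground-truth permeability and multiplicative measurement
noise, and coarse-grained chain ensembles (straight rod, freely-jointed,
fixed-angle) whose Rg is analytically checkable.

## Worked example

Simulate a noisy triplicate assay campaign (feed levels 1/5/10 mg/L, 5 h,
0.5 mL permeate chamber, 0.785 cm² coupon) at the reference peptide
permeability and refit it:

```sh
$ osmoflux simulate assay --config sim.json --out assay_noisy.csv --seed 11
wrote 9 measurements (true P = 1.390e-12 m2/s) -> assay_noisy.csv
$ osmoflux fit --assay assay_noisy.csv
GGG SGA GKT: P = 1.409e-12 m2/s (95% CI [1.370e-12, 1.448e-12]), R^2 = 0.99884, n = 9
```

where `sim.json` is `{"compound": "GGG SGA GKT", "noise_cv": 0.05}`. The
fitted permeability (1.409×10⁻¹² m² s⁻¹) recovers the ground truth
(1.39×10⁻¹²) within its confidence interval at 5% measurement noise. From
the packaged constants (membrane thickness 112 µm, water flux
9.71 L m⁻² h⁻¹):

```sh
$ osmoflux reject --compound "GGG SGA GKT"
GGG SGA GKT: rejection = 99.5%
$ osmoflux flux --compound "GGG SGA GKT" --dc 1.0
GGG SGA GKT: flux = 44.68 ug/m2/h at dC = 1.0 mg/L
```

i.e. at a 1 mg/L gradient roughly 45 µg of the 692 Da peptide crosses each
square metre per hour, and under operating water flux 99.5% of it is
rejected. The same numbers for all five reference compounds, with the
stored reference values and deviations:

```sh
$ osmoflux table1
compound,class,permeability_m2_s,...,flux_ug_m2_h,rejection_pct,...
AGKT,peptide,3.8e-13,...,12.0,99.9,...
GGG SGA GKT,peptide,1.39e-12,...,45.0,99.5,...
DEIA,pesticide,5.36e-12,...,172.0,98.2,...
BAM,pesticide,3.9e-12,...,125.0,98.7,...
Atrazine,pesticide,4.31e-12,...,139.0,98.6,...
```

(exit status is non-zero if any recomputed cell deviates from the stored
reference). Ensemble geometry works the same way from Python or the shell:

```sh
$ osmoflux simulate chain --out chain.pdb --seed 2
wrote 1 frame(s) of 8 beads -> chain.pdb
$ osmoflux rg --traj chain.pdb
chain: Rg = 1.62 +/- 0.00 A over 1 frame(s) (heavy atoms)
```

The library surface mirrors this: `fit_permeability` /
`PermeabilityRegressor` (a scikit-learn estimator), `predicted_flux`,
`rejection_from_permeability`, `ensemble_rg`, `cluster_frames` /
`ConformerClusterer`, `simulate_assay`, `simulate_chain`.

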