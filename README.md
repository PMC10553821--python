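# dermadisperse

Analytics for mesenchymal cell dispersal in embryonic skin: how newly born
cells scatter after mitosis, how that motility feeds recruitment into
dermal condensates (the nascent dermal papillae of hair and feather
follicles), and how mitosis orientations are organised in space.

The package is aimed at people analysing time-lapse tracking of labelled
dermal nuclei: it consumes plain tabular trajectories (one row per cell per
frame) and condensate geometries, and provides

* **Motility metrics** — per-step speed, Euclidean/accumulated displacement,
  persistence (Euclidean/accumulated), time-ensemble MSD and its fitted
  slope, stratified into 180-min windows around each division (mother
  −180–0, daughters 0–180 and 180–360 min).
* **Condensate recruitment** — first-entry detection with absorbing
  censoring, per-window entry rates with two-sided Fisher exact tests, and
  entry-distance densities per group.
* **Spatial statistics of mitosis angles** — condensate-referenced angular
  variograms (semivariance of acute axial angle differences against
  distance-to-condensate, omnidirectional or in 45° cones), nested
  exponential fits γ(h) = c₀ + Σ cₖ(1 − e^(−h/aₖ)) with effective ranges
  3aₖ and nugget-to-sill ratio, a seeded Monte Carlo permutation test of
  condensate influence, ordinary kriging of axial angles via doubled-angle
  vectors, and permutation-referenced local randomness maps.
* **Alignment scoring** — the pairwise alignment coefficient
  d = (1/N) ΣᵢΣⱼ uᵢ·uⱼ over all N = n² ordered pairs of orientation unit
  vectors (the squared resultant length; 1 = one shared orientation,
  → 0 for isotropy), in axial or directed mode, plus a colour-segmentation
  + 2D-FFT pipeline that scores collagen-fibre alignment from RGB images.
* **An agent-based model** — diffusive walkers on a periodic square with
  absorbing condensate discs; division replaces a mother by two daughters
  displaced diametrically at angle θ, each running a 180-min persistent
  random walk (steps d_pers, turning angles Φᵢ) before reverting to
  diffusion. It reproduces the recruitment advantage of newly born cells.
* **Synthetic data generators** — seeded tracking tables, mitosis-angle
  fields and fibre images with ground-truth sidecars, so the whole pipeline
  is testable without any experimental download.

See `docs/methods.md` for the models, conventions (axial angles, image
coordinate frame, censoring rules) and parameter defaults.

## Worked example

Generate a synthetic 25-h tracking experiment (0.02 μm/min interphase
speed, 3× fast phase for 180 min after each division, two 50-μm
condensates), then run the motility and recruitment stages:

```bash
cat > params.yaml <<'YAML'
n_nondividing: 100
n_lineages: 60
duration: 1500.0
condensates:
  - {id: c1, cx_um: 100.0, cy_um: 100.0, radius_um: 50.0}
  - {id: c2, cx_um: 300.0, cy_um: 300.0, radius_um: 50.0}
field: [0.0, 0.0, 400.0, 400.0]
YAML
dermadisperse synth --kind tracks --params params.yaml --seed 7 --out-prefix demo
dermadisperse metrics --tracks demo_tracks.csv --out-prefix met
dermadisperse recruit --tracks demo_tracks.csv --condensates demo_condensates.csv --out-prefix rec
```

The `metrics` step prints

```
MSD slope 0.01578 um^2/min over 280 tracks
```

and writes `met_summary.json`:

```json
{
  "frame_interval_min": 10.0,
  "n_tracks": 280,
  "msd_slope_um2_min": 0.01577868415225477,
  "diffusion_coefficient_um2_min": 0.003944671038063692,
  "intercept_um2": -0.09181771126495462,
  "r_squared": 0.9925481594000253,
  "fit_window_min": [10.0, 40.0]
}
```

The slope pools all tracks, so it sits well above the pure-interphase value
(4D ≈ 0.0051 μm²/min for 0.02 μm/min steps) — the dividing lineages' fast
phase dominates the short-lag MSD. `recruit` writes the entry events, the
per-window Fisher rate table, densities, and `rec_summary.json`:

```json
{
  "dividing":     {"n_entered": 1, "n_tracked": 158, "fraction": 0.0063},
  "non_dividing": {"n_entered": 0, "n_tracked": 84,  "fraction": 0.0}
}
```

(at this field size only cells born near a disc can reach one — the
dividing group still gets there first). The other subcommands follow the
same pattern: `variogram` and `randmap` for mitosis-angle fields, `align`
and `fibres` for orientation sets and images, `simulate` for the
agent-based model. Every run writes a `*_manifest.json` with inputs,
parameters, seed and package version; re-running with the same seed
reproduces the outputs byte for byte.

The same functionality is available as a library:

```python
import dermadisperse as dd

field, truth = dd.gen_mitosis_field(dd.AngleFieldParams(seed=0))
vg = dd.empirical_angular_variogram(field, (200, 200), frame="radial")
model = dd.fit_variogram_model(vg, n_structures=2)
print(model.effective_ranges, model.variance_fractions)
```

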