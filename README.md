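# stabkrig

Stabilized kriging and empirical-Bayes methods for mapping small-area
disease rates.

Disease maps drawn per local administrative area (LAA) are unstable
wherever populations are small: the crude log-rate θ̂ᵢ = log(dᵢ/pᵢ) of an
area with dᵢ cases and population pᵢ has variance vᵢ ≈ 1/dᵢ, so
sparsely-populated areas show spuriously extreme rates. Empirical-Bayes
shrinkage stabilizes the rates but keeps the map chained to administrative
polygons; ordinary kriging draws a smooth boundary-free surface but
assumes every observation is equally precise. **Stabilized kriging** does
both: the usual constrained minimum-variance weights

```
[ w ]   [ τ² + v₁   C₁₂  …  C₁ₙ  1 ]⁻¹ [ C₁₀ ]
[ . ] = [   C₂₁   τ²+v₂ …  C₂ₙ  1 ]    [ C₂₀ ]
[ . ]   [    ⋮       ⋮   ⋱   ⋮   ⋮ ]    [  ⋮  ]
[ . ]   [   Cₙ₁    Cₙ₂  … τ²+vₙ 1 ]    [ Cₙ₀ ]
[ λ ]   [    1      1   …   1   0 ]    [  1  ]
```

carry each area's sampling variance vᵢ on the diagonal, so the prediction
θ̂₀ = Σwᵢθ̂ᵢ (rate r̂₀ = exp θ̂₀) shrinks unreliable areas toward the
regional mean — a zero-case area (vₖ = ∞) automatically gets weight
exactly 0 — while reproducing ordinary kriging wherever populations are
large. The covariances come from a spherical semivariogram fitted to the
half squared log-rate differences; τ² is the covariance at distance zero.

The package also ships the comparator estimators (traditional and
nugget-adjusted kriging; global and local DerSimonian–Laird and
Poisson-gamma empirical Bayes), direct age standardization under the WHO
2000 World Standard Population (with Var(log DASIR) so standardized rates
feed straight into the kriging system), synthetic county geometry, and a
Monte Carlo harness that scores all eight methods by symmetric mean
absolute percentage error (SMAPE) on Gaussian hotspot surfaces.

## Worked example

`laa.csv` holds eight areas; area `D` has an extreme rate from a small
population (30 cases / 9 000 people) and area `E` has zero cases:

```sh
$ stabkrig fit-variogram --input laa.csv --fit-mode cloud --out params.json
{
  "nugget": 0.0611508915773892,
  "partial_sill": 0.0611508915773892,
  "range": 1.8027756377319946,
  "sill": 0.1223017831547784,
  "tau2": 0.1223017831547784,
  ...
}
```

The fitted spherical model says log-rate covariance dies off over ~1.8
distance units and the between-area variance is τ² ≈ 0.12. Kriging a
3 × 3 mesh:

```sh
$ stabkrig krige --input laa.csv --variogram params.json \
      --flavor stabilized --targets mesh:3,3,0,4.5,0,4.5 --out grid.csv
wrote 9 predictions to grid.csv
```

At area `D`'s own representative point the two flavors differ exactly as
designed — traditional kriging interpolates the noisy raw rate, the
stabilized flavor shrinks it toward the neighbourhood:

| flavor | predicted rate at D (1.0, 2.0) |
|---|---|
| traditional | 3.3333333333e-03 (= D's raw rate) |
| stabilized | 2.8355092222e-03 |

Empirical-Bayes shrinkage of the same table (`stabkrig eb --method dl`)
shows the same pattern per area: well-observed areas keep their rates
(shrinkage factor ≈ 1), `D` is pulled from 3.33e-3 to 2.46e-3, and
zero-case `E` gets the prior mean 1.55e-3 outright.

Run a full Monte Carlo scenario (26-LAA synthetic county, hotspot
surface, log-normal populations, Poisson counts, all eight methods):

```sh
$ stabkrig simulate --surface single_slow --pop-mean 25000 --pop-cv 1.0 \
      --reps 500 --seed 1 --out sim.csv
```

which prints each method's mean SMAPE (%) — smaller is better; the
stabilized flavor should come out lowest.

Every output CSV gets a `.meta.json` sidecar recording the exact
invocation, seed and package version.

## Library use

```python
import stabkrig as sk

table = sk.from_counts(records)                       # or sk.laa_data.read_csv(...)
D = sk.pairwise_distance(table.coords, table.coords)  # metric="haversine" for lon/lat
cloud = sk.build_cloud(table, D)
model = sk.CovarianceModel(sk.fit_spherical(cloud))
theta0 = sk.predict_grid(table, model, mesh.points, flavor="stabilized")
```

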