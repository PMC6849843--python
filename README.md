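# sewscape

Spatial early-warning signals for ecosystem regime shifts.

Ecosystems with strong positive feedbacks — semi-arid rangelands,
shallow lakes, peatlands — can tip abruptly between alternative stable
states once a slowly changing driver crosses a fold bifurcation.
Because recovery from small perturbations slows down near the tipping
point (*critical slowing down*), the **spatial pattern** of a single
snapshot carries warning information: spatial variance and
autocorrelation rise, the spatial power spectrum reddens, and vegetation
becomes organized into larger, more coherent patches.  `sewscape` is a
toolkit for ecologists and remote-sensing analysts who want to compute,
calibrate and stress-test these indicators:

* a stochastic spatial **grazing model** (Noy-Meir) as controllable
  ground truth: dB/dt = r B (1 − B/K) − c B²/(B0² + B²) per lattice
  cell, plus diffusive seed dispersal and spatio-temporally fluctuating
  grazing pressure — bistable for grazing rates 18 < c < 26 with the
  default parameters;
* the four classic snapshot indicators — spatial variance, spatial
  skewness, Moran's I, spectral density ratio (SDR) — with permutation
  null envelopes and gradient trend tests;
* preprocessing for categorical maps: class merging, binarization,
  coarse-graining with Hartigan-dip-test-based factor selection, and the
  exact binary-moment identities (var = m(1−m)) that make raw indicator
  trends on binary maps treacherous;
* **variogram** analysis: empirical/directional/cross variograms,
  spherical/exponential fits for nugget, partial sill and correlation
  range, relative structural variance, and the D_c/2 optimal-resolution
  rule;
* **recovery-time** quantification from pulse experiments via the
  saturating exponential p1(1 − e^(−t/p2)) + p3 (recovery time = 3·p2,
  goodness of fit = Willmott's index of agreement);
* chi-square screening of state maps against environmental covariate
  maps, ESRI ASCII / TIFF raster I/O, and a `sewscape` CLI with a
  YAML-configurable pipeline.

## Worked example

Where are the tipping points, and how does recovery slow down as
grazing pressure approaches the upper fold?

```sh
$ sewscape bifurcation
fold points: c_lower = 17.8723, c_upper = 26.0437

$ sewscape recovery --c-base 5,10,15,20 --out recovery.csv
c=5: recovery time 3.36 yr, d = 1.0000
c=10: recovery time 3.86 yr, d = 1.0000
c=15: recovery time 4.68 yr, d = 1.0000
c=20: recovery time 6.39 yr, d = 1.0000
```

The fold points bound the bistable window (rounding to 18 and 26
g m⁻² yr⁻¹): below 17.87 only the vegetated state exists, above 26.04
only the degraded one, and in between the state depends on history
(hysteresis).  The recovery lines show critical slowing down: a
standard pulse of grazing pressure (+1.0 for one year) takes 3.4 years
to heal at low grazing but 6.4 years at c = 20, well inside the
bistable window — the loss of resilience is measurable long before the
collapse at c ≈ 26.  Willmott's index d ≈ 1.0 says the fitted
saturating-exponential curves are essentially exact, so 3·p2 is a
faithful recovery-time estimate.

The same slowing down is visible from space, without time series.
Simulate snapshots along a grazing gradient and compute the indicators:

```sh
sewscape --seed 1 simulate --L 64 --c-gradient 5:24:5 --burn-in 100 --out snaps/
sewscape sews snaps/manifest.csv --nulls 200 --out sews.csv
sewscape variogram snaps/snapshot_c20.asc --family spherical --out vario.csv
```

Spatial variance and Moran's I rise with c, the spectrum reddens, and
the fitted correlation range (mean patch size) grows.

In Python, the same pieces compose directly:

```python
from sewscape import (ModelParams, gradient_snapshots, sews_summary,
                      permutation_null, fold_points)

params = ModelParams(L=64, sigma=1.0, D=0.1, seed=1)
series = gradient_snapshots(params, [5, 10, 15, 20, 24], burn_in=100.0)
for c, grid in series:
    s = sews_summary(grid, periodic=True)
    print(c, s.spatial_variance, s.morans_i, s.sdr)
```

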