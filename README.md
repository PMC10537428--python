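# memchrom

Dynamic-adsorption analysis for membrane-bed chromatography: breakthrough-curve
performance indicators, breakthrough-to-uptake conversion, linearized kinetic
fits, breakthrough-curve model fitting with error statistics and ranking, and
BDST scale-up — plus a synthetic curve generator with known ground truth for
end-to-end validation.

## What it does

A breakthrough curve is the outlet/inlet concentration ratio C/C₀ versus time
for a bed fed at constant inlet concentration. From such curves (plus an
operating descriptor: inlet concentration, flow rate, bed geometry, adsorptive
mass), the package computes:

- **Performance indicators** (`memchrom.metrics`): breakthrough/exhaustion
  times (logistic-front fit or interpolation), loaded volume, bed volumes,
  dynamic and equilibrium binding capacity (DBC/EBC), adsorbent exhaustion
  rate, mass-transfer-zone length, bed utilization, productivity, residence
  time, permeation flux.
- **Kinetic fits** (`memchrom.kinetics`): uptake curve q_t(t) by trapezoidal
  integration, then pseudo-first-order, pseudo-second-order, Elovich and
  piecewise (1–3 stage) intraparticle-diffusion regressions with R².
- **Breakthrough-curve models** (`memchrom.btc_models`): Bohart–Adams,
  Thomas, Yoon–Nelson and single-depth BDST linearized fits, physical
  parameters back-solved from slope/intercept, percent-error versus
  experimental comparators, model ranking, curve prediction, and multi-depth
  BDST service-time scale-up.
- **Synthetic data** (`memchrom.synthetic`): closed-form logistic /
  early-front-exponential curves with seeded Gaussian noise, condition grids,
  and a standard 12-condition fixture set with ground-truth sidecars.

## Command line

```bash
# write the standard 12-condition synthetic set (curves + descriptors + truth)
memchrom fixtures fixtures/ --seed 1

# indicator panel for one curve
memchrom metrics fixtures/curve_02.tsv -d fixtures/curve_02.descriptor

# kinetic and breakthrough-model tables for one curve
memchrom kinetics fixtures/curve_02.tsv -d fixtures/curve_02.descriptor
memchrom models fixtures/curve_02.tsv -d fixtures/curve_02.descriptor

# full pipeline (indicators + kinetics + models + ranking + run log)
memchrom run --synthetic --seed 1 -o out/

# depth/service-time scale-up from runs at several bed heights
memchrom bdst-scaleup c1.tsv@c1.descriptor c2.tsv@c2.descriptor --predict 345
```

Curves are two-column delimited text (time in minutes, C/C₀); descriptors and
run configs are flat `key = value` files. `memchrom run -c run.cfg` accepts a
config with `mode`, `seed`, `outdir`, `fractions` and `curves` entries.

## Python API

```python
import memchrom as mc

spec = mc.SyntheticSpec(model="thomas", params={"k_T": 0.5, "q_e": 700.0},
                        C0=2.0, F=1.0, noise_sd=0.02, seed=7)
curve = mc.generate_breakthrough(spec)

ind = mc.performance_indicators(curve)        # DBC, EBC, HMTZ, MBU, ...
kin = mc.to_kinetic_curve(curve)              # uptake q_t(t)
pso = mc.fit_pso(kin)                         # {'k2': ..., 'q2': ...}
fits = mc.fit_all(curve)                      # four models + E% attached
best = mc.rank_models(fits)[0]
```

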