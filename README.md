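# fapsense

Modeling and identification of a FapR-based whole-cell malonyl-CoA
biosensor from plate-reader kinetics.

## The problem

Malonyl-CoA is the limiting precursor for fatty-acid and flavonoid
production in engineered *E. coli*.  A FapR/RFP sensor circuit reports
intracellular malonyl-CoA as fluorescence, which lets a 96-well plate
reader screen candidate production pathways — but the raw readout is a
dynamic signal entangled with growth.  This package provides the analysis
chain that turns OD600/fluorescence kinetics into interpretable sensor
parameters, for synthetic biologists characterizing such screens and for
anyone building feedback control on top of a transcription-factor sensor.

The core model treats the sensor as a linear filter from biomass X(t) to
fluorescence R(t):

    R(s)/X(s) = K (1 - τ_z s) / ((1 + τ_p1 s)(1 + τ_p2 s))

with gain K (sensitivity: steady-state fluorescence per OD, set by the
malonyl-CoA production rate) and integral time constants τ_p1 ≥ τ_p2
(response lag, constitutive per construct).  The filter is discretized with
the bilinear transform s = (2/Ts)(z−1)/(z+1) into an ARX difference
equation, fitted to the sampled series by ordinary least squares, and
mapped back to (K, τ_z, τ_p) — so a gain and two time constants summarize
each well.  A mechanistic three-stage cascade (malonyl-CoA balance, FapR
binding at K_d = 2.4 μM, reporter expression) backs the filter picture and
drives the synthetic plate generator.  See `docs/methods.md` for the full
model account.

## Worked example

```python
import numpy as np
from fapsense import (GrowthParams, REFERENCE_MODEL2, bilinear_discretize,
                      identify, logistic_growth, simulate_discrete_arx)

# a 48 h growth curve sampled every 12 min
t = np.arange(240) * 12.0
x = logistic_growth(GrowthParams(x0=0.05, xmax=1.2, mu=0.01, lag=0.0), t)

# fluorescence generated by the matCmatB reference model, then re-identified
ref = REFERENCE_MODEL2["matCmatB"]          # K=250.84, tau_p=(290.11, 12.69)
r = simulate_discrete_arx(bilinear_discretize(ref, ts=12.0), x)
fit = identify(r, x, order=2, ts=12.0)
print(f"K={fit.continuous.k:.2f}  tau1={fit.continuous.tau_p[0]:.2f}  "
      f"tau2={fit.continuous.tau_p[1]:.2f}  R^2={fit.r_squared:.6f}")
```

prints

```
K=250.84  tau1=290.11  tau2=12.69  R^2=1.000000
```

— the identification pipeline is an exact inverse of the simulation on
noise-free data: the gain and both time constants of the malonyl-CoA
synthase construct come back to eleven significant digits.

## The analysis chain

Numbered drivers under `analysis/` run the full study on synthetic plates
and write their tables to `results/`:

1. `01_simulate_plate.py` — 96-well characterization plate (5 constructs ×
   6 IPTG doses × 3 replicates + controls, 2% measurement noise).
2. `02_identify_models.py` — per-well order-2 fits (`fits.csv`, the
   per-construct K/τ₁/τ₂ table) and the order-1/2/3 residual comparison.
3. `03_response_analysis.py` — OD = 0.6 readouts, dose–response curves,
   parameter-vs-induction correlation (gain tracks log dose, r ≈ 0.96 on
   the default plate; time constants don't, |r| < 0.05, and cluster by
   construct), replicate CVs.
4. `04_substrate_effects.py` — Welch tests for substrate supplementation
   effects, recovering the generator's boost/hindrance truth per construct.
5. `05_roundtrip_benchmark.py` — exact parameter recovery for all five
   reference constructs.

The same steps are available as a CLI (`fapsense simulate | identify |
analyze | report`, configured by `configs/default.toml`), and everything is
importable from the `fapsense` package.

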