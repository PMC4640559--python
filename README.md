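# aktdyn

Comparative ODE modeling of the Akt Thr308 phosphorylation overshoot in
serum-stimulated fibroblasts.

When starved fibroblasts are re-fed with serum, the membrane lipid PIP3
spikes at ~2 minutes, yet Akt phosphorylation at Thr308 peaks only at
30–60 minutes before declining to a moderate steady state.  `aktdyn` is
for systems biologists who want to ask, quantitatively, *which single
non-canonical effect explains that delay*: it implements a canonical
PIP3 → PDK1/Akt → Aktp308 ODE model (H0), five alternatives that each
insert one latent, spline-encoded deviation (PIP3-dependent recruitment
M1, PIP3-independent recruitment M2, membrane retention M3, phosphatase
sequestration M4, phosphorylation modulation M5), weighted-SSE
calibration by multistart particle swarm + Nelder–Mead, semi-qualitative
peak scoring (peak time, width, amplitude), in-silico PI3K-inhibition
experiments, and a four-stage hypothesis-exclusion protocol that reduces
the field of six models to the single surviving mechanism — retention of
phosphorylated Akt at the membrane.

The core objects: a `ModelSpec` (variant + rates + initial state + input
and deviation splines), the calibration objective

    min_k  Σ_s Σ_e Σ_t  w_{s,e} · (x_data(t) − x_sim(t, k))²,
    w_{s,e} = n_t / Σ_t x_data(t)²,

with the spline knots v(0), v(2), …, v(120) treated as ordinary free
parameters, and a verdict table over the tests
{Aktp308 fit, membrane time series, PIP3 clamp, constitutive activation +
clamp} with prior-fail propagation.

Because the study deposits no public dataset, the package ships a
first-class synthetic-data generator (`aktdyn.synth`) that reproduces the
study's printed curve-shape anchors and densitometry-normalization chain
from a retention-model ground truth, so every stage of the pipeline is
testable end to end.  See `docs/methods.md` for the model equations,
optimizer settings, scoring thresholds and known limitations.

## Worked example

```python
import numpy as np
from aktdyn import (make_fixture_bundle, NoiseModel, peak_features,
                    run_protocol, ProtocolConfig)

# a noiseless synthetic study bundle
bundle = make_fixture_bundle(seed=0, noise=NoiseModel(0, 0, 0))
aktp308 = bundle.dataset("aktp308").series("Aktp308", "serum")
f = peak_features(aktp308.index.to_numpy(), aktp308.to_numpy())
print(f"Aktp308 peaks at {f.peak_time:g} min, "
      f"amplitude {f.peak_amplitude:.2f}-fold over its final level")

# the full exclusion protocol on the noisy default bundle (several minutes)
result = run_protocol(make_fixture_bundle(seed=0), ProtocolConfig())
print(result.verdicts)
print("survivors:", result.survivors)
```

prints

```
Aktp308 peaks at 30 min, amplitude 1.53-fold over its final level
   aktp308_fit membrane_timeseries ly29_timeseries constitutive_plus_ly29
H0        fail          prior_fail      prior_fail             prior_fail
M1        pass                pass            pass                   fail
M2        pass                pass            fail             prior_fail
M3        pass                pass            pass                   pass
M4        pass                fail      prior_fail             prior_fail
M5        pass                fail      prior_fail             prior_fail
survivors: ('M3',)
```

— the lysate phospho-Akt series peaks at 30 minutes and declines, the
canonical model cannot reproduce that shape at all, the dephosphorylation
and phosphorylation variants die on the membrane time series, the
PIP3-independent recruitment variant accumulates membrane Akt under the
PIP3 clamp where the data stay flat, the PIP3-dependent recruitment
variant predicts no post-clamp decline of membrane Akt where a partial
decline is observed, and only the retention model survives every test.

A `aktdyn` console script exposes the same steps
(`generate-data`, `simulate`, `score`, `pipeline`, `export-sbml`).

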