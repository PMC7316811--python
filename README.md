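# ihcsync

Modelling electrically coupled cochlear inner hair cells (IHCs).

A minority of mature IHCs are joined into small "mini-syncytia" by
low-resistance, macromolecule-permeant junctions, so a handful of receptor
cells share one receptor potential.  This package provides the
computational tool-chain for studying what such coupling does to sound
encoding:

* **`coupling_circuit`** — the two-cell dual voltage-clamp equivalent
  circuit (cell capacitances C₁, C₂, junctional resistance R_J, membrane
  resistances R_M, pipette series resistances R_S): steady states,
  step transients, junctional-resistance estimation from I_J–V_J relations
  with series/input-resistance compensation, apparent capacitance C_m and
  slope conductance G_m of N-cell chains.
* **`syncytium_sim`** — a stochastic signal-chain simulation of N coupled
  or uncoupled IHCs: a sinusoidal stimulus gates mechanotransducer (MET)
  channels (two-state Markov chains), the transduction current drives each
  cell's membrane voltage (R_J-coupled chain), the receptor potential
  controls Ca²⁺-channel gating, long (≥ 2 ms) single-channel openings
  trigger release events, and refractoriness turns these into auditory-nerve
  (SGN) action potentials.  Lag-compensated Pearson correlations summarize
  how faithfully each stage tracks the stimulus.
* **`cn_coincidence`** — an M-of-K coincidence-detection model of a
  cochlear-nucleus bushy cell pooling K SGN inputs, and the
  coupled-vs-uncoupled improvement of its signal detection.
* **`tonotopy`** — place–frequency map arithmetic: the tonotopic span of an
  n-IHC pool as a length fraction, in octaves and in cents, for mouse
  (log-linear map) and human (Greenwood map) cochleae.
* **`imaging_fv`** — the presynaptic Ca²⁺-imaging analysis: dye time-series
  normalization, ΔF hotspot extraction with the mean + 2 SD criterion,
  interleaved voltage-ramp merging, fluorescence–voltage (FV) fitting

      F(V) = F₀ + f_v (V_r − V) / (1 + exp((V_h − V)/k)),

  and the fractional-activation (Boltzmann) curve derived from it.
* **`synthetic_data`** — seeded generators for every input the estimators
  consume (paired recordings, FV traces, hotspot image stacks), with known
  ground truth for recovery tests.

## Worked example

```python
import numpy as np
from ihcsync.coupling_circuit import ClampCircuit, estimate_rj
from ihcsync.synthetic_data import gen_paired_recording

# a coupled pair with R_J = 35 MOhm, recorded with 50 pA current noise
rec = gen_paired_recording(ClampCircuit(rj=35.0),
                           np.arange(-100.0, 101.0, 25.0),
                           noise_sd_pA=50.0, seed=0)
est = estimate_rj(rec.to_paired_iv())
print(f"R_J estimate: {est.rj_hat:.1f} MOhm (apparent {est.rj_apparent:.1f} MOhm)")

from ihcsync.syncytium_sim import (SyncytiumConfig, simulate_conditions,
                                   correlation_summary)
coupled, uncoupled = simulate_conditions(SyncytiumConfig(seed=0))
rc = correlation_summary(coupled).vs_stimulus["ca_open_prob"]
ru = correlation_summary(uncoupled).vs_stimulus["ca_open_prob"]
print(f"Ca-channel stimulus correlation: coupled {rc:.3f}, uncoupled {ru:.3f}")

from ihcsync.tonotopy import (human_map, mouse_map, cents_per_ihc,
                              length_fraction, octave_span,
                              syncytium_resolution_cents)
m = mouse_map()
frac = length_fraction(9, m)
print(f"9-IHC mouse span: {frac:.2f}% of the cochlea, "
      f"{octave_span(frac, m):.3f} octaves")
h = human_map()
print(f"human single IHC: {cents_per_ihc(h):.2f} cents -> "
      f"3-IHC resolution {syncytium_resolution_cents(3, h):.0f} cents")
```

prints

```
R_J estimate: 35.2 MOhm (apparent 56.1 MOhm)
Ca-channel stimulus correlation: coupled 0.904, uncoupled 0.827
9-IHC mouse span: 1.29% of the cochlea, 0.060 octaves
human single IHC: 2.60 cents -> 3-IHC resolution 9 cents
```

The raw I_J–V_J slope overestimates R_J by the series/shunt pathway
(56 MΩ apparent vs 35 MΩ truth); inverting the full network recovers the
truth to within the noise.  Electrical coupling raises the correlation
between Ca²⁺-channel gating and the mechanical stimulus because the three
cells average out each other's transduction noise, and the broadest
mini-syncytia remain far below the physiological frequency-resolution
limits of the cochlea.

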