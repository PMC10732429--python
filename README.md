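# merkelsim

A biophysical whole-cell simulator of Merkel-cell mechanotransduction.

Merkel cells are the epidermal mechanosensors behind slowly-adapting
type-1 (SA1) touch afferents. Their puzzle: the mechanosensitive channel
Piezo2 inactivates within tens of milliseconds, yet the downstream
afferent fires for tens of seconds under a static indentation.
`merkelsim` implements a deterministic 28-state ODE model of one Merkel
cell that reproduces the proposed resolution — a brief Piezo2 Ca²⁺ influx
hands off to intracellular Ca²⁺ handling, which sustains Ca²⁺-dependent
vesicle release long after the membrane potential has repolarised.

The model couples:

* **Membrane electrophysiology** — Hodgkin–Huxley kinetics for Kv1.4,
  Kv4.2, BKCa, KDR, Cav1.2 and Cav2.1; four ohmic leaks; the Na⁺/K⁺
  pump, NKCC1/KCC2 cotransport, PMCA and the electrogenic 3:1 Na⁺/Ca²⁺
  exchanger. C_m·dV_m/dt = F·Σᵢ zᵢ·Jᵢ + I_app/S_ref, with every molar
  flux Jᵢ positive into the cytosol.
* **A stress-gated Piezo2 state machine** — closed/open/inactivated
  fractions plus a slow availability factor, driven by the cortex stress
  σ, carrying pure Ca²⁺ current g·O·h_slow·(V_m − E_Piezo2).
* **Ca²⁺ stores** — SERCA, RyR (hard CICR threshold at 0.3 µM), IP₃
  receptors with bell-shaped Ca²⁺ gating and dynamic IP₃ turnover;
  mitochondrial MCU uptake and Na⁺/Ca²⁺ exchange.
* **Cell mechanics** — osmotic water flow dV/dt = −S·α(ΔP − ΔΠ), an
  elastic cortex σ = K/2·(S/S_ref − 1) − σ_a, Laplace pressure, and a
  volume-conserving sphere→cylinder map for indentation.
* **A vesicle cycle** — Ca²⁺-gated exocytosis (the neurotransmitter-release
  proxy), tension-gated endocytosis, and the membrane-area bookkeeping
  that couples them back into the mechanics.

Four stimulus protocols are built in: rectangular current pulses, high-K⁺
bath swaps, hypotonic shock (mannitol removal) and ramp-and-hold
compression. `docs/methods.md` documents every rate law, the unit system,
the numerical scheme and the known model limitations.

## Worked example

Relax the default cell to rest and drive it with the standard strong test
pulse (114.1 pA, 200 ms), with and without the BKCa brake:

```python
from merkelsim import (MerkelCellModel, ModelParameters,
                       StimulusProtocol, summarize_trace)

pulse = StimulusProtocol(kind="current_pulse", onset=0.01,
                         duration=0.2, current=114.1e-12)

for label, overrides in [("intact", {}), ("BKCa knocked out",
                                          {"g_BKCa": 0.0})]:
    model = MerkelCellModel(ModelParameters.preset("fig2", **overrides))
    rest = model.initialize_rest()
    trace = model.run_protocol(rest, pulse, horizon=0.5)
    s = summarize_trace(trace)
    print(f"{label}: rest {rest.vm * 1e3:.1f} mV, "
          f"peak {s['peak_vm_mV']:.1f} mV, "
          f"peak Ca {s['peak_c_ca_uM']:.2f} uM")
```

prints

```
intact: rest -55.3 mV, peak 75.9 mV, peak Ca 4.38 uM
BKCa knocked out: rest -55.1 mV, peak 275.4 mV, peak Ca 3.42 uM
```

With BKCa present the depolarisation peaks near +76 mV and settles back;
remove the Ca²⁺-activated K⁺ conductance and the same current drives a
runaway depolarisation far beyond +100 mV — BKCa is what caps the
response. The Ca²⁺ transient (a few µM) comes from the voltage-gated
Cav channels opened by the depolarisation.

The same machinery is scriptable from the shell. `merkelsim
list-scenarios` shows the registered validation experiments (each mirrors
one published figure panel with its exact caption values); for example

```bash
merkelsim rest                 # print the relaxed resting state
merkelsim run --scenario fig12_compression --out out/
```

writes one trace CSV per indentation depth (3–7 µm) plus a summary table.
Columns are time (ms), V_m (mV), cytosolic/ER/mitochondrial Ca²⁺ (µM),
IP₃ (µM), bulk ions (mM), cortex stress (Pa), volume (µm³), S_ref (µm²),
vesicle count, exocytosis rate (vesicles/ms) and depth (µm). Parameters
can be overridden with a YAML config carrying explicit unit strings
(`merkelsim run --config my.yaml ...`); see `merkelsim.config`.

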