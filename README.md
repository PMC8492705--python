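# eegpsi

Quasi-quantum analysis of multichannel EEG in sensor space.

`eegpsi` treats a multichannel EEG recording as a time-indexed state vector
over the electrode array: each channel's time course is extended to its
analytic signal (Hilbert transform), and at every sample the complex channel
vector is normalized to unit Euclidean norm across channels. The squared
moduli of this *pseudo-wavefunction* define a per-electrode probability
distribution `P_j(t)` — "where the signal energy sits on the scalp" — from
which the package derives:

- **Region occupancy frequencies** `f_G = (1/T) Σ_t Σ_{j∈G} P_j(t)` over
  eight scalp regions (anterior / posterior / parietal / occipital, left and
  right);
- **Position observables** `⟨x(t)⟩ = Σ_j x_j P_j(t)` (and y), with the
  electrode coordinates projected onto the horizontal plane;
- **Momentum observables** via an Ehrenfest-style identity,
  `⟨p_x(t)⟩ = m · d⟨x(t)⟩/dt` with `m = 1` and derivatives per sample
  interval;
- **Momentum-basis probabilities** `P̃_j(t)` through a scattered-to-scattered
  (type-3) 2-D Fourier transform from electrode positions to a fixed
  92-point momentum grid;
- **Uncertainty products** `Δx(t)·Δp_x(t)` (and y), whose per-recording
  minimum, averaged over a cohort, yields the summary constant **K** — the
  floor the product never goes below. At 250 Hz the product carries units of
  cm²/4 ms.

No claim about quantum behaviour of the brain is made or implied; the
formalism is borrowed as a descriptive tool for sensor-space dynamics.

The intended users are EEG researchers who want a compact, reproducible
implementation of this analysis for their own recordings (EDF or plain
delimited matrices) or for simulation studies with the bundled synthetic
generator.

## Worked example

```python
import eegpsi as e

montage = e.default_montage()          # synthetic 92-channel stand-in layout
grouping = e.default_grouping(montage) # eight regions, counts 8..17 per side

# simulate a "rest"-like recording: 60 % of signal energy anterior
spec = e.SynthSpec(duration=10.0, seed=7,
                   localization=("Anterior L", "Anterior R"),
                   localization_strength=0.6)
rec = e.generate_recording(spec, montage, grouping)

# region occupancy
wf = e.trim_edges(e.normalize(e.analytic_signal(rec), rec.fs), 50)
regs = e.compute_regions(e.probability(wf), montage, grouping)
f_ant = sum(regs.f_G[regs.names.index(g)] for g in ("Anterior L", "Anterior R"))
print(f"anterior occupancy f_G = {f_ant:.3f}")

# uncertainty products
obs, us, P = e.analyze_recording(rec, montage, n_edge=50)
s = e.summarize_k([us])
print(f"min product = {s.recordings[0].min_x:.3f} cm^2 per sample interval")
print(f"K estimate  = {s.k_estimate:.3f}")
```

Output:

```
anterior occupancy f_G = 0.598
min product = 4.359 cm^2 per sample interval
K estimate  = 5.527
```

The anterior occupancy recovers the generator's localization parameter
(0.6); the minimum uncertainty product is strictly positive — localizing the
state in electrode space forces spread in the conjugate momentum variable,
exactly as for any Fourier-conjugate pair.

The same pipeline is available from the shell:

```bash
eegpsi simulate --out-dir sim --n-rest 2 --n-task 2 --seed 1
eegpsi analyze  --input sim/rec_00_rest.csv --fs 250 --edge-trim 50 --out-dir out
eegpsi uncertainty --input sim/rec_00_rest.csv --fs 250 --edge-trim 50 --out-dir out
```

All outputs are plain CSV plus a `run_config.txt` provenance echo; reruns
with the same inputs are byte-identical.

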