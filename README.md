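# snarezip

Single-molecule magnetic-tweezers analysis of SNARE complex zippering and
its regulation by complexin (Cpx).

The neuronal SNARE complex — syntaxin-1A, SNAP-25 and synaptobrevin-2 —
drives synaptic vesicle fusion by zippering into a four-helix bundle.  In a
magnetic-tweezers assay a single pre-assembled complex is held between two
510-bp dsDNA handles and loaded from its C-terminal ends; between 12 and
16 pN the complex exchanges among a fully zippered state, a "linker-open"
state (SNARE motifs folded, C-terminal linker domains unstructured), a
half-zippered state, and the unzipped state.  `snarezip` implements the
full analysis chain for such experiments, together with a construct model
and a trace simulator, for researchers analyzing (or planning) tweezers
experiments on coiled-coil and SNARE-family systems:

* **Construct extension model** (`snarezip.polymer`) — per-state end-to-end
  extension from the Marko–Siggia worm-like chain,
  `F = (kBT/P) [ 1/4 (1 − x/L)⁻² − 1/4 + x/L ]`,
  with an enthalpic stretch term for dsDNA, a residue-level leucine-zipper
  layer map, and calibrated rigid-body axial terms.
* **Kinetic Monte-Carlo simulator** (`snarezip.kinetics`, `snarezip.simulate`)
  — Markov jumps among conformational states with Bell-equation rates
  `k(F) = k_w exp[(−ΔG‡ + F Δx‡)/kBT]` (kBT = 4.11 pN nm,
  k_w = 10⁶ s⁻¹), force protocols (holds, ±1 pN/s ramps, >50 pN/s jumps)
  and camera-frame Gaussian or Ornstein–Uhlenbeck noise.
* **Force-ramp analysis** (`snarezip.ramp`) — moving-median step detection,
  unzip/rezip force distributions, the construct QC signature, and
  per-bead normalization of unzip forces to the 14.4 pN global mean.
* **Dwell-time energy landscapes** (`snarezip.dwell`) — censored
  exponential MLE of force-jump latencies, weighted Bell regression
  `kBT ln(k/k_w) = −ΔG‡ + F Δx‡`, and reconstruction of the coarse
  unzipping/rezipping landscape at any force.
* **Equilibrium populations** (`snarezip.equilibrium`) — Gaussian-mixture
  identification of the zippered intermediates from 1.2 kHz extension
  distributions and a three-state Boltzmann equilibrium fit
  `p_i(F) ∝ exp[−(G_i − F x_i)/kBT]`.
* **HMM kinetics** (`snarezip.hmm`) — Gaussian-emission hidden-Markov
  idealization of high-speed traces, dwell-counting rate matrices, and
  per-transition Bell fits and free-energy differences.
* **Workbench** (`snarezip.workbench`, `snare` CLI) — trace I/O
  (TSV + JSON sidecar), seeded fixture trees, and report assembly.

## Worked example

Predict the intermediate-state extensions and recover an unzipping barrier
from a simulated force-jump experiment:

```python
from snarezip import ConstructSpec, state_delta
from snarezip.benchmarks import unzip_scheme, measure_unzip_rate
from snarezip.dwell import barrier_at_force

spec = ConstructSpec()
for state in ("LINKER_OPEN", "HALF_ZIPPERED", "UNZIPPED"):
    print(f"{state:>14}: {state_delta(14.0, state, spec):.1f} nm")

fit = measure_unzip_rate(spec, unzip_scheme(15.0), target_force_pn=14.0,
                         n_dwells=25, seed=7, window_s=60.0)
print(f"k_unzip(14 pN) = {fit.rate_s:.3f} /s "
      f"(95% CI {fit.ci95_rate_s[0]:.3f}-{fit.ci95_rate_s[1]:.3f})")
print(f"barrier        = {barrier_at_force(fit.rate_s):.1f} kBT")
```

```
   LINKER_OPEN: 5.4 nm
 HALF_ZIPPERED: 13.9 nm
      UNZIPPED: 26.7 nm
k_unzip(14 pN) = 0.375 /s (95% CI 0.247-0.542)
barrier        = 14.8 kBT
```

The three extensions are the model increases, relative to the fully
zippered complex at 14 pN, for opening the linker domains, unzipping the
C-terminal half of the bundle, and fully unraveling synaptobrevin.  The
jump experiment holds the construct at 10 pN, steps to 14 pN within 0.1 s,
and measures 25 latencies to unzipping; the censored exponential MLE and
the k_w = 10⁶ s⁻¹ attempt frequency convert the rate into a force-tilted
barrier height, here recovered within its confidence interval of the
programmed 15 kBT.

The same workflow is available from the shell:

```sh
snare simulate --scale smoke --seed 1 --out exp --conditions none,WT
snare ramp detect exp/none/ramp/*.tsv --out exp/none/ramp_events.tsv
snare dwell extract exp/none/jump/jump_14.0*.tsv --target-force 14 --out dwells.tsv
snare dwell fit-exp dwells.tsv --out rates.json
snare report exp
```

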