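# Methods

## The construct extension model

The pulling construct is a single SNARE complex flanked by two 510-bp
dsDNA handles attached to C-terminal cysteines (syntaxin K266C,
synaptobrevin I97C), with the N-termini crosslinked by a disulfide
(syntaxin I202C, synaptobrevin L32C).  The end-to-end extension at force
F is modeled as three serial contributions:

1. **dsDNA handles** — one extensible worm-like chain of 1020 bp
   (persistence length 45 nm, contour 0.338 nm/bp, stretch modulus
   1200 pN).  The Marko–Siggia interpolation is inverted by bracketed root
   finding (Brent, tolerance 1e-12); the enthalpic term adds F/K to the
   relative extension.
2. **Unfolded polypeptide** — an inextensible WLC over the residues that
   are random coil in the current conformational state (persistence
   0.6 nm, contour 0.365 nm/residue).
3. **Folded remainder** — a force-independent axial length per state.

State definitions follow the leucine-zipper layer map (layers −7…+8,
zero layer synaptobrevin R56 / syntaxin Q226, 3.5 residues per layer,
rounded half-up so layer −7 coincides with the crosslink sites).  Coil
residue counts per state: linker-open 22 (syb 85–96, syx 256–265);
half-zippered 58 (syb beyond layer +2, syx beyond +4); unzipped 103 (syb
fully unraveled, syx beyond layer 0); SNAP-25-dissociated 127 (syx fully
unraveled as well).  SNAP-25 itself is not in the tether path and
contributes no extension.

The folded-axial terms absorb everything the serial-WLC picture cannot
see — projection of the remaining bundle onto the pulling axis, bundle
reorientation, and the double traversal of the folded core between the
crosslink and the two attachment points.  They are calibrated once
(`scripts/calibrate_construct.py`) so the model reproduces the four
anchors: state increases of 5.4, 13.9 and 26.7 nm at 14 pN and the 5 nm
extension gain on SNAP-25 dissociation at 16 pN.  The calibrated offsets
are small (0.5–3.6 nm) and stored in the packaged, human-editable
`construct.json`; the layer map ships as a 3-column TSV.  The folded
bundle is treated as a rigid rod aligned with the pulling axis — no
orientational averaging — which is the simplest geometry consistent with
the anchors.

## Kinetics: Bell rates, schemes, landscapes

Every transition rate obeys the Bell equation with kBT = 4.11 pN nm and a
diffusion-limited attempt frequency k_w = 10⁶ s⁻¹.  A `KineticScheme` is
a directed graph of Bell edges, optionally force-gated (SNAP-25 rebinding
is active only below 2 pN, default 1 s⁻¹).  `scheme_from_landscape`
builds both directed rates of each edge from state energies and barrier
(position, height) pairs so that detailed balance holds exactly at every
force.  Landscapes are quoted at a **reference force** (usually the 14 pN
working force) because the force tilt reorders the landscape: at zero
force the unzipped state sits far above the unzipping barrier and a
barrier-above-wells check would be meaningless there.

Pinned condition parameters (kBT units, quoted at 14 pN):

| condition | linker-open G | half-zippered G | unzip barrier |
|-----------|---------------|-----------------|---------------|
| none      | 1.0           | 0.8             | 15.0          |
| WT / NAC  | −0.9          | 3.7             | 19.3          |
| AC        | 1.9           | 3.7             | 19.3          |
| C         | 1.4           | 2.2             | 18.5          |

These encode the observed phenomenology: no-Cpx populations of roughly
0.55/0.20/0.25 at 14 pN; Cpx abolishing the half-zippered state and
promoting the linker-open state (dominant above 14.5 pN, more than
three-fold at 14 pN) through its N-terminal domain; stabilization of
4.3 kBT carried by the central/accessory helices; rezipping untouched by
Cpx (the unzipped-state energy and the barrier shift together).  The
zippered-intermediate barriers (9.7 kBT at 2.6 nm; 11.4 kBT at 9.0 nm)
put all exchange rates within the 1–10³ s⁻¹ band measurable at 1.2 kHz.
The main rupture transition uses Δx‡ = 7 nm (unzip) and 18 nm (rezip)
with the unzipped state at 25 nm, reproducing unzipping near 14–15 pN and
rezipping near 10 pN in ±1 pN/s ramps, and the mechanical hysteresis
between them.

## Simulator

State paths are generated by kinetic Monte Carlo: exact exponential
waiting times during holds; during ramps, time-discretized thinning on a
1 ms grid using the cumulative hazard of the mid-step rates (the accuracy
/ speed trade-off is negligible against 0.1 pN-scale force resolution).
Observed extension is the construct-model extension of the current state
at the instantaneous force (interpolated from a 0.01 pN grid) plus
per-frame noise.  Noise defaults: σ = 2.5 nm at 1.2 kHz and σ = 1.0 nm at
100 Hz, i.i.d. Gaussian, chosen so the three intermediate components are
resolvable at 1.2 kHz; an Ornstein–Uhlenbeck mode (2 ms default
correlation) emulates bead relaxation.  Equilibrium-scan simulations can
override the state levels with the *measured* peak offsets (0/5.3/13.0 nm)
rather than the model-calculated ones (0/5.4/13.9 nm), mirroring the
distinction between measured and predicted positions.  A trace can be
truncated shortly after its first transition, emulating serial jump
protocols.  One RNG per trace, seeded explicitly; identical seeds give
byte-identical traces.

A missed-event warning is raised when the realized path contains dwells
shorter than a tenth of a frame (equivalently, exit rates above ten times
the sampling rate along the visited states).

## Ramp analysis

Steps are detected by comparing trailing and leading moving medians
(window 11 frames at 100 Hz, 61 at 1.2 kHz; thresholds 10 nm for
unzip/rezip, 3 nm for the SNAP-25 classes); candidate boundaries closer
than one window merge into the strongest one, and the event force is the
force at the change-point frame.  On simulated ground truth this detector
has ≥ 99% recall for 25 nm steps at σ = 2.5 nm with a false-positive rate
below 1 per 10⁴ frames, and its mean detected unzip force is within
0.05 pN of the simulator's first-passage truth.  QC requires one event of
each signature class inside its window (unzip 12–16, rezip 8–12, unfold
15–18, refold < 2 pN).  Normalization scales each bead's unzip forces by
(14.4 pN / bead mean), which is exact and idempotent by construction.

## Dwell-time landscapes

Latencies are timed from the end of the jump's 0.1 s settling window to
the detected transition.  Traces ending without a transition contribute
censored records; the exponential MLE is rate = events / total observed
time, with a profile-likelihood 95% CI.  Transitions completing during
the ramp or settling window are flagged `sub_resolution` and excluded
from the MLE: they are left-truncated observations, and by memorylessness
the surviving dwells are unbiased samples of the hold-force exponential.
(Including them as epsilon-duration events biased fast rates by up to
~20%.)

The Bell fit is a weighted linear regression of kBT ln(k/k_w) on force;
weights are the inverse variances of ln k implied by the per-force CIs.
When those variances are supplied the parameter covariance is the
unscaled (XᵀWX)⁻¹ — with 3–4 forces the residual-variance estimate has
~1 degree of freedom and destroys interval calibration (joint 95%
coverage drops from ~94% to ~62%).  The landscape at force F places the
zippered well at (0, 0), the barrier at (Δx‡_unzip, ΔG‡_unzip(F)) and the
unzipped well at (Δx‡_unzip + |Δx‡_rezip|, ΔG‡_unzip(F) − ΔG‡_rezip(F)).
ΔΔG between conditions is kBT ln of the rate ratio and is independent of
k_w.

## Equilibrium populations

`fit_gmm` is standard EM (best of 10 seeded restarts, ≤ 500 iterations,
tolerance 1e-6 on the per-sample mean log-likelihood).  For population
tables the default estimator pins the component means to the known state
levels and estimates only the weights and one shared width
(`fit_fixed_level_mixture`): at 2.5 nm noise against 5.3 nm state spacing
the fully free three-component mixture is weakly identified and its
weights are biased by more than 0.1, while the fixed-level weights track
the true occupancies to a few parts per thousand.  This mirrors the use
of measured emission parameters as priors in the HMM stage; the free
mixture (with nearest-level component assignment, 2.5 nm tolerance,
unassigned weight excluded and the three states renormalized) remains
available.  Mixture order follows the force threshold: two components
below 13 pN, three at or above.

The three-state model p_i(F) ∝ exp[−(G_i − F x_i)/kBT] with
(G₀, x₀) = (0, 0) is fit by multinomial negative log-likelihood using the
per-row frame counts, initialized from per-state linear fits of
ln(p_i/p₀) against force — the exact inverse on noiseless tables — and
polished by Nelder–Mead.  The extension coordinates x_i can be fixed to
the construct-model deltas; the default fits them freely.

## HMM kinetics

Gaussian-emission HMMs are fit by Baum–Welch (hmmlearn), emissions
initialized — and by default frozen — at the mixture values, with a
near-diagonal transition-matrix start.  Rates are derived canonically by
Viterbi dwell counting, k_ij = (i→j transitions)/(time in i); the
per-frame transition matrix is also available.  Rates outside 1–10³ s⁻¹
are flagged unreliable; no missed-event correction is applied beyond this
band.  Free-energy differences are ΔG_ij = kBT ln(k_ij/k_ji) (equal to
G_i − G_j under detailed balance), and the three-state cycle closes to
zero within estimation error on simulated paths.

## Synthetic data: what it does and does not emulate

The simulator reproduces the statistical structure the analyses assume:
Markov exchange with Bell force dependence, state-dependent WLC
extensions, protocol-driven forces, and frame-wise Gaussian noise.  It
does not emulate bead–surface hydrodynamics, camera blur/aliasing or
temporal averaging within a frame (so 100 Hz traces do not blur fast
intermediates the way a real camera does), force-calibration error,
drift, or heterogeneity between molecules.  Passing tests therefore
demonstrate correctness of the inference chain under the stated model,
not robustness to instrument artifacts absent from that model.

## Problem sizes and determinism

Statistical tests use sizes chosen to make the checked contrast several
standard errors wide while keeping the whole suite fast on one CPU:
19–25 dwells per force and 20 seeded replicates for barrier/stabilization
recovery (matching the N ≥ 19 scale of the jump experiments); 15–60 s of
1.2 kHz data for mixture and HMM checks; 120–200 synthetic experiments
for coverage properties.  Every stochastic routine takes an explicit seed
and is reproducible bit-for-bit on one platform.

## Known limitations

* The folded-axial calibration is anchor-driven; the model's absolute
  extensions inherit any bias in the pinned polymer constants, though
  state *differences* near 12–16 pN are insensitive to them.
* Bell (ν = 1) kinetics only; no Dudko–Hummer–Szabo shape corrections.
* Dwell counting applies no missed-event correction inside the reliable
  band; rates near 10³ s⁻¹ at 1.2 kHz carry a downward bias of order 10%.
* The three-state fit assumes force-independent x_i over 12–16 pN;
  compliance of the unfolded linkers makes the true coordinates weakly
  force-dependent.
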