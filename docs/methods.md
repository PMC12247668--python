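# Methods

## The circuit model

`hvcseq` implements a five-population firing-rate model of the zebra finch
premotor nucleus HVC as a continuous attractor network (CAN) whose
traveling activity bump paces the song motif. The populations are:

- **HVC_RA** (`r_RA`) and **HVC_X** (`r_X`): the two excitatory
  projection-neuron classes, `N` units each arranged along a chain. Only
  *inter*-class connections exist (no RA–RA or X–X coupling), matching the
  observed heterosynaptic motif; the mutual RA↔X loop is what sustains the
  bump.
- **Local inhibitory units** (`r_I`, `N` units): structured feedback whose
  bump lags the excitatory bump (slow time constant), so trailing
  positions are suppressed more than leading ones and the excitatory bump
  is pushed forward.
- **A global inhibitory unit** (`r_g`): fast, with a quadratic (steeper
  than excitatory) activation. It normalizes bump amplitude during song
  and flips the network into net suppression when excitation is
  synchronous — the inhibition-stabilized response that truncates the
  sequence under a homogeneous pulse.
- **A peri-song unit** (`r_ps`): receives the tonic thalamic (Uva) drive
  and inhibition from the global unit, and projects a Gaussian column onto
  the start of the HVC_RA chain. It charges up whenever the network is
  silent and reseeds the chain — the model's account of song initiation
  and of motif restart after truncation or natural completion.

The dynamics are leaky rate equations integrated with explicit Euler
(Euler–Maruyama when the rate noise is on), rates clamped at zero after
each step. Inhibitory-source terms enter with an explicit minus sign;
weight matrices store non-negative magnitudes. Structured weights are
Gaussian kernels of chain distance with width `sigma` in radians (the
`2π/N` scaling), so geometry is independent of `N`.

Two boundary factors break the chain's symmetry: local inhibition onto
the excitatory chains is enhanced near the start by `1 + c0·exp(−d²/4σ²)`
(giving the nascent bump its direction), and the mutual excitation fades
approaching a point `φ = 0.5σN/2π` positions beyond the last index by
`1 − c1·exp(−d²/4σ²)` (extinguishing the bump instead of letting it
bounce). Both factors index the postsynaptic (row) position — the stated
purpose is enhancement/fade *felt by* early/late-chain excitatory neurons
— with a switch (`index_axis="pre"`) for the other convention.

Degradation of the HVC_X output (modelling tetanus-toxin blockade)
replaces each X→RA entry by `[(1−p)W + (1−p)W·σ_W·ξ]₊` with independent
standard-normal `ξ`: a mean reduction by the degraded proportion `p` plus
multiplicative scatter, rectified at zero. Per-unit "Poisson-like" rate
noise `√(F·r)·ξ(t)` on HVC_RA (optionally HVC_X) supplies the
trial-to-trial variability that randomizes where a weakened sequence dies.

## Default parameters and how they were chosen

No published parameter table accompanies the model, so the defaults are
package defaults calibrated to reproduce the model's qualitative claims;
they are not fitted to recordings. The calibration targets were: a single
stable bump that (i) launches reliably at the chain start, (ii) traverses
the chain in ~650 ms (a zebra finch motif timescale), (iii) covers ≥95% of
the chain before the terminal fade extinguishes it, (iv) is truncated by
an intense homogeneous pulse via fast global inhibition, and (v) restarts
through the peri-song pathway identically after truncations and natural
ends.

| parameter | default | units | role |
|---|---|---|---|
| `N` | 100 | – | chain positions per population |
| `sigma` | 0.1 | rad | kernel width (≈1.6 positions); narrow enough that the terminal fade only acts in the last ~5% of the chain |
| `tau_E` | 2 | ms | excitatory time constant; with `tau_I` sets bump speed |
| `tau_I` | 24 | ms | local-inhibitory lag driving forward motion |
| `tau_g` | 0.1 | ms | global unit is effectively an instantaneous follower |
| `tau_ps` | 300 | ms | peri-song recharge; sets the ~320 ms initiation/restart latency |
| `w_X→RA`, `w_RA→X` | 1.2 | – | mutual excitation (bare loop gain ≈ 3.4) |
| `w_I→RA/X` | 0.6, `w_RA/X→I` 0.15 | – | local inhibitory loop |
| `w_RA/X→g` | 0.15, `w_g→RA/X` 1.2 | – | global amplitude control |
| `w_g→ps` | 120 | – | disinhibition level of the peri-song unit |
| `w_ps→RA` | 0.3 | – | seeding strength at the chain start |
| `c0`, `c1` | 2.0, 1.0 | – | start-enhancement / terminal-fade amplitudes |
| `I_Uva` | 1.0 | – | tonic drive to the peri-song unit |
| `noise_fano` | 0.005 | – | Fano factor of the rate noise |
| `degradation_sigma_W` | 0.05 | – | weight-scatter coefficient of the degradation transform |
| `dt` | 0.1 | ms | Euler step; halving it moves the bump's arrival time by <1% |

Three calibration decisions deserve comment.

**Bistable initiation.** The excitatory activation is threshold-linear
with a small threshold (0.02) rather than pure rectification. This makes
the silent state strongly stable and turns initiation into a barrier
crossing: as the peri-song drive ramps up (its own activation has
threshold 0.5 on the Uva-charged rate), the seed input approaches the
barrier and the rate noise decides the crossing moment. Launches are then
decisive — once over the barrier the full recurrent gain takes over — and
initiation/restart latencies carry ~10–15 ms of physiological jitter
instead of being numerically deterministic. With a zero threshold we
found the opposite regime: nucleation always happened at the margin of
viability, so launches were coin flips under noise.

**Restart equivalence.** The model's claim is that a truncation-evoked
restart uses the same silence → disinhibition → recharge → reseed pathway
as the natural motif cycle. Residues of the perturbation (pulse-driven
local inhibition at the chain start decaying with `tau_I`) would bias the
post-pulse restart late; the slow peri-song recharge (`tau_ps` = 300 ms)
keeps the shared gate closed until those residues are ~12 time constants
old, and the disinhibition level `w_g→ps` = 120 was set so that the
remaining millisecond-scale bias vanishes against the nucleation jitter.
Restart latencies after pulses and after natural ends are then
statistically indistinguishable (rank-sum, n = 20 seeds per arm, across
independent seed batches).

**Degradation scatter.** For the one figure-level value the text states
(a 20% mean reduction with scatter 0.5 in the degradation demo), the
scatter is incompatible with this network size: with a bump averaging
over only ~5–6 synaptic inputs per unit, σ_W = 0.5 gives ~20% quenched
per-unit drive inhomogeneity and no propagation at any `p` (the original
network's `N` is not stated). The package default σ_W = 0.05 preserves
the reported phenomenology — near-complete traversals at `p` = 0, random
termination positions at intermediate `p`, collapse by `p` ≈ 0.4 — and is
the value used by the sweep unless overridden.

## Readouts

The bump is tracked by the center of mass of summed excitatory rates
(argmax is noise-fragile). "Active" means total excitatory activity at or
above 10% of its running *unperturbed* maximum: steps under an external
pulse, plus a 5 ms relaxation window after it, are excluded from the
maximum (the hyper-activated amplitude is not a propagation scale), and
activity only counts once the running maximum itself is at threshold
scale, so pre-launch stirrings are not events. Sub-threshold dips shorter
than 2 ms are bridged: the fast excitation/suppression cycling while a
pulse fights the global unit is flicker, not sequence ends.

Active onsets are initiations (restarts when they follow an earlier end
at a position inside the initial region); offsets inside the terminal
region — both regions `4σN/2π` positions wide, the kernel footprint — are
natural ends, elsewhere truncations, attributed to a pulse when within
100 ms of one (generous relative to the suppression dynamics) and to the
rate noise otherwise. Sequence length is the maximum position reached in
a traversal over `N − 1`.

The degradation sweep reports, per degraded proportion, the mean over
replicates of each replicate's mean completed-traversal length. Bumps
that never escape the initial region are tallied separately as failed
starts — mirroring how failed motif starts (intro notes not leading to a
motif) are scored apart from motifs behaviourally — and traversals still
running at the simulation horizon are discarded. Each replicate draws a
fresh degradation seed (a new "day" of synaptic weights) and a fresh
noise seed.

## Behavioural statistics

The estimators operate on per-trial records (stimulation onset, truncation
flag and latency, post-truncation outcome category, restart latency) and
per-bout records. Conventions follow the behavioural analysis they
emulate: a truncation is stimulation-contingent only within 300 ms of
light onset; outcome categories (motif reset, intro notes only, call,
pause-and-continuation, or none) are exclusive within a 1 s post-event
window, with *none* an explicit fifth level; events are binned in 10%
steps of motif advancement where 100% is the motif duration minus 100 ms,
and events in the final 100 ms or during intro notes/connectors fall into
two −20–0% bins by temporal distance to the next syllable-A onset
(left-closed, like the positive bins; events with no syllable-A reference
are excluded). The normalized motif-reset probability divides the raw
reset fraction by `1 − 1/M` (M = mean motifs per bout), the probability
that a motif would be followed by another anyway; it can exceed 1.
Statistics are computed per bird first and aggregated as mean ± SEM, with
Wilson 95% intervals attached to the per-bird proportions (pooled-trial
variants sit behind the same functions).

Lesion extent is extrapolated from retrograde cell counts: control
hemispheres give a mean target/reference count ratio, the lesioned
animal's intact reference count predicts the expected target count, and
percent lesion is `100·(1 − observed/expected)`, clamped to [0, 100]
(sampling noise can push observed counts past expected; negative lesion
reads 0 — this clamping makes the estimator read ~10–13%, not 0%, on an
un-lesioned animal with 30% count noise, an upward bias worth remembering
when interpreting small lesions).

## Synthetic data

The cohort generator emulates the statistical structure of the
stimulation experiments with known ground truth: uniform stimulation
onsets across the motif, Bernoulli truncation, lognormal latencies
(positive, right-skewed; medians default to the behavioural scales of
~66 ms truncation / ~135 ms restart), multinomial outcome categories, and
shifted-geometric bout lengths (memoryless motif chaining, consistent
with the `1/M` last-motif logic). The cell-count generator draws
negative-binomial reference counts (over-dispersed, as real counts are)
and lognormal ratio noise. What the generators do **not** emulate:
acoustic structure of any kind, within-bird latency correlations, day
effects, or category probabilities that depend on stimulation phase —
so estimator-recovery tests certify the arithmetic of the pipeline, not
its behaviour under those real-data complications.

## Numerical notes and limitations

- Explicit Euler at `dt` = 0.1 ms; the global unit with `tau_g` = `dt`
  degenerates to an instantaneous follower by construction, which is the
  intended "more rapid dynamics" limit. A convergence test halves `dt`
  and requires the bump's arrival time to move by <5% (observed <1%).
- Determinism: every stochastic element (rate noise, degradation scatter,
  generators) flows from an explicit seed; identical seeds give
  bit-identical traces and tables.
- Problem sizes in the shipped analyses — `N` = 100, 1.4–2.4 s horizons,
  20 seeds per condition, 5-point degradation grids — were chosen so the
  full analysis chain re-runs in a few minutes on one core while leaving
  the Monte-Carlo intervals meaningful.
- The model is one hemisphere; interhemispheric coordination is out of
  scope, as are plasticity, spiking dynamics, and any fitting to
  electrophysiological recordings.
- The traveling pulse is only marginally robust to *quenched* weight
  inhomogeneity (see the σ_W discussion): at this `N`, per-synapse
  scatter beyond ~10% of the mean stalls propagation. Conclusions about
  degradation therefore concern the mean-reduction pathway with mild
  scatter, not strong synapse-level heterogeneity.
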