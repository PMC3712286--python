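# Methods

## Model

`thalamodbs` simulates a lumped-parameter (neural mass) model of a
thalamocortical loop containing three compartments:

* **Cortex** — pyramidal cells `P` with a Jansen-style collateral
  excitation loop (virtual excitatory subpopulation `P'`), a
  soma-targeting interneuron population `IC1` (fast GABA_A kinetics,
  gain `G_C`, time constant `tau_gc`) and a dendrite-targeting
  population `IC2` (slow kinetics, `B_C`, `tau_bc`).
* **Thalamus** — excitatory relay cells `TC` receiving cortical
  excitation (`A_Th`, `tau_aTh`) and both fast (`G_Th`, `tau_gTh`) and
  slow (`B_Th`, `tau_bTh`) reticular IPSPs; the slow time constant also
  stands in for GABA_B currents.
* **Reticular nucleus** — two GABAergic populations `Rt1` (fast IPSP on
  TC) and `Rt2` (slow IPSP on TC), both excited by cortex and thalamus
  (`A_Rt`, `tau_aRt`).

Every synaptic pathway is the second-order "pulse-to-wave" filter with
impulse response `h(t) = (W/tau_w) t exp(-t/tau_w)` (peak `W/e` at
`t = tau_w`, decay to `1/e` of the peak at `3.146 tau_w`), driven by the
presynaptic firing rate scaled by the pathway's connectivity constant
`C_src_tgt`.  Population firing rates are the static sigmoid
`S(v) = 2 e0 / (1 + exp(r (v0 - v)))` of the summed postsynaptic
potentials.  The cortical and thalamic LFP outputs are the summed PSPs on
`P` and `TC` respectively; the stimulation artifact is kept out of the
LFPs (but contributes to the membrane potentials used for the rates).

Thalamocortical relay cells target the pyramidal cells directly
(`C_TC_P`, gain `kappa(t)·A_C`) and both cortical interneuron
populations (`C_TC_IC1`, `C_TC_IC2`); the latter pathways are the
structural substrate of feed-forward inhibition (FFI) and can be ablated
with `ModelParameters.without_ffi()`.

Two Gaussian pulse-density inputs represent nonspecific drive:
`p_P ~ N(mu_P1, sigma_P1)` enters the pyramidal excitatory pathway
(kernel `A_C`, `tau_ac`, summed with the collateral drive) and
`p_TC ~ N(mu_P2, sigma_P2)` the thalamic one (kernel `A_Th`,
`tau_aTh`).  The printed values of the noise SDs are typographically
ambiguous ("20.v6"/"35.v6"); this package reads them as the decimals
20.6 and 35.6 per sample at the 512 Hz output rate.  The alternative
reading 20·sqrt(6) ≈ 49 / 35·sqrt(6) ≈ 85.7 makes the cortical
compartment an autonomous noise-driven delta spiker, in which case the
epileptiform rhythm no longer depends on the thalamocortical loop and no
thalamic manipulation (depression, FFI, relay silencing) can modulate
it; with the decimal reading the rhythm is loop-generated, which is the
regime the mechanism analyses require.  Per-step noise is scaled by
`1/sqrt(512·dt)` so its spectral density does not depend on the
integration step.

### Short-term depression (STD)

The TC→P gain is `kappa(t)·A_C` with `kappa ∈ [0.6, 1]`.  The TC firing
rate is low-pass filtered (10 Hz cutoff, causal); whenever the filtered
rate crosses the threshold `eta = 0.8 s^-1` upward, `kappa` decays as
`kappa_eta · exp(-(t - t_eta)/tau)` with `tau = 8 s`, where
`(t_eta, kappa_eta)` anchor the crossing.  The decay stays active until
0.45 s after the last suprathreshold sample (a sliding envelope, so a
sustained drive produces one continuous exponential decay down to the
hard floor 0.6 — a maximal EPSP drop of 40 %).  Outside active episodes
`kappa` recovers toward 1 with the same time constant; the recovery rule
is this package's choice (the depression is transient, so some recovery
is mandatory, and reusing `tau` adds no new parameter).  The low-pass is
a single-pole filter by default (`StdParams.lp_order = 1`; a 2nd-order
Butterworth is available): the single-pole response is fast enough to
register the few-millisecond stimulus-locked relay bursts that engage
depression at low-frequency stimulation, while still averaging fast
drive below threshold — with the Butterworth realization the filtered
bursts never reach `eta` and depression cannot engage at any stimulation
frequency.

### Stimulation

DBS is a train of monophasic 1 ms depolarizing pulses at `f_s`
(0–150 Hz), low-pass filtered by a first-order filter with the average
repolarization time 4.8 ms (unit DC gain), and added to the membrane
potentials of TC, Rt1, Rt2 with weights `S_TC = 5`, `S_Rt1 = S_Rt2 = 4`.
Cortical populations receive nothing.  The absolute membrane scale of
the λE depolarization is not fixed by the published parameterization
(the filtered unit pulse only reaches 0.19 at the filter output); the
conversion is the model constant `StimProtocol.drive_gain` (default 12),
calibrated once so that the simulated regime transitions occur at the
published frequencies: depression engages and the delta rhythm is
suppressed at 2 Hz, the no-stimulation run keeps `kappa ≈ 1`, and the
relay cells are silenced (`HtoLR = 0`) above 70 Hz.  `u_stim` is linear
in the pulse amplitude `A_fs` and clamped to zero outside
`[t_on, t_off + 5·tau_rep]`.

### Integration

Fixed-step classical Runge–Kutta (RK4) on the 13 second-order pathway
filters, default `dt = 1/4096 s`, outputs stored at 512 Hz; noise, the
stimulation drive and `kappa` are held constant within a step; all
filter states start at zero and the first 2 s are discarded before any
analysis.  The integrator is numba-compiled (a 20 s run takes ~0.1 s),
deterministic given the seed, and verified against the analytic kernel
step response to <1 % and against step-halving to <2 % RMS change.
Divergence (non-finite state) raises `SimulationDiverged` with the
failure time.

## Signal characterization

Five-second LFP segments are demeaned (AC-coupling convention) and
decomposed by greedy matching pursuit over a multi-scale dictionary:
Gabor atoms (Gaussian-windowed cosines, window SD = scale/8) at ten
log-spaced durations 0.125–5 s — whether the published ten scales were
linearly or logarithmically spaced is unstated; log spacing matches the
dyadic tradition of multiscale dictionaries — with frequencies on the
`1/scale` grid up to 128 Hz and positions on a `scale/2` hop grid;
full-segment Fourier atoms; and single-sample Dirac atoms.  Inner
products over one scale are computed with a windowed FFT and the optimal
amplitude/phase of the real atom from the 2×2 Gram system of the
cosine/sine pair, so recovery of a dictionary atom is exact in one
iteration.  Atom energies are measured residual-energy drops, which
makes `sum(energies) + residual = total` an identity.  The default
stopping rule is 200 atoms or 5 % residual energy, whichever comes
first; the simulation pipelines use 60 atoms (the band distribution is
stable well before that depth and it keeps the full experiments fast).

Atoms are binned by central frequency into the nine classical bands
(delta1 [0–1.9), delta2 [1.9–3.4), theta1 [3.4–5.4), theta2 [5.4–7.4),
alpha1 [7.4–10), alpha2 [10–12), beta1 [12–18), beta2 [18–24),
gamma [24–128] Hz; band edges belong to the higher band).  Dirac atoms
carry no central frequency and are excluded from the band energies
(their count is reported).  The 9-D feature vector is the per-band
energy normalized by the total band-assignable energy, so it sums to 1
and is invariant to amplitude scaling; "time-averaged atom energy"
normalizations cancel in this ratio.  The fixed 3-D projection
`[e(delta2)+e(theta1), e(theta2)+e(alpha1)+e(alpha2)+e(beta1),
e(beta2)+e(gamma)]` is for display; clustering operates on the 9-D
vectors (3-D available behind a flag).

## Clustering, fitting, firing analysis

* **Mahalanobis k-means** — Lloyd iterations in the space whitened by
  the pooled covariance of all vectors (ridge-regularized: band
  fractions sum to one, so the covariance is always rank-deficient),
  25 seeded random restarts, best inertia kept.  Note the metric
  amplifies directions without structure to unit variance, so clusters
  separated only within a low-dimensional subspace of a high-dimensional
  noisy space can become inseparable — a property of the metric, not of
  the implementation.
* **Brute-force excitability fit** — exhaustive search of
  `(A_C, B_C, G_C)` (default grid 2–8 × 5–50 × 5–25, steps 0.5/3/1.5,
  bracketing both presets) minimizing the Euclidean distance between the
  target feature vector and the seed-matched average model feature
  vector; diverged grid points are excluded from the argmin.
* **Firing regimes** — `Lambda` is the median of the no-stimulation TC
  rate (computed once per parameter set and reused at every frequency);
  `HtoLR = Delta2/Delta1` with `Delta2`/`Delta1` the time above/below
  `Lambda` (ties belong to neither; `Delta1 = 0` yields an infinity
  sentinel).  The frequency sweep pools up/down times across seeds
  before forming the ratio; the jump frequency is the midpoint of the
  largest single-step increase (ties toward lower frequency) and the
  zero band the lowest frequency after which the ratio stays zero.
* **Sensitivity** — the seven gains `(A_C, B_C, G_C, A_Th, B_Th, G_Th,
  A_Rt)` are multiplied by independent uniform factors in
  `[1-zeta, 1+zeta]`; each perturbed model is simulated per condition
  with the same noise seed as its unperturbed reference (paired design,
  so the identity perturbation is preserved by construction) and
  assigned to the nearest reference centroid; assignment within the
  condition's regime group ({NS, IFS}, {LFS}, {HFS}) counts as
  preserved.

## What the synthetic data does and does not show

All testing uses model-generated signals plus a fixture generator that
assembles known dictionary atoms with seeded Gaussian noise.  Fixtures
validate the decomposition machinery exactly (known ground truth);
simulated LFPs exercise the full pipeline under the study conditions but
cannot stand in for clinical recordings: results against patient iEEG
(the optimized triplet {6, 14, 16.5} as a fit to real signals, the
real-data cluster geometry) are out of reach by construction.

## Known limitations

With the published parameter table and the conventions above, the
implementation reproduces the no-stimulation pathological rhythm
(delta-dominant spiking generated by the thalamocortical loop, absent in
the normal preset), depression-plus-FFI suppression at 2 Hz, and
complete relay silencing above 70 Hz.  Three published behaviors are not
reproduced, and the acceptance tests that assert them fail by design
rather than being weakened:

* **No thalamic reinforcement at intermediate frequencies.**  At the
  table's operating point the relay cells sit at a low rate
  (~0.13 s^-1) and the marginal reticular inhibition per unit of
  stimulation drive (`G_Th·tau_gTh·C_Rt1_TC + B_Th·tau_bTh·C_Rt2_TC ≈
  12.6 mV·s` against `S_TC = 5`) outweighs the direct depolarization at
  every frequency, for every stimulation-amplitude convention scanned.
  The 50 Hz condition is therefore suppressed like early high-frequency
  stimulation instead of resembling the no-stimulation state, the
  high-to-low ratio has no abrupt rise near 22 Hz, and removing the slow
  reticular depolarization at 50 Hz restores rather than abolishes the
  rhythm.
* **Regime clustering.**  The normalized band-energy vectors of the
  suppressed conditions overlap with the no-stimulation vectors
  (within-condition scatter exceeds centroid separation), so the strict
  three-group partition of the six conditions is not reliably recovered.
* **Perturbation robustness.**  The pathological point lies at the
  ignition bifurcation of the loop rhythm (0.95·A_C is silent, 1.0·A_C
  oscillates, with no hysteresis), so ±10–20 % excitability perturbation
  destroys the rhythm in about half the draws and the published ±20 %
  robustness is not attained.

Problem sizes used by the packaged analyses (20 s sweep segments with
3 seeds, 5 s feature segments, 60-atom decompositions, 20 sensitivity
draws) are the package's standard configuration; every driver accepts
larger values.
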