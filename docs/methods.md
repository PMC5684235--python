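# Methods

This note documents the models, estimators, defaults and numerical choices
behind `if2fret`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Kinetic model

A tethered 30S IC is a two-state continuous-time Markov chain: *free*
(no IF2) and *bound* (one IF2). Binding is pseudo-first-order at
`k_on = k_a·[IF2]` with free IF2 in solution at 25 nM (the imaging-buffer
concentration); dissociation is first-order at `k_d`. Dwell times are
exponential; the initial state is drawn from the equilibrium occupancy
`k_on/(k_on + k_d)`, which matches a movie started at an arbitrary time and
leaves the counting estimator's expectation unchanged. With `k_a = 0` a
trajectory is a single free dwell.

Each binding event draws one bound substate from the configured weights and
an ideal efficiency from a Gaussian around the substate mean (clipped to
[0, 1]); the substate is held for the whole dwell. An intra-dwell switching
rate is exposed but defaults to 0: at 0.1 s frames a position that
interconverts faster than the frame time is indistinguishable from a fixed
time-averaged position, so nothing in the analysis could resolve the
difference.

## Photophysics in the generator

* **Cy3 (donor, on the P-site tRNA)** bleaches on a single per-trace
  exponential clock from t = 0; after it, both channels drop to zero and
  the analysis truncates the trace.
* **Cy5 (acceptor, on IF2)** is carried by the ligand, and IF2 exchanges
  with solution: every binding event arrives with a fresh acceptor.  The
  default bleach model therefore restarts the Cy5 clock at each dwell
  entry; a bleach inside a dwell zeroes FRET for the remainder of that
  dwell only.  A per-trace Cy5 clock (one shared acceptor) is available as
  `cy5_bleach_mode="per_trace"`, but with a single clock the final-dwell
  exclusion cannot remove the spurious bleach-induced exits: every
  apparent dissociation after the bleach is terminal, and either counting
  convention then leaves the dissociation-rate bias in place.  The
  per-event model is both the realistic one and the one under which the
  published correction behaves as described.
* Bleach clocks tick regardless of excitation state. Real Cy5 bleaching is
  FRET-gated (the acceptor is only excited while FRET occurs); this
  simplification slightly overstates bleaching during free dwells, which
  is inconsequential because a free-state Cy5 bleach changes nothing
  observable.

Rendering uses exact dwell-time-weighted averaging of the piecewise-
constant ideal efficiency within each frame, so transition frames land at
intermediate values as in real camera data. Pre-noise, pre-bleach channel
sums equal the configured total intensity exactly; 7% of the donor signal
is added to the acceptor channel (bleed-through) before adding independent
zero-mean Gaussian noise per channel.

### Defaults and units

| parameter | default | meaning |
|---|---|---|
| `frame_time` | 0.1 s | acquisition interval |
| `if2_conc` | 0.025 µM | free labeled IF2 |
| `n_frames` | 1800 (180 s) | observation window |
| `n_traces`, `n_replicates` | 150, 3 | dataset size |
| `total_intensity` | 1000 a.u. | summed pre-noise signal |
| `noise_sd` | 80 a.u. (≈0.08 E) | per-channel additive noise |
| `bleedthrough` | 0.07 | donor→acceptor crosstalk |
| `kb_cy3`, `kb_cy5` | 0.005, 0.01 s⁻¹ | bleach rates |
| substate width | 0.02 (bundled conditions) | per-dwell conformational spread |

The window length matters: the transition-matrix estimator with final-dwell
exclusion needs the window to be long compared with the slowest mean dwell
(24 s bound, 20 s free for the wild-type GTP condition). At 60 s windows
the censored-exposure distortion biases `k_a` by tens of percent whatever
the correction; at 180 s (about 7× the longest dwell) a ground-truth-label
study shows both rates recovered within ~2% (8000-trace oracle run:
`k_a` 2.03 vs 2.0, `k_d` 0.0414 vs 0.041). 180 s is therefore the default.

Bound-substate widths are 0.02 in the bundled conditions because the
observed peak widths (~0.08 E units) are dominated by per-frame measurement
noise, which the generator already supplies at the channel level; stacking
a large dwell-level width on top would make the simulated histograms
broader than the published ones and the two-peak conditions unresolvable.

## Trajectory processing

Order: bleed-through subtraction → photobleach detection → baseline
subtraction → selection → efficiency. Bleed-through and baseline are both
linear shifts and commute on noiseless data; the pipeline fixes and records
this order.

Photobleach detection scans windowed-mean drops (window 5 frames); a step
qualifies only if its drop exceeds 5× the robust noise sd (1.4826×MAD of
first differences, per channel) *and* the post-step segment sits at the
channel's dark level. The dark level is the minimum rolling mean of the
channel — not a low percentile, which for a mostly-bright channel lands
inside the bright cluster and would let brief dark excursions masquerade as
bleaches. The Cy3 bleach is sought on the summed channel (FRET-independent
while the donor lives) and requires both channels dark afterwards. A
terminal acceptor drop is physically indistinguishable from a final
dissociation; the Cy5 candidate is used only for curation and baselines,
never for kinetics.

Baselines are medians of the segment where the channel is genuinely dark
(donor: after Cy3 bleach; acceptor: after the later bleach). Without such a
segment the channel is left unshifted — an offset estimated from a
bleach-free trace would subtract real signal and bias E upward by ~0.03 at
the default noise. (The generator produces offset-free data, so this
default is also the correct-by-construction choice there.)

Selection accepts a trace iff (a) the Pearson correlation of donor vs.
acceptor frame-to-frame changes over FRET-active pairs is ≤ −0.3, and
(b) a single-step bleach is detected or the pre-bleach total intensity
falls in the single-fluorophore band (0.5–1.5× nominal). A frame pair is
FRET-active when both channels move by >3× their difference noise sd; with
a single active pair its sign decides, and with none the correlation over
all differences (≈0 for signal-free traces) rejects the trace. Traces with
no observable transition are thus rejected, as a human curator would —
this is precisely why the donor-bleach (padding) correction measures its
event fractions on the *pre-selection* population.

Efficiency is `acceptor/(acceptor+donor)` per frame up to the Cy3 bleach;
frames whose summed intensity falls below 10% of the nominal total are
masked invalid (NaN), never divided, clamped or interpolated.

## Idealization

Per trace, Gaussian-emission HMMs with 1–3 states are fit by EM from five
deterministic quantile-based seedings (best likelihood kept; convergence at
ΔlogL < 1e-5, ≤200 iterations, emission sd floored at 1e-3); the state
count minimizes BIC with `(K−1) + K(K−1) + 2K` parameters. Masked frames
contribute a unit emission likelihood, so the chain bridges them through
the transition structure. Decoding is Viterbi; optimality is verified in
the tests against exhaustive enumeration on short traces, and the whole fit
is cross-checked against hmmlearn on complete traces. States with mean
`E ≤ 0.2` are free — the tie at exactly 0.2 is free, per the inclusive
definition of the zero-FRET state.

## Rate estimation and corrections

Within a replicate, frame-pair counts are pooled over traces before
normalization (one dataset-level transition matrix), then
`k_a = −ln(p_FF)/([IF2]·t)` and `k_d = −ln(p_BB)/t`, with `[IF2]` in µM so
`k_a` emerges in µM⁻¹s⁻¹; `K_d = k_d/k_a` is reported in nM and the
identity `K_d·k_a = k_d` holds to machine precision per replicate. Zero
rows are flagged and the corresponding rate reported unavailable. Replicate
aggregation is mean ± SE (sd/√n).

**Acceptor-bleach correction.** A Cy5 bleach while bound mimics a
dissociation and leaves a zero-FRET tail. Excluding each trajectory's final
free dwell removes that tail. The exclusion removes the *entire* dwell,
including the bound→free transition entering it: that entering transition
is exactly the spurious exit when the dwell is bleach-induced, and keeping
it (available as `keep_entry_transition=True`) demonstrably leaves the
`k_d` bias in place. The cost is that genuinely final dissociations lose
their exit too, which is negligible when the window is long enough that
most real dissociations are followed by a visible rebinding.

**Donor-bleach correction.** For rare binders, traces whose donor bleaches
before the first binding event show no transitions and fail selection,
removing free-state exposure and inflating `k_a`. The correction computes
`Cf = (%capable − %observed)/%observed`, where %capable is the
at-least-one-event fraction in a readily binding reference condition and
%observed the same fraction in the full processed population of the
condition under analysis, and appends `round(n_observed_with_event × Cf)`
noise-free all-zero trajectories of the average observed length (only
their free→free dwell mass matters). Padding restores the estimate within
3 replicate SE in its validity regime (see limitations).

## Distributions and interpretation

Bound-frame samples pool all valid frames decoded bound, dropping one
frame at each dwell edge (transition-straddling frames carry time-averaged
intermediate values that belong to neither state; `trim_edges=0` restores
strict all-frame pooling). Mixtures of 1–2 Gaussians are fit on raw
samples (never on binned data) with BIC selection; because overlapping
components make the likelihood surface multimodal, each fit takes the best
of k-means++ and three quantile-spread initializations under tight
convergence (tol 1e-6), all deterministic. Replicate fits are reconciled
to a consensus component count and aggregated as mean ± SE with components
matched by descending mean.

The intensity-ratio transform makes frame-level E samples mildly skewed
(skewness ≈ 0.4 at the default noise), and with tens of thousands of
frames BIC resolves that skew as a spurious extra Gaussian. The pipeline's
comparison report therefore fits at the published component count; the
BIC route is exercised where emissions are genuinely Gaussian (draw-level
data, as in the acceptance checks).

Condition comparisons use a two-sided pooled-variance two-sample t-test on
replicate-level means (the test actually used in the original analysis is
unnamed; p values are not acceptance quantities). Post-synchronized
surfaces re-index each binding event from its start frame and accumulate
(lag, E-bin) counts, bin width 0.02.

Distances use `d = R0(1/E − 1)^{1/6}` with `R0 = 55 Å` and the isotropic
κ² assumption adopted unchanged; E = 0 or 1 is a domain error, and
rounding to integer Å is applied only in paper-comparison mode.
Occupancies default to the depletion-corrected two-component equilibrium
(smaller root of `B² − B(R+L+K_d) + RL = 0`) at 600 nM IF2 and 360 nM
30S IC — the subunit-joining assay concentrations; the uncorrected
`θ = L/(L+K_d)` is available as `model="simple"` and is an upper bound on
the depletion result.

## Problem sizes

The acceptance script runs the wild-type GTP recovery at the full study
size (3 replicates × 150 traces × 1800 frames, ~30 s on one CPU) and the
mixture recovery at 3 × 5000 samples. The test suite uses reduced sizes
chosen for statistical headroom at desk scale: 3 × 60 traces for the
pipeline recovery (tolerances scale with the replicate SE), 100–500 traces
for oracle-label estimator properties, 25–30 traces for HMM selection and
dwell-count studies, and 10³–10⁴ dwells for distributional checks.

## Known limitations

* **Sub-frame dwells are invisible.** At 0.1 s frames, conditions with
  `k_d ≥ ~1 s⁻¹` (GDP- and pseudo-complex rows) have a substantial
  fraction of bound dwells shorter than ~2 frames that no idealization can
  count; `k_a` is correspondingly underestimated and the padding
  correction, sized from an event-capable reference, then overcorrects.
  The quantitative recovery claims are therefore made for the slow
  wild-type GTP row, and the corrections are validated in regimes where
  dwells span several frames. This is a physical limit of the frame time,
  not of the estimator.
* **The generator's noise is additive, homoscedastic Gaussian** per
  channel — no shot-noise scaling, blinking, spectral fluctuations or
  anisotropy effects. Passing tests show the analysis recovers the
  generating parameters under this noise model; they cannot certify
  robustness to noise structure the generator does not produce.
* **Selection emulates curation only statistically.** Real curation
  involves judgment on correlated artifacts (stage drift, multiple
  tethers) that the generator does not synthesize.
* **The free-state efficiency is near zero by construction**; conditions
  where the free state carries genuine low FRET would stress the fixed
  0.2 threshold in ways not exercised here.
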