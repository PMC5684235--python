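# if2fret

Simulation and analysis of single-molecule FRET trajectories reporting on
the binding and conformational dynamics of translation initiation factor 2
(IF2) on bacterial 30S initiation complexes (30S ICs).

## The scientific problem

IF2 selects the initiator fMet-tRNA^fMet into the ribosomal P site and
accelerates 50S subunit joining, contingent on a GTP- and
fMet-tRNA^fMet^-dependent conformational switch. In the underlying
experiment, a Cy5 acceptor on IF2 domain IV and a Cy3 donor on the P-site
tRNA produce an smFRET signal from surface-tethered 30S ICs imaged by TIRF
microscopy at 0.1 s/frame. Each trajectory shows reversible excursions
between a zero-FRET (IF2-free) state and one or more non-zero-FRET
(IF2-bound) states, from which two kinds of quantities follow:

* **binding kinetics** — the association rate constant `k_a`, dissociation
  rate constant `k_d`, and equilibrium constant `K_d = k_d/k_a` of the
  IF2–30S IC interaction under eight nucleotide/tRNA conditions;
* **conformational subpopulations** — the bound-state FRET-efficiency
  distribution and its one- or two-Gaussian decomposition, interpreted as
  dye–dye distances through the Förster relation.

No raw trajectories were deposited with the study, so this package includes
a first-class synthetic-trajectory generator with the same statistical
structure, letting the entire analysis chain be exercised and validated
against known ground truth.

## The method

1. **Simulation** — a continuous-time two-state Markov path per tethered
   complex (free→bound at `k_a·[IF2]`, bound→free at `k_d`; [IF2] = 25 nM),
   one Gaussian-distributed FRET substate per binding event, single-step
   Cy3/Cy5 photobleaching (the acceptor clock restarts at each binding
   event because each event brings a fresh labeled IF2), exact
   dwell-time-weighted frame averaging, 7% donor→acceptor bleed-through and
   additive channel noise.
2. **Processing** — bleed-through subtraction, change-point photobleach
   detection, dark-segment baseline correction, curation by
   donor/acceptor anti-correlation plus single-step bleaching or
   single-fluorophore intensities, and
   `E_FRET = I_Cy5 / (I_Cy5 + I_Cy3)` truncated at the Cy3 bleach.
3. **Idealization** — a per-trace Gaussian-emission HMM (EM with
   deterministic quantile seedings, state count by BIC, Viterbi decoding);
   states with mean `E ≤ 0.2` are macro-labeled *free*, the rest *bound*.
4. **Kinetics** — frame-to-frame transitions pooled into a 2×2 counting
   matrix `n_ij`, row-normalized to probabilities `p_ij`, converted by

       k_a = −ln(p_free→free) / ([IF2]·t)        k_d = −ln(p_bound→bound) / t

   with `t = 0.1 s`. Acceptor-bleach bias is corrected by excluding each
   trajectory's final zero-FRET dwell; donor-bleach bias on rare binders by
   padding with simulated zero-FRET trajectories sized by
   `Cf = (%capable − %observed)/%observed`. Three replicate data sets give
   mean ± SE.
5. **Distributions & interpretation** — pooled bound-frame histograms,
   BIC-selected Gaussian mixtures with replicate errors, post-synchronized
   population surfaces, distances `d = R0·(1/E − 1)^(1/6)` with
   `R0 = 55 Å`, and equilibrium occupancies `θ` from `K_d` with ligand
   depletion (`B² − B(R+L+K_d) + RL = 0`).

## Worked example

Recover the wild-type IF2(GTP) kinetics from synthetic data (3 replicates ×
30 traces × 180 s):

```python
import if2fret as f

cond = f.bundled_conditions()["wT"]          # 30S IC_wT parameters
res = f.run_condition(cond, seed=1, sim_overrides={"n_traces": 30},
                      mixture_components=1)
est = res.kinetics
print(f"k_a = {est.k_a:.2f} +/- {est.k_a_se:.2f} uM^-1 s^-1")
print(f"k_d = {est.k_d:.4f} +/- {est.k_d_se:.4f} s^-1")
print(f"K_d = {est.kd_nM:.1f} +/- {est.kd_nM_se:.1f} nM")
print(f"<E_FRET> = {res.mixture.means[0]:.3f}")
```

prints

```
k_a = 2.04 +/- 0.08 uM^-1 s^-1
k_d = 0.0474 +/- 0.0024 s^-1
K_d = 23.2 +/- 0.5 nM
<E_FRET> = 0.873
```

i.e. the generating values (2.0 µM⁻¹s⁻¹, 0.041 s⁻¹, ~21 nM, 0.87) are
recovered through the full corrected pipeline; the mean bound-state
efficiency of 0.87 corresponds to a ~40 Å dye separation
(`f.efret_to_distance(0.87)`).

The same stages are available as a CLI:

```bash
if2fret simulate --out raw/ --seed 1
if2fret process --in raw/ --out eff/
if2fret idealize --in eff/ --out ideal/
if2fret kinetics --in ideal/ --exclude-final-free-dwell
if2fret distances --efret 0.87,0.67
if2fret occupancy --kd 2328
if2fret run --out report.json --n-traces 30
```

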