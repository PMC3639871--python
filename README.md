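# clgfnet

Analysis pipeline linking beta/gamma-band oscillation abnormalities and
phase synchrony in multichannel neural recordings to the abundance of
**coupled local-and-global feedback (CLGF) circuits** — a hub sensor
holding both a long-delay inter-regional positive feedback and a
short-delay intra-regional one — exercised end-to-end on synthetic
two-group cohorts with known ground truth.

It is aimed at researchers studying resting-state MEG/EEG synchrony
abnormalities (e.g. in schizophrenia, where patients show reduced gamma
power, increased beta phase locking, and sparser local feedback
circuitry than controls) who want the full chain — from raw
multichannel signals to group statistics — as tested, reusable code.

## What it computes

Given channels × samples recordings (102 magnetometers at 1000 Hz over
80 s at full scale):

1. **Spectral power** — complex Morlet transform (width 7, 13–80 Hz),
   channel-averaged magnitude maps, beta [13,30] / gamma (30,80] band
   powers and mean spectra.
2. **Beta–gamma switching** — a latched binary state that triggers when
   dβ/dt < 0, dγ/dt > 0 and γ > β simultaneously and holds while γ > β;
   summarised per subject as total duration and event count.
3. **Phase synchrony** — zero-phase band-pass, Hilbert phases, and the
   phase-locking value γₙₘ = √(⟨sin φₙₘ⟩² + ⟨cos φₙₘ⟩²) in 1000 ms
   windows slid by 200 ms, averaged over windows and channel pairs;
   edge-wise group topography at p < 0.01 and p < 0.001.
4. **Feedback networks** — two-sided (causal + non-causal) impulse
   responses per channel pair by GCV-ridge regression; a pair is a
   feedback edge iff both the positive-lag and negative-lag peaks beat
   a circular time-shift surrogate null, with the sign read off the
   dominant peaks; edges must recur identically in four non-overlapping
   windows.
5. **Motif census** — edges classified local/global by a 10-subregion
   map; CLGF instances counted as Σ_hub (global degree × local degree)
   over positive edges, verified against exhaustive triple enumeration.
6. **Wilson–Cowan circuits** — delayed excitatory/inhibitory oscillator
   networks (method-of-steps RK4, cubic history interpolation, numba):
   single-oscillator frequency regime, and the three-node CLGF circuit
   whose local coupling sweep switches the rhythm from beta-dominant
   (global 21 ms loop) to gamma-dominant (local 6 ms loop).
7. **Group statistics** — Welch t-tests, Pearson correlations of CLGF
   counts with (synthetic) clinical scores, chi-square for 2×2 tables.

The synthetic-data module generates cohorts whose ground-truth feedback
topologies have *exact* requested censuses, with control-like subjects
richer in local feedbacks and CLGF motifs than patient-like subjects,
and a negative-symptom score generated with a known negative
correlation to the CLGF count — so every stage is testable by
parameter recovery.  See `docs/methods.md` for models, assumptions and
numerical choices.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a demo
cohort (6 control-like + 6 patient-like subjects, 20 channels, 8 s,
seed 7), writing tables under `results/`:

```
cd analysis
python 01_simulate_cohort.py
python 02_band_power_switching.py
python 03_phase_synchrony.py
python 04_feedback_networks.py
python 05_wilson_cowan_sweep.py
python 06_group_report.py
```

Script 04 prints, for this cohort:

```
detected vs true positive-feedback count: r = 0.70 (p = 0.0108)
positive feedbacks: control 4.8 vs patient 3.7 (t = 1.01, p = 0.344)
CLGF motifs (detected): control 0.3 vs patient 0.0 (t = 1.58, p = 0.175)
```

i.e. the inferred networks track each subject's planted feedback count
(r = 0.70 across 12 subjects), while at this miniature scale the group
contrasts point the right way without reaching significance.  Script 06
assembles the cohort table and reports the full surface; the
ground-truth CLGF counts separate the groups (control 1.83 vs patient
0.67, t = 2.57, p = 0.028) and correlate with the synthetic
negative-symptom score (r = −0.92) — with only six patients the
*independent* positive/general scales can show large spurious
correlations, which this seed illustrates.  Script 05 maps the circuit
regimes:

```
single oscillator: oscillatory for P in [1.0, 2.6], 63-148 Hz
delays (21,6) ms: gamma/beta crossover at local strength 3.0
```

with summed beta power dominant at local strengths 0–2.5 (~20 Hz
round-trip rhythm of the 21 ms global loop) and gamma power abruptly
dominant at strength 3 (~59 Hz local-loop rhythm) — the mechanism by
which losing CLGF circuits shifts a network toward beta-dominated,
hyper-synchronous dynamics.

A configured end-to-end run is also available as a console command:
`clgfnet run --config docs/run_example.yaml --seed 1 --out results/run1`
(the example config is annotated; omitted keys default to the full
study conditions).

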