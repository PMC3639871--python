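# Methods

`clgfnet` reproduces, on synthetic cohorts with known ground truth, an
analysis chain linking beta/gamma-band oscillation abnormalities and
phase synchrony to the abundance of *coupled local-and-global feedback*
(CLGF) circuits in a cortical sensor network, together with the
delayed Wilson–Cowan simulations that motivate the link.  This note
documents the models, the numerical choices, and the places where the
design was genuinely open.

## Signal model and synthetic cohorts

Every synthetic channel is the excitatory output E(t) of one
Wilson–Cowan oscillator (see below), emulating one MEG magnetometer of
a 102-sensor array sampled at 1000 Hz over 80 s.  The full-scale
defaults of `CohortSpec` are those study conditions; analyses and tests
run scaled-down cohorts (6–10 subjects per group, 10–20 channels,
2–10 s), which changes statistical power but none of the contrasts
being tested.

A subject's ground truth is a signed feedback topology over the
channels:

* **Region map.** Channels are partitioned into 10 contiguous blocks
  labelled prefrontal/middle-frontal/temporal/parietal/occipital ×
  left/right (10 or 11 channels each at full scale).  The true
  sensor-to-region assignment of a physical helmet is a user input for
  real data; the generated map is its synthetic counterpart.  For small
  channel counts the number of regions shrinks so each region keeps at
  least two channels.
* **Edges.** A feedback edge is an unordered channel pair with a sign,
  a conduction lag (local edges 6–10 ms, global 15–25 ms, uniform), and
  a scope label (local = both endpoints in one region).  Topologies are
  *constructed to exact requested censuses*: CLGF motifs are planted as
  hub channels carrying one global feedback plus a batch of local
  feedbacks; remaining local (global) edges are placed on channels
  without global (local) edges so no unintended motifs arise.  The
  construction is verified against the census module on every build.
* **Archetypes.** Control-like subjects draw abundances around 8 local
  / 6 global / 6 CLGF; patient-like around 4 / 5 / 2 (sd 1 each,
  rounded, clipped at feasibility).  The patient archetype has strictly
  fewer local feedbacks and CLGF motifs by contract, while the global
  count barely differs — the group contrast the package is designed to
  recover.  Infeasible draws on small layouts are redrawn
  deterministically.
* **Dynamics.** Each edge becomes a reciprocal pair of delayed
  excitatory couplings.  Per-edge weight is `coupling_strength /
  sqrt(degree)` of the target (default scale 2.0), and the constant
  drive of coupled channels is reduced by 0.15 per unit incoming weight
  — a synaptic-scaling-like compensation that keeps multi-edge hubs out
  of the runaway high-activity regime while individual edges stay
  strong enough to be identified.  Channel drives are jittered
  uniformly in [1.6, 2.3] so intrinsic frequencies differ (~83–135 Hz)
  and uncoupled channels do not phase-lock.  Broadband white noise
  (sd 0.3, held per 0.05 ms step) enters the excitatory input of every
  oscillator: it gives the dynamics the broadband content that makes
  directed transfer identifiable, and is the main respect in which the
  generator goes beyond the deterministic circuit simulations.
  Measurement noise (white, sd 0.5 × per-channel signal sd) is added on
  top.  The first 500 ms are discarded.
* **Clinical scores.** The patient group's synthetic negative-symptom
  score is `mean + r·sd·(C − μ_C)/σ_C + sqrt(1−r²)·sd·z` with C the
  subject's CLGF count and (μ_C, σ_C) the *exact* moments of the
  integer count distribution (computed from the normal CDF), so the
  generating correlation equals `score_r` (default −0.5) exactly.
  Positive and general scores are independent noise; with very small
  groups their sample correlations with the count are unstable, which
  the demo cohort (n = 6 patients) illustrates.

What passing tests on these cohorts shows: the analysis chain recovers
the structures the generator planted, at realistic noise levels, with
the stated specificity.  What it cannot show: behaviour under real MEG
artifacts (eye/muscle), volume conduction and field spread, 1/f
background, non-stationarity across 80 s, or head-position effects —
none of which the generator emulates.

## Spectral analysis

Complex Morlet wavelets, width 7 cycles (σ_t = 7/2πf), on a 13–80 Hz
grid in 1 Hz steps (1 Hz resolves the 30/31 Hz band boundary).
Kernels are discretely L2-normalised; only magnitudes |W| are used and
all comparisons are relative, so the normalisation constant is a fixed
documented convention, not a physical claim.  "Power" means |W|;
channel-averaged maps are the mean over channels of |W| (never
|mean W|).  Band powers are band means of the map rows: beta = [13, 30]
(closed), gamma = (30, 80] (open at 30), a disjoint partition chosen
because the source material prints both 30 and 31 Hz as the gamma
floor.  The first and last 3σ_t of the slowest wavelet (~257 ms at
13 Hz, 1000 Hz) are flagged edge-contaminated and excluded from all
scalar (time-averaged) summaries.

## Beta–gamma switching

On the 1 ms band-power grid the switching indicator triggers when,
simultaneously, dβ/dt < 0, dγ/dt > 0 and γ − β > 0 (derivatives as
backward first differences; the first sample cannot trigger), then
latches at 1 while γ > β strictly — a tie releases.  A subject is
summarised by total switched duration (ms) and the count of 0→1
transitions.  The production implementation segments γ>β runs and
lights each run from its first trigger; tests hold it equal to a
literal per-step state machine on thousands of random traces.

## Phase synchronisation

Band-pass filtering is zero-phase FIR (firwin, odd length spanning 3
cycles of the low cutoff, applied forward–backward), phases come from
the analytic signal, and the phase-locking value of a channel pair is
the resultant length of the within-window phase differences —
`sqrt(<sin φ>² + <cos φ>²)` — over 1000 ms windows slid by 200 ms and
averaged over windows; windows truncated by the record end are dropped.
The subject-level scalar is the mean over all distinct channel pairs.
For scalar summaries that must be exact (e.g. the PLV of a constant
phase relation), the filter/Hilbert edge margin (twice the FIR length)
is excluded before windowing; per the source procedure this exclusion
is off by default and exposed as `drop_edges`/`edge_ms`.  Group
topography compares each pair across subjects with a two-tailed Welch
t-test at raw thresholds 0.01 and 0.001 — deliberately no
multiple-testing correction, mirroring the procedure being reproduced;
an FDR step could be added downstream but is out of scope.

## Feedback identification from two-sided impulse responses

The exact estimator behind the original feedback-identification
procedure is not publicly specified; this module fixes one concrete,
defensible realisation and validates it by ground-truth recovery, *not*
by agreement with any published edge count:

* Two-sided FIR: y(t) regressed on lagged x over τ ∈ [−L, +L]
  (L = 50 ms at full scale; 35 ms in scaled tests — both cover the
  6–25 ms conduction delays with margin), both series z-scored, ridge
  penalty chosen by generalised cross-validation on the SVD of the lag
  design matrix.
* Significance: circular time-shift surrogates of y (offsets beyond the
  lag horizon, ≥100 draws) refitted through the cached SVD give a null
  for the per-side peak |h|; a pair is a feedback edge iff *both* the
  causal (τ>0) and non-causal (τ<0) peaks exceed their side's 95th
  percentile.  Sign is positive when the two dominant peaks agree in
  algebraic sign.  Edges are unordered; pairs are processed in
  canonical channel order, so classification is order-invariant by
  construction.
* Consistency: the record is cut into four non-overlapping windows
  (4 × 20 s at full scale) and only edges identical in pair and sign in
  *all* windows survive.  The joint two-sided 95% exceedance makes the
  per-window false-edge rate ≈ 0.25%, and the four-window intersection
  drives it far below that, which the specificity test asserts.

Detected dominant lags sit near the true conduction delay plus the
driven oscillator's rise time, i.e. a 21 ms loop typically peaks at
~25–35 ms; tests therefore bound lags in [10, 40] ms rather than
asserting the nominal delay.

## CLGF motif census

A CLGF instance is an unordered triple (hub a, global partner b, local
partner c) with positive global feedback {a,b} and positive local
feedback {a,c}; since b lies outside and c inside the hub's region they
are always distinct, and the instance count is Σ_hub (global degree ×
local degree) over positive edges.  Instances are the default
statistic; the number of participating hubs is also reported because
the source figure does not disambiguate the two.  The census is held
equal to exhaustive triple enumeration (~172k triples at 102 channels)
in tests.

## Delayed Wilson–Cowan circuits

Each oscillator follows

    dE/dt = −αE + β_E (1 − rE) f_E(s_E)
    dI/dt = −αI + β_I (1 − rI) f_I(s_I)

with f(s) = 1/(1+e^{−a(s−θ)}) − 1/(1+e^{aθ}) and the classic
source→target weight orientation

    s_E = w_ee E − w_ie I + P,     s_I = w_ei E − w_ii I + Q,

parameters α=0.35 /ms, β=1, r=0.65, a_E=1.3, a_I=2, θ_E=4.5, θ_I=3.5,
(w_ee, w_ei, w_ie, w_ii) = (16, 15, 12, 3), Q=0, time in ms.  The
printed weight list admits two subscript readings; the orientation
above is the one that reproduces the stated single-oscillator regime —
limit cycles from 80.8 Hz at P=1.2 up to ~148 Hz near P=2.6, with
quiescence below P≈0.9 and a saturated non-oscillatory
("hyper-excited") state from P≈2.8 — and is adopted throughout.  Note
the regime's upper edge: P = 2.8 and 3.0 already hyper-excite, so the
P grid used for frequency-range readouts reports extremes over the
oscillatory points only, and hyper-excited points are flagged and
excluded everywhere (matching the source's stated convention of
ignoring hyper-excitatory oscillation).

Delay coupling adds `w · E_src(t − τ)` to the target's s_E.
Integration is method-of-steps RK4 (dt = 0.05 ms default, ≤ 0.1 ms
enforced) with 4-point cubic Lagrange interpolation of the stored
excitatory history at stage times, compiled with numba; halving dt
changes trajectories by < 1e−4 over 500 ms.  Initial history is the
quiescent state (E, I) = (0, 0) with a brief excitatory kick (0.5 for
2 ms) to leave the trivial fixed point's basin.

### Circuit operating point

With these parameters an *undriven* oscillator cannot be ignited by
couplings in the explored 0–4 range — its sigmoid input peaks around
0.7 against a threshold of 4.5 — so circuit simulations drive one
oscillator per cortical region: in the three-node CLGF circuit the hub
a and its global partner b (distinct regions) both receive P, the
local partner c (same region as a) does not.  The coupled system is
strongly multistable; the ignition kick is applied to the hub only,
which reliably selects the slow delayed-loop relaxation over in-phase
modes.  The sweep operating point is P = 1.25 (lower third of the
oscillatory range; ~85 Hz solo) with global coupling 2.6, the smallest
grid strength at which the two-node loop settles into its beta-dominant
relaxation rhythm (`calibrate_global_coupling`); at the
nearest-100-Hz drive (P ≈ 1.45, `calibrate_input`) no local-coupling
strength becomes gamma-dominant before hyper-excitation, so the
100 Hz calibration is used for single-oscillator analyses and cohort
drives but not for the sweep.

Under this protocol at the default delays (global 21 ms, local 6 ms)
the circuit reproduces the qualitative regime switch: summed beta power
dominates for local strengths 0–2.5 (a ~20 Hz rhythm set by the 42 ms
global round trip), gamma power abruptly dominates at strength 3 (a
~59 Hz local-loop rhythm), and the grid top collapses or
hyper-excites.  The beta-band PLV between a and b decreases across the
crossover, though only slightly in the deterministic protocol.  At the
delay corner (25, 10) ms the crossover occurs earlier (strength 2–2.5)
and the strength-3 point collapses; at (15, 6) ms no gamma-dominant
point coexists with beta dominance at strength 0 at any global
strength — the beta relaxation there transitions directly to
hyper-excitation.  The delay-robustness claim is therefore only
partially reproduced, and the corresponding acceptance checks at the
corners are left failing rather than weakened; the grid scans behind
this conclusion covered global strengths 1.5–3.4 and drive layouts
(hub-only, hub+partner, all-driven) with multiple ignition patterns.

## Statistics

Two-sample comparisons are two-tailed Welch t-tests
(Welch–Satterthwaite df): recomputing the demographic table of the
emulated study from its printed means/SDs reproduces every printed t
to 2 dp under Welch but not under the pooled form, which fixes the
choice.  Correlations are Pearson r with the t-transform p (n−2 df);
the 2×2 sex table uses Pearson chi-square without continuity
correction, whose computed value (0.92) does not match the printed
0.95 under any standard variant — reported as computed.  α = 0.05, no
multiple-testing correction anywhere.  Degenerate inputs (zero variance
in both groups) return t = 0 / p = 1 on equal means and are flagged
infinite on unequal means.

## Reproducibility and scale

All randomness flows from per-run seeds through `numpy` Generators;
cohorts fan a `SeedSequence` out per subject, so any subject is
reproducible in isolation.  Identical (spec, seed) gives byte-identical
cohort tables.  The numbered scripts under `analysis/` run a demo
cohort (6+6 subjects, 20 channels, 8 s) in a few minutes on one CPU;
tests use the same scaled conditions, chosen as the package's working
scale for exploratory runs.
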