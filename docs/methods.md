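# Methods

## Scope and model

`olmtheta` asks when a hippocampal CA1 oriens-lacunosum/moleculare (O-LM)
interneuron, placed in an in-vivo-like high-conductance state, is recruited to
spike by frequency-modulated inhibitory input — and how that recruitment
depends on where its h-channels (HCN) sit, on the slow delayed-rectifier
potassium conductance (Kdrs), and on cAMP modulation of h-channel activation.

The biophysical identity of a model variant is one row of the packaged
parameter table (`olmtheta/data/model_parameters.csv`): maximum conductance
densities (pS/µm²) for nine voltage-gated currents — transient Na (somatic
Nas, dendritic Nad), fast and slow delayed rectifiers (Kdrf, Kdrs), A-type K
(KA), T- and L-type Ca (CaT, CaL), a Ca-activated AHP current, H, and the
Kv7/M current — plus the passive membrane resistivity R_m (Ω·cm²), specific
capacitance C_m (µF/cm²) and a holding bias current.  There are 32 rows, 16
with somatic-only H (density 0.5 pS/µm²) and 16 with uniform somatodendritic
H (0.1 pS/µm²), split evenly over two morphologies.  The bias current is
stored but never injected during high-conductance runs.

The membrane equation per compartment is the standard ohmic HH form

    C_m dV/dt = − Σ_c ḡ_c x_c^p y_c (V − E_c) − g_syn(t) (V − E_syn)
                + I_inj + axial coupling,

with first-order gates dx/dt = (x_∞(V) − x)/τ_x(V),
x_∞(V) = 1/(1 + exp((V − V½)/k)) (negative k opens with depolarization).

## Morphologies

The experiments consume only two geometric facts: total somatodendritic
surface area and the segmentation grid that fixes synapse placement.  The
package therefore builds reduced synthetic trees — a 20 µm × 20 µm soma, two
dendritic stems (2.0 µm) each branching once into thinner daughters
(≈0.8 µm, a few percent seed jitter), and a 200 µm² truncated passive axon —
with one shared segment length solved so the non-axonal area matches the
reference values exactly-to-1%: 16,193.6 µm² with 84 segments (morphology 1)
and 9,980.1 µm² with 76 segments (morphology 2).  Synapses sit at the
midpoints of every fourth segment in depth-first order (soma segments
included, axon excluded), giving 21 and 19 sites; the `soma_only` rule places
a single mid-soma site.  Area convention is lateral cylinder area π·d·L.
Axial resistivity is not part of the printed table; default 300 Ω·cm.

## Reference channel kinetics

The conductance-density table does not define kinetics, so the package
carries a fully parameterized "reference O-LM channel set"; every V½, slope,
and τ(V) parameter is exposed (`reference_channel_set()`) so published
kinetics can be substituted.  The generic time-constant form is
τ(V) = τ_min + τ_amp / (exp((V−v₁)/k₁) + exp(−(V−v₂)/k₂)), which covers both
bell-shaped and sigmoidal profiles.  Anchors and defaults:

* **H** — activation V½ = −84 mV (the control value; the cAMP operation
  shifts it by +5 mV to −79 mV), slope 10.2 mV, first order; τ_h sigmoidal,
  ≈50–110 ms below −70 mV rising toward ≈700 ms at depolarized potentials;
  E_h = −20 mV.  The fast hyperpolarized τ lets H be recruited within one
  inhibitory half-cycle at theta frequencies.
* **Na (Nas/Nad)** — m³h with activation V½ −48 mV (k 5.5) and inactivation
  V½ −60 mV; this places spike threshold near −58 mV so the calibrated
  operating point (mean V_m ≈ −70 mV) sits inside the steep region of the H
  activation curve — the property that gives H-block and cAMP manipulations
  leverage.
* **Kdrf** — n⁴ delayed rectifier for spike repolarization.
* **Kdrs** — n², slow: τ ≈ 6 ms at spike potentials (so each spike loads it)
  decaying with τ ≈ 150–190 ms subthreshold; it builds the long
  post-spike hyperpolarized shoulder characteristic of the somatodendritic-H
  group (density 42 vs 2.3 pS/µm²).
* **KA** — inactivating A-current; de-inactivates during the hyperpolarized
  "peak of inhibition" half-cycle and transiently opposes the early-trough
  depolarization (τ_inact ≈ 30–60 ms), delaying spikes toward late trough.
* **CaT** — low-threshold rebound current: de-inactivates during the
  inhibitory peak (inact V½ −70 mV) and activates slowly (m², τ ≈ 40–70 ms
  subthreshold), cresting tens of ms into the trough.
* **CaL, AHP** — spike-triggered Ca influx charges a first-order Ca pool
  (gain 0.07 per unit inward Ca current density, decay τ 200 ms); the AHP
  conductance follows the pool with a Michaelis fraction ca/(ca+1) and a
  40 ms gate.  This is the slow brake that holds baseline firing near the
  fluctuation-driven regime.
* **M** — small slow K current; minor at the operating point.
* Reversals: E_Na +50, E_K −90, E_Ca +120 (ohmic approximation), E_leak −68.

These kinetics are the package's own design, chosen so the two model groups
reproduce the targeted qualitative phenotype (low- vs high-theta recruitment,
H/Kdrs involvement); they are not the database's unpublished equations.

## Numerical integration

Fixed-step implicit (Crank–Nicolson-style) integration with a staggered
exponential gate update, default dt = 0.025 ms.  Each compartment is one
morphology segment; the tree system is solved per step by Hines elimination
(parents precede children in depth-first order).  Gate rates are tabulated
on a 0.05 mV grid over [−120, 60] mV with linear interpolation, and the step
loop is JIT-compiled (numba).  Accuracy guard: halving dt on a driven active
model changes the somatic trace by far less than 0.5 mV RMS (test suite).
Divergence (|V_m| > 200 mV) raises an error naming the offending time.
Spike detection: upward crossing of −10 mV with a 2 ms refractory window —
O-LM spikes overshoot 0 mV, so detection is insensitive to thresholds in
[−20, 0].  Subthreshold statistics cut 3 ms before to 8 ms after each spike.

## Synaptic bombardment and modulation

Each site receives one excitatory (500 Hz) and one inhibitory (1000 Hz)
homogeneous Poisson stream; streams are independent across sites and classes
(counter-based seed derivation from a master seed).  Conductances are double
exponentials with τ_rise 0.5 ms and τ_decay 6.8 ms for both classes
(GABA_A/kainate-like), normalized so one event peaks at g_peak;
E_exc = 0 mV, E_inh = −80 mV.  Modulation is a square wave on the inhibitory
rate only: the first half of each cycle runs at +40% ("peak of inhibition"),
the second at −40% ("trough"); the peak→trough transitions are the release
times that define phase 0°.  Modulated streams are generated by thinning a
homogeneous process at the peak rate, which keeps them exactly
piecewise-Poisson.  The sweep frequency list is 0.5, 1, 2, 3, 4, 5, 8, 9,
10, 12, 15, 16, 20, 25, 30 Hz (denser through theta).

## Operating-point calibration

Every condition must be compared at the same baseline: ~2.5 Hz firing under
unmodulated bombardment with subthreshold fluctuations as large as possible
(the ~2 mV fluctuation target is a soft objective — among qualifying
conductance pairs the one maximizing the SD wins, ties toward smaller
g_exc).  The default search domain spans a moderate high-conductance band
(g_inh per site 0.03–0.065 nS, g_exc 0.008–0.08 nS) in which total synaptic
conductance remains within a few multiples of the resting conductance; a
many-fold shunt would swamp the ~1 nS H conductance whose role is the point
of the experiment.  The search is a coarse grid at reduced duration followed by
full-length re-measurement of candidates, with a monotone bisection on
g_exc as fallback when the rate jumps between grid columns.  Search and
validation use disjoint seed sets; a held-out guard keeps the rate within
twice the calibration tolerance (±0.3 Hz).

After a channel block the inhibitory conductance is held bit-exactly fixed
(re-scaling it would confound the inhibitory-rate modulation itself) and
only g_exc is re-searched on a line.  Blocking Kdrs or KA alone leaves the
model unable to reach the operating point at any probed excitation
(runaway firing); the calibration layer reports this as a hard failure.  The
H-leak control replaces gated H by an ohmic conductance at the same
reversal, initialized at ḡ_H × h_∞(mean subthreshold V_m) and scanned
downward until the baseline rate recovers.  The cAMP condition is acute:
no recalibration.

## Output measures

* **Power ratio** — the spike train is binned at 1 ms into a binary
  sequence; Welch PSD (Hann, 2¹⁴-sample segments capped at train length,
  50% overlap, DC retained, **two-sided** so a perfectly locked periodic
  train gives ratio exactly 1); value at the grid frequency nearest f_mod
  divided by the 0 Hz value.  Note that one-sided PSD conventions double
  all non-DC values; thresholds quoted here are on the two-sided scale.
* **Rotation number** — spikes per complete input cycle.
* **Vector strength** — VS = √((Σcosθ)² + (Σsinθ)²)/N with
  θ_i = 2π(t_diff mod T)/T, t_diff the time since the most recent release
  from peak inhibition; spikes before the first release are dropped and
  counted.  The circular mean phase is reported only when VS ≥ 0.6.

## Statistics

Two-sample comparisons follow the normality-gated protocol: Anderson–Darling
on each sample at α = 0.05; if either rejects, Wilcoxon rank-sum, otherwise
a (paired) t test; identical degenerate samples return p = 1.  The rank-sum
branch treats samples as independent even when nominally paired — the
mismatch is flagged in the result metadata rather than silently resolved.
The two-way fully-within rmANOVA decomposes subjects × A × B with error
terms A×S, B×S, A×B×S; the Huynh–Feldt epsilon is estimated from the
covariance of orthonormalized within-subject contrast scores, truncated at 1
for the correction (a two-level factor has ε = 1 exactly), and the corrected
p is floored at the uncorrected p so the correction can never be
anti-conservative.  Tukey post-hoc tests are out of scope; per-level paired
comparisons with Holm correction are provided as a labelled substitute.

## Reference models and problem sizes

The analysis scripts and acceptance run use one representative model per H
group: rank 6 (somatodendritic H) and rank 26 (somatic H), selected by
screening all 32 variants under the reference kinetics for the
best-conditioned group-typical behavior.  Desk-scale problem sizes: 10 s
simulated per run and 3–5 drive seeds per condition (a full-scale design
would use all 16 models per group and 20–30 s runs); the tidy tables keep one
row per (model, condition, frequency, seed).

## What the synthetic data do and do not show

The generator reproduces the stated study conditions — two surface-matched
morphologies with 21/19 sites, 500/1000 Hz uncorrelated Poisson drive,
±40% square-wave modulation at the printed frequencies, ~2.5 Hz calibrated
baselines — but not features of real O-LM input such as synaptic
correlations, short-term plasticity, NMDA-type voltage dependence, or
realistic dendritic branching statistics.  Passing tests therefore show that
the pipeline reproduces the in-silico phenomenology under its own stated
conditions, not that biological O-LM cells behave this way.

## Measured behavior, limitations, open choices

With the frozen defaults the somatic-H reference locks tightly at 2–3 Hz
and loses majority-cycle recruitment above ~5 Hz, while the
somatodendritic-H reference holds one-spike-per-cycle recruitment at 4 Hz,
keeps its 8 Hz power ratio above 0.6 (two-sided scale) with high vector
strength, and fires in the second half of the trough at 8 Hz.  Known
quantitative gaps, left honest rather than tuned away:

* The somatodendritic-H mean phase at 8 Hz measures ≈135–145°, earlier than
  the 180° preferred phase expected from the in vivo relationship (O-LM
  cells fire half a cycle after their septal inhibitory input).  In this
  implementation the release
  ramp reaches threshold around mid-trough; pushing the preferred phase to
  the trough's end would require post-spike recovery dynamics (or a
  synaptic shunt time constant) slower than the calibrated operating point
  allows while keeping one-per-cycle recruitment at 4 Hz.
* The somatic-H vector strength at 3 Hz measures ≈0.75–0.85 across seed
  sets, at the edge of the >0.8 band, because the model occasionally fires
  twice within the long 3 Hz trough.
* cAMP modulation (+5 mV) raises 4–5 Hz recruitment and precision and the
  high-theta power ratios, but the power-ratio *peak* does not always move
  fully into 8–10 Hz; the H conductance (≈1 nS total at the printed
  density) shifts spike probability by only a few pA at the operating
  point.
* The input-resistance drop under bombardment is about 1.4-fold for the
  somatodendritic-H reference and ~2.6-fold for the somatic-H reference,
  bracketing the "at most two-fold" working regime.
* Open choices fixed by documentation: soma segments participate in
  every-fourth-segment placement; per-site peak conductances are identical
  across sites; PSD uses density scaling (the ratio is insensitive); the
  Ca dependence of the AHP current is a first-order pool proxy, not a
  buffered-diffusion model.
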