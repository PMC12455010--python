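# Methods

## Gating model

Each channel sub-population (glycoform) is a Hodgkin–Huxley conductance
with open probability `P_open(t) = m(t)^p · h(t)`.

* **Activation** `m` relaxes toward a Boltzmann steady state
  `m_inf(V) = 1/(1+exp(−(V−V½)/s))` with time constant `τ_m`. Within a
  constant-voltage segment the relaxation is solved exactly
  (`m(t) = m_inf + (m0 − m_inf)·e^{−t/τ_m}`), so there is no integration
  error in the activation path. Defaults: `p = 4` (classic
  delayed-rectifier exponent), `V½ = 0 mV`, `s = 9 mV` — placing threshold
  in the high-voltage range typical of Kv3-family channels — and
  `τ_m = 2 ms`, a fast Kv3-like activation.
* **Inactivation** is the survival of a k-step docking chain for the
  N-terminal inactivation ball: after channel-opening conditions are
  reached, the ball reaches its blocking pose via k sequential steps at
  rate λ each, so the latency is Erlang(k, λ) with mean `k/λ` and CV
  `1/√k`. Survival has the closed form
  `h(t) = f_ss + (1−f_ss)·Q(k, λt)` with Q the regularized upper
  incomplete gamma function; `f_ss` is a non-inactivating steady-state
  fraction (default 0.02 in the cohort presets). A one-step chain (k = 1)
  is a memoryless, purely exponential inactivation with no delay; longer
  chains produce the sigmoidal delayed onset that motivates the model.
  The closed form is cross-checked in the tests against an independent
  numerical route (direct LSODA integration of the k-state chain ODE);
  the two agree to better than 1e−6 sup-norm for k up to 20.
* **Chain engagement.** The docking chain advances only during voltage
  segments at or above an engagement threshold (default −40 mV),
  reflecting the open-state coupling of N-type block; during
  hyperpolarized holding segments the chain holds its occupancy. Because
  the chain is a time-homogeneous pure-birth process, occupancy is
  propagated across segments analytically (Poisson step counts), so
  multi-segment sweeps are also integration-free. λ itself carries no
  voltage dependence by default.

A recorded cell is a weighted mixture of such components; per-sweep
current is the weighted sum of component currents times the driving force
`(V − E_K)`, plus ohmic leak and Gaussian baseline noise.

`E_K` defaults to the Nernst potential of the standard planar-patch
solutions — 4 mM K⁺ external, 110 mM internal (50 KCl + 60 K-fluoride) —
at 25 °C: −85.15 mV. Temperature is carried as metadata only; no Q10
scaling is applied.

## Voltage protocol

Default: 18 steps from −90 to +80 mV in 10 mV increments, 500 ms pulse,
−90 mV holding, 10 kHz sampling. The pulse is preceded by a 100 ms holding
segment and followed by none, giving a 600 ms sweep; this is our
reconciliation of a 500 ms pulse with a sweep-relative 70–599 ms analysis
window (the window then covers the last 30 ms of holding plus the full
pulse). The pre/post durations are a package choice, not a measured
quantity, and are configurable.

## The width statistic

Per cell, the +80 mV sweep is restricted to the 70–599 ms window and
normalized to its in-window peak; peak search and normalization are both
confined to the window (a whole-sweep-peak alternative is selectable).
The inactivation width at level ℓ (default 0.70) is `t_down − t_up` where
`t_up` is the first upward level crossing and `t_down` the last downward
one, both linearly interpolated between bracketing samples. The
first-up/last-down rule bridges brief noise dips; an optional zero-phase
Butterworth low-pass (e.g. 2.9 kHz, mimicking a bench Bessel filter) can
be applied before crossing detection but is off by default, as is
pre-window baseline subtraction (simulated leak is part of the trace).

Degenerate inputs: a sweep whose in-window peak is not positive is
unanalysable and is excluded-with-reason rather than raising mid-cohort; a
normalized trace that never reaches the level raises a dedicated error. A
trace still at or above the level at the window end is **censored**: its
width is recorded as `window_end − t_up` and flagged. Censored widths are
included in the heterogeneity statistics by default (they carry real
spread information); a sensitivity mode excludes them.

On an idealized instant-rise trace with exponential decay τ, the width is
analytically `τ·ln(1/ℓ)`; at 10 kHz with linear interpolation the measured
value agrees to well under 0.2 ms (one sample), which the acceptance tests
pin at τ = 50 ms (17.83 ms).

## Heterogeneity statistics

Boxplots follow the Tukey convention: outliers are points more than
1.5·IQR beyond the box; whiskers run to the furthest observation within
that fence; heterogeneity is the whisker-to-whisker span. Quartiles use
linear interpolation of the empirical quantile function (numpy's default,
the "type 7" rule) and a Tukey-hinges alternative is exposed for
sensitivity checks, since plotting software disagrees on quartile
algorithms and the span inherits that choice. Note one small-sample
subtlety: with interpolated quartiles and tied data, the furthest
observation within the fence can lie inside the box, so the whiskers are
guaranteed to bracket the median but not the quartiles; we keep the
observation-based rule (it is also what matplotlib computes) rather than
clamping whiskers to the box edges. Condition comparison reports
per-condition boxplot statistics, span ratios against a designated
reference, censored counts, and the Pearson correlation between peak
current and width (a diagnostic that amplitude is not driving the spread);
no hypothesis tests are attached — the span is a descriptive measure.

## Quality control

Stage 1 screens recording metadata with strict inequalities as
conventionally printed: |V-offset| < 45 mV, seal resistance > 200 MΩ,
series resistance < 15 MΩ, C-slow < 35 pF. V-offset is compared as a
magnitude since offsets are signed. Missing metadata fails its criterion
with a "missing" observation instead of raising. Stage 2, evaluated only
for stage-1 passers, keeps cells with peak current between 0.5 and 45 nA
inclusive ("between" read inclusively). Manual review of unstable cells is
modelled as an explicit exclusion list; an optional sweep-drift heuristic
was considered and deliberately left out of the default path because it
has no measured counterpart. The filter is monotone (tightening any
threshold never admits a cell) and conservative (one report row per input
cell), both pinned by property tests.

## Synthetic cohorts

The generator's presets define the study conditions:

* **control** — each cell mixes a fast component (k = 1, mean latency
  drawn uniformly from 8–15 ms) with a slow one (k uniform on {4,…,12},
  mean latency uniform on 60–400 ms), fast-fraction uniform on
  0.15–0.6. Measured widths then span tens to hundreds of ms across a
  cohort, reproducing the heterogeneous overlay this analysis targets.
* **deglyco / tunicamycin** — every cell is the single fast component:
  the kinetic collapse expected when glycoform diversity is removed.
* **delay-spread** — single component (k = 4) whose per-cell mean latency
  is Normal(mean, SD²) truncated at 5 ms; used for recovery studies where
  the between-cell delay SD is the ground truth.

Per-cell maximal conductance is log-uniform on 15–220 nS, which at +80 mV
against E_K ≈ −85 mV yields peak currents of roughly 1–25 nA — inside the
0.5–45 nA stage-2 window — and is drawn independently of the kinetics, so
amplitude and width are uncorrelated by construction. QC metadata is drawn
uniformly from safely-passing ranges; a configurable fraction of cells per
condition is planted as stage-1 failures by redrawing one randomly chosen
metric from a failing range. Noise defaults: 5 pA Gaussian baseline SD and
0.5 nS ohmic leak to 0 mV — arbitrary but documented and configurable.

Determinism: cell *i* (global index) draws parameters from
`default_rng(seed + i)` and noise from `default_rng([noise_seed, i])`, so
a fixed cohort seed with varying noise seed reproduces identical ground
truth under fresh noise, and identical seeds reproduce cohorts bit-exactly.

**What the generator does not emulate:** capacitive transients,
series-resistance voltage error, seal drift and run-down, stochastic
single-channel gating, temperature dependence, and any specific mapping
from glycan structure to kinetics (the component parameters are
phenomenological). Passing recovery tests therefore show the *statistic*
behaves correctly when its assumptions hold — not that real recordings
satisfy those assumptions; on real data the QC and censoring machinery
carry more of the load.

## On-disk layout and numeric conventions

Cohorts are exchanged as `manifest.tsv` plus one long-format TSV per cell
(`step_potential_mV, time_ms, current_pA`), time in ms from sweep start,
current in pA (nA inputs converted on write). Floats are written with
shortest round-trip decimal representation: write→read is bit-exact on
the data model and read→write is byte-identical on canonical files, which
is what makes whole-pipeline byte-level determinism testable. Vendor
formats are out of scope for the core; `convert` canonicalises data
already in this layout.

## Problem sizes

Tests and the acceptance script use desk-scale cohorts: 29–30 cells per
condition (the scale of a typical patch-clamp figure panel), the full
18-step protocol where the whole pipeline is exercised, and single-step
(+80 mV only) protocols where only the target sweep is analysed (delay-SD
recovery, 200-replicate null-correlation checks). These sizes are the
package's own defaults; all of them run in seconds.

## Known limitations

* The Erlang-chain inactivation gate is a phenomenological latency model,
  not a biophysical Markov scheme fit to data; only its delay structure is
  meaningful.
* Whisker spans depend on the quartile convention for small n; both
  conventions are exposed but results should state which was used.
* Censored widths make the span window-dependent; the censored flag and
  the exclusion sensitivity mode are provided so both readings can be
  reported.
* The holding-segment portion of the analysis window contributes baseline
  (leak + noise) only; cells with large leak relative to peak current can
  bias `t_up` earlier. Baseline subtraction is available but off by
  default.
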