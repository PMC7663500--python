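# Methods

This note documents the models implemented in `dyndse`, the defaults
and the reasoning behind the design choices that were genuinely open,
what the synthetic data generator does and does not emulate, and the
package's known limitations.

## 1. Design-space formalism and selection

A design space is an ordered list of functionalities, each realised by
one of several components, each component carrying finite, explicitly
listed parameter grids. The configuration count therefore factorises as
Π_ξ Σ_q Π_w |ω_ξ,q,w|, and `DesignSpace.size` computes exactly that
product; enumeration is the lexicographic cartesian product over
declared functionality → component → parameter-value order, so two runs
always visit configurations in the same order and tie-breaks are
reproducible. Continuous parameter domains are out of scope: the
exploration is an exhaustive grid search by construction.

Selection relaxes the general benefits-minus-costs objective to a pure
benefit maximisation over the feasible region: a configuration is
feasible iff every requirement-normalised cost is ≤ 1 and every
normalised benefit is ≥ 1, and among feasible configurations the one
maximising P + R wins. The unweighted benefits-minus-costs sum is not
offered as a selector — its terms carry incompatible units (fractions,
seconds, mWh, bytes) and any implicit weighting would be arbitrary; the
feasibility-constrained maximisation needs no such weights. Ties are
broken by lower total energy, then enumeration order: energy is the
binding resource in this application class, and enumeration order makes
the final choice deterministic. Infeasibility of an entire space is a
reported outcome (`optimum: none`), not an error — all-infeasible
sweeps are an expected and informative result.

Pareto dominance (`dominates`, `pareto_front`) is provided for
trade-off analysis: a metric vector dominates another when it is at
least as good on every axis (benefits up, costs down) and strictly
better on at least one. Latency participates in dominance only when
both vectors carry it.

## 2. Cost models

**Execution time.** Each pipeline function is reduced to a tally of
additions/subtractions, multiplications, divisions, roots, exponentials
and comparisons; machine cycles are the dot product of that tally with
the microcontroller's per-operation cycle table, and time is cycles
over clock. All operations are costed as float-typed; the int/float
distinction is kept only for memory cells. In real-time mode the ET
metric is the (worst-case) per-frame pipeline time, checked against the
frame length m; in online mode it is the total over frames, checked
against the runtime T.

Two tally conventions coexist in the sources for the oc-SVM stage: the
in-text worked example counts v additions for the kernel pass and
v(d−1) multiplications for the RBF kernel, while the printed breakdown
table lists v+1 and v(d+1). `kernel_svm_counts`/`rbf_kernel_counts`
default to the worked-example convention (it reproduces the printed
cycle totals of ≈24×10⁴ and ≈525×10⁴ exactly); the table variant is
available via `convention="table"`. The per-frame stage breakdown in
`spotting_op_count` follows the printed table rows, with the RBF
multiplication convention switchable in the same way.

The depth-l wavelet-packet row of the printed breakdown is
typographically corrupted in the available text; it is implemented as
Add = Σ_{i=1..l} ((m/2^i − 1)·2 + 1)·2^i and
Mult = Σ_{i=1..l} ((m/2^i) + 1)·4·2^i — a 4-tap (db2) filter bank over
all 2^i nodes of level i — which matches the structure and magnitude of
the legible parts. The pre-processing cost for both pipelines is the
tabulated m-addition low-pass row, even though the described WPD
preprocessing is a notch + high-pass + rectification stack; the cost
table and the described pipeline disagree in the source, and we keep
the table for accounting while implementing the described filters.

**Energy.** EC = EC^μC + EC^s + EC^m + EC^r, all in mWh.
The μC term charges active power I_act·V for the summed execution time
and stand-by power for the remainder of the runtime (an active time
exceeding the runtime raises, signalling an over-committed schedule;
the evaluation layer catches this and reports it as a diagnostic).
The sensor term integrates I_act·D_t + I_stb·(1−D_t) over the duty
trace at the simulation step t_r (default 1 s, the sampler's decision
period). The memory term charges one block write (I_write·V·t_write)
per retrieved event; no stand-by current for the memory component is
given in the shipped tables, so the static term defaults to zero and
accepts a datasheet value. The radio term charges
I_trans·V·t_trans = 21.7 mA · 3.3 V · 16 ms per packet, one packet per
retrieved event (two 2-byte timestamps fit one 114-byte packet;
batching is out of scope). The energy requirement is battery-derived:
zρ2 = BC/RT·ϕ = 925/16·0.9 = 52.03 mWh. (A printed summary table in
the source rounds this to 52.8 mWh, which does not follow from the
formula and its stated inputs; the computed value is the default and
the printed one can be set explicitly.)

**Memory demand.** MD = m_c + m_d + Σ_f m_f + m_e: a configurable code
constant (default 8 KiB — the sources never quantify it), the data
memory (one frame of K·frame_len 4-byte floats in real time; the
simulated ring-buffer peak in online mode), the per-function cells
(ints at the μC's data resolution, floats at 4 bytes), and 4 bytes per
buffered event. The ring-buffer simulation services frames serially:
when the per-frame ET is below the frame duration the peak is one
frame; otherwise the backlog grows and the peak scales with the stream
length. Feasibility compares MD against the μC's **flash** capacity:
the dominant terms are static model constants (the v(d+1) support-
vector floats, the c×d PCA matrix) that live in flash on a real
deployment, and this choice reproduces the expected feasibility
pattern across the three shipped parts (breaches on the 32 kB PSoC1,
headroom on the 512 kB ARM CortexM3); against RAM, every v = 1500
configuration would be infeasible on all three parts.

**Latency.** CL = Σ_f ET_f + m_e/ν_tr with ν_tr = MPS/connInterval
(216 bits / 7.5 ms = 28.8 kbit/s by default; one source passage says
215 bits, the profile field is overridable). CL is computed and
reported but excluded from the default feasibility conjunction —
events are rare and their payloads tiny — and re-enters it when a
latency tolerance is set on the requirement set.

**Shipped profiles.** `profiles/hardware.yaml` carries the three μCs
(cycle tables, clocks, currents, voltages, data resolution, flash/RAM,
memory-write characteristics), the EMG front-end, the BLE radio and
the 925 mWh Li-Ion battery, field for field from the component tables.
Memory capacities printed in kB are stored as 1000-byte kilobytes.

## 3. Context-adaptive sampling

Once per decision period the sensor wakes and takes n samples per
channel (the *n-shots measure*). The context measure θt is the
per-channel mean of the **rectified** samples, maximised across
channels — surface EMG is zero-mean, so a raw mean would vanish; the
rectified mean is the natural reading of "signal energy" here, and we
flag it as an interpretation. The linear map
D* = Dl + (Dh−Dl)/(θh−θl)·(θt−θl) is clamped to [Dl, Dh] outside the
anchor interval.

The response model has two states. A candidate above the duty
threshold DTH switches to (or keeps) the *attentive* state, applies
max(Dt, D*) — duty never decreases while attentive — and rewinds the
attention clock to τ. A candidate at or below DTH while attentive
holds the current duty until τ has elapsed, then falls back to the
inattentive state and applies the candidate; when inattentive, the
candidate is applied directly. The hold-while-τ-runs case is implicit
in the source's case rules and is resolved this way because the
attention time "expiring" is what triggers the switch back. Equality
with DTH is routed to the inattentive branch (the source uses strict
inequalities on both sides, leaving equality open).

Defaults are the study's operating point: Dl = 0.1, Dh = 1, DTH = 0.6,
n = 4, τ = 3 s, θl = 10 mV, and θh = 180 mV (θh appears only as the
chosen operating point in the source's figure annotations and is an
ordinary tunable here). The decision period is 1 s — the source never
states the inter-measure interval, and 1 s gives the duty controller a
bandwidth well above the minutes-scale dynamics of eating episodes.
Within a period, the kept samples are evenly spaced (placement is
unspecified in the source) and the n shot samples are counted as kept,
since they are physically acquired; both conventions enter the
reduction accounting.

Downstream consumers see the acquired stream reconstructed on the
uniform grid by linear interpolation between kept samples.
Zero-filling the gaps instead (available as `fill="zero"`) injects
artificial wide-band content and an amplitude bias that no real
consumer of the acquired samples would see, and in early integration
testing it collapsed recall under modest reduction much faster than
the gradual degradation the mechanism is known for; interpolation is
the physically sensible default and the choice is recorded here.

## 4. Spotting pipelines

Both pipelines segment the stream into non-overlapping frames of m
seconds (m is externally in seconds, internally in samples at 256 Hz;
configs may give samples directly with `m_unit="samples"`), classify
frames with a one-class SVM (RBF kernel) trained on eating frames
only, and merge runs of positive frames into retrieved events.

**WPD pipeline.** Frames are gated on their maximum raw amplitude
(inclusive ≥; threshold default: the 95th percentile of non-event
frame maxima on the training folds, standing in for the source's
"experimentally found" but never published value); gated-out frames
never reach feature extraction. Preprocessing is a causal 50 Hz notch
(2nd-order IIR, Q = 30) → 20 Hz 4th-order Butterworth high-pass →
rectification; the source gives only the cutoff frequencies, the
realizations are ours. Features are the depth-2 wavelet-packet leaf
coefficients (db2, periodic extension, so the c = frame_len
coefficients per channel conserve energy exactly), concatenated over
channels, projected to d dimensions by PCA fitted on training event
frames, then L2-normalised. The implementation uses both channels'
coefficients (2c inputs to PCA) while the printed cost table is
written in terms of a single channel's c; the cost accounting follows
the table's convention.

**FFT pipeline.** Per channel, the standard deviation and the maximum
FFT magnitude of the (two-tap-smoothed, zero-padded to the next power
of two) frame, concatenated and L2-normalised; the source defers its
feature details to prior work, so this schema — and the feature length
d, which the source never states for this pipeline (default 2K = 4) —
is a documented interpretation. No amplitude gate: the source
describes gating only for the WPD pipeline.

**Training.** Leave-one-participant-out: for each grid point
(γ, ν of the one-class SVM), fit on the training folds' event frames
and score frame-level F1 on the held-out participant; the grid point
with the best mean held-out F1 is refit on all training participants.
Everything is deterministic given the data (PCA and the SVM solver are
deterministic; the seed argument is accepted for interface uniformity).
The default grid is small (γ ∈ {scale, 0.5}, ν ∈ {0.05, 0.2}); ties go
to the first grid point in declared order. The support-vector budget
v = 1500 is a cost-accounting constant; the trained model's actual
support-vector count is recorded and a warning is issued if it exceeds
the budget (the source does not say how v is enforced).

Trained spotters serialize to JSON (support vectors, dual
coefficients, intercept, kernel width, PCA mean and components,
normalisation scheme, hyperparameters, fold scores); restored models
use an explicit RBF decision function, keeping the artifact plain
text.

## 5. Synthetic data generator

The generator emulates the surface statistics of day-long two-channel
chewing EMG: a zero-mean Gaussian noise floor of σ = 10 mV (the lower
context bound θl), and within eating events band-limited (20–120 Hz)
noise bursts amplitude-modulated by a half-wave envelope at the chew
rate, applied to both channels with independent carriers and a ±20 %
per-channel gain spread. Defaults describe one study-like participant:
16 h worn time, 6 eating events of 5–20 min, chew rate 1.6 Hz
(typical human chewing cadence), burst amplitude 150 mV (comfortably
between the 10 mV noise floor and the 180 mV upper context bound, so
the duty controller actually modulates). Event annotations are whole
minutes — the resolution of a diet journal — and the actual burst
activity starts and stops up to 20 s inside the annotated span,
deliberately injecting label noise at event edges. Optional knobs add
50 Hz line interference (off by default; it exercises the notch
filter) and brief non-eating confounder bursts (off by default — the
source does not characterise non-eating confounders, so no principled
default exists).

What the generator does **not** emulate: motor-unit-level EMG
physiology, electrode-skin impedance drift, motion artifacts, speaking
or facial-expression confounders with realistic statistics, and
between-participant variability beyond the seed. Passing tests
therefore demonstrate that the machinery behaves correctly and that
the trade-off mechanisms act as designed — not that the specific
retrieval percentages transfer to real free-living EMG.

Streams are written as UTF-8 tab-separated text (metadata comment
lines, a header, time in s and channels in mV at six decimals) with a
separate `*.events` file of start/end seconds; reading validates
channel-count consistency and event ordering.

## 6. Evaluation and orchestration

Retrieval is scored at the sample level: both event lists are expanded
to per-sample masks; precision is correct/retrieved, recall is
correct/truth, F1 the harmonic mean. Conventions for empty sets (the
source is silent): empty retrieval against non-empty truth scores
P = 0; when both truth and retrieval are empty, P = R = 1.

`evaluate_configuration` runs, per participant: sampling → stream
reconstruction → spotting with that participant's LOPO model → sample
PRF; it accumulates operation counts (every frame pays the tabulated
pre-processing; only gated-in frames pay feature extraction and
classification; the adaptive sampler adds its per-period tally),
prices ET/EC/MD/CL, and aggregates: P and R as unweighted means over
participants (the source reports averages without stating the
weighting; per-participant values are retained in the diagnostics),
EC as the per-participant mean with the four-part breakdown, ET and MD
as worst cases. The ET and MD requirement bounds are
configuration-dependent (frame length vs runtime; the chosen μC's
flash), so the exploration specialises the requirement set per row and
applies the same selection rule over the per-row feasibility.
Per-configuration failures are recorded in the report row and never
abort the sweep.

## 7. Problem sizes in the shipped experiments

The bundled trade-off experiment runs five synthetic participants of
2 h each over a θh grid of {60, 120, 180, 300} mV with five master
seeds and a single-point hyperparameter grid — sizes chosen so the
full experiment completes in a few minutes while leaving the
monotonicity of the reduction curve and the graceful degradation of F1
clearly resolvable above Monte-Carlo noise (tolerance 0.03 on the
mean-F1 monotonicity check). Unit tests use half-hour or shorter
streams. The generator's day-long defaults are used where duration
itself is not the object under test.

## 8. Known limitations

* Cycle counts are architectural approximations; real compilers,
  pipelines and memory hierarchies will deviate, and no
  instruction-accurate emulation is attempted.
* Electronic-circuit overheads (regulators, ADC front-end) are outside
  the energy model, as are radio back-off and retransmission.
* The printed cost-table's FFT memory entry ("k" floats) is not
  defined in the source; it is taken as the padded FFT length.
* The communication-latency example printed in the source (886 ms)
  depends on unstated inputs (the FFT pipeline's d and the chosen
  connInterval) and is not reproducible; CL is therefore validated
  structurally (rate arithmetic, monotonicity), not against that
  figure.
* One-minute annotation granularity bounds achievable sample-level
  recall on real journals and, by design, on the synthetic streams.
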