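# Methods

This note documents the models implemented in `songmem`, the parameter
choices that matter, and what the simulations do and do not show.

## Shunting dynamics (`songmem.shunting`)

Every circuit in the package is a recurrent on-center off-surround
network of cells obeying membrane-equation ("shunting") dynamics:

    dx_i/dt = -A x_i + (B - x_i)[I_i + Σ_k on_ik f(x_k)]
                     - (x_i + C)[J_i + Σ_k off_ik g(s_k)]

with `s_k = x_k` (fast off-surround) or `s_k = y_k`,
`dy_k/dt = ε(-y_k + x_k)` (slow inhibitory interneurons).  The source
literature describes this circuit verbally but does not print the ODE;
this standard form is adopted as the single source of truth for all
modules.  Integration is explicit Euler with default
`dt = 0.001/A`; non-finite updates raise an error naming the offending
cell.  We chose fixed-step Euler over adaptive solvers for exact
reproducibility: every quantity the tests assert is a deterministic
function of the parameters.

Key closed forms used throughout: a feedforward off-surround layer with
inputs `I` settles at `x_i = B I_i / (A + Σ I)`, which normalizes total
activity to `B ΣI/(A + ΣI) < B` (limited capacity) while preserving
input ratios exactly (the substrate of stable category learning).

The travelling-wave utility models apparent motion between two
sequentially flashed Gaussian receptive fields.  Envelopes are
first-order low-pass on/off transients (rise 20/s, decay 8/s by
default) — the simplest mechanism exhibiting the observed speed laws:
sweep speed increases as the inter-stimulus interval shrinks and as the
separation grows.  The continuous sweep requires overlapping fields
(separation ≲ 2σ); with disjoint fields the activity peak jumps.

## Item-Order-Rank working memory (`songmem.working_memory`)

A sequence is stored as activities over `(token, rank)` cells; the k-th
occurrence of a token is routed to rank k by the numerosity map.
Observable activities are the shunting-normalized shares
`x_i = B u_i/(A + Σu)` of underlying drives `u_i`.  Arrival dynamics are
resolved at their steady state: a new item enters with drive equal to
the input intensity, and every stored drive is multiplied by a common
consolidation factor

    ρ = shrink · (1 + η (B - T)) · (1 + g λ)

where `T` is the current total activity.  `shrink < 1` is the transient
inhibition exerted by the arriving item; `η` is recurrent on-center
consolidation, strong while the field is far from capacity; `λ` is
top-down expectation support with pathway gain `g`, multiplicative
because the learned expectation is proportional to the stored pattern
itself (top-down matching is modulatory).  Because every update
multiplies all stored drives by a common factor, ratios of previously
stored activities are preserved exactly.

A list is recalled in the correct order iff its gradient is strictly
decreasing (primacy), which holds exactly while ρ > 1; as the field
approaches capacity ρ falls below 1 and later items overtake, bowing
the gradient.  The frozen calibration — `A = B = 1`, input intensity
0.5, shrink 0.71, η = 1.2, g = 0.155, default λ = 1 — places the
crossover at list length 4 without top-down support and 7 with it (the
transient and immediate memory spans).  These two integers were the
calibration targets; the span is then measured, not assigned, by
storing lists of increasing length and classifying their gradients.

Rehearsal is winner-take-all with inhibition of return: the most active
cell is read out, self-inhibits, and the remaining field renormalizes
upward (each removal releases off-surround inhibition, which is why the
final list item rebounds above its stored value once the penultimate
item has been performed).  Exact ties break toward the earlier
presentation index, for determinism.  Output latency per item is
`0.05 + 0.1/(1 + x)` seconds — faster for stronger activities; only the
ordering and monotonicity of latencies are meaningful.

Noisy recall adds Gaussian perturbations per readout cycle, an output
threshold, and a multiplicative attentional fade (default 1.0 = none;
the serial-position experiments use 0.88/cycle).  Omissions concentrate
on low-activity interior items, giving the U-shaped recall curve;
transpositions are counted against the noise-free recall order of the
same gradient, since that is the order the stored pattern dictates, and
are most frequent between items adjacent in that order (most similar
activities).  Top-down support is applied during storage; a flag exists
to extend it to recall but is off by default.

## Numerosity map (`songmem.number_map`)

Event transients are summed by a perfect integrator (reset per
sequence; the source account gives the accumulator no leak).  The total
is broadcast to 48 map cells with geometrically spaced thresholds
spanning counts 1–16 (25% margin) and sensitivities inversely
proportional to threshold, i.e. each cell's tuning width in numerosity
units is proportional to its preferred numerosity.  One competitive
pass — each cell inhibited by its higher-threshold neighbour, with a
virtual boundary cell continuing the threshold ladder — converts the
activation step into a unimodal bump.  Profile widths are measured on
the preferred-numerosity axis, where they grow in proportion to the
count (Weber-law widening); on the geometric position axis the bump
width is nearly constant, which is the same statement.  A calibration
table built at configuration time maps peak positions back to counts;
construction fails loudly if any two counts collide, so rank decoding
is exact over 1–16 by construction.

## Masking-field chunking (`songmem.chunking`)

Chunks store L2-normalized working-memory patterns in bottom-up
(instar) and top-down (outstar) weights; only the winner learns, with
learning rate 1 (one-shot convergence to the normalized pattern; the
fixed point is the same for any rate).  The masking field is
multi-scale and self-similar: a chunk's scale is its number of learned
item connections; excitability grows with scale
(gain `1 + 0.2·scale`) and so does its effective competition.  The
settled outcome of the recurrent competition is computed directly:

* a chunk is *eligible* only if ≥ 95% of its weight mass lies on
  currently active cells (an incompletely supported large chunk is
  quenched by the fully supported smaller chunks' inhibition);
* among eligible chunks the largest scale-weighted gated input wins.

This yields the masking property: the full list MYSELF selects the
MYSELF chunk and suppresses MY, while MY alone — or any strict prefix
of MYSELF — selects MY.  Vigilance for learning is the fraction of
input energy covered by the winner's item set (≥ 0.8 to resonate);
mismatch commits a fresh chunk (capacity 64, error on exhaustion).
Because working-memory storage preserves ratios, previously learned
chunks keep matching their patterns after longer lists are learned: the
stability audits verify zero weight drift on MY while MYSELF is
learned.  Habituative transmitter gates (`dz/dt = δ(1-z) - ρSz`) sit on
the bottom-up pathways and depress a repeatedly winning chunk.
Top-down read-out with volition reproduces the stored gradient (and
hence the training order under rehearsal); without volition the
expectation only primes, scaled to half the firing threshold.

Static multi-scale connectivity is assumed; the developmental growth
process that produces it is not modeled.

## Spectral timing (`songmem.spectral_timing`)

Each of 40 cells reacts to the conditioned stimulus at its own rate
(`dx/dt = r(-x + (1-x)I)`), feeds a sharp sigmoid
(`f = x^12/(0.45^12 + x^12)`) through a habituating gate
(`dy/dt = r^q [0.005(1-y) - 16 f y]`), and the gated signal
`g = f·y` is a unimodal pulse.  Peak times are laid out geometrically
over 0.12–6 s by numerically inverting the rate → peak-time map.
Training samples `g_i` at the teaching instant:
`Δz_i = 0.2 g_i(ISI)(US - z_i)` per trial.  The population output
`R(t) = Σ g_i(t) z_i` peaks at the trained interval to within ~1%
across 0.18–4 s.

The gate-rate exponent `q = 0.85` is the load-bearing choice.  At
`q = 1` the spectrum is exactly self-similar: Weber's law and the
window proportionality are exact, but the amplitude envelope across
trainable intervals is flat to four decimals.  At `q = 0.85` the gate
kinetics almost track each cell's timescale — widths still grow in
proportion to the interval and the 0.3-of-peak duration window stays
0.92–1.06 × ISI across 0.25–4 s (which is what lets the window round to
the notated beat count) — while slower cells produce genuinely smaller
pulses, giving the falling limb of the inverted-U envelope.  The rising
limb comes from training below the fastest peak time (0.12 s), where no
cell has risen much by the teaching instant; such intervals are
trainable (representable range starts at 0.05 s) but weakly and with
late-biased peaks, exactly the regime where timed behavior degrades.

The cerebellar expression of the same signal is long-term depression:
Purkinje output = tonic P0 − R(t), and nuclear disinhibition
= max(P0 − Purkinje, 0) = R(t).  Both conventions are exposed and give
identical duration windows by algebraic identity.  The duration
threshold is frozen at 0.3 × max R.

## VITE (`songmem.motor_vite`)

`dD/dt = α(-D + T - P)`, `dP/dt = G([D]+ - [-D]+)` with α = 10/s.
The per-component dynamics are identical and linear, so the path is the
straight line to the target for every GO value — only timing changes.
GO ≤ α/4 keeps the system overdamped (monotone approach); the default
reach horizon scales as 12/G since the slow closed-loop pole is ≈ −G.
The completion detector time-averages outflow speed fast (a = 20/s) and
slowly (b = 4/s); (B − A) is negative while speed rises and crosses
zero after the peak, triggering the next rehearsal before the movement
ends.  The trigger is applied at the item (within-word) level.

## CPG (`songmem.rhythm_cpg`)

Channels are shunting cells (A = 1, B = 1, floor C = 0.5, sigmoid
on-center f with gain 8, half-point 0.4) with *slow* self-inhibitory
interneurons (ε = 0.1, coefficient D0 = 20): above a finite arousal
threshold (GO ≈ 0.17) the circuit is a relaxation oscillator whose
period falls monotonically with GO; `rate_scale = 20/s` puts the beat
near 120 BPM at GO = 1, with inter-beat CV < 0.1%.

Coupled channels revealed a clean empirical dichotomy that the package
exploits throughout: *fast* mutual inhibition (carried by the partner's
activity) stabilizes anti-phase firing, while *slow* mutual inhibition
(carried by the partner's interneuron) plus weak on-center
cross-excitation stabilizes in-phase firing.

**Tapping.** The two-channel configuration (slow mutual 5.0,
cross-excitation 0.1, baseline GO 0.1) tracks anti-phase pulse trains
faithfully at low input rates; once the pulses arrive faster than the
membrane can resolve them, the effective drive is tonic and the
intrinsic in-phase mode captures the network, which then persists for
the rest of an ascending ramp.  Removing one input leaves its channel
oscillating at full amplitude (missing beat), carried by rebound from
the slow mutual inhibition and the cross-excitation.  Limitation: the
in-phase transition occurs at drive rates far above the intrinsic
tapping rate (tens of cycles per intrinsic period), much higher than in
human bimanual data; the bifurcation structure, not its frequency
scale, is reproduced.

**Gaits.** Four channels (LF, RF, LH, RH) couple through three classes —
D1 (fore–fore and hind–hind), D2 (ipsilateral), D3 (diagonal).  The
class whose fast inhibition is weakest synchronizes its pairs: all
classes balanced gives the frustrated splay state (walk, quarter-cycle
lags), weak D3 gives trot, weak D2 pace, weak D1 gallop.  A purely
linear GO modulation of the coefficients cannot produce the full
sequence: each gait needs exactly one class sync-dominant, and a
monotone schedule cannot restore a class's fast inhibition after its
window (every linear variant tried collapsed to pronk above the trot
range).  The implemented modulation is therefore non-monotone: each
class's fast inhibition is V-shaped in GO with its minimum at a
class-specific level (D3 at 0.9, D2 at 1.5, D1 at 2.1; width 0.35,
maximum 1.2; slow couplings constant 3.0).  The frozen ascending grid
GO = (0.5, 0.9, 1.5, 2.1) then yields walk → trot → pace → gallop.
Between windows the network passes through mixed, unclassified states;
the grid samples the centers.  Integrators are numba-compiled;
simulations use dt = 0.002 natural time units.

## Pipeline (`songmem.pipeline`)

The continuous-time modules are orchestrated by a discrete-event
scheduler that implements the hierarchy's gating semantics (each level
rehearses to completion while the rehearsal node above it is held off;
the handoff trace records this), rather than one monolithic ODE — the
control logic is what the architecture specifies, and this keeps every
stage testable in isolation.

Encoding stores items → word chunks → phrase chunks → song chunk for
the lyrics stream and in parallel for the pitch stream; the two streams
are bound by shared word-event index, a declared simplification (no
binding mechanism is specified by the source account).  Rests are
stored as ordinary silent tokens, so they occupy serial positions and
consume beats but emit no events.  Phrases are limited to the immediate
span of 7 stored events; the packaged songs respect this (the 11-word
"Smoke" lyric is split at its musical phrase boundary so both
occurrences of "true" share one phrase and acquire ranks 1 and 2).

Rhythm training freezes the beat period at 0.5 s, counts beat pulses
during each word's rehearsal window, and delivers the teaching pulse
when the notated count completes — so the trained interval is
`duration_beats × 0.5 s` and durations are effectively stored *in
beats*.  Each (phrase, word token, rank) triple owns a private
spectrum, gated polyvalently by phrase chunk × word-rank cell: entries
other than the rehearsed word's are untouched by construction, and the
audit verifies zero weight change.  Performance decodes each learned
window against the training beat period (yielding beats, rounded to the
half-beat of the notation palette) and converts to seconds with the
current tempo: the beat-domain score is bit-identical across tempi and
the seconds domain scales exactly inversely — the factorization of
order and rhythm is exact by construction.  The volitional tempo signal
maps to beat period as `0.5 s / GO_tempo`, the idealization of the CPG
beat (whose simulated period decreases monotonically in GO but not
exactly as 1/GO).  Untrained words default to 1 beat; sustained vs
staccato rendering within the allotted beats is a configuration flag
affecting event duration only.

**Synthetic songs.** The generator samples 2 phrases of 3–6 words from
a 16-word vocabulary and an 8-pitch palette, durations from
{0.5, 1, 2, 4} beats, a 25% within-phrase repeat probability (at least
one repeat is forced per song) and 10% rests, all within span limits.
It emulates the structural properties the architecture is about —
bounded groupings, repeated words at distinct ranks, a half/whole/
multi-beat duration palette — and none of the acoustic, prosodic or
expressive variability of real music; round-trip fidelity on these
songs shows the order and rhythm machinery is exact under its stated
span and palette conditions, not that the model parses real
performances.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script
run in a few minutes on one core: CPG runs simulate 20–25 s of
behavior per condition; serial-position experiments use 400 noisy
trials of 12-item lists; round-trip fidelity uses 50 generated songs;
spectral-timing outputs are evaluated on 1 ms grids.

## Known limitations

* Working-memory storage uses steady-state arrival updates, not the
  full transient ODE between item arrivals.
* The tapping bifurcation's frequency scale is far above human data
  (above).
* Gait windows are sampled at calibrated GO centers; transitions
  between windows pass through unclassified mixed states.
* Chunk recognition assumes patterns within one stream level share one
  cell space; cross-level masking is not modeled.
* Lyric–pitch binding is by index, not by a learned mechanism.
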