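# songmem

Neural-dynamics simulation of how a brain can store, learn and perform
musical lyrics and melodies with variable rhythms and beats — built for
computational-neuroscience researchers and students who want a tested,
runnable implementation of the underlying circuit models rather than a
box-diagram description.

The package addresses a deceptively simple question: how can the words
of a song be stored *once*, in a tempo-invariant code, yet be performed
at any tempo and with learned, word-specific timing — including the
same word sung with different durations at different places ("my true
love was true")?  The answer implemented here is the **factorization of
order and rhythm**: serial *order* lives in working-memory activity
gradients and learned list chunks; *rhythm* lives in separately learned
cerebellar timing circuits and volitionally scaled beat oscillators.

## The models

Every circuit is a recurrent on-center off-surround network obeying
shunting (membrane-equation) dynamics

$$\dot x_i = -A x_i + (B - x_i)\Big[I_i + \sum_k C_{ik} f(x_k)\Big]
            - (x_i + C)\Big[J_i + \sum_k E_{ik} g(s_k)\Big],$$

whose activities are bounded, self-normalizing and ratio-preserving.
On this substrate the package implements:

* **Item-Order-Rank working memory** — a sequence is stored as a
  *primacy gradient* over (token, rank) cells: earlier items more
  active, repeats routed to distinct ranks by an analog numerosity map.
  Winner-take-all rehearsal with inhibition of return reads the list
  back in order.  With the frozen calibration the longest correctly
  recallable list is **4 items** from bottom-up storage alone and
  **7 items** with top-down expectation support — the magical numbers
  four and seven.  Longer lists bow (ends recalled first, interior
  transpositions local), as in free recall.
* **Masking-field list chunking with adaptive resonance** — variable-
  length list chunks learned by instar/outstar updates under a
  vigilance test; larger chunks mask their sublists when complete
  (MYSELF beats MY) yet learning MYSELF never recodes MY.
* **Cerebellar spectral timing** — a spectrum of cells reacting at
  graded rates; five paired trials teach the population output to peak
  at the trained delay, with Weber-law widths and an inverted-U
  amplitude envelope.  Its thresholded window supplies each word's
  performance duration, in beats.
* **VITE motor control** — difference-vector reaches with bell-shaped
  speed profiles; a fast/slow speed-average comparator triggers the
  next item just before each movement completes.
* **Shunting CPGs** — slow-inhibition relaxation oscillators: a
  volitionally scaled beat (~120 BPM at GO = 1), the bimanual-tapping
  anti-phase → in-phase bifurcation with missing-beat persistence, and
  quadruped gait transitions (walk → trot → pace → gallop) under an
  ascending GO sweep.
* **The pipeline** — encode a song's lyrics and pitch streams into a
  chunk hierarchy, train per-(phrase, word, rank) durations from beat
  counting through polyvalent gates, and perform the song as a timed
  score.  Two fixtures are packaged: the Alphabet Song fragment and the
  opening phrase of *Smoke Gets in Your Eyes*, plus a seeded random
  song generator.

## Worked example

Perform the *Smoke Gets in Your Eyes* fixture (encode → train rhythm →
perform at the default tempo, GO_tempo = 1, i.e. a 0.5 s beat):

```text
$ songmem perform smoke_fragment
   0.0 beats   0.000 s      they (Eb4)  4.0 beats
   4.0 beats   2.000 s     asked (F4)  1.0 beats
   5.0 beats   2.500 s        me (G4)  1.0 beats
   6.0 beats   3.000 s       how (F4)  1.0 beats
   7.0 beats   3.500 s         I (G4)  1.0 beats
   8.0 beats   4.000 s      knew (Ab4)  4.0 beats
  12.0 beats   6.000 s        my (G4)  1.0 beats
  13.0 beats   6.500 s      true (F4)  1.0 beats
  14.0 beats   7.000 s      love (Eb4)  1.0 beats
  15.0 beats   7.500 s       was (D4)  1.0 beats
  16.0 beats   8.000 s      true (Eb4)  4.0 beats
```

Word order is reproduced exactly from the stored hierarchy, and every
duration is *recalled from the trained timing spectra*, not copied from
the notation: "they", "knew" and the second "true" are held four beats
while the first "true" gets one beat — the same word at two ranks
carries two learned durations.  Re-running with `--tempo-go 2` leaves
the beats column untouched and halves every entry in the seconds
column: order and rhythm factorize.

The component circuits can be probed directly:

```text
$ songmem wm-span
transient span (bottom-up only): 4
immediate span (with expectations): 7

$ songmem timing-demo --isi 0.4
trained ISI      : 400 ms
output peak      : 396 ms
duration window  : 237-654 ms

$ songmem cpg-demo --mode beat --go 1.0
GO=1.0: beat period 475 ms (126 BPM), CV 0.01%

$ songmem cpg-demo --mode gait
walk -> trot -> pace -> gallop
```

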