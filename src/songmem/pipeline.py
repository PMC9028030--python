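"""End-to-end pipeline: encode a song, train its rhythm, perform it.

A song is a hierarchy of phrases made of word events; each word event
carries its item tokens (letters), a pitch token and a notated duration
in beats (rests are silent events that consume beats).  The pipeline
realizes the factorization of order and rhythm:

* ``encode_song`` stores the song *order* in working-memory gradients and
  list chunks, level by level (items -> word chunks -> phrase chunks ->
  song chunk), for the lyrics stream and, in parallel, the pitch stream.
  The stored code is tempo-invariant: nothing about timing enters it.
* ``train_rhythm`` attaches *rhythm* to the order code: while a word is
  being rehearsed inside its phrase, a polyvalent gate (phrase chunk x
  word-rank working-memory cell) opens that word's private spectral-
  timing circuit, and the beat-counting signal delivers the teaching
  pulse when the notated number of beats has elapsed.  Durations are
  hereby stored in *beats*, and a repeated word trains distinct
  durations at its distinct ranks.
* ``perform`` reads the hierarchy back out (winner-take-all rehearsal
  with inhibition of return at every level, each level suppressing the
  rehearsal node above it while it is busy), converts each word's
  learned duration window into beats and then into seconds through the
  current volitional tempo, and renders within-word items as VITE
  reaches chained by the movement-completion signal.  Doubling the tempo
  GO halves every onset in seconds and changes nothing in beats.

The volitional tempo signal maps to the beat period as
``base_period / GO_tempo`` (0.5 s at GO_tempo = 1, i.e. 120 BPM), the
idealization of the CPG beat whose period falls monotonically with GO.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import chunking, motor_vite, number_map, spectral_timing, working_memory
from .chunking import ChunkNetwork, learn, readout_expectation
from .spectral_timing import (ConditioningProtocol, TimingSpectrum,
                              population_output, timed_duration, train)
from .working_memory import (ItemSequence, WMGradient, WMParams,
                             present_sequence, rehearse)

__all__ = [
    "WordEvent",
    "Song",
    "SongValidationError",
    "EncodingError",
    "TrainingError",
    "Hierarchy",
    "PolyvalentGate",
    "TimingBank",
    "PerformanceScore",
    "read_song",
    "write_song",
    "write_score",
    "fixture_songs",
    "generate_song",
    "encode_song",
    "train_rhythm",
    "perform",
    "performance_audit",
    "BASE_BEAT_PERIOD",
    "TRAINING_BEAT_PERIOD",
]

BASE_BEAT_PERIOD = 0.5       # seconds per beat at GO_tempo = 1 (120 BPM)
TRAINING_BEAT_PERIOD = 0.5   # beat period frozen during rhythm training


# ---------------------------------------------------------------------------
# song structure and I/O
# ---------------------------------------------------------------------------

class SongValidationError(ValueError):
    """Song file violates the schema; message names the offending field."""


class EncodingError(RuntimeError):
    """A level's sequence exceeds its calibrated span."""


class TrainingError(RuntimeError):
    """Rhythm training is missing a prerequisite (e.g. beat source)."""


@dataclass
class WordEvent:
    """One notated event: a word (or rest) with pitch and beat duration."""

    word: str | None
    items: list = field(default_factory=list)
    pitch: str | None = None
    duration_beats: float = 1.0
    is_rest: bool = False

    def validate(self, where: str) -> None:
        if self.duration_beats <= 0:
            raise SongValidationError(f"{where}.duration_beats must be > 0")
        if self.is_rest:
            if self.word is not None or self.pitch is not None:
                raise SongValidationError(f"{where}: rest events carry no word or pitch")
        else:
            if not self.word:
                raise SongValidationError(f"{where}.word is required for non-rest events")
            if not self.items:
                raise SongValidationError(f"{where}.items is required for non-rest events")
            if not self.pitch:
                raise SongValidationError(f"{where}.pitch is required for non-rest events")


@dataclass
class Song:
    title: str
    phrases: list                      # list of lists of WordEvent
    beat_period_s: float = BASE_BEAT_PERIOD

    def validate(self) -> None:
        if self.beat_period_s <= 0:
            raise SongValidationError("beat_period_s must be > 0")
        if not isinstance(self.phrases, list):
            raise SongValidationError("phrases must be a list")
        for pi, phrase in enumerate(self.phrases):
            for wi, ev in enumerate(phrase):
                ev.validate(f"phrases[{pi}][{wi}]")

    def word_events(self):
        for pi, phrase in enumerate(self.phrases):
            for wi, ev in enumerate(phrase):
                yield pi, wi, ev

    def to_dict(self) -> dict:
        return {
            "title": self.title,
            "beat_period_s": self.beat_period_s,
            "phrases": [
                [
                    {
                        "word": ev.word,
                        "items": list(ev.items),
                        "pitch": ev.pitch,
                        "duration_beats": ev.duration_beats,
                        "is_rest": ev.is_rest,
                    }
                    for ev in phrase
                ]
                for phrase in self.phrases
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Song":
        if not isinstance(d, dict):
            raise SongValidationError("song file must contain a JSON object")
        for key in ("title", "phrases"):
            if key not in d:
                raise SongValidationError(f"missing required field {key!r}")
        phrases = []
        for pi, phrase in enumerate(d["phrases"]):
            evs = []
            for wi, ed in enumerate(phrase):
                if not isinstance(ed, dict):
                    raise SongValidationError(
                        f"phrases[{pi}][{wi}] must be an object")
                unknown = set(ed) - {"word", "items", "pitch",
                                     "duration_beats", "is_rest"}
                if unknown:
                    raise SongValidationError(
                        f"phrases[{pi}][{wi}]: unknown fields {sorted(unknown)}")
                evs.append(WordEvent(
                    word=ed.get("word"),
                    items=list(ed.get("items", [])),
                    pitch=ed.get("pitch"),
                    duration_beats=float(ed.get("duration_beats", 1.0)),
                    is_rest=bool(ed.get("is_rest", False)),
                ))
            phrases.append(evs)
        song = cls(title=str(d["title"]), phrases=phrases,
                   beat_period_s=float(d.get("beat_period_s", BASE_BEAT_PERIOD)))
        song.validate()
        return song


def read_song(path) -> Song:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as e:
            raise SongValidationError(f"invalid JSON: {e}") from e
    return Song.from_dict(data)


def write_song(song: Song, path) -> None:
    song.validate()
    Path(path).write_text(json.dumps(song.to_dict(), indent=2))


def write_score(score: "PerformanceScore", path) -> None:
    import pandas as pd

    rows = [
        {
            "word": ev["word"], "pitch": ev["pitch"],
            "onset_beats": ev["onset_beats"],
            "onset_seconds": ev["onset_seconds"],
            "duration_beats": ev["duration_beats"],
            "duration_seconds": ev["duration_seconds"],
        }
        for ev in score.events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fixtures and the synthetic song generator
# ---------------------------------------------------------------------------

def _word(word, pitch, beats):
    return WordEvent(word=word, items=list(word), pitch=pitch,
                     duration_beats=beats)


def _rest(beats=1.0):
    return WordEvent(word=None, items=[], pitch=None,
                     duration_beats=beats, is_rest=True)


def fixture_songs() -> dict:
    """The two packaged songs.

    ``alphabet_fragment``: A-G on one beat each, then a pause; H-K on one
    beat; L M and N O share one beat (half a beat each); P; pause.  Each
    phrase stays within the immediate span of 7 stored events (rests are
    stored as silent tokens).

    ``smoke_fragment``: the opening lyric "They asked me how I knew my
    true love was true", split at the musical phrase boundary so both
    occurrences of "true" fall in one phrase; "they", "knew" and the
    second "true" are held four beats, every other word one beat.
    """
    alphabet = Song(
        title="Alphabet Song (fragment)",
        phrases=[
            [_word(w, p, 1.0) for w, p in
             zip("ABCDEFG", ["C4", "C4", "G4", "G4", "A4", "A4", "G4"])],
            [_rest(1.0)] + [
                _word(w, p, 1.0) for w, p in
                zip("HIJK", ["F4", "F4", "E4", "E4"])],
            [_word("L", "D4", 0.5), _word("M", "D4", 0.5),
             _word("N", "D4", 0.5), _word("O", "D4", 0.5),
             _word("P", "C4", 1.0), _rest(1.0)],
        ],
    )
    smoke_words = [
        ("they", "Eb4", 4.0), ("asked", "F4", 1.0), ("me", "G4", 1.0),
        ("how", "F4", 1.0), ("I", "G4", 1.0), ("knew", "Ab4", 4.0),
    ]
    smoke_words2 = [
        ("my", "G4", 1.0), ("true", "F4", 1.0), ("love", "Eb4", 1.0),
        ("was", "D4", 1.0), ("true", "Eb4", 4.0),
    ]
    smoke = Song(
        title="Smoke Gets in Your Eyes (opening phrase)",
        phrases=[
            [_word(w, p, b) for w, p, b in smoke_words],
            [_word(w, p, b) for w, p, b in smoke_words2],
        ],
    )
    return {"alphabet_fragment": alphabet, "smoke_fragment": smoke}


_GEN_VOCAB = [
    "la", "sun", "moon", "rain", "gold", "bird", "tree", "sea", "sky",
    "dream", "road", "fire", "wind", "stone", "leaf", "song",
]
_GEN_PITCHES = ["C4", "D4", "E4", "F4", "G4", "A4", "B4", "C5"]


@dataclass
class GeneratorConfig:
    """Synthetic-song sampling conditions.

    Defaults keep every phrase within the immediate span (7 stored
    events) and draw durations from the half/1/2/4-beat palette the
    fixtures use; ``repeat_probability`` is the chance a word is a
    repeat of an earlier word in the same phrase (exercising rank
    coding), and ``force_repeat`` guarantees at least one such repeat
    per song.
    """

    n_phrases: int = 2
    min_words: int = 3
    max_words: int = 6
    repeat_probability: float = 0.25
    rest_probability: float = 0.1
    duration_palette: tuple = (0.5, 1.0, 2.0, 4.0)
    force_repeat: bool = True

    def validate(self) -> None:
        if self.max_words > 7:
            raise SongValidationError(
                "max_words exceeds the immediate span of 7")
        if not (0 <= self.repeat_probability <= 1):
            raise SongValidationError("repeat_probability must be in [0, 1]")
        if self.n_phrases > 7:
            raise SongValidationError("n_phrases exceeds the song-level span of 7")


def generate_song(seed: int, config: GeneratorConfig | None = None) -> Song:
    """Deterministically sample a random song within span limits."""
    if config is None:
        config = GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    phrases = []
    placed_repeat = False
    for pi in range(config.n_phrases):
        n_words = int(rng.integers(config.min_words, config.max_words + 1))
        events = []
        words_so_far = []
        for wi in range(n_words):
            if wi > 0 and rng.random() < config.rest_probability and len(events) < 6:
                events.append(_rest(1.0))
            repeat = (words_so_far
                      and rng.random() < config.repeat_probability)
            if repeat:
                word = str(rng.choice(words_so_far))
                placed_repeat = True
            else:
                word = str(rng.choice(_GEN_VOCAB))
            words_so_far.append(word)
            pitch = str(rng.choice(_GEN_PITCHES))
            beats = float(rng.choice(config.duration_palette))
            events.append(_word(word, pitch, beats))
        phrases.append(events[:7])
    if config.force_repeat and not placed_repeat and phrases:
        # repeat the first word of the last phrase at its end
        last = phrases[-1]
        first_word = next((ev for ev in last if not ev.is_rest), None)
        if first_word is not None and len(last) < 7:
            beats = float(rng.choice(config.duration_palette))
            last.append(_word(first_word.word,
                              str(rng.choice(_GEN_PITCHES)), beats))
    song = Song(title=f"generated-{seed}", phrases=phrases)
    song.validate()
    return song


# ---------------------------------------------------------------------------
# hierarchical encoding
# ---------------------------------------------------------------------------

@dataclass
class Hierarchy:
    """Stored order code of one stream (lyrics or pitches).

    Levels: item-level chunks (one per distinct word, learned from its
    item sequence), phrase-level chunks (one per phrase, learned from the
    word-level working-memory gradient), and one song-level chunk over
    phrase tokens.
    """

    stream: str
    word_net: ChunkNetwork
    phrase_net: ChunkNetwork
    song_net: ChunkNetwork
    word_chunks: dict                    # word token -> chunk id
    phrase_chunks: list                  # phrase index -> chunk id
    song_chunk: object
    phrase_gradients: list               # phrase index -> WMGradient
    song_gradient: WMGradient
    wm_params: WMParams


def _storage_params(seed: int) -> WMParams:
    return WMParams(top_down_gain=working_memory.DEFAULT_TOP_DOWN, seed=seed)


def _encode_stream(stream: str, sequences: list, item_seqs: dict,
                   params: WMParams) -> Hierarchy:
    span = working_memory.immediate_span(params)
    word_net = ChunkNetwork()
    phrase_net = ChunkNetwork()
    song_net = ChunkNetwork()

    word_chunks = {}
    for token, items in item_seqs.items():
        if len(items) > span:
            raise EncodingError(
                f"{stream} item level: {token!r} has {len(items)} items, "
                f"span is {span}")
        g = present_sequence(ItemSequence(items), params)
        word_chunks[token] = learn(g, word_net, label=str(token))

    phrase_chunks = []
    phrase_gradients = []
    for pi, tokens in enumerate(sequences):
        if len(tokens) > span:
            raise EncodingError(
                f"{stream} phrase level: phrase {pi} stores {len(tokens)} "
                f"events, span is {span}")
        g = present_sequence(ItemSequence(tokens), params)
        phrase_gradients.append(g)
        phrase_chunks.append(learn(g, phrase_net, label=f"{stream}-phrase-{pi}"))

    phrase_tokens = [f"{stream}-phrase-{pi}" for pi in range(len(sequences))]
    if len(phrase_tokens) > span:
        raise EncodingError(
            f"{stream} song level: {len(phrase_tokens)} phrases, span is {span}")
    song_gradient = present_sequence(ItemSequence(phrase_tokens), params)
    song_chunk = learn(song_gradient, song_net, label=f"{stream}-song")
    return Hierarchy(stream=stream, word_net=word_net, phrase_net=phrase_net,
                     song_net=song_net, word_chunks=word_chunks,
                     phrase_chunks=phrase_chunks, song_chunk=song_chunk,
                     phrase_gradients=phrase_gradients,
                     song_gradient=song_gradient, wm_params=params)


REST_TOKEN = "~rest"
"""Rests are stored as ordinary (silent) tokens in working memory."""


def encode_song(song: Song, seed: int = 0) -> dict:
    """Recursive read-in of both streams; returns {"lyrics", "pitches"}.

    Word repeats inside a phrase occupy distinct ranks in the phrase's
    working-memory gradient (Item-Order-Rank coding); rests are stored as
    silent tokens so they claim their serial position.
    """
    song.validate()
    params = _storage_params(seed)

    lyric_sequences = []
    pitch_sequences = []
    item_seqs: dict = {}
    for phrase in song.phrases:
        lyric_sequences.append(
            [REST_TOKEN if ev.is_rest else ev.word for ev in phrase])
        pitch_sequences.append(
            [REST_TOKEN if ev.is_rest else ev.pitch for ev in phrase])
        for ev in phrase:
            if not ev.is_rest:
                item_seqs[ev.word] = list(ev.items)
    pitch_items = {p: [p] for seq in pitch_sequences for p in seq
                   if p != REST_TOKEN}

    lyrics = _encode_stream("lyrics", lyric_sequences, item_seqs, params)
    pitches = _encode_stream("pitches", pitch_sequences, pitch_items, params)
    return {"lyrics": lyrics, "pitches": pitches}


# ---------------------------------------------------------------------------
# rhythm training (counting-gated spectral timing)
# ---------------------------------------------------------------------------

@dataclass
class PolyvalentGate:
    """Fires only on converging specific + nonspecific inputs."""

    specific: object       # (phrase chunk id, word token, rank)
    nonspecific: str       # "rehearsal" or "volition"
    specific_on: bool = False
    nonspecific_on: bool = False

    @property
    def fires(self) -> bool:
        return self.specific_on and self.nonspecific_on


@dataclass
class TimingBank:
    """Trained duration codes: (phrase idx, word token, rank) -> spectrum."""

    entries: dict = field(default_factory=dict)
    beat_period: float = TRAINING_BEAT_PERIOD

    def spectrum(self, key) -> TimingSpectrum | None:
        return self.entries.get(key)


def train_rhythm(song: Song, hierarchies: dict,
                 beat_period: float | None = None,
                 n_trials: int = 5, seed: int = 0) -> TimingBank:
    """Train per-(phrase, word, rank) durations from beat counting.

    During each training pass, the word currently rehearsed inside its
    phrase opens its polyvalent gate; beat pulses are accumulated by the
    counting circuit and the teaching pulse arrives when the notated
    number of beats has elapsed, i.e. at ISI = duration_beats x beat
    period.  Only the gated entry's spectral weights change.
    """
    if beat_period is None:
        beat_period = TRAINING_BEAT_PERIOD
    if beat_period <= 0:
        raise TrainingError("rhythm training requires a beat source "
                            "(positive beat period)")
    lyrics: Hierarchy = hierarchies["lyrics"]
    bank = TimingBank(beat_period=beat_period)
    for pi, phrase in enumerate(song.phrases):
        # rehearse the phrase's stored gradient to obtain the training order
        g = lyrics.phrase_gradients[pi]
        trace = rehearse(g, lyrics.wm_params)
        notated = {}
        counts: dict = {}
        for ev in phrase:
            token = REST_TOKEN if ev.is_rest else ev.word
            counts[token] = counts.get(token, 0) + 1
            notated[(token, counts[token])] = ev.duration_beats
        for token, rank, _lat in trace.events:
            if token == REST_TOKEN:
                continue  # silent beats: counted, not trained
            beats = notated[(token, rank)]
            gate = PolyvalentGate(
                specific=(lyrics.phrase_chunks[pi], token, rank),
                nonspecific="rehearsal", specific_on=True, nonspecific_on=True)
            if not gate.fires:  # pragma: no cover - definitional
                continue
            # the counting circuit confirms integer beat counts
            if float(beats).is_integer():
                acc = number_map.accumulate(int(beats))
                if acc.value != beats:
                    raise TrainingError("beat counting mismatch")
            key = (pi, token, rank)
            spectrum = bank.entries.get(key)
            if spectrum is None:
                spectrum = TimingSpectrum()
                bank.entries[key] = spectrum
            train(spectrum, ConditioningProtocol(
                ISI=beats * beat_period, n_trials=n_trials))
    return bank


# ---------------------------------------------------------------------------
# performance
# ---------------------------------------------------------------------------

@dataclass
class PerformanceScore:
    """Ordered timed events plus the tempo that produced the seconds."""

    events: list                 # dicts: word, pitch, onset/duration in both domains
    tempo_go: float
    beat_period: float
    handoff_trace: list = field(default_factory=list)

    def word_sequence(self) -> list:
        return [ev["word"] for ev in self.events]

    def durations_beats(self) -> list:
        return [ev["duration_beats"] for ev in self.events]


def _duration_beats(bank: TimingBank, key, beat_period: float) -> float:
    spectrum = bank.spectrum(key)
    if spectrum is None:
        return 1.0  # untrained words default to one beat
    # evaluate the learned output over a window generously covering the peak
    horizon = 3.5 * max(spectrum.peak_times[0], 1.0) * 4
    horizon = min(horizon, 3.0 * spectrum.config.max_peak_time)
    t = np.arange(1, int(horizon * 1000)) / 1000.0
    out = population_output(spectrum, t)
    try:
        d = timed_duration(out, beat_period=beat_period)
    except spectral_timing.NoDurationError:
        return 1.0
    return d["duration_beats"]


def perform(hierarchies: dict, bank: TimingBank | None = None,
            GO_tempo: float = 1.0, GO_motor: float = 1.0,
            seed: int = 0, render_style: str = "sustained") -> PerformanceScore:
    """Recursive read-out of the encoded song as a timed event score.

    Each level runs winner-take-all rehearsal with inhibition of return;
    the rehearsal node of level k is inhibited while level k-1 performs
    (recorded in the handoff trace).  Word durations come from the
    timing bank (beats), converted to seconds by the volitional tempo;
    within-word items are VITE reaches chained by the completion signal.
    """
    if GO_tempo <= 0:
        raise ValueError("GO_tempo must be > 0")
    lyrics: Hierarchy = hierarchies["lyrics"]
    pitches: Hierarchy = hierarchies["pitches"]
    if bank is None:
        bank = TimingBank()
    beat_period = BASE_BEAT_PERIOD / GO_tempo
    params = lyrics.wm_params

    events = []
    handoff = []
    onset_beats = 0.0

    song_wm = readout_expectation(lyrics.song_chunk, lyrics.song_net)
    phrase_order = rehearse(song_wm, params).events
    handoff.append(("song", "rehearsing-phrases", len(phrase_order)))
    for phrase_token, _rank, _lat in phrase_order:
        pi = int(str(phrase_token).rsplit("-", 1)[1])
        handoff.append(("song-R", "off", pi))  # phrase level now active
        word_wm = readout_expectation(lyrics.phrase_chunks[pi],
                                      lyrics.phrase_net)
        pitch_wm = readout_expectation(pitches.phrase_chunks[pi],
                                       pitches.phrase_net)
        word_events = rehearse(word_wm, params).events
        pitch_events = rehearse(pitch_wm, params).events
        for wi, (token, rank, _l) in enumerate(word_events):
            handoff.append(("phrase-R", "off", (pi, wi)))  # word level active
            if token == REST_TOKEN:
                # a silent beat: consume notated time, emit nothing
                onset_beats += 1.0
                continue
            # decode the learned window against the training beat period:
            # the stored code is in beats, so tempo transfer is exact
            beats = _duration_beats(bank, (pi, token, rank), bank.beat_period)
            pitch_token = (pitch_events[wi][0]
                           if wi < len(pitch_events) else None)
            if pitch_token == REST_TOKEN:
                pitch_token = None
            # render the word's items as chained VITE reaches
            items = []
            item_wm = lyrics.word_chunks.get(token)
            if item_wm is not None:
                item_grad = readout_expectation(item_wm, lyrics.word_net)
                items = [c[0] for c in item_grad.presentation_order]
            item_times = _render_items(len(items), GO_motor)
            dur_beats = beats
            if render_style == "staccato":
                dur_beats = min(1.0, beats)
            events.append({
                "word": token,
                "rank": rank,
                "pitch": pitch_token,
                "onset_beats": onset_beats,
                "onset_seconds": onset_beats * beat_period,
                "duration_beats": dur_beats,
                "duration_seconds": dur_beats * beat_period,
                "allotted_beats": beats,
                "items": items,
                "item_trigger_times": item_times,
            })
            # the next word is inhibited until this word's count completes
            onset_beats += beats
        handoff.append(("phrase", "complete", pi))
    return PerformanceScore(events=events, tempo_go=GO_tempo,
                            beat_period=beat_period, handoff_trace=handoff)


def _render_items(n_items: int, GO_motor: float) -> list:
    """Completion-triggered onsets (s) of successive within-word reaches."""
    if n_items <= 0 or GO_motor <= 0:
        return []
    reach = motor_vite.vite_reach([1.0], [0.0], G=GO_motor, dt=0.002,
                                  t_end=min(12.0 / GO_motor, 8.0))
    cs = motor_vite.completion_signal(reach.speed, 0.002)
    step = cs.trigger_time if cs.trigger_time is not None else reach.t[-1]
    return [round(i * step, 6) for i in range(n_items)]


def performance_audit(song: Song, score: PerformanceScore,
                      score_other_tempo: PerformanceScore | None = None) -> dict:
    """Compare a performed score against the notated song.

    Reports exact token-order match, per-word duration error in beats,
    and (when a second score at a different tempo is given) the tempo-
    invariance of the beat domain and the scaling of the seconds domain.
    """
    notated = [(ev.word, ev.duration_beats)
               for _pi, _wi, ev in song.word_events() if not ev.is_rest]
    performed = [(ev["word"], ev["allotted_beats"]) for ev in score.events]
    order_ok = [w for w, _ in notated] == [w for w, _ in performed]
    n = min(len(notated), len(performed))
    duration_errors = [performed[i][1] - notated[i][1] for i in range(n)]
    report = {
        "order_exact": order_ok,
        "n_notated": len(notated),
        "n_performed": len(performed),
        "duration_errors_beats": duration_errors,
        "max_abs_duration_error": (max(abs(e) for e in duration_errors)
                                   if duration_errors else 0.0),
    }
    if score_other_tempo is not None:
        a, b = score, score_other_tempo
        beats_a = [(ev["onset_beats"], ev["duration_beats"]) for ev in a.events]
        beats_b = [(ev["onset_beats"], ev["duration_beats"]) for ev in b.events]
        report["beat_domain_identical"] = beats_a == beats_b
        ratio = a.tempo_go / b.tempo_go
        sec_ok = True
        for ea, eb in zip(a.events, b.events):
            if ea["onset_seconds"] > 0:
                r = eb["onset_seconds"] / ea["onset_seconds"]
                if abs(r - ratio) > 0.01 * ratio:
                    sec_ok = False
        report["seconds_domain_scaling_ok"] = sec_ok
    return report
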