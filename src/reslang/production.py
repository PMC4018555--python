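"""Sentence production: the scene-description model.

The inverse task: given a predicate-argument meaning (one or two spatial
relations sharing their agent) plus a flag choosing the canonical or
non-canonical construction, generate the describing sentence.

The meaning is coded on the same 36-cell role grid the comprehension model
emits, but indexed by *surface* position: the construction pattern decides
which SW slot each content word will occupy in the sentence.  The grid is
presented as a constant input; the readout is trained to reproduce the word
sequence as square waves (5 steps per word, 5-step gaps), one output unit
per closed-class word plus one for the SW marker.  Decoding scans the trace
for supra-threshold winners and rebinds the FIFO words into the SW slots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .comprehension import Lexicon, to_grammatical_form
from .esn import (
    ReadoutWeights,
    ReservoirConfig,
    ReservoirWeights,
    apply_readout,
    init_weights,
    run_reservoir,
    run_reservoir_batch,
    train_readout,
)
from .meaning import (
    GRID_CELLS,
    ROLE_ARG1,
    ROLE_ARG2,
    ROLE_PREDICATE,
    MeaningRecord,
    RoleGrid,
)

__all__ = [
    "CANONICAL",
    "NON_CANONICAL",
    "DEFAULT_SD_LEXICON",
    "ConstructionPattern",
    "ProductionModel",
    "MalformedProductionError",
    "meaning_to_coded_input",
    "encode_meaning_input",
    "encode_production_teacher",
    "decode_word_trace",
    "train_production",
    "produce",
]

CANONICAL = "canonical"
NON_CANONICAL = "non_canonical"

#: Scene-description closed-class words; the terminal dot is part of the
#: seven-unit output layout but unused by the stock corpora.
DEFAULT_SD_LEXICON = Lexicon(closed_class_words=("and", "is", "of", "the", "to", "."))

#: Default production hyperparameters (500 units, leak 0.75, input scaling
#: 0.01, spectral radius 2).
SD_DEFAULTS = dict(
    n_units=500,
    leak_rate=0.75,
    spectral_radius=2.0,
    input_scaling=0.01,
)


@dataclass(frozen=True)
class ConstructionPattern:
    """Surface positions (1-based SW indices) for each meaning slot.

    ``mapping[k]`` gives (predicate, arg1, arg2) surface positions of
    relation k.  The four stock patterns:

    ========================  ==============================
    single, canonical         SW2(SW1, SW3)
    single, non-canonical     SW1(SW3, SW2)
    double, canonical         SW2(SW1, SW3); SW4(SW1, SW5)
    double, non-canonical     SW1(SW5, SW2); SW3(SW5, SW4)
    ========================  ==============================
    """

    relation_count: int
    mapping: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.relation_count != len(self.mapping):
            raise ValueError("mapping length must equal relation_count")
        positions = sorted({p for triple in self.mapping for p in triple})
        if positions != list(range(1, len(positions) + 1)):
            raise ValueError(
                f"surface positions must be a permutation of 1..n, got {positions}"
            )


PATTERNS: dict[tuple[int, str], ConstructionPattern] = {
    (1, CANONICAL): ConstructionPattern(1, ((2, 1, 3),)),
    (1, NON_CANONICAL): ConstructionPattern(1, ((1, 3, 2),)),
    (2, CANONICAL): ConstructionPattern(2, ((2, 1, 3), (4, 1, 5))),
    (2, NON_CANONICAL): ConstructionPattern(2, ((1, 5, 2), (3, 5, 4))),
}


def meaning_to_coded_input(
    meaning: MeaningRecord, form: str
) -> tuple[RoleGrid, list[str]]:
    """Code a meaning for the chosen construction.

    Returns the role grid (indexed by surface SW position) and the FIFO of
    content words ordered by surface position.  Double relations must share
    their agent (first argument), the only two-relation shape the stock
    patterns cover.
    """
    if form not in (CANONICAL, NON_CANONICAL):
        raise ValueError(f"form must be {CANONICAL!r} or {NON_CANONICAL!r}, got {form!r}")
    n_rel = len(meaning.predications)
    pattern = PATTERNS[(n_rel, form)]
    for pred in meaning.predications:
        if not (pred.arg1 and pred.arg2):
            raise ValueError(
                f"unsupported meaning shape: relation {pred} needs two arguments"
            )
    if n_rel == 2:
        a, b = meaning.predications
        if a.arg1 != b.arg1:
            raise ValueError(
                "unsupported meaning shape: double relations must share their agent "
                f"({a.arg1!r} vs {b.arg1!r})"
            )
    n_positions = max(p for triple in pattern.mapping for p in triple)
    fifo: list[str | None] = [None] * n_positions
    grid = RoleGrid()
    for k, pred in enumerate(meaning.predications):
        pos = pattern.mapping[k]
        for role, surface, word in (
            (ROLE_PREDICATE, pos[0], pred.predicate),
            (ROLE_ARG1, pos[1], pred.arg1),
            (ROLE_ARG2, pos[2], pred.arg2),
        ):
            slot = surface - 1
            if fifo[slot] is not None and fifo[slot] != word:
                raise ValueError(
                    f"surface slot SW{surface} assigned both {fifo[slot]!r} and {word!r}"
                )
            fifo[slot] = word
            grid.active[slot, role, k] = True
    return grid, [w for w in fifo if w is not None]


def encode_meaning_input(grid: RoleGrid, T: int) -> np.ndarray:
    """Constant input: active grid cells at 1 for all T steps, others 0."""
    if T < 1:
        raise ValueError("T must be >= 1")
    return np.tile(grid.flatten()[None, :], (T, 1))


def encode_production_teacher(
    form_tokens,
    T_max: int,
    lexicon: Lexicon = DEFAULT_SD_LEXICON,
    word_len: int = 5,
    gap_len: int = 5,
) -> np.ndarray:
    """Square-wave teacher: word k at 1 on steps [k*(word_len+gap_len), +word_len).

    The gap after the last word doubles as the final pause; the signal is
    zero-padded to ``T_max`` so all teachers share the maximal length.
    """
    period = word_len + gap_len
    needed = len(form_tokens) * period
    if T_max < needed:
        raise ValueError(f"T_max {T_max} too short for {len(form_tokens)} tokens")
    trace = np.zeros((T_max, lexicon.input_dim))
    for k, tok in enumerate(form_tokens):
        trace[k * period : k * period + word_len, lexicon.unit_index(tok)] = 1.0
    return trace


def decode_word_trace(
    trace: np.ndarray,
    threshold: float = 0.5,
    lexicon: Lexicon = DEFAULT_SD_LEXICON,
    min_run: int = 2,
) -> list[str]:
    """Scan a word trace into a token sequence.

    Per time step the winning unit is the supra-threshold maximum (no winner
    if everything is below threshold).  Maximal runs of consecutive identical
    winners collapse to one token; runs shorter than ``min_run`` steps are
    discarded as noise.
    """
    trace = np.asarray(trace, dtype=float)
    vocab = list(lexicon.closed_class_words) + [lexicon.sw_symbol]
    winners: list[int] = []
    for row in trace:
        above = row >= threshold
        winners.append(int(np.argmax(np.where(above, row, -np.inf))) if above.any() else -1)
    tokens: list[str] = []
    i = 0
    while i < len(winners):
        j = i
        while j < len(winners) and winners[j] == winners[i]:
            j += 1
        if winners[i] >= 0 and (j - i) >= min_run:
            tokens.append(vocab[winners[i]])
        i = j
    return tokens


@dataclass
class ProductionModel:
    """A trained meaning-to-sentence model."""

    config: ReservoirConfig
    weights: ReservoirWeights
    readout: ReadoutWeights
    lexicon: Lexicon
    T_max: int
    word_len: int = 5
    gap_len: int = 5
    min_run: int = 2


class MalformedProductionError(ValueError):
    """Decoded SW-marker count differs from the FIFO length."""

    def __init__(self, n_markers: int, n_fifo: int, tokens: list[str]):
        super().__init__(
            f"malformed production: {n_markers} SW markers for {n_fifo} content words"
        )
        self.n_markers = n_markers
        self.n_fifo = n_fifo
        self.tokens = tokens


def _form_of_pair(pair) -> str:
    if pair.style not in (CANONICAL, NON_CANONICAL):
        raise ValueError(
            f"pair {pair.id!r}: style {pair.style!r} is not a sentence form"
        )
    return pair.style


def train_production(
    pairs,
    config: ReservoirConfig | None = None,
    lexicon: Lexicon | None = None,
    word_len: int = 5,
    gap_len: int = 5,
    n_units: int = 500,
    seed: int = 0,
    ridge: float = 0.0,
) -> ProductionModel:
    """Train the production readout on scene-description pairs.

    Each pair contributes (constant coded-meaning input, square-wave word
    teacher); all teachers are padded to the longest sentence's length.  The
    sentence's own content-word order must match the construction pattern
    for the pair's form, otherwise the pair id is reported.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty corpus")
    if lexicon is None:
        lexicon = DEFAULT_SD_LEXICON
    if config is None:
        config = ReservoirConfig(
            input_dim=GRID_CELLS,
            output_dim=lexicon.input_dim,
            seed=seed,
            ridge=ridge,
            **{**SD_DEFAULTS, "n_units": n_units},
        )
    period = word_len + gap_len
    encoded = []
    t_max = 0
    for pair in pairs:
        try:
            form = _form_of_pair(pair)
            grid, fifo = meaning_to_coded_input(pair.meaning, form)
            gform = to_grammatical_form(pair.sentence, lexicon)
        except ValueError as exc:
            raise ValueError(f"pair {pair.id!r}: {exc}") from exc
        if list(gform.fifo) != fifo:
            raise ValueError(
                f"pair {pair.id!r}: sentence content-word order {list(gform.fifo)} "
                f"does not match the {form} pattern order {fifo}"
            )
        encoded.append((grid, gform.tokens))
        t_max = max(t_max, len(gform.tokens) * period)
    inputs = np.stack([encode_meaning_input(g, t_max) for g, _ in encoded])
    teachers = np.stack(
        [
            encode_production_teacher(toks, t_max, lexicon, word_len, gap_len)
            for _, toks in encoded
        ]
    )
    weights = init_weights(config)
    states = run_reservoir_batch(weights, config, inputs)
    readout = train_readout(list(states), list(teachers), ridge=config.ridge)
    return ProductionModel(
        config=config,
        weights=weights,
        readout=readout,
        lexicon=lexicon,
        T_max=t_max,
        word_len=word_len,
        gap_len=gap_len,
    )


def produce(
    model: ProductionModel, meaning: MeaningRecord, form: str
) -> tuple[str, np.ndarray]:
    """Generate the sentence for a meaning under the chosen construction.

    Returns the sentence (lowercase, space-joined) and the raw T x 7 word
    trace.  The i-th decoded SW marker is replaced by the i-th FIFO word;
    a marker/FIFO count mismatch raises :class:`MalformedProductionError`.
    """
    grid, fifo = meaning_to_coded_input(meaning, form)
    u = encode_meaning_input(grid, model.T_max)
    states = run_reservoir(model.weights, model.config, u)
    trace = apply_readout(model.readout, states)
    tokens = decode_word_trace(
        trace, model.config.threshold, model.lexicon, model.min_run
    )
    n_markers = sum(1 for t in tokens if t == model.lexicon.sw_symbol)
    if n_markers != len(fifo):
        raise MalformedProductionError(n_markers, len(fifo), tokens)
    it = iter(fifo)
    words = [next(it) if t == model.lexicon.sw_symbol else t for t in tokens]
    return " ".join(words), trace
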