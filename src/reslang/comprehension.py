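"""Sentence comprehension: the action-performing model.

Pipeline (one trained readout, everything else fixed or symbolic):

1. The sentence is reduced to its *grammatical form*: every open-class
   (content) word is replaced by a generic SW marker and pushed onto a FIFO
   working memory.  The network therefore only ever sees the pattern of
   closed-class words and markers — the construction — never word identity.
2. The form is coded one input unit per closed-class word plus one for the
   marker, one time step per word, left-padded so every sentence ends at the
   same step, followed by a short final pause.
3. The reservoir state trajectory is read out into 36 units coding the role
   grid (6 SW x 3 roles x 2 actions).  During training the grid cells are
   clamped to 1 from the first word onward, which yields predictive
   ("anytime") activity at test time.
4. The last-step activations are thresholded and, per SW and action, the
   maximal surviving role wins; FIFO words are bound back into a
   predicate-argument meaning.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np

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
    N_ACTIONS,
    N_ROLES,
    N_SW,
    ROLE_ARG1,
    ROLE_ARG2,
    ROLE_PREDICATE,
    MeaningRecord,
    Predication,
    RoleGrid,
    bind_meaning_to_fifo,
)

log = logging.getLogger(__name__)

__all__ = [
    "Lexicon",
    "GrammaticalForm",
    "ComprehensionModel",
    "IncompleteMeaningError",
    "DEFAULT_AP_LEXICON",
    "to_grammatical_form",
    "encode_sentence_input",
    "meaning_to_grid",
    "encode_teacher",
    "decode_meaning",
    "train_comprehension",
    "comprehend",
]

#: Default comprehension hyperparameters (100 units, leak 1/6, input
#: scaling 0.75, spectral radius 1).
AP_DEFAULTS = dict(
    n_units=100,
    leak_rate=1.0 / 6.0,
    spectral_radius=1.0,
    input_scaling=0.75,
)

_STRIP = str.maketrans("", "", string.punctuation.replace(".", ""))


@dataclass(frozen=True)
class Lexicon:
    """Closed-class word inventory plus the semantic-word marker symbol."""

    closed_class_words: tuple[str, ...]
    sw_symbol: str = "SW"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "closed_class_words", tuple(self.closed_class_words)
        )
        words = self.closed_class_words
        if len(set(words)) != len(words):
            raise ValueError("duplicate closed-class words")
        if any(w != w.lower() for w in words):
            raise ValueError("closed-class words must be lowercase")
        if self.sw_symbol in words:
            raise ValueError("sw_symbol must not be a closed-class word")

    def __len__(self) -> int:
        return len(self.closed_class_words)

    def __contains__(self, word: str) -> bool:
        return word in self.closed_class_words

    @property
    def input_dim(self) -> int:
        """One unit per closed-class word plus one for the SW marker."""
        return len(self.closed_class_words) + 1

    def unit_index(self, token: str) -> int:
        """Input/output unit index of a token; the SW marker is the last unit."""
        if token == self.sw_symbol:
            return len(self.closed_class_words)
        try:
            return self.closed_class_words.index(token)
        except ValueError:
            raise KeyError(f"token {token!r} not in lexicon") from None


#: The eight closed-class words of the original action-performing sessions.
DEFAULT_AP_LEXICON = Lexicon(
    closed_class_words=("after", "and", "before", "it", "on", "the", "then", "you")
)


@dataclass(frozen=True)
class GrammaticalForm:
    """Token pattern over closed-class words and SW markers, plus the FIFO."""

    tokens: tuple[str, ...]
    fifo: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "fifo", tuple(self.fifo))


class IncompleteMeaningError(ValueError):
    """Decoded grid has argument cells for an action with no predicate.

    Carries the partial grid so evaluation code can inspect it; counted as a
    comprehension error, never a crash.
    """

    def __init__(self, message: str, grid: RoleGrid):
        super().__init__(message)
        self.grid = grid


def tokenize(sentence_text: str) -> list[str]:
    """Lowercase, whitespace-split, strip punctuation except a terminal dot."""
    raw = sentence_text.lower().split()
    tokens = []
    for tok in raw:
        tok = tok.translate(_STRIP)
        if tok.endswith(".") and tok != ".":
            tok = tok[:-1]
            if tok:
                tokens.append(tok)
            tokens.append(".")
        elif tok:
            tokens.append(tok)
    return tokens


def to_grammatical_form(
    sentence_text: str, lexicon: Lexicon, max_sw: int = N_SW
) -> GrammaticalForm:
    """Replace every open-class word by the SW marker, keeping it in the FIFO.

    Any token not in the lexicon is by definition open-class
    (closed-class-by-exclusion); unknown words never fail, they become
    markers.
    """
    tokens: list[str] = []
    fifo: list[str] = []
    for tok in tokenize(sentence_text):
        if tok in lexicon:
            tokens.append(tok)
        else:
            tokens.append(lexicon.sw_symbol)
            fifo.append(tok)
    if len(fifo) > max_sw:
        raise ValueError(
            f"too many semantic words: {len(fifo)} > limit {max_sw} "
            f"in {sentence_text!r}"
        )
    return GrammaticalForm(tokens=tuple(tokens), fifo=tuple(fifo))


def encode_sentence_input(
    form: GrammaticalForm, lexicon: Lexicon, max_len: int, pause_len: int = 1
) -> np.ndarray:
    """One-hot code a grammatical form, one time step per word.

    Sentences shorter than ``max_len`` are left-padded with all-zero rows so
    that every sentence's last word falls just before the final pause; the
    pause (``pause_len`` zero rows) marks the end of the sentence.  Returns a
    (max_len + pause_len) x (|lexicon| + 1) matrix.
    """
    n_tok = len(form.tokens)
    if max_len < n_tok:
        raise ValueError(f"max_len {max_len} < token count {n_tok}")
    mat = np.zeros((max_len + pause_len, lexicon.input_dim))
    offset = max_len - n_tok
    for i, tok in enumerate(form.tokens):
        mat[offset + i, lexicon.unit_index(tok)] = 1.0
    return mat


def meaning_to_grid(meaning: MeaningRecord, fifo: list[str]) -> RoleGrid:
    """Code a meaning as the role grid relative to the sentence's FIFO."""
    if len(fifo) > N_SW:
        raise ValueError(f"FIFO longer than {N_SW} is not codable: {fifo!r}")
    return bind_meaning_to_fifo(meaning, list(fifo))


def encode_teacher(grid: RoleGrid, T: int, start: int = 0) -> np.ndarray:
    """Teacher signal: active grid cells clamped to 1 from ``start`` to T.

    ``start`` is the time step of the first word (the end of the left pad);
    rows before it are zero, matching the zero reservoir state there.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    teacher = np.zeros((T, GRID_CELLS))
    teacher[start:, :] = grid.flatten()[None, :]
    return teacher


def decode_meaning(
    final_outputs: np.ndarray, threshold: float, fifo: list[str]
) -> MeaningRecord:
    """Threshold + per-SW max decode of the last-step readout activations.

    For each (SW, action) the roles at or above threshold compete and the
    maximal one wins (ties break to the lowest role index:
    predicate < arg1 < arg2).  An action is emitted iff its predicate cell
    survives; surviving argument cells without a predicate raise
    :class:`IncompleteMeaningError`.
    """
    if len(fifo) == 0:
        raise ValueError("empty FIFO: nothing to decode")
    acts = np.asarray(final_outputs, dtype=float).reshape(N_SW, N_ROLES, N_ACTIONS)
    grid = RoleGrid()
    for sw in range(min(len(fifo), N_SW)):
        for k in range(N_ACTIONS):
            roles = acts[sw, :, k]
            surviving = roles >= threshold
            if not surviving.any():
                continue
            masked = np.where(surviving, roles, -np.inf)
            grid.active[sw, int(np.argmax(masked)), k] = True

    preds: list[Predication] = []
    for k in range(N_ACTIONS):
        pred_sws = [sw for sw in range(N_SW) if grid.active[sw, ROLE_PREDICATE, k]]
        arg1_sws = [sw for sw in range(N_SW) if grid.active[sw, ROLE_ARG1, k]]
        arg2_sws = [sw for sw in range(N_SW) if grid.active[sw, ROLE_ARG2, k]]
        if not pred_sws:
            if arg1_sws or arg2_sws:
                raise IncompleteMeaningError(
                    f"action {k + 1} has argument roles but no predicate", grid
                )
            continue
        arg1 = fifo[arg1_sws[0]] if arg1_sws else ""
        arg2 = fifo[arg2_sws[0]] if arg2_sws else ""
        if arg2 and not arg1:
            raise IncompleteMeaningError(
                f"action {k + 1} has a second argument but no first", grid
            )
        preds.append(Predication(fifo[pred_sws[0]], arg1, arg2))
    if not preds:
        raise IncompleteMeaningError("no action survived the threshold", grid)
    return MeaningRecord(tuple(preds))


@dataclass
class ComprehensionModel:
    """A trained sentence-to-meaning model."""

    config: ReservoirConfig
    weights: ReservoirWeights
    readout: ReadoutWeights
    lexicon: Lexicon
    max_len: int
    pause_len: int = 1


def _encode_pairs(
    pairs, lexicon: Lexicon, max_len: int, pause_len: int
) -> tuple[np.ndarray, np.ndarray, list[GrammaticalForm]]:
    """Encode a corpus into stacked input and teacher tensors (N, T, dim)."""
    inputs, teachers, forms = [], [], []
    for pair in pairs:
        try:
            form = to_grammatical_form(pair.sentence, lexicon)
            grid = meaning_to_grid(pair.meaning, list(form.fifo))
        except ValueError as exc:
            raise ValueError(f"pair {pair.id!r}: {exc}") from exc
        u = encode_sentence_input(form, lexicon, max_len, pause_len)
        start = max_len - len(form.tokens)
        teachers.append(encode_teacher(grid, u.shape[0], start=start))
        inputs.append(u)
        forms.append(form)
    return np.stack(inputs), np.stack(teachers), forms


def train_comprehension(
    pairs,
    config: ReservoirConfig | None = None,
    lexicon: Lexicon | None = None,
    pause_len: int = 1,
    n_units: int = 100,
    seed: int = 0,
    ridge: float = 0.0,
) -> ComprehensionModel:
    """Train the comprehension readout on a corpus of sentence-meaning pairs.

    ``max_len`` is the longest grammatical form in the corpus; every sentence
    of the session (training and later queries) is padded to it.  With
    ``lexicon=None`` the closed-class words are extracted from the corpus by
    exclusion; with ``config=None`` the stock hyperparameters are used with
    the given ``n_units`` and ``seed``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty corpus")
    if lexicon is None:
        from .corpus import extract_closed_class

        lexicon = extract_closed_class(pairs)
    if config is None:
        config = ReservoirConfig(
            input_dim=lexicon.input_dim,
            output_dim=GRID_CELLS,
            seed=seed,
            ridge=ridge,
            **{**AP_DEFAULTS, "n_units": n_units},
        )
    if config.input_dim != lexicon.input_dim:
        raise ValueError(
            f"config.input_dim {config.input_dim} != lexicon dim {lexicon.input_dim}"
        )
    max_len = max(
        len(to_grammatical_form(p.sentence, lexicon).tokens) for p in pairs
    )
    inputs, teachers, _ = _encode_pairs(pairs, lexicon, max_len, pause_len)
    weights = init_weights(config)
    states = run_reservoir_batch(weights, config, inputs)
    readout = train_readout(list(states), list(teachers), ridge=config.ridge)
    return ComprehensionModel(
        config=config,
        weights=weights,
        readout=readout,
        lexicon=lexicon,
        max_len=max_len,
        pause_len=pause_len,
    )


def comprehend(
    model: ComprehensionModel, sentence_text: str
) -> tuple[MeaningRecord, np.ndarray]:
    """Decode a sentence with a trained model.

    Returns the meaning read off the last time step together with the full
    T x 36 readout trajectory (the anytime estimates).  A sentence longer
    than anything seen at training is encoded unpadded at its own length,
    with a warning.
    """
    form = to_grammatical_form(sentence_text, model.lexicon)
    max_len = model.max_len
    if len(form.tokens) > max_len:
        log.warning(
            "sentence longer (%d tokens) than the training maximum (%d); "
            "encoding unpadded",
            len(form.tokens),
            max_len,
        )
        max_len = len(form.tokens)
    u = encode_sentence_input(form, model.lexicon, max_len, model.pause_len)
    states = run_reservoir(model.weights, model.config, u)
    outputs = apply_readout(model.readout, states)
    meaning = decode_meaning(
        outputs[-1], model.config.threshold, list(form.fifo)
    )
    return meaning, outputs
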