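"""Comprehension pipeline: grammatical forms, coding, decoding, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reslang.comprehension import (
    DEFAULT_AP_LEXICON,
    IncompleteMeaningError,
    Lexicon,
    comprehend,
    decode_meaning,
    encode_sentence_input,
    encode_teacher,
    meaning_to_grid,
    to_grammatical_form,
    train_comprehension,
)
from reslang.evaluation import meanings_equal
from reslang.meaning import (
    GRID_CELLS,
    N_ACTIONS,
    N_ROLES,
    N_SW,
    MeaningRecord,
    Predication,
    RoleGrid,
)

from conftest import make_pair

LEX = DEFAULT_AP_LEXICON


class TestGrammaticalForm:
    def test_open_class_words_become_markers(self):
        form = to_grammatical_form("put on the left the trumpet", LEX)
        assert list(form.tokens) == ["SW", "on", "the", "SW", "the", "SW"]
        assert list(form.fifo) == ["put", "left", "trumpet"]

    def test_empty_sentence(self):
        form = to_grammatical_form("", LEX)
        assert form.tokens == () and form.fifo == ()

    def test_all_closed_class(self):
        form = to_grammatical_form("the on the", LEX)
        assert list(form.tokens) == ["the", "on", "the"] and form.fifo == ()

    def test_case_and_punctuation_normalized(self):
        form = to_grammatical_form("Put, the Toy!", LEX)
        assert list(form.fifo) == ["put", "toy"]

    def test_terminal_dot_kept_as_token(self):
        lex = Lexicon(closed_class_words=("the", "."))
        form = to_grammatical_form("touch the toy.", lex)
        assert list(form.tokens) == ["SW", "the", "SW", "."]

    def test_too_many_content_words(self):
        with pytest.raises(ValueError, match="too many semantic words.*6"):
            to_grammatical_form("a b c d e f g", LEX)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from(
        ["the", "on", "before", "you", "toy", "left", "put", "grasp"]
    ), max_size=9))
    def test_marker_count_equals_fifo_length(self, words):
        try:
            form = to_grammatical_form(" ".join(words), LEX)
        except ValueError:
            return  # > 6 content words
        assert sum(t == "SW" for t in form.tokens) == len(form.fifo)
        assert len(form.tokens) == len(words)


class TestSentenceInputCoding:
    def test_one_hot_rows_and_final_pause(self):
        form = to_grammatical_form("put on", LEX)  # SW, on
        mat = encode_sentence_input(form, LEX, max_len=2, pause_len=1)
        assert mat.shape == (3, 9)
        assert mat[0, LEX.unit_index("SW")] == 1.0 and mat[0].sum() == 1.0
        assert mat[1, LEX.unit_index("on")] == 1.0 and mat[1].sum() == 1.0
        assert np.all(mat[2] == 0.0)

    def test_left_padding_offset(self):
        form = to_grammatical_form("put", LEX)
        mat = encode_sentence_input(form, LEX, max_len=3, pause_len=1)
        assert np.all(mat[:2] == 0.0)
        assert mat[2, LEX.unit_index("SW")] == 1.0
        assert np.all(mat[3] == 0.0)

    def test_row_sums(self):
        form = to_grammatical_form("put the toy on the left", LEX)
        mat = encode_sentence_input(form, LEX, max_len=8, pause_len=2)
        sums = mat.sum(axis=1)
        np.testing.assert_array_equal(sums, [0, 0] + [1] * 6 + [0, 0])

    def test_max_len_too_small(self):
        form = to_grammatical_form("put the toy", LEX)
        with pytest.raises(ValueError, match="max_len"):
            encode_sentence_input(form, LEX, max_len=2)


class TestMeaningGrid:
    def test_double_action_binding(self):
        # "before you put the guitar on the right push the trumpet on the
        # left" executes push(trumpet, left) then put(guitar, right)
        fifo = ["put", "right", "guitar", "push", "trumpet", "left"]
        meaning = MeaningRecord.parse("push(trumpet,left); put(guitar,right)")
        grid = meaning_to_grid(meaning, fifo)
        assert set(grid.cells()) == {
            (3, 0, 0), (4, 1, 0), (5, 2, 0),
            (0, 0, 1), (2, 1, 1), (1, 2, 1),
        }

    def test_single_action_without_location(self):
        grid = meaning_to_grid(MeaningRecord.parse("point(guitar)"), ["point", "guitar"])
        assert set(grid.cells()) == {(0, 0, 0), (1, 1, 0)}

    def test_repeated_word_consumes_slots_left_to_right(self):
        # "point the cross then point the triangle"
        fifo = ["point", "cross", "point", "triangle"]
        grid = meaning_to_grid(
            MeaningRecord.parse("point(cross); point(triangle)"), fifo
        )
        assert set(grid.cells()) == {(0, 0, 0), (1, 1, 0), (2, 0, 1), (3, 1, 1)}

    def test_anaphora_reuses_slot(self):
        # "grasp the circle and then point to it"
        fifo = ["grasp", "circle", "point"]
        grid = meaning_to_grid(
            MeaningRecord.parse("grasp(circle); point(circle)"), fifo
        )
        assert set(grid.cells()) == {(0, 0, 0), (1, 1, 0), (2, 0, 1), (1, 1, 1)}

    def test_unbound_meaning_word_errors(self):
        with pytest.raises(ValueError, match="'left'"):
            meaning_to_grid(MeaningRecord.parse("put(toy,left)"), ["put", "toy"])

    def test_teacher_clamps_active_cells(self):
        grid = meaning_to_grid(MeaningRecord.parse("put(toy,left)"), ["put", "toy", "left"])
        teacher = encode_teacher(grid, T=10)
        assert teacher.shape == (10, GRID_CELLS)
        assert np.array_equal(teacher.sum(axis=0) > 0, grid.flatten() > 0)
        assert set(np.unique(teacher)) <= {0.0, 1.0}
        assert teacher.sum() == 10 * 3

    def test_teacher_start_offset(self):
        grid = meaning_to_grid(MeaningRecord.parse("point(toy)"), ["point", "toy"])
        teacher = encode_teacher(grid, T=8, start=3)
        assert np.all(teacher[:3] == 0.0)
        assert np.array_equal(teacher[3:], np.tile(grid.flatten(), (5, 1)))


class TestDecode:
    def _acts(self, cells):
        a = np.zeros((N_SW, N_ROLES, N_ACTIONS))
        for (sw, role, k), v in cells.items():
            a[sw, role, k] = v
        return a.reshape(-1)

    def test_simple_decode(self):
        acts = self._acts({(0, 0, 0): 0.9, (2, 2, 0): 0.8, (1, 1, 0): 0.7})
        got = decode_meaning(acts, 0.5, ["put", "trumpet", "left"])
        assert meanings_equal(got, MeaningRecord.parse("put(trumpet,left)"))

    def test_all_below_threshold_is_incomplete(self):
        with pytest.raises(IncompleteMeaningError):
            decode_meaning(np.full(GRID_CELLS, 0.3), 0.5, ["put"])

    def test_per_sw_max_wins(self):
        acts = self._acts({(0, 0, 0): 0.9, (1, 0, 0): 0.6, (1, 1, 0): 0.7})
        got = decode_meaning(acts, 0.5, ["push", "toy"])
        assert meanings_equal(got, MeaningRecord.parse("push(toy)"))

    def test_tie_breaks_to_lowest_role(self):
        acts = self._acts({(0, 0, 0): 0.8, (1, 1, 0): 0.6, (1, 2, 0): 0.6})
        got = decode_meaning(acts, 0.5, ["push", "toy"])
        assert got.predications[0].arg1 == "toy" and got.predications[0].arg2 == ""

    def test_arguments_without_predicate_signal(self):
        acts = self._acts({(0, 0, 0): 0.9, (1, 1, 0): 0.9, (2, 1, 1): 0.9})
        with pytest.raises(IncompleteMeaningError) as exc:
            decode_meaning(acts, 0.5, ["put", "toy", "left"])
        assert isinstance(exc.value.grid, RoleGrid)

    def test_empty_fifo_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            decode_meaning(np.zeros(GRID_CELLS), 0.5, [])


def _random_meaning_and_fifo(rng):
    verbs = ["point", "grasp", "touch", "put", "push", "move"]
    nouns = ["guitar", "violin", "trumpet", "toy", "circle", "cross", "left", "right"]
    n_pred = int(rng.integers(1, 3))
    preds, words = [], []
    for _ in range(n_pred):
        v = verbs[rng.integers(len(verbs))]
        n_args = int(rng.integers(1, 3))
        args = list(rng.choice(nouns, size=n_args, replace=False))
        preds.append(Predication(v, *args))
        words.extend([v] + args)
    uniq = list(dict.fromkeys(words))
    if len(uniq) > N_SW:
        return None
    fifo = list(uniq)
    rng.shuffle(fifo)
    return MeaningRecord(tuple(preds)), fifo


def test_grid_roundtrip_on_random_meanings():
    """Coding a well-formed meaning onto the grid and decoding the binarized
    grid reproduces the meaning exactly (1000 random cases)."""
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 1000:
        sample = _random_meaning_and_fifo(rng)
        if sample is None:
            continue
        meaning, fifo = sample
        grid = meaning_to_grid(meaning, fifo)
        got = decode_meaning(grid.flatten(), 0.5, fifo)
        assert meanings_equal(got, meaning), (meaning, fifo, got)
        checked += 1


class TestTraining:
    def test_single_pair_recall(self):
        pairs = [make_pair(1, "put the toy on the left", "put(toy,left)")]
        model = train_comprehension(pairs, lexicon=LEX, n_units=60, seed=0)
        got, traj = comprehend(model, "put the toy on the left")
        assert meanings_equal(got, pairs[0].meaning)
        assert traj.shape[1] == GRID_CELLS

    def test_same_seed_identical_readout(self, ap_corpus_20):
        a = train_comprehension(ap_corpus_20, n_units=80, seed=5)
        b = train_comprehension(ap_corpus_20, n_units=80, seed=5)
        assert np.array_equal(a.readout.w_out, b.readout.w_out)

    def test_surface_invariance(self, ap_corpus_20):
        """The network never sees content words: swapping them transforms the
        decoded meaning by pure word substitution."""
        model = train_comprehension(ap_corpus_20, n_units=100, seed=1)
        m1, _ = comprehend(model, "put the toy on the left")
        m2, _ = comprehend(model, "put the drums on the right")
        assert m1.predications[0].arg1 == "toy" and m2.predications[0].arg1 == "drums"
        assert m1.predications[0].arg2 == "left" and m2.predications[0].arg2 == "right"
        assert m1.predications[0].predicate == m2.predications[0].predicate == "put"

    def test_generalization_to_unseen_sentence_of_trained_construction(self):
        verbs = ["put", "push", "move"]
        objs = ["toy", "guitar", "violin", "drums"]
        locs = ["right", "middle"]
        pairs = []
        i = 0
        for v in verbs:
            for o in objs:
                for l in locs:
                    i += 1
                    pairs.append(
                        make_pair(i, f"{v} on the {l} the {o}", f"{v}({o},{l})")
                    )
        model = train_comprehension(pairs, lexicon=LEX, n_units=100, seed=0)
        # unseen filling of the trained construction
        got, _ = comprehend(model, "put on the left the trumpet")
        assert meanings_equal(got, MeaningRecord.parse("put(trumpet,left)"))

    def test_anytime_trajectory_final_step_consistent(self, ap_corpus_20):
        model = train_comprehension(ap_corpus_20, n_units=100, seed=1)
        pair = ap_corpus_20[0]
        meaning, traj = comprehend(model, pair.sentence)
        form = to_grammatical_form(pair.sentence, model.lexicon)
        redecoded = decode_meaning(traj[-1], model.config.threshold, list(form.fifo))
        assert meanings_equal(redecoded, meaning)

    def test_bad_pair_reports_id(self):
        pairs = [make_pair(1, "put the toy", "put(toy,left)")]
        with pytest.raises(ValueError, match="p1"):
            train_comprehension(pairs, lexicon=LEX, n_units=20, seed=0)
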