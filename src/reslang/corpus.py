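"""Corpus handling: file formats, lexicon extraction, synthetic generators.

A corpus is a list of sentence-meaning pairs with category metadata
(task, style, action count, subject).  Two file dialects are supported:

* ``native`` — one record per line, tab-separated, with an explicit header
  (id, task, style, n_actions, subject, template, sentence, meaning);
* ``two_column`` — ``sentence<TAB>meaning`` (also accepts an arrow
  separator), for importing externally transcribed data.

The closed-class lexicon of a corpus is defined by exclusion: every sentence
token that never occurs in any meaning is a closed-class (grammatical) word.

The synthetic generators emulate the structure of the human-subject data:
the action-performing generator produces 5 subjects x 38 behaviors
(5 single + 33 double actions) x 2 styles (simple / elaborate) = 380
command-meaning pairs by default, drawn from a frozen template inventory
covering temporal before/after constructions (with and without inversion),
anaphoric "it", "twice"/"two times" repetition, filler words, and optional
irrelevant-location distractors; the scene-description generator produces
spatial-relation scenes in canonical and non-canonical form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .comprehension import Lexicon, to_grammatical_form, meaning_to_grid
from .meaning import MeaningRecord, Predication

__all__ = [
    "CorpusPair",
    "GeneratorParams",
    "TEMPLATES",
    "read_corpus",
    "write_corpus",
    "extract_closed_class",
    "generate_ap_corpus",
    "generate_sd_corpus",
    "filter_codable",
    "is_inverting",
]

_FIELDS = ("id", "task", "style", "n_actions", "subject", "template", "sentence", "meaning")


@dataclass(frozen=True)
class CorpusPair:
    """One sentence-meaning pair with category metadata."""

    id: str
    task: str  # "AP" | "SD"
    sentence: str
    meaning: MeaningRecord
    style: str  # simple | elaborate | canonical | non_canonical
    n_actions: int
    subject: str = ""
    template: str = ""

    def __post_init__(self) -> None:
        if self.task not in ("AP", "SD"):
            raise ValueError(f"task must be AP or SD, got {self.task!r}")
        if self.n_actions != len(self.meaning.predications):
            raise ValueError(
                f"pair {self.id!r}: n_actions {self.n_actions} != "
                f"{len(self.meaning.predications)} predications"
            )


def _load_inventory() -> dict:
    with resources.files("reslang.data").joinpath("templates.json").open() as fh:
        return json.load(fh)


_INVENTORY = _load_inventory()
#: Frozen template registry, id -> template record.
TEMPLATES: dict[str, dict] = {t["id"]: t for t in _INVENTORY["templates"]}
_VP_SHAPES: dict[str, dict] = _INVENTORY["vp_shapes"]


def is_inverting(template_id: str) -> bool:
    """True for before/after templates whose surface order reverses execution."""
    base = template_id.split("+")[0]
    return bool(TEMPLATES.get(base, {}).get("inversion", False))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_corpus(path: str | Path, dialect: str = "native") -> list[CorpusPair]:
    """Read a corpus file; malformed lines are reported with their numbers."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    pairs: list[CorpusPair] = []
    errors: list[str] = []
    seen_ids: set[str] = set()

    if dialect == "native":
        body = lines[1:] if lines and lines[0].startswith("id\t") else lines
        for lineno, line in enumerate(body, start=2 if body is not lines else 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != len(_FIELDS):
                errors.append(f"line {lineno}: expected {len(_FIELDS)} fields, got {len(cols)}")
                continue
            rec = dict(zip(_FIELDS, cols))
            try:
                pair = CorpusPair(
                    id=rec["id"],
                    task=rec["task"],
                    sentence=rec["sentence"],
                    meaning=MeaningRecord.parse(rec["meaning"]),
                    style=rec["style"],
                    n_actions=int(rec["n_actions"]),
                    subject=rec["subject"],
                    template=rec["template"],
                )
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            if pair.id in seen_ids:
                errors.append(f"line {lineno}: duplicate id {pair.id!r}")
                continue
            seen_ids.add(pair.id)
            pairs.append(pair)
    elif dialect == "two_column":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" in line:
                sent, _, mean = line.partition("\t")
            elif "⟶" in line:
                sent, _, mean = line.partition("⟶")
            else:
                errors.append(f"line {lineno}: no separator (tab or ⟶)")
                continue
            try:
                meaning = MeaningRecord.parse(mean.strip())
                pairs.append(
                    CorpusPair(
                        id=f"line-{lineno:04d}",
                        task="AP",
                        sentence=sent.strip(),
                        meaning=meaning,
                        style="simple" if len(meaning.predications) == 1 else "elaborate",
                        n_actions=len(meaning.predications),
                    )
                )
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return pairs


def write_corpus(pairs, path: str | Path) -> None:
    """Write the native tab-separated format (inverse of :func:`read_corpus`)."""
    path = Path(path)
    rows = ["\t".join(_FIELDS)]
    for p in pairs:
        rows.append(
            "\t".join(
                [p.id, p.task, p.style, str(p.n_actions), p.subject, p.template, p.sentence, str(p.meaning)]
            )
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def extract_closed_class(pairs, sw_symbol: str = "SW") -> Lexicon:
    """Closed-class lexicon by exclusion: sentence tokens never used in meanings."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty corpus")
    from .comprehension import tokenize

    sentence_tokens: set[str] = set()
    meaning_words: set[str] = set()
    for p in pairs:
        sentence_tokens.update(tokenize(p.sentence))
        meaning_words.update(p.meaning.words())
    closed = sorted(sentence_tokens - meaning_words)
    return Lexicon(closed_class_words=tuple(closed), sw_symbol=sw_symbol)


def filter_codable(pairs, lexicon: Lexicon | None = None):
    """Split a corpus into codable pairs and ill-formed rejects.

    A pair is rejected when its sentence has more content words than the
    role grid can hold or its meaning references a word that does not occur
    in the sentence (the "minimal conditions" cleanup).
    """
    pairs = list(pairs)
    if lexicon is None:
        lexicon = extract_closed_class(pairs)
    good, bad = [], []
    for p in pairs:
        try:
            form = to_grammatical_form(p.sentence, lexicon)
            meaning_to_grid(p.meaning, list(form.fifo))
            good.append(p)
        except ValueError:
            bad.append(p)
    return good, bad


# ---------------------------------------------------------------------------
# Synthetic generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Corpus generator settings; the defaults reproduce the 380-pair layout
    (5 subjects x 38 behaviors x 2 styles)."""

    n_subjects: int = 5
    n_single: int = 5
    n_double: int = 33
    obj_verbs: tuple[str, ...] = ("point", "grasp", "touch")
    loc_verbs: tuple[str, ...] = ("put", "push", "move")
    objects: tuple[str, ...] = (
        "guitar", "violin", "trumpet", "drums", "toy", "circle", "cross", "triangle"
    )
    locations: tuple[str, ...] = ("left", "right", "middle")
    repeat_rate: float = 0.12
    shared_object_rate: float = 0.2
    distractor_rate: float = 0.1
    illformed_rate: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class _Action:
    verb: str
    obj: str
    loc: str = ""  # empty for object-only actions

    @property
    def type(self) -> str:
        return "loc" if self.loc else "obj"

    def predication(self) -> Predication:
        return Predication(self.verb, self.obj, self.loc)


def _sample_action(rng: np.random.Generator, p: GeneratorParams, kind: str | None = None) -> _Action:
    if kind is None:
        kind = "loc" if rng.random() < 0.5 else "obj"
    if kind == "obj":
        return _Action(str(rng.choice(p.obj_verbs)), str(rng.choice(p.objects)))
    return _Action(
        str(rng.choice(p.loc_verbs)),
        str(rng.choice(p.objects)),
        str(rng.choice(p.locations)),
    )


def _sample_behaviors(rng: np.random.Generator, p: GeneratorParams):
    """Draw the behavior inventory: single actions and double-action pairs."""
    singles: list[tuple[_Action, ...]] = []
    seen = set()
    guard = 0
    while len(singles) < p.n_single:
        act = _sample_action(rng, p)
        if act not in seen:
            seen.add(act)
            singles.append((act,))
        guard += 1
        if guard > 10000:
            raise ValueError("vocabulary too small for distinct single actions")
    doubles: list[tuple[_Action, ...]] = []
    seen_d = set()
    guard = 0
    while len(doubles) < p.n_double:
        a1 = _sample_action(rng, p)
        r = rng.random()
        if r < p.repeat_rate:
            a1 = _sample_action(rng, p, kind="obj")
            a2 = a1
        elif r < p.repeat_rate + p.shared_object_rate:
            a2 = _sample_action(rng, p)
            a2 = _Action(a2.verb, a1.obj, a2.loc)
            if a2 == a1:
                continue
        else:
            a2 = _sample_action(rng, p)
            if a2 == a1:
                continue
        key = (a1, a2)
        if key not in seen_d:
            seen_d.add(key)
            doubles.append(key)
        guard += 1
        if guard > 100000:
            raise ValueError("vocabulary too small for distinct double actions")
    return singles + doubles


def _compatible(tpl: dict, behavior: tuple[_Action, ...]) -> bool:
    if tpl["arity"] != len(behavior):
        return False
    if len(behavior) == 2:
        a1, a2 = behavior
        is_repeat = a1 == a2
        shares_obj = a1.obj == a2.obj
        if tpl.get("repeat"):
            return is_repeat
        if tpl.get("anaphora"):
            # pronoun templates drop the second object from the surface, so
            # they only fit behaviors whose second action reuses the object
            return shares_obj and not is_repeat and a2.type == tpl["second_type"]
        if tpl.get("inversion"):
            # surface order reverses execution order; left-to-right FIFO
            # binding is only surface-consistent when the two actions share
            # no word, so inverting templates require disjoint word sets
            w1 = set(a1.predication().words())
            w2 = set(a2.predication().words())
            return not (w1 & w2)
    return True


def _realize_vp(action: _Action, shape: str) -> str:
    return _VP_SHAPES[shape][action.type].format(V=action.verb, O=action.obj, L=action.loc)


def _realize(tpl: dict, behavior: tuple[_Action, ...]) -> str:
    subst: dict[str, str] = {}
    for i, act in enumerate(behavior, start=1):
        subst[f"V{i}"] = act.verb
        subst[f"O{i}"] = act.obj
        subst[f"L{i}"] = act.loc
        shapes = tpl["shapes"]
        if i <= len(shapes):
            subst[f"VP{i}"] = _realize_vp(act, shapes[i - 1])
    return tpl["surface"].format(**subst)


_ILLFORMED = (
    ("make a u-turn", "turn(around)"),
    ("touch both objects", "touch(circle); touch(cross)"),
    ("do it again", "point(guitar)"),
)


def generate_ap_corpus(params: GeneratorParams | None = None) -> list[CorpusPair]:
    """Generate a synthetic action-performing corpus.

    Behaviors (verb/object/location fillings) are sampled once; every subject
    describes every behavior twice, once in a simple style and once in an
    elaborate style, with the template drawn from the frozen inventory in a
    balanced round-robin (so each compatible construction accrues exemplars
    evenly).  Meanings are annotated in execution order: for inverting
    before/after templates the surface order of the verbs is the reverse.
    With ``distractor_rate`` > 0, some simple sentences carry an irrelevant
    "on my <location>" phrase, recreating the natural ambiguity between
    sentences where the trailing location does and does not matter; with
    ``illformed_rate`` > 0, pairs violating the minimal coding conditions
    are mixed in.
    """
    p = params or GeneratorParams()
    rng = np.random.default_rng(p.seed)
    behaviors = _sample_behaviors(rng, p)
    inventory = list(TEMPLATES.values())
    order = rng.permutation(len(inventory))
    inventory = [inventory[i] for i in order]
    cursors: dict[tuple, int] = {}

    pairs: list[CorpusPair] = []
    idx = 0
    for subj in range(p.n_subjects):
        for beh in behaviors:
            for style in ("simple", "elaborate"):
                options = [
                    t for t in inventory if t["style"] == style and _compatible(t, beh)
                ]
                if not options:
                    raise ValueError(f"no {style} template for behavior {beh}")
                key = (style, tuple(t["id"] for t in options))
                k = cursors.get(key, 0)
                cursors[key] = k + 1
                tpl = options[k % len(options)]
                sentence = _realize(tpl, beh)
                template_id = tpl["id"]
                if (
                    style == "simple"
                    and tpl["arity"] == 1
                    and not tpl.get("repeat")
                    and rng.random() < p.distractor_rate
                ):
                    loc = str(rng.choice(p.locations))
                    if beh[0].type == "obj":
                        sentence = f"{sentence} on my {loc}"
                    else:
                        sentence = sentence.replace(" on the ", " on my ", 1)
                    template_id = template_id + "+distr"
                idx += 1
                pairs.append(
                    CorpusPair(
                        id=f"ap-{idx:03d}",
                        task="AP",
                        sentence=sentence,
                        meaning=MeaningRecord(
                            tuple(a.predication() for a in beh)
                        ),
                        style=style,
                        n_actions=len(beh),
                        subject=f"s{subj + 1}",
                        template=template_id,
                    )
                )
    n_ill = int(round(p.illformed_rate * len(pairs)))
    for j in range(n_ill):
        sent, mean = _ILLFORMED[j % len(_ILLFORMED)]
        idx += 1
        pairs.append(
            CorpusPair(
                id=f"ap-{idx:03d}",
                task="AP",
                sentence=sent,
                meaning=MeaningRecord.parse(mean),
                style="simple",
                n_actions=len(MeaningRecord.parse(mean).predications),
                subject="s0",
                template="illformed",
            )
        )
    return pairs


_SD_SENTENCES = {
    (1, "canonical"): "the {A} is to the {R1} of the {B}",
    (1, "non_canonical"): "to the {R1} of the {B} is the {A}",
    (2, "canonical"): "the {A} is to the {R1} of the {B} and to the {R2} of the {C}",
    (2, "non_canonical"): "to the {R1} of the {B} and to the {R2} of the {C} is the {A}",
}


def generate_sd_corpus(params: GeneratorParams | None = None) -> list[CorpusPair]:
    """Generate a scene-description corpus.

    Each scene is a focus object in one or two left/right relations to other
    objects (doubles share the focus as their agent); every scene is emitted
    in both the canonical and the non-canonical construction.
    """
    p = params or GeneratorParams(n_single=12, n_double=12)
    if len(p.objects) < 3:
        raise ValueError("scene description needs at least 3 distinct objects")
    rng = np.random.default_rng(p.seed)
    relations = ("left", "right")
    scenes: list[tuple] = []
    seen = set()
    guard = 0
    while len(scenes) < p.n_single + p.n_double:
        want_double = len(scenes) >= p.n_single
        objs = rng.choice(len(p.objects), size=3 if want_double else 2, replace=False)
        names = [p.objects[i] for i in objs]
        r1 = str(rng.choice(relations))
        if want_double:
            r2 = "left" if r1 == "right" else "right"
            scene = (names[0], r1, names[1], r2, names[2])
        else:
            scene = (names[0], r1, names[1])
        if scene not in seen:
            seen.add(scene)
            scenes.append(scene)
        guard += 1
        if guard > 100000:
            raise ValueError("vocabulary too small for distinct scenes")

    pairs: list[CorpusPair] = []
    idx = 0
    for scene in scenes:
        if len(scene) == 3:
            a, r1, b = scene
            meaning = MeaningRecord((Predication(r1, a, b),))
            subst = dict(A=a, R1=r1, B=b)
            n_rel = 1
        else:
            a, r1, b, r2, c = scene
            meaning = MeaningRecord((Predication(r1, a, b), Predication(r2, a, c)))
            subst = dict(A=a, R1=r1, B=b, R2=r2, C=c)
            n_rel = 2
        for form in ("canonical", "non_canonical"):
            idx += 1
            pairs.append(
                CorpusPair(
                    id=f"sd-{idx:03d}",
                    task="SD",
                    sentence=_SD_SENTENCES[(n_rel, form)].format(**subst),
                    meaning=meaning,
                    style=form,
                    n_actions=n_rel,
                    template=f"sd-{n_rel}-{form}",
                )
            )
    return pairs
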