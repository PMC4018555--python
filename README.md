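# reslang

Reservoir-network models of grammatical-construction learning: sentence
**comprehension** (command → predicate-argument meaning) and sentence
**production** (meaning → describing sentence), with corpus tooling and the
learnability / leave-one-out evaluation protocols. The package targets
researchers in computational (neuro)linguistics and developmental robotics
who want a hardware-free, fully scriptable implementation of
construction-based language learning with echo state networks.

## The model

A *grammatical construction* is a stored pairing of a sentence's surface
form with its meaning. The surface form here is the ordered pattern of
closed-class (function) words and `SW` markers that replace every
open-class (content) word; the content words themselves wait in a FIFO
working memory. Because the network only ever sees the pattern, anything it
learns transfers to new content words for free.

Both directions use a leaky echo state network: a fixed random recurrent
reservoir

x(t+1) = (1 − α)·x(t) + α·tanh(W_res·x(t) + W_in·u(t+1)),  x(0) = 0

and a linear readout y(t) = W_out·[x(t); 1] trained offline by
pseudo-inverse regression — the readout is the only learned component.

* **Comprehension** reads the word-by-word coded form and emits a
  6 content words × 3 roles (predicate / argument 1 / argument 2) × 2
  actions grid; thresholding the final step and rebinding the FIFO yields
  meanings such as `put(trumpet,left)` or, for temporal constructions like
  "before you X please Y", two predications in *execution* order.
* **Production** receives that grid (indexed by surface position, chosen by
  a canonical or non-canonical construction pattern) as constant input and
  emits the word sequence as square waves on one output unit per word;
  scanning the trace and re-inserting the FIFO words yields the sentence.

The corpus tools read/write sentence–meaning files, extract the
closed-class lexicon by exclusion, and generate synthetic corpora that
emulate a naive-subject experiment (5 subjects × 38 behaviors × 2 styles =
380 command–meaning pairs by default, with before/after inversion,
anaphoric "it", "twice", fillers, and optional ambiguity-inducing
distractors). The evaluation module implements the learnability test
(train = test), leave-one-out generalization, multi-instance aggregation
(mean/std and common-failure "best"), and the simple/elaborate ×
single/double category breakdown.

## Worked example

```
$ reslang generate --task ap -o corpus.tsv --seed 7 \
    --n-subjects 1 --n-single 4 --n-double 6 --distractor-rate 0
wrote 20 pairs to corpus.tsv

$ reslang train --task ap --corpus corpus.tsv -o ap_model.zip --units 100 --seed 1
trained on 20 pairs; model saved to ap_model.zip

$ reslang comprehend --model ap_model.zip \
    --sentence "touch the trumpet after you grasp the toy"
grasp(toy); touch(trumpet)
```

The decoded meaning lists the two actions in *execution* order: "after you"
inverts the surface order, so the grasp is performed first. The
learnability protocol on the same corpus:

```
$ reslang learnability --corpus corpus.tsv --units 100 --instances 2 --seed 0
pairs: 20   instances: 2
mean error: 0.00%  (std 0.00)
best error: 0.00%  (0/20 common failures)

category                    n    mean err    best err
elaborate, 1 action(s)      4        0.0%        0.0%
elaborate, 2 action(s)      6        0.0%        0.0%
simple, 1 action(s)         4        0.0%        0.0%
simple, 2 action(s)         6        0.0%        0.0%
```

Every pair is memorized (0% error); on ambiguous corpora the report instead
lists the minority-construction pairs that lose the frequency competition.
Production works the same way from the library or the CLI
(`reslang produce --model sd_model.zip --meaning "right(trumpet,guitar)"
--form noncanonical` → `to the right of the guitar is the trumpet`), and
`reslang demo` runs an interactive text session with a simulated table.

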