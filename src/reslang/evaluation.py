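"""Evaluation protocols: learnability, leave-one-out generalization, aggregation.

*Learnability* trains and tests on the same corpus: a pair that cannot even
be memorized is an outlier or is ambiguous against the rest of the corpus
(two constructions sharing one surface form: least squares favors the more
frequent mapping).  *Leave-one-out* (LoO) trains on all pairs but one and
tests the held-out pair, for every pair.

Both protocols run several model *instances* (identical except for the
weight-generation seed) and aggregate: per-instance error rates, their mean
and sample standard deviation, and the "best" error — the fraction of pairs
failed by *every* instance, i.e. the error of an oracle combination of the
instances.  Errors are also broken down by sentence category
(simple/elaborate x single/double action).

A pair fails if decoding raises any failure signal or the decoded meaning
differs from the annotation in any predication, argument, or in execution
order; partial credit is not computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .comprehension import (
    AP_DEFAULTS,
    Lexicon,
    _encode_pairs,
    decode_meaning,
    to_grammatical_form,
)
from .esn import ReservoirConfig, init_weights, run_reservoir_batch, train_readout
from .meaning import GRID_CELLS, MeaningRecord

__all__ = [
    "EvalConfig",
    "SentenceResult",
    "EvalReport",
    "meanings_equal",
    "learnability_test",
    "leave_one_out",
    "aggregate_instances",
    "category_breakdown",
]


def meanings_equal(a: MeaningRecord, b: MeaningRecord) -> bool:
    """Exact-match comparison: same predication count and, position by
    position in execution order, identical predicate and arguments."""
    if len(a.predications) != len(b.predications):
        return False
    return all(
        x.predicate == y.predicate and x.arg1 == y.arg1 and x.arg2 == y.arg2
        for x, y in zip(a.predications, b.predications)
    )


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation settings; instance i uses seed ``base_seed + i``."""

    n_units: int = 1000
    n_instances: int = 10
    base_seed: int = 0
    leak_rate: float = AP_DEFAULTS["leak_rate"]
    spectral_radius: float = AP_DEFAULTS["spectral_radius"]
    input_scaling: float = AP_DEFAULTS["input_scaling"]
    ridge: float = 0.0
    threshold: float = 0.5
    pause_len: int = 1

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")

    def reservoir_config(self, lexicon: Lexicon, instance: int) -> ReservoirConfig:
        return ReservoirConfig(
            n_units=self.n_units,
            leak_rate=self.leak_rate,
            spectral_radius=self.spectral_radius,
            input_scaling=self.input_scaling,
            input_dim=lexicon.input_dim,
            output_dim=GRID_CELLS,
            seed=self.base_seed + instance,
            ridge=self.ridge,
            threshold=self.threshold,
        )


@dataclass(frozen=True)
class SentenceResult:
    """Outcome of one (pair, instance) test."""

    pair_id: str
    instance_id: int
    passed: bool
    decoded: MeaningRecord | None = None
    error: str = ""


@dataclass
class EvalReport:
    """Aggregated evaluation outcome; error rates are fractions in [0, 1]."""

    n_pairs: int
    n_instances: int
    per_instance_error: list[float]
    mean_error: float
    std_error: float
    best_error: float
    common_failure_ids: list[str]
    category_table: dict
    results: list[SentenceResult] = field(repr=False, default_factory=list)

    def render(self) -> str:
        """Human-readable summary mirroring the mean/std/best table layout."""
        lines = [
            f"pairs: {self.n_pairs}   instances: {self.n_instances}",
            f"mean error: {100 * self.mean_error:.2f}%  (std {100 * self.std_error:.2f})",
            f"best error: {100 * self.best_error:.2f}%  "
            f"({len(self.common_failure_ids)}/{self.n_pairs} common failures)",
            "",
            f"{'category':<24}{'n':>5}{'mean err':>12}{'best err':>12}",
        ]
        for (style, n_act), cell in sorted(self.category_table.items()):
            lines.append(
                f"{style + ', ' + str(n_act) + ' action(s)':<24}{cell['n']:>5}"
                f"{100 * cell['mean_rate']:>11.1f}%{100 * cell['best_rate']:>11.1f}%"
            )
        return "\n".join(lines)


def aggregate_instances(results: list[SentenceResult], pairs=None) -> EvalReport:
    """Aggregate a complete (pair x instance) result grid into a report."""
    if not results:
        raise ValueError("no results to aggregate")
    pair_ids = sorted({r.pair_id for r in results})
    instances = sorted({r.instance_id for r in results})
    grid: dict[tuple[str, int], SentenceResult] = {}
    for r in results:
        key = (r.pair_id, r.instance_id)
        if key in grid:
            raise ValueError(f"duplicate result for {key}")
        grid[key] = r
    missing = [
        (p, i) for p in pair_ids for i in instances if (p, i) not in grid
    ]
    if missing:
        raise ValueError(f"missing result cells: {missing[:5]}...")

    n_pairs = len(pair_ids)
    per_instance = [
        sum(1 for p in pair_ids if not grid[(p, i)].passed) / n_pairs
        for i in instances
    ]
    common = [
        p for p in pair_ids if all(not grid[(p, i)].passed for i in instances)
    ]
    mean = float(np.mean(per_instance))
    std = float(np.std(per_instance, ddof=1)) if len(instances) > 1 else 0.0
    best = len(common) / n_pairs
    assert best <= min(per_instance) + 1e-12, "best must bound every instance"
    table = category_breakdown(results, pairs) if pairs is not None else {}
    return EvalReport(
        n_pairs=n_pairs,
        n_instances=len(instances),
        per_instance_error=per_instance,
        mean_error=mean,
        std_error=std,
        best_error=best,
        common_failure_ids=common,
        category_table=table,
        results=results,
    )


def category_breakdown(results: list[SentenceResult], pairs) -> dict:
    """Per-(style, action-count) error cells, mean and common-failure ("best").

    Returns ``{(style, n_actions): {"n", "mean_failures", "mean_rate",
    "best_failures", "best_rate"}}``.
    """
    by_id = {p.id: p for p in pairs}
    instances = sorted({r.instance_id for r in results})
    cells: dict[tuple[str, int], dict] = {}
    failures_by_pair: dict[str, list[bool]] = {}
    for r in results:
        failures_by_pair.setdefault(r.pair_id, []).append(not r.passed)
    for pid in failures_by_pair:
        if pid not in by_id:
            raise ValueError(f"unlabeled pair {pid!r}")
    for pid, fails in failures_by_pair.items():
        p = by_id[pid]
        key = (p.style, p.n_actions)
        cell = cells.setdefault(
            key, {"n": 0, "mean_failures": 0.0, "best_failures": 0}
        )
        cell["n"] += 1
        cell["mean_failures"] += sum(fails) / len(instances)
        cell["best_failures"] += int(all(fails))
    for cell in cells.values():
        cell["mean_rate"] = cell["mean_failures"] / cell["n"]
        cell["best_rate"] = cell["best_failures"] / cell["n"]
    return cells


def _augment_block(states: np.ndarray) -> np.ndarray:
    """(T, U) -> (T, U+1) with the bias column."""
    return np.hstack([states, np.ones((states.shape[0], 1))])


def _prepare(pairs, lexicon: Lexicon | None, pause_len: int):
    from .corpus import extract_closed_class

    pairs = list(pairs)
    if lexicon is None:
        lexicon = extract_closed_class(pairs)
    max_len = max(
        len(to_grammatical_form(p.sentence, lexicon).tokens) for p in pairs
    )
    inputs, teachers, forms = _encode_pairs(pairs, lexicon, max_len, pause_len)
    return pairs, lexicon, inputs, teachers, forms


def _test_pair(final_out, form, pair, instance, threshold) -> SentenceResult:
    try:
        decoded = decode_meaning(final_out, threshold, list(form.fifo))
    except ValueError as exc:
        return SentenceResult(pair.id, instance, False, None, str(exc))
    ok = meanings_equal(decoded, pair.meaning)
    return SentenceResult(
        pair.id, instance, ok, decoded, "" if ok else "meaning mismatch"
    )


def learnability_test(
    pairs, eval_config: EvalConfig | None = None, lexicon: Lexicon | None = None
) -> EvalReport:
    """Train and test on the same corpus, per instance; aggregate.

    The corpus must already be codable (filter ill-formed pairs first, e.g.
    with :func:`reslang.corpus.filter_codable`).
    """
    cfg = eval_config or EvalConfig()
    pairs, lexicon, inputs, teachers, forms = _prepare(pairs, lexicon, cfg.pause_len)
    results: list[SentenceResult] = []
    for i in range(cfg.n_instances):
        rc = cfg.reservoir_config(lexicon, i)
        weights = init_weights(rc)
        states = run_reservoir_batch(weights, rc, inputs)
        readout = train_readout(list(states), list(teachers), ridge=cfg.ridge)
        finals = _augment_block(states[:, -1, :]) @ readout.w_out.T
        for j, pair in enumerate(pairs):
            results.append(_test_pair(finals[j], forms[j], pair, i, cfg.threshold))
    return aggregate_instances(results, pairs)


def leave_one_out(
    pairs, eval_config: EvalConfig | None = None, lexicon: Lexicon | None = None
) -> EvalReport:
    """Leave-one-out generalization: every pair is tested after training on
    all the others, for every instance.

    The reservoir states of a sentence do not depend on the training fold,
    so they are simulated once per instance; each fold's readout is the
    pseudo-inverse regression on the remaining pairs, obtained by downdating
    the pooled normal equations (see docs/methods.md).  Input padding uses
    the maximal sentence length of the full session, held-out pair included.
    """
    cfg = eval_config or EvalConfig()
    pairs, lexicon, inputs, teachers, forms = _prepare(pairs, lexicon, cfg.pause_len)
    if len(pairs) < 2:
        raise ValueError("leave-one-out needs at least 2 pairs")
    results: list[SentenceResult] = []
    n_aug = cfg.n_units + 1
    eye = np.eye(n_aug)
    for i in range(cfg.n_instances):
        rc = cfg.reservoir_config(lexicon, i)
        weights = init_weights(rc)
        states = run_reservoir_batch(weights, rc, inputs)
        xs = [_augment_block(s) for s in states]
        ys = list(teachers)
        gram = sum(x.T @ x for x in xs)
        cross = sum(x.T @ y for x, y in zip(xs, ys))
        for j, pair in enumerate(pairs):
            g = gram - xs[j].T @ xs[j]
            b = cross - xs[j].T @ ys[j]
            if cfg.ridge > 0.0:
                w = np.linalg.solve(g + cfg.ridge * eye, b)
            else:
                w, *_ = np.linalg.lstsq(g, b, rcond=None)
            final = xs[j][-1] @ w
            results.append(_test_pair(final, forms[j], pair, i, cfg.threshold))
    return aggregate_instances(results, pairs)
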