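"""Predicate-argument meanings and the role-grid coding shared by both models.

A meaning is an ordered list (execution order) of at most two predications
``pred(arg1[, arg2])``, e.g. ``put(toy, left)`` or
``push(trumpet, left); put(guitar, right)``.  Order is semantic: temporal
constructions ("before X do Y") put the predications in execution order even
when the surface order is reversed.

The coded meaning exchanged with the networks is a boolean grid of
6 semantic-word slots x 3 roles x 2 actions = 36 cells: cell
(sw, role, action) says that the sw-th content word of the sentence fills
the given role of the given action.  Role 0 is the predicate; roles 1 and 2
are the two argument slots (displayed as agent/location for the
action-performing task and agent/object for scene description).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Predication",
    "MeaningRecord",
    "RoleGrid",
    "N_SW",
    "N_ROLES",
    "N_ACTIONS",
    "GRID_CELLS",
    "ROLE_PREDICATE",
    "ROLE_ARG1",
    "ROLE_ARG2",
]

N_SW = 6
N_ROLES = 3
N_ACTIONS = 2
GRID_CELLS = N_SW * N_ROLES * N_ACTIONS  # 36

ROLE_PREDICATE = 0
ROLE_ARG1 = 1
ROLE_ARG2 = 2

_PRED_RE = re.compile(r"^\s*([^\s(),]+)\s*(?:\(\s*([^(),]*?)\s*(?:,\s*([^(),]*?)\s*)?\))?\s*$")


@dataclass(frozen=True)
class Predication:
    """One atomic event: ``predicate(arg1[, arg2])``; empty args are ''."""

    predicate: str
    arg1: str = ""
    arg2: str = ""

    def __post_init__(self) -> None:
        if not self.predicate:
            raise ValueError("predication needs a nonempty predicate")
        if self.arg2 and not self.arg1:
            raise ValueError("arg2 without arg1 is not a supported shape")

    def words(self) -> list[str]:
        return [w for w in (self.predicate, self.arg1, self.arg2) if w]

    def __str__(self) -> str:
        args = ",".join(w for w in (self.arg1, self.arg2) if w)
        return f"{self.predicate}({args})" if args else f"{self.predicate}()"


@dataclass(frozen=True)
class MeaningRecord:
    """Ordered predications (execution order), at most two."""

    predications: tuple[Predication, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "predications", tuple(self.predications))
        if not (1 <= len(self.predications) <= N_ACTIONS):
            raise ValueError(
                f"a meaning has 1..{N_ACTIONS} predications, got {len(self.predications)}"
            )

    @classmethod
    def parse(cls, text: str) -> "MeaningRecord":
        """Parse ``pred(arg1[,arg2])[; pred(...)]`` (also bare ``pred``)."""
        parts = [p for p in text.split(";") if p.strip()]
        preds = []
        for part in parts:
            m = _PRED_RE.match(part)
            if m is None:
                raise ValueError(f"unparseable predication: {part!r}")
            pred, a1, a2 = m.group(1), m.group(2) or "", m.group(3) or ""
            preds.append(Predication(pred.strip(), a1.strip(), a2.strip()))
        return cls(tuple(preds))

    def words(self) -> list[str]:
        out: list[str] = []
        for p in self.predications:
            out.extend(p.words())
        return out

    def __str__(self) -> str:
        return "; ".join(str(p) for p in self.predications)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeaningRecord):
            return NotImplemented
        return self.predications == other.predications

    def __hash__(self) -> int:
        return hash(self.predications)


@dataclass
class RoleGrid:
    """Boolean grid of shape (6 semantic words, 3 roles, 2 actions)."""

    active: np.ndarray = field(
        default_factory=lambda: np.zeros((N_SW, N_ROLES, N_ACTIONS), dtype=bool)
    )

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape != (N_SW, N_ROLES, N_ACTIONS):
            raise ValueError(
                f"grid must have shape {(N_SW, N_ROLES, N_ACTIONS)}, got {self.active.shape}"
            )

    def flatten(self) -> np.ndarray:
        """Flatten to the 36-vector layout used on the network boundary."""
        return self.active.reshape(GRID_CELLS).astype(float)

    @classmethod
    def from_flat(cls, vec: np.ndarray) -> "RoleGrid":
        vec = np.asarray(vec)
        if vec.shape != (GRID_CELLS,):
            raise ValueError(f"expected a {GRID_CELLS}-vector, got shape {vec.shape}")
        return cls(active=vec.reshape(N_SW, N_ROLES, N_ACTIONS) > 0.5)

    def cells(self) -> list[tuple[int, int, int]]:
        """Active cells as (sw, role, action) index triples."""
        return [tuple(ix) for ix in np.argwhere(self.active)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RoleGrid):
            return NotImplemented
        return bool(np.array_equal(self.active, other.active))


def bind_meaning_to_fifo(meaning: MeaningRecord, fifo: list[str]) -> RoleGrid:
    """Bind the words of a meaning to FIFO slots, producing the role grid.

    Each predication k activates (slot, role, k) for its predicate and
    arguments.  Repeated occurrences of a word in the FIFO are consumed
    left to right across predications ("point the cross then point the
    triangle" uses both "point" slots); once a word's occurrences are
    exhausted the most recent slot is reused, which is exactly the anaphora
    case ("grasp the circle and then point to it" reuses the "circle" slot).
    """
    occurrences: dict[str, list[int]] = {}
    for i, w in enumerate(fifo):
        occurrences.setdefault(w, []).append(i)
    cursor: dict[str, int] = {w: 0 for w in occurrences}

    grid = RoleGrid()
    for k, pred in enumerate(meaning.predications):
        for role, word in ((ROLE_PREDICATE, pred.predicate), (ROLE_ARG1, pred.arg1), (ROLE_ARG2, pred.arg2)):
            if not word:
                continue
            if word not in occurrences:
                raise ValueError(
                    f"meaning word {word!r} does not occur among the sentence's "
                    f"content words {fifo!r}"
                )
            slots = occurrences[word]
            i = cursor[word]
            if i < len(slots):
                slot = slots[i]
                cursor[word] = i + 1
            else:
                slot = slots[-1]
            grid.active[slot, role, k] = True
    return grid
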