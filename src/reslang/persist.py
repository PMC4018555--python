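"""Save/load trained comprehension and production models.

A model archive is a zip holding the dense weight matrices as ``.npy``
members plus a JSON metadata document (hyperparameters, lexicon, sequence
geometry).  Archives round-trip bitwise.
"""

from __future__ import annotations

from pathlib import Path

from .comprehension import ComprehensionModel, Lexicon
from .esn import load_model, save_model
from .production import ProductionModel

__all__ = ["save_any", "load_any"]


def save_any(model: ComprehensionModel | ProductionModel, path: str | Path) -> None:
    if isinstance(model, ComprehensionModel):
        meta = {
            "kind": "comprehension",
            "closed_class_words": list(model.lexicon.closed_class_words),
            "sw_symbol": model.lexicon.sw_symbol,
            "max_len": model.max_len,
            "pause_len": model.pause_len,
        }
    elif isinstance(model, ProductionModel):
        meta = {
            "kind": "production",
            "closed_class_words": list(model.lexicon.closed_class_words),
            "sw_symbol": model.lexicon.sw_symbol,
            "T_max": model.T_max,
            "word_len": model.word_len,
            "gap_len": model.gap_len,
            "min_run": model.min_run,
        }
    else:
        raise TypeError(f"cannot persist {type(model).__name__}")
    save_model(path, model.config, model.weights, model.readout, meta)


def load_any(path: str | Path) -> ComprehensionModel | ProductionModel:
    config, weights, readout, meta = load_model(path)
    if readout is None:
        raise ValueError(f"{path}: archive has no trained readout")
    lexicon = Lexicon(
        closed_class_words=tuple(meta["closed_class_words"]),
        sw_symbol=meta["sw_symbol"],
    )
    if meta["kind"] == "comprehension":
        return ComprehensionModel(
            config=config,
            weights=weights,
            readout=readout,
            lexicon=lexicon,
            max_len=meta["max_len"],
            pause_len=meta["pause_len"],
        )
    if meta["kind"] == "production":
        return ProductionModel(
            config=config,
            weights=weights,
            readout=readout,
            lexicon=lexicon,
            T_max=meta["T_max"],
            word_len=meta["word_len"],
            gap_len=meta["gap_len"],
            min_run=meta["min_run"],
        )
    raise ValueError(f"{path}: unknown model kind {meta['kind']!r}")
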