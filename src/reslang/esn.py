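"""Leaky echo state network core.

A reservoir is a fixed random recurrent network of leaky tanh units whose
state encodes the spatio-temporal context of an input sequence.  The state
update is

    x(t+1) = (1 - alpha) * x(t) + alpha * tanh(W_res x(t) + W_in u(t+1))

with x(0) = 0, where ``alpha`` is the leak rate (1/alpha acts as a time
constant).  The only trained component is a linear readout with bias,

    y(t) = W_out [x(t); 1],

fitted offline by least squares (Moore-Penrose pseudo-inverse, optionally
ridge-regularised).
"""

from __future__ import annotations

import io
import json
import logging
import warnings
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ReservoirConfig",
    "ReservoirWeights",
    "ReadoutWeights",
    "init_weights",
    "run_reservoir",
    "run_reservoir_batch",
    "train_readout",
    "apply_readout",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ReservoirConfig:
    """Hyperparameters of one reservoir instance.

    Parameters
    ----------
    n_units : int
        Number of internal units.
    leak_rate : float
        Update fraction ``alpha`` per time step, in (0, 1].
    spectral_radius : float
        Largest absolute eigenvalue imposed on the recurrent matrix (> 0).
    input_scaling : float
        Magnitude of the (dense) input weights.
    input_dim, output_dim : int
        Input / readout dimensionality.
    seed : int
        Seed for weight generation; same seed, same weights, bitwise.
    ridge : float
        Readout regularisation; 0 means pure pseudo-inverse regression.
    threshold : float
        Decoding threshold applied to readout activations, in (0, 1).
    win_dist : str
        ``"binary"`` draws input weights as +/- input_scaling with equal
        probability; ``"uniform"`` draws from U(-1, 1) scaled by
        input_scaling.
    """

    n_units: int
    leak_rate: float
    spectral_radius: float
    input_scaling: float
    input_dim: int
    output_dim: int
    seed: int = 0
    ridge: float = 0.0
    threshold: float = 0.5
    win_dist: str = "binary"

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError(f"n_units must be >= 1, got {self.n_units}")
        if not (0.0 < self.leak_rate <= 1.0):
            raise ValueError(f"leak_rate must be in (0, 1], got {self.leak_rate}")
        if self.spectral_radius <= 0.0:
            raise ValueError(
                f"spectral_radius must be > 0, got {self.spectral_radius}"
            )
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.ridge < 0.0:
            raise ValueError(f"ridge must be >= 0, got {self.ridge}")
        if self.win_dist not in ("binary", "uniform"):
            raise ValueError(f"win_dist must be 'binary' or 'uniform', got {self.win_dist!r}")


@dataclass(frozen=True)
class ReservoirWeights:
    """Fixed random weights: ``w_in`` (n_units x input_dim), ``w_res`` (n_units x n_units)."""

    w_in: np.ndarray
    w_res: np.ndarray


@dataclass(frozen=True)
class ReadoutWeights:
    """Trained readout ``w_out`` of shape (output_dim, n_units + 1); last column is the bias."""

    w_out: np.ndarray


def init_weights(config: ReservoirConfig) -> ReservoirWeights:
    """Generate the fixed random weight matrices for a reservoir.

    ``w_res`` is drawn standard normal and rescaled so its spectral radius
    (largest absolute eigenvalue) equals ``config.spectral_radius``.  ``w_in``
    is fully dense; each entry is +/- ``input_scaling`` with equal probability
    (or uniform in [-input_scaling, input_scaling] with ``win_dist="uniform"``).

    A degenerate draw whose spectral radius is numerically zero is resampled
    with an incremented seed (a warning is logged).
    """
    seed = config.seed
    for _ in range(100):
        rng = np.random.default_rng(seed)
        w_res = rng.standard_normal((config.n_units, config.n_units))
        if config.win_dist == "binary":
            w_in = config.input_scaling * rng.choice(
                [-1.0, 1.0], size=(config.n_units, config.input_dim)
            )
        else:
            w_in = config.input_scaling * rng.uniform(
                -1.0, 1.0, size=(config.n_units, config.input_dim)
            )
        rho = float(np.max(np.abs(np.linalg.eigvals(w_res))))
        if rho > 1e-12:
            w_res = w_res * (config.spectral_radius / rho)
            return ReservoirWeights(w_in=w_in, w_res=w_res)
        log.warning("degenerate recurrent draw (spectral radius ~ 0) for seed %d; resampling", seed)
        seed += 1
    raise RuntimeError("could not draw a non-degenerate recurrent matrix")


def run_reservoir(
    weights: ReservoirWeights, config: ReservoirConfig, inputs: np.ndarray
) -> np.ndarray:
    """Simulate the leaky-tanh state update over an input sequence.

    Parameters
    ----------
    inputs : array of shape (T, input_dim)
        One input vector per time step.

    Returns
    -------
    array of shape (T, n_units)
        States x(1..T) computed from the all-zero initial state.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2 or inputs.shape[1] != config.input_dim:
        raise ValueError(
            f"inputs must have shape (T, {config.input_dim}), got {inputs.shape}"
        )
    return run_reservoir_batch(weights, config, inputs[None, :, :])[0]


def run_reservoir_batch(
    weights: ReservoirWeights, config: ReservoirConfig, inputs: np.ndarray
) -> np.ndarray:
    """Simulate N equal-length sequences at once.

    ``inputs`` has shape (N, T, input_dim); returns (N, T, n_units).  All
    sequences start from the zero state.  Batching is exact: each sequence's
    trajectory is identical to a solo :func:`run_reservoir` run.
    """
    inputs = np.asarray(inputs, dtype=float)
    n_seq, n_steps, _ = inputs.shape
    alpha = config.leak_rate
    w_res_t = weights.w_res.T
    # project all inputs up front: (N, T, n_units)
    driven = inputs @ weights.w_in.T
    states = np.empty((n_seq, n_steps, config.n_units))
    x = np.zeros((n_seq, config.n_units))
    for t in range(n_steps):
        x = (1.0 - alpha) * x + alpha * np.tanh(x @ w_res_t + driven[:, t, :])
        states[:, t, :] = x
    return states


def _augment(states: np.ndarray) -> np.ndarray:
    """Append the constant-1 bias column to a (T, n_units) state matrix."""
    return np.hstack([states, np.ones((states.shape[0], 1))])


def train_readout(
    state_sets: list[np.ndarray],
    teacher_sets: list[np.ndarray],
    ridge: float = 0.0,
) -> ReadoutWeights:
    """Fit the linear readout by offline regression.

    All time steps of all sequences are concatenated; each state row is
    augmented with a constant-1 bias entry.  With ``ridge=0`` the solution is
    the Moore-Penrose pseudo-inverse least-squares fit (minimum-norm when the
    system is rank deficient); otherwise the ridge-regularised normal
    equations are solved.  The bias term is regularised along with the rest,
    which is immaterial at the ridge magnitudes in use here.
    """
    if len(state_sets) == 0:
        raise ValueError("empty training set")
    if len(state_sets) != len(teacher_sets):
        raise ValueError("state_sets and teacher_sets must be paired lists")
    for s, y in zip(state_sets, teacher_sets):
        if s.shape[0] != y.shape[0]:
            raise ValueError(
                f"state/teacher length mismatch: {s.shape[0]} vs {y.shape[0]}"
            )
    x = np.vstack([_augment(np.asarray(s, dtype=float)) for s in state_sets])
    y = np.vstack([np.asarray(t, dtype=float) for t in teacher_sets])
    if ridge == 0.0:
        w, *_ = np.linalg.lstsq(x, y, rcond=None)
    else:
        gram = x.T @ x + ridge * np.eye(x.shape[1])
        w = np.linalg.solve(gram, x.T @ y)
    return ReadoutWeights(w_out=w.T)


def apply_readout(readout: ReadoutWeights, states: np.ndarray) -> np.ndarray:
    """Apply the linear readout to a state trajectory.

    Returns y(t) for every time step of ``states`` (shape (T, output_dim)).
    The readout is purely linear, so intermediate rows are meaningful
    "anytime" estimates of the final answer given the input seen so far.
    """
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[1] != readout.w_out.shape[1] - 1:
        raise ValueError(
            f"states must have shape (T, {readout.w_out.shape[1] - 1}), got {states.shape}"
        )
    return _augment(states) @ readout.w_out.T


# ---------------------------------------------------------------------------
# Persistence: a zip archive holding the dense arrays (.npy) and a JSON
# metadata document.  Round-trips bitwise.
# ---------------------------------------------------------------------------

def save_model(
    path: str | Path,
    config: ReservoirConfig,
    weights: ReservoirWeights,
    readout: ReadoutWeights | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a model archive: weight matrices as .npy members plus meta.json."""
    path = Path(path)
    arrays = {"w_in": weights.w_in, "w_res": weights.w_res}
    if readout is not None:
        arrays["w_out"] = readout.w_out
    meta = {"config": asdict(config), "extra": metadata or {}}
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"{name}.npy", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=1, sort_keys=True))


def load_model(
    path: str | Path,
) -> tuple[ReservoirConfig, ReservoirWeights, ReadoutWeights | None, dict]:
    """Read a model archive written by :func:`save_model`."""
    with zipfile.ZipFile(Path(path)) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = {}
        for name in ("w_in", "w_res", "w_out"):
            if f"{name}.npy" in zf.namelist():
                arrays[name] = np.load(io.BytesIO(zf.read(f"{name}.npy")))
    config = ReservoirConfig(**meta["config"])
    weights = ReservoirWeights(w_in=arrays["w_in"], w_res=arrays["w_res"])
    readout = ReadoutWeights(w_out=arrays["w_out"]) if "w_out" in arrays else None
    return config, weights, readout, meta["extra"]
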